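"""DNA alignments as small integer matrices, with FASTA I/O and site-pattern
compression.

States are encoded 0..3 for A, C, G, T and 4 for gap/unknown.  Pattern
compression (unique columns + multiplicities) is what keeps likelihood
evaluation on concatenated alignments cheap: the Jukes-Cantor likelihood
depends on the data only through site-pattern counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "GAP", "BASES"]

BASES = "ACGT"
GAP = 4

_ENCODE = np.full(256, GAP, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.array(list(BASES + "-"), dtype="U1")


@dataclass
class Alignment:
    """A taxa x sites DNA matrix.

    ``boundaries`` records locus end columns after concatenation (cumulative),
    so per-locus provenance survives a concatenated analysis.
    """

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) uint8 in {0..4}
    boundaries: list[int] | None = None
    _patterns: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def subset(self, taxa) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.data[idx].copy())

    # -- site patterns -------------------------------------------------------

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their multiplicities.

        Returns ``(patterns, counts)`` with ``patterns`` of shape
        ``(n_taxa, n_patterns)``.  The uncompressed likelihood is identical by
        construction (sites are exchangeable under i.i.d. models).
        """
        if self._patterns is None:
            if self.n_taxa * np.log2(5) < 62:
                powers = (5 ** np.arange(self.n_taxa, dtype=np.int64))[:, None]
                codes = (self.data.astype(np.int64) * powers).sum(axis=0)
                _, first, counts = np.unique(
                    codes, return_index=True, return_counts=True
                )
                patterns = self.data[:, first]
            else:  # many taxa: fall back to column-wise unique
                patterns, counts = np.unique(self.data, axis=1, return_counts=True)
            self._patterns = (
                np.ascontiguousarray(patterns),
                counts.astype(np.float64),
            )
        return self._patterns

    # -- distances -----------------------------------------------------------

    def jc_distance_matrix(self) -> np.ndarray:
        """Pairwise Jukes-Cantor distances (expected substitutions/site).

        ``d = -(3/4) ln(1 - (4/3) p)`` with ``p`` the mismatch proportion over
        ungapped site pairs; saturated pairs (p >= 3/4) are capped just below
        saturation so downstream initializations stay finite.
        """
        pat, w = self.site_patterns()
        n = self.n_taxa
        D = np.zeros((n, n))
        valid_all = pat != GAP
        for i in range(n):
            for j in range(i + 1, n):
                ok = valid_all[i] & valid_all[j]
                tot = w[ok].sum()
                p = (w[ok & (pat[i] != pat[j])].sum() / tot) if tot else 0.0
                p = min(p, 0.74999)
                D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 / 3.0 * p)
        return D

    # -- I/O -----------------------------------------------------------------

    def to_fasta(self, path_or_handle) -> None:
        records = [
            SeqRecord(Seq("".join(_DECODE[row])), id=t, description="")
            for t, row in zip(self.taxa, self.data)
        ]
        SeqIO.write(records, path_or_handle, "fasta")

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(path_or_handle, "fasta"):
            taxa.append(rec.id)
            rows.append(_ENCODE[np.frombuffer(str(rec.seq).encode(), dtype=np.uint8)])
        if not taxa:
            raise ValueError("empty FASTA input")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        return cls(taxa, np.vstack(rows))

    @classmethod
    def from_dict(cls, seqs: dict) -> "Alignment":
        handle = io.StringIO(
            "".join(f">{k}\n{v}\n" for k, v in seqs.items())
        )
        return cls.from_fasta(handle)

    def to_phylip(self, path_or_handle) -> None:
        """Relaxed PHYLIP writer (label, two spaces, sequence)."""
        close = False
        if isinstance(path_or_handle, (str, bytes)):
            path_or_handle = open(path_or_handle, "w")
            close = True
        try:
            path_or_handle.write(f"{self.n_taxa} {self.n_sites}\n")
            for t, row in zip(self.taxa, self.data):
                path_or_handle.write(f"{t}  {''.join(_DECODE[row])}\n")
        finally:
            if close:
                path_or_handle.close()
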