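"""Site-specific frequency profiles from multiple sequence alignments.

Alignment columns are treated as independent samples of a site-specific
equilibrium distribution.  Because the sequences in a family are
phylogenetically related rather than independent draws, the column counts
are weighted with the position-based scheme of Henikoff & Henikoff before
normalisation.  Alignments below a minimum size (columns or sequences) are
rejected outright, and columns dominated by gaps are dropped, mirroring the
filters commonly applied to Pfam-scale profile estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import AA_ALPHABET, AA_INDEX

__all__ = [
    "Alignment",
    "AlignmentProfileSet",
    "read_alignment",
    "henikoff_weights",
    "site_profiles",
    "frequency_scatter",
]

GAP = "-"
MISSING = "X"
_VALID = set(AA_ALPHABET) | {GAP, MISSING}


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein alignment over the 20 amino acids, '-' and 'X'."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: rows differ in length")
        bad = set("".join(self.rows)) - _VALID
        if bad:
            raise ValueError(f"invalid residues in alignment: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def to_array(self) -> np.ndarray:
        """Integer matrix: amino acid index, -1 for gap/missing."""
        lut = np.full(128, -1, dtype=np.int8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        return lut[np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            self.n_sequences, self.n_columns)]

    def write(self, path, fmt: str = "fasta") -> None:
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows)]
        )
        AlignIO.write(msa, str(path), fmt)


def _normalise_residues(seq: str) -> str:
    out = seq.upper().replace(".", GAP)
    return "".join(c if c in _VALID else MISSING for c in out)


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or Stockholm alignment; unknown residues become 'X'."""
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    if len(msa) == 0:
        raise ValueError(f"{path}: empty alignment")
    return Alignment(
        ids=tuple(rec.id for rec in msa),
        rows=tuple(_normalise_residues(str(rec.seq)) for rec in msa),
    )


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Position-based sequence weights of Henikoff & Henikoff.

    In each column every residue receives weight 1/(r*s), where r is the
    number of distinct residues in the column and s the multiplicity of that
    residue; gaps and missing characters contribute nothing.  Per-sequence
    weights are the sums over columns, normalised to sum to 1.
    """
    X = aln.to_array()
    w = np.zeros(aln.n_sequences)
    any_residue = False
    for j in range(aln.n_columns):
        col = X[:, j]
        present = col >= 0
        if not present.any():
            continue
        any_residue = True
        vals, inv, counts = np.unique(col[present], return_inverse=True, return_counts=True)
        r = len(vals)
        w[present] += 1.0 / (r * counts[inv])
    if not any_residue:
        raise ValueError("degenerate alignment: every column is all-gap")
    return w / w.sum()


@dataclass(frozen=True)
class AlignmentProfileSet:
    """Per-column frequency profiles for the columns that survived filtering."""

    profiles: np.ndarray            # (n_kept, 20)
    weights: np.ndarray             # per-sequence weights used
    kept_columns: np.ndarray        # 0-based indices into the alignment
    meta: dict = field(default_factory=dict)
    rejection_reason: str | None = None

    @property
    def rejected(self) -> bool:
        return self.rejection_reason is not None

    @property
    def n_sites(self) -> int:
        return 0 if self.rejected else self.profiles.shape[0]


def site_profiles(
    aln: Alignment,
    weights=None,
    *,
    min_columns: int = 100,
    min_sequences: int = 100,
    max_gap_fraction: float = 0.5,
    pseudocount: float = 0.0,
) -> AlignmentProfileSet:
    """Weighted per-column amino acid frequencies with size and gap filters.

    Returns an empty set carrying a rejection reason when the alignment
    fails the size gates.  Columns whose weighted gap ('-' or 'X') fraction
    strictly exceeds ``max_gap_fraction`` are dropped.  An optional
    pseudocount is added to every amino acid before renormalisation.
    """
    if min_columns <= 0 or min_sequences <= 0:
        raise ValueError("size thresholds must be positive")
    if weights is None:
        weights = henikoff_weights(aln)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (aln.n_sequences,) or np.any(weights < 0):
        raise ValueError("weights must be a nonnegative per-sequence vector")
    weights = weights / weights.sum()

    meta = {
        "min_columns": min_columns,
        "min_sequences": min_sequences,
        "max_gap_fraction": max_gap_fraction,
        "pseudocount": pseudocount,
    }
    empty = np.zeros((0, 20))
    if aln.n_columns < min_columns:
        return AlignmentProfileSet(empty, weights, np.zeros(0, int), meta,
                                   rejection_reason="too few columns")
    if aln.n_sequences < min_sequences:
        return AlignmentProfileSet(empty, weights, np.zeros(0, int), meta,
                                   rejection_reason="too few sequences")

    X = aln.to_array()
    kept, rows = [], []
    for j in range(aln.n_columns):
        col = X[:, j]
        present = col >= 0
        gap_fraction = weights[~present].sum()
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        np.add.at(counts, col[present], weights[present])
        total = counts.sum()
        if total <= 0:
            continue
        p = counts / total
        if pseudocount > 0:
            p = p + pseudocount
            p = p / p.sum()
        kept.append(j)
        rows.append(p)
    return AlignmentProfileSet(
        profiles=np.asarray(rows, dtype=float).reshape(-1, 20),
        weights=weights,
        kept_columns=np.asarray(kept, dtype=int),
        meta=meta,
    )


@dataclass(frozen=True)
class FrequencyScatter:
    """Per-site (pi_X, pi_Y) frequency pairs and their Pearson correlation."""

    pair: tuple
    points: np.ndarray
    correlation: float


def frequency_scatter(profile_set: AlignmentProfileSet, aa_pair) -> FrequencyScatter:
    """Across-site scatter of the frequencies of two amino acids."""
    from scipy.stats import pearsonr

    x_aa, y_aa = aa_pair
    if x_aa == y_aa or x_aa not in AA_INDEX or y_aa not in AA_INDEX:
        raise ValueError(f"need two distinct amino acids, got {aa_pair!r}")
    if profile_set.n_sites < 3:
        raise ValueError("need at least 3 sites to compute a correlation")
    pts = profile_set.profiles[:, [AA_INDEX[x_aa], AA_INDEX[y_aa]]]
    r = pearsonr(pts[:, 0], pts[:, 1]).statistic
    return FrequencyScatter(pair=(x_aa, y_aa), points=pts, correlation=float(r))
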