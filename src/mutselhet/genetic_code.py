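"""Standard genetic code and codon-averaged amino acid mutation models.

Amino acid substitution processes built from nucleotide mutation inherit
structure from the genetic code: each amino acid X is encoded by ``d_X``
sense codons, and only pairs of amino acids connected by a single-nucleotide
codon change are directly exchangeable.  This module builds the codon space
of the standard nuclear code, a K80 (Kimura two-parameter) nucleotide
mutation model, and the codon-averaged amino-acid-level mutation rates
``v_XY`` together with the code/codon-bias weights ``lambda_X`` and the
symmetric part ``vS_XY = v_XY * lambda_X`` required for reversibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

#: Internal amino acid ordering: alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Amino acid ordering used by PAML-style matrix files.
PAML_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
NUCLEOTIDES = "ACGT"

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
#: Permutation taking a PAML-ordered 20-vector to alphabetical order.
PAML_TO_ALPHA = np.array([PAML_AA_ORDER.index(a) for a in AA_ALPHABET])

_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


class UnsupportedCodeError(ValueError):
    """Raised for genetic-code identifiers other than the standard code."""


@dataclass(frozen=True)
class GeneticCodeTable:
    """The sense-codon space of a genetic code.

    Attributes
    ----------
    codons : tuple of str
        The 61 sense codons, sorted alphabetically.
    codon_to_aa : dict
        Map codon -> one-letter amino acid.
    degeneracy : dict
        Map amino acid -> number of sense codons encoding it (``d_X``).
    """

    codons: tuple
    codon_to_aa: dict
    degeneracy: dict
    stop_codons: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.codons) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.codons)}")
        if sum(self.degeneracy.values()) != 61:
            raise ValueError("codon degeneracies must sum to 61")
        if set(self.degeneracy) != set(AA_ALPHABET):
            raise ValueError("degeneracy table must cover all 20 amino acids")

    @property
    def d(self) -> np.ndarray:
        """Degeneracy ``d_X`` as a 20-vector in alphabetical order."""
        return np.array([self.degeneracy[a] for a in AA_ALPHABET], dtype=float)

    def aa_index_of_codon(self) -> np.ndarray:
        """Amino acid index (alphabetical) for each sense codon."""
        return np.array([AA_INDEX[self.codon_to_aa[c]] for c in self.codons])


def build_genetic_code(code_id: str = "standard") -> GeneticCodeTable:
    """Build the codon table for the standard nuclear genetic code.

    Parameters
    ----------
    code_id : str
        Only ``"standard"`` is supported.
    """
    if code_id != "standard":
        raise UnsupportedCodeError(f"unsupported genetic code: {code_id!r}")
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = {c: aa for c, aa in table.forward_table.items() if set(c) <= set(NUCLEOTIDES)}
    codons = tuple(sorted(codon_to_aa))
    degeneracy = {a: 0 for a in AA_ALPHABET}
    for aa in codon_to_aa.values():
        degeneracy[aa] += 1
    return GeneticCodeTable(
        codons=codons,
        codon_to_aa=codon_to_aa,
        degeneracy=degeneracy,
        stop_codons=frozenset(table.stop_codons),
    )


def k80_nucleotide_rates(kappa: float) -> dict:
    """Per-pair nucleotide exchange rates under the K80 model.

    Transversions have rate 1 (this normalisation defines the neutral time
    unit throughout the package); transitions (A<->G, C<->T) have rate
    ``kappa``.  Returns a dict keyed by ordered nucleotide pairs.
    """
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    rates = {}
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            if a == b:
                continue
            rates[(a, b)] = float(kappa) if frozenset((a, b)) in _TRANSITIONS else 1.0
    return rates


@dataclass(frozen=True)
class MutationModel:
    """Codon-averaged amino-acid-level mutation model.

    ``v[X, Y]`` is the rate of mutations producing amino acid Y in a
    background of X (zero unless some codon of X is a single-nucleotide
    neighbour of a codon of Y); ``lam`` are the code/codon-usage weights
    (``d_X/61`` under uniform usage) and ``vS = v * lam[:, None]`` is the
    symmetric flux part satisfying ``v_XY lam_X = v_YX lam_Y``.
    """

    v: np.ndarray
    lam: np.ndarray
    vS: np.ndarray
    kappa: float | None = None

    def __post_init__(self):
        if self.v.shape != (20, 20) or self.vS.shape != (20, 20) or self.lam.shape != (20,):
            raise ValueError("mutation model arrays have wrong shape")
        if np.any(self.lam <= 0):
            raise ValueError("lambda weights must be positive")

    @property
    def single_step_mask(self) -> np.ndarray:
        """Boolean mask of ordered amino acid pairs connected by one nucleotide change."""
        mask = self.v > 0
        np.fill_diagonal(mask, False)
        return mask


def codon_averaged_mutation(
    code: GeneticCodeTable,
    nuc_rates: dict,
    codon_weights=None,
) -> MutationModel:
    """Average a nucleotide mutation process over codons within amino acids.

    With uniform codon weights (the default) this is the plain average over
    the codons of each amino acid, and ``lambda_X = d_X / 61``.  Nonuniform
    weights are interpreted as a stationary codon-usage distribution; the
    codon-level rates are then biased as ``mu_w(c, c') = mu(c, c') *
    sqrt(w_c' / w_c)`` so that the codon process is reversible with respect
    to the weights, which keeps the amino-acid-level reversibility identity
    ``v_XY lambda_X = v_YX lambda_Y`` exact for arbitrary positive weights.
    """
    n = len(code.codons)
    if codon_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(codon_weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"codon weights must have length {n}")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("codon weights must be positive and finite")
        w = w / w.sum()

    aa_idx = code.aa_index_of_codon()
    lam = np.zeros(20)
    np.add.at(lam, aa_idx, w)

    codon_pos = {c: i for i, c in enumerate(code.codons)}
    flux = np.zeros((20, 20))  # symmetric codon flux aggregated to amino acids
    for i, c in enumerate(code.codons):
        X = aa_idx[i]
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == c[pos]:
                    continue
                c2 = c[: pos] + nt + c[pos + 1 :]
                j = codon_pos.get(c2)
                if j is None:  # stop codon
                    continue
                Y = aa_idx[j]
                if Y == X:
                    continue
                flux[X, Y] += np.sqrt(w[i] * w[j]) * nuc_rates[(c[pos], nt)]
    flux = (flux + flux.T) / 2.0  # symmetric up to float noise; make it exact
    v = flux / lam[:, None]
    np.fill_diagonal(v, 0.0)
    vS = flux
    kappa = None
    if (NUCLEOTIDES[0], NUCLEOTIDES[2]) in nuc_rates:  # (A, G) transition
        kappa = nuc_rates[("A", "G")] / nuc_rates[("A", "C")]
    return MutationModel(v=v, lam=lam, vS=vS, kappa=kappa)


def codon_averaged_k80(kappa: float = 2.0, codon_weights=None) -> MutationModel:
    """Convenience constructor: standard code + K80 nucleotide model."""
    code = build_genetic_code("standard")
    return codon_averaged_mutation(code, k80_nucleotide_rates(kappa), codon_weights)
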