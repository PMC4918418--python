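"""Synthetic inputs: heterogeneous site profiles, alignments, contact maps.

Real profile databases mix sites with very different amino acid
propensities (hydrophobic cores, charged surfaces, catalytic residues...),
which induces physicochemically structured covariance between the
frequencies of different amino acids across sites.  The profile generator
emulates this with a small set of propensity classes (by default grouped by
physicochemistry) and Dirichlet sampling around each class centre.  The
alignment generator evolves sequences from those profiles down a star or
balanced tree under the per-site F81-style process, producing the
phylogenetic redundancy real families have.  The structure generator makes
random native/decoy contact maps of equal contact count for the stability
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .alignments import Alignment
from .genetic_code import AA_ALPHABET, AA_INDEX, MutationModel
from .mutsel import f81_approximation
from .stability import ContactStructure

__all__ = [
    "ProfileGeneratorConfig",
    "DEFAULT_CLASSES",
    "generate_profiles",
    "evolve_alignment",
    "generate_structure",
]

#: Default propensity classes, grouped by physicochemistry: aliphatic,
#: aromatic, polar, positively charged, negatively charged, small/special.
DEFAULT_CLASSES = ("AILMV", "FWY", "NQST", "HKR", "DE", "CGP")

#: Residue volumes (A^3, Zamyatnin) used by the similarity kernel.
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


def physicochemical_features() -> np.ndarray:
    """Standardised (hydropathy, volume, charge) feature vectors per amino acid."""
    from Bio.SeqUtils.ProtParamData import kd

    cols = []
    for table in (kd, _VOLUME, {a: _CHARGE.get(a, 0.0) for a in AA_ALPHABET}):
        x = np.array([table[a] for a in AA_ALPHABET], dtype=float)
        cols.append((x - x.mean()) / x.std())
    return np.stack(cols, axis=1)


def similarity_class_centres(tau: float = 1.0, epsilon: float = 1e-3) -> np.ndarray:
    """Graded propensity classes anchored at each of the 20 amino acids.

    Class centre k puts mass on amino acids in proportion to a Gaussian
    kernel in physicochemical feature space (hydropathy, volume, charge)
    around anchor residue k, with bandwidth ``tau``.  Sites drawn from these
    classes carry the smoothly graded across-site frequency covariance that
    empirical profile databases show, rather than hard block structure.
    """
    if tau <= 0:
        raise ValueError("kernel bandwidth tau must be positive")
    F = physicochemical_features()
    d2 = ((F[:, None, :] - F[None, :, :]) ** 2).sum(axis=-1)
    centres = np.exp(-d2 / (2.0 * tau**2)) + epsilon
    return centres / centres.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ProfileGeneratorConfig:
    """Settings for the heterogeneous site-profile sampler.

    Classes may be given as amino acid subset strings (members share the
    class mass uniformly) or as explicit 20-vector concentration centres.
    ``concentration`` scales the Dirichlet sharpness around each centre;
    ``epsilon`` is the base mass every amino acid keeps so downstream
    log-frequency rates stay finite.
    """

    n_sites: int
    classes: tuple = DEFAULT_CLASSES
    class_weights: tuple | None = None
    concentration: float = 50.0
    epsilon: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if len(self.classes) == 0:
            raise ValueError("need at least one profile class")
        if self.concentration <= 0 or self.epsilon <= 0:
            raise ValueError("concentration and epsilon must be positive")

    def class_centres(self) -> np.ndarray:
        centres = []
        for cls in self.classes:
            if isinstance(cls, str):
                c = np.full(20, self.epsilon)
                for a in cls:
                    c[AA_INDEX[a]] = 1.0 / len(cls)
            else:
                c = np.asarray(cls, dtype=float)
                if c.shape != (20,) or np.any(c <= 0):
                    raise ValueError("class centres must be positive 20-vectors")
            centres.append(c / c.sum())
        return np.asarray(centres)


def generate_profiles(config: ProfileGeneratorConfig):
    """Draw site profiles from a mixture of Dirichlet propensity classes.

    Returns ``(profiles, labels)``: an (n_sites, 20) matrix and the true
    class index of each site, for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    centres = config.class_centres()
    k = len(centres)
    if config.class_weights is None:
        weights = np.full(k, 1.0 / k)
    else:
        weights = np.asarray(config.class_weights, dtype=float)
        if weights.shape != (k,) or np.any(weights < 0):
            raise ValueError("class weights must be nonnegative, one per class")
        weights = weights / weights.sum()
    labels = rng.choice(k, size=config.n_sites, p=weights)
    profiles = np.empty((config.n_sites, 20))
    for i, lab in enumerate(labels):
        profiles[i] = rng.dirichlet(config.concentration * centres[lab])
    # keep every amino acid strictly representable
    profiles = profiles + config.epsilon / 20.0
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles, labels


def evolve_alignment(
    profiles,
    n_sequences: int,
    branch_length: float,
    tree_shape: str = "star",
    mutation: MutationModel | None = None,
    seed: int | None = None,
) -> Alignment:
    """Evolve an alignment whose per-site stationary law is the given profiles.

    Each site evolves independently under Q_L,XY = vS_XY pi_L,Y (the
    site-specific F81-style reduction of the mutation-selection process),
    normalised to one expected substitution per unit time, so
    ``branch_length`` is in expected substitutions per site.  The root state
    is drawn from the site profile; descendants are sampled from the matrix
    exponential along each branch of a star or balanced binary tree.
    """
    if mutation is None:
        from .genetic_code import codon_averaged_k80

        mutation = codon_averaged_k80()
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if branch_length < 0:
        raise ValueError("branch length must be nonnegative")
    if tree_shape not in ("star", "balanced"):
        raise ValueError(f"unknown tree shape {tree_shape!r}")
    P = np.asarray(profiles, dtype=float)
    rng = np.random.default_rng(seed)
    n_sites = P.shape[0]

    seqs = np.empty((n_sequences, n_sites), dtype=int)
    for L in range(n_sites):
        pi = P[L]
        rm = f81_approximation(pi, mutation, pseudocount=1e-12)
        rate = rm.average_rate()
        Q = rm.Q / rate if rate > 0 else rm.Q
        root = rng.choice(20, p=pi)
        if branch_length == 0:
            seqs[:, L] = root
            continue
        T = expm(Q * branch_length)
        T = np.clip(T, 0, None)
        T /= T.sum(axis=1, keepdims=True)
        if tree_shape == "star":
            seqs[:, L] = rng.choice(20, size=n_sequences, p=T[root])
        else:
            depth = int(np.ceil(np.log2(n_sequences)))
            states = [root]
            for _ in range(depth):
                states = [rng.choice(20, p=T[s]) for s in states for _ in range(2)]
            seqs[:, L] = states[:n_sequences]

    rows = tuple("".join(AA_ALPHABET[i] for i in seq) for seq in seqs)
    ids = tuple(f"seq{i + 1}" for i in range(n_sequences))
    return Alignment(ids=ids, rows=rows)


def generate_structure(
    n_residues: int,
    contact_density: float = 2.0,
    n_decoys: int = 55,
    seed: int | None = None,
):
    """Random native and decoy contact maps with identical contact counts.

    ``contact_density`` is the mean number of contacts per residue; the
    total contact count is ``round(contact_density * n_residues / 2)`` pairs
    drawn without replacement from all pairs with |i - j| >= 2.  Decoys are
    resampled until distinct from the native map.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if contact_density < 0:
        raise ValueError("contact density must be nonnegative")
    rng = np.random.default_rng(seed)
    eligible = np.array(
        [(i, j) for i in range(n_residues) for j in range(i + 2, n_residues)], dtype=int
    )
    n_contacts = int(round(contact_density * n_residues / 2.0))
    if n_contacts > len(eligible):
        raise ValueError(
            f"cannot place {n_contacts} contacts among {len(eligible)} eligible pairs"
        )

    def sample():
        idx = rng.choice(len(eligible), size=n_contacts, replace=False)
        return ContactStructure(n_residues=n_residues, contacts=eligible[idx])

    native = sample()
    decoys = []
    native_key = native.contact_key()
    while len(decoys) < n_decoys:
        d = sample()
        if n_contacts and d.contact_key() == native_key:
            continue
        decoys.append(d)
    return native, decoys
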