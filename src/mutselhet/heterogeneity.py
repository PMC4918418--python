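"""Site-averaged substitution models and heterogeneity statistics.

When a substitution process is site-specific but an observer averages both
the substitution fluxes and the equilibrium frequencies over sites (as any
single-matrix model implicitly does), the averaged rate picks up a
covariance correction:

    Qhat_XY = vS_XY (1 + Cov(pi_L,X, pi_L,Y) / (pihat_X pihat_Y)) pihat_Y

with ``pihat_X`` the across-site mean frequency.  The corresponding
symmetric exchangeability is the bracketed factor (times ``vS``); computed
from alignment-derived site profiles it can be compared directly with the
exchangeabilities of standard empirical matrices.

Two scalar summaries of a single profile quantify the strength of
selection at a site: the effective number of acceptable amino acids

    Omega = exp(-sum_X pi_X ln pi_X)

(the exponential of the sequence entropy, between 1 and 20), and the
substitution rate relative to the neutral, mutation-limited rate

    omega = sum_<XY> pi_X Q_XY / sum_<XY> lambda_X v_XY

with the sums running over single-nucleotide-accessible amino acid pairs.
A neutral profile (pi = lambda) gives omega = 1 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genetic_code import MutationModel
from .mutsel import SiteRateMatrix, as_profile_array, fixation_factor

logger = logging.getLogger(__name__)

__all__ = [
    "AveragedModel",
    "OmegaPoint",
    "average_model",
    "exchangeability_from_profiles",
    "normalize_exchangeability",
    "effective_n_amino_acids",
    "relative_rate",
    "relative_rates",
    "mixture_statistics",
    "normalize_rate_matrix",
]


def _profile_matrix(profiles) -> np.ndarray:
    """Stack profiles (SiteProfiles or arrays) into an (n_sites, 20) matrix."""
    rows = [as_profile_array(p) for p in profiles] if not isinstance(profiles, np.ndarray) else list(profiles)
    P = np.asarray(rows, dtype=float)
    if P.ndim != 2 or P.shape[1] != 20:
        raise ValueError("profiles must be an (n_sites, 20) collection")
    return P


def _mean_and_cov(P: np.ndarray):
    """Across-site mean and population covariance (divisor n) of frequencies."""
    if P.shape[0] < 2:
        raise ValueError("need at least 2 site profiles to estimate covariances")
    pihat = P.mean(axis=0)
    D = P - pihat
    cov = D.T @ D / P.shape[0]
    return pihat, (cov + cov.T) / 2.0


@dataclass(frozen=True)
class AveragedModel:
    """Result of averaging a site-heterogeneous F81-style process over sites."""

    pihat: np.ndarray
    cov: np.ndarray
    Qhat: np.ndarray
    S: np.ndarray  # symmetric exchangeability, vS included


@dataclass
class OmegaPoint:
    """A point in the (Omega, omega) plane: breadth of acceptable amino acids
    versus substitution rate relative to neutral."""

    label: str
    omega_eff: float
    rate_ratio: float
    omega_eff_lo: float | None = None
    omega_eff_hi: float | None = None
    rate_ratio_lo: float | None = None
    rate_ratio_hi: float | None = None

    def __post_init__(self):
        if not (1.0 - 1e-9 <= self.omega_eff <= 20.0 + 1e-9):
            raise ValueError(f"Omega must lie in [1, 20], got {self.omega_eff}")
        if self.rate_ratio < 0:
            raise ValueError("relative rate must be nonnegative")


def average_model(profiles, mutation: MutationModel) -> AveragedModel:
    """Average the per-site process Q_L,XY = vS_XY pi_L,Y over sites.

    Uses the covariance form; identical to brute-force flux averaging
    <pi_L,X Q_L,XY> / <pi_L,X>.  Entries driven negative by extreme
    anticorrelation (Cov < -pihat_X pihat_Y) are floored at zero.
    """
    P = _profile_matrix(profiles)
    pihat, cov = _mean_and_cov(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = 1.0 + cov / np.outer(pihat, pihat)
    S = mutation.vS * corr
    Qhat = S * pihat[None, :]
    off = ~np.eye(20, dtype=bool)
    n_neg = int(np.sum(Qhat[off] < 0))
    if n_neg:
        logger.warning("flooring %d negative averaged-rate entries at 0", n_neg)
        Qhat = np.where((Qhat < 0) & off, 0.0, Qhat)
        S = np.where((S < 0) & off, 0.0, S)
    np.fill_diagonal(Qhat, 0.0)
    np.fill_diagonal(Qhat, -Qhat.sum(axis=1))
    return AveragedModel(pihat=pihat, cov=cov, Qhat=Qhat, S=(S + S.T) / 2.0)


def exchangeability_from_profiles(profiles, *, normalize: bool = True) -> np.ndarray:
    """Exchangeabilities implied by across-site frequency covariances alone.

    Computes ``S_XY = 1 + Cov(pi_X, pi_Y) / (pihat_X pihat_Y)`` (the mutation
    term deliberately omitted so the matrix reflects selection only), floored
    at zero, with the diagonal set to NaN.  Amino acids with zero mean
    frequency yield NaN rows/columns rather than infinities.  If
    ``normalize``, the matrix is rescaled so the rate matrix ``S_XY pihat_Y``
    has average rate 1 at ``pihat``.
    """
    P = _profile_matrix(profiles)
    pihat, cov = _mean_and_cov(P)
    denom = np.outer(pihat, pihat)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = 1.0 + cov / denom
    S[denom == 0] = np.nan
    S = np.where(S < 0, 0.0, S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, np.nan)
    if normalize:
        S = normalize_exchangeability(S, pihat)
    return S


def normalize_exchangeability(S: np.ndarray, pi) -> np.ndarray:
    """Scale exchangeabilities so that Q_XY = S_XY pi_Y has average rate 1."""
    pi = as_profile_array(pi)
    off = ~np.eye(20, dtype=bool)
    contrib = np.where(np.isnan(S), 0.0, S) * np.outer(pi, pi)
    total = contrib[off].sum()
    if total <= 0:
        raise ValueError("degenerate exchangeability matrix: zero total rate")
    return S / total


def effective_n_amino_acids(pi) -> float:
    """Effective number of acceptable amino acids, exp of the sequence entropy."""
    pi = as_profile_array(pi)
    p = pi[pi > 0]
    return float(np.exp(-np.sum(p * np.log(p))))


def relative_rates(profiles, mutation: MutationModel, *, pseudocount=1e-10) -> np.ndarray:
    """Vectorised substitution rate relative to neutral for a batch of profiles.

    For each profile, numerator = total stationary flux pi_X Q_XY over
    single-step amino acid pairs with Q from the frequency form of the
    mutation-selection rates; denominator = the same flux under the neutral
    profile lambda, i.e. sum lambda_X v_XY.  Ordered-pair sums are used in
    both, so the unordered/ordered convention cancels.
    """
    P = _profile_matrix(profiles)
    if np.any(P <= 0):
        if pseudocount is None or pseudocount <= 0:
            raise ValueError("profiles contain zeros; need a positive pseudocount")
        P = P + pseudocount
        P = P / P.sum(axis=1, keepdims=True)
    lp = np.log(P) - np.log(mutation.lam)[None, :]
    t = lp[:, None, :] - lp[:, :, None]  # (n, X, Y)
    mask = mutation.single_step_mask
    Q = mutation.v[None, :, :] * fixation_factor(t)
    num = (P[:, :, None] * Q * mask[None, :, :]).sum(axis=(1, 2))
    den = mutation.vS[mask].sum()
    return num / den


def relative_rate(pi, mutation: MutationModel, *, pseudocount=1e-10) -> float:
    """Substitution rate relative to the neutral rate for one profile."""
    return float(relative_rates([as_profile_array(pi)], mutation, pseudocount=pseudocount)[0])


def mixture_statistics(class_profiles, class_weights, mutation: MutationModel,
                       *, label: str = "mixture", pseudocount=1e-10) -> OmegaPoint:
    """Weight-averaged (Omega, omega) over the classes of a site mixture model."""
    P = _profile_matrix(class_profiles)
    w = np.asarray(class_weights, dtype=float)
    if w.shape != (P.shape[0],):
        raise ValueError("class weights must match the number of classes")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("class weights must be nonnegative and sum to 1")
    omegas = np.array([effective_n_amino_acids(p) for p in P])
    rates = relative_rates(P, mutation, pseudocount=pseudocount)
    return OmegaPoint(label=label, omega_eff=float(w @ omegas), rate_ratio=float(w @ rates))


def normalize_rate_matrix(rm: SiteRateMatrix) -> SiteRateMatrix:
    """Rescale a rate matrix to one expected substitution per unit time."""
    rate = rm.average_rate()
    if rate <= 1e-300:
        raise ValueError("degenerate rate matrix: zero average rate")
    return SiteRateMatrix(rm.Q / rate, rm.stationary)
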