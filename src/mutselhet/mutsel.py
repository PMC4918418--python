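"""Site-level mutation-selection substitution rates and equilibria.

The substitution rate from amino acid X to Y at a site is the mutation rate
times the (Kimura diffusion) relative fixation probability,

    Q_XY = v_XY * S / (1 - exp(-S)),    S = 4 Ne (m_Y - m_X),

where ``m_X`` is the marginal Malthusian fitness of the amino acid at that
site and ``Ne`` the effective population size.  The stationary distribution
is a Boltzmann-like weighting of the code factors,

    pi_X  proportional to  lambda_X exp(4 Ne m_X),

and the rates can equivalently be written purely in terms of the stationary
frequencies,

    Q_XY = v_XY * ln(lambda_X pi_Y / (lambda_Y pi_X))
                / (1 - lambda_Y pi_X / (lambda_X pi_Y)),

which is the form used when site profiles are estimated from data rather
than derived from an explicit fitness vector.  A first-order expansion of
the log gives the amino acid analogue of the Felsenstein 81 model,
``Q_XY ~= vS_XY pi_Y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import MutationModel

__all__ = [
    "SiteFitness",
    "SiteProfile",
    "SiteRateMatrix",
    "fixation_factor",
    "equilibrium_distribution",
    "rate_from_frequencies",
    "f81_approximation",
]


@dataclass(frozen=True)
class SiteFitness:
    """Marginal Malthusian fitnesses of the 20 amino acids at one site."""

    m: np.ndarray
    Ne: float

    def __post_init__(self):
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        if self.m.shape != (20,) or not np.all(np.isfinite(self.m)):
            raise ValueError("m must be a finite 20-vector")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")

    def scaled_selection(self) -> np.ndarray:
        """Population-scaled selection coefficients S_XY = 4 Ne (m_Y - m_X)."""
        return 4.0 * self.Ne * (self.m[None, :] - self.m[:, None])


@dataclass(frozen=True)
class SiteProfile:
    """Equilibrium amino acid frequencies at one site (or class, or instant)."""

    pi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        if self.pi.shape != (20,):
            raise ValueError("profile must be a 20-vector")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("profile entries must be >= 0 and sum to 1")


def as_profile_array(pi) -> np.ndarray:
    """Accept a SiteProfile or bare array; return a validated 20-vector."""
    if isinstance(pi, SiteProfile):
        return pi.pi
    return SiteProfile(np.asarray(pi, dtype=float)).pi


@dataclass(frozen=True)
class SiteRateMatrix:
    """A 20x20 instantaneous substitution rate matrix with its stationary profile."""

    Q: np.ndarray
    stationary: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "stationary", as_profile_array(self.stationary))
        off = self.Q[~np.eye(20, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10:
            raise ValueError("rate matrix rows must sum to zero")

    @property
    def flux(self) -> np.ndarray:
        """Stationary substitution flux Phi_XY = pi_X Q_XY."""
        return self.stationary[:, None] * self.Q

    def average_rate(self) -> float:
        """Expected substitutions per unit time at stationarity."""
        return float(-np.dot(self.stationary, np.diag(self.Q)))


def fixation_factor(scaled_S):
    """Relative fixation rate S / (1 - exp(-S)) of the Kimura diffusion.

    ``scaled_S`` is the population-scaled selection coefficient 4 Ne dm.
    Evaluates stably across the whole real line: equals 1 at S = 0, tends
    to S for strongly advantageous changes and to |S| exp(-|S|) for
    strongly deleterious ones.  Accepts scalars or arrays.
    """
    S = np.asarray(scaled_S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("scaled selection coefficient must be finite")
    out = np.empty_like(S)
    small = np.abs(S) < 1e-4
    # series of S / (1 - e^-S) around 0
    out[small] = 1.0 + S[small] / 2.0 + S[small] ** 2 / 12.0
    pos = (~small) & (S > 0)
    out[pos] = S[pos] / (-np.expm1(-S[pos]))
    neg = (~small) & (S < 0)
    out[neg] = S[neg] * np.exp(S[neg]) / np.expm1(S[neg])
    return out if out.ndim else float(out)


def equilibrium_distribution(fitness: SiteFitness, mutation: MutationModel) -> SiteProfile:
    """Stationary profile pi_X proportional to lambda_X exp(4 Ne m_X).

    Computed through max-shifted exponentials, so arbitrarily large scaled
    fitnesses never overflow.
    """
    x = 4.0 * fitness.Ne * fitness.m + np.log(mutation.lam)
    x -= x.max()
    p = np.exp(x)
    return SiteProfile(p / p.sum())


def _prepare_pi(pi, pseudocount):
    pi = as_profile_array(pi)
    if np.any(pi <= 0):
        if pseudocount is None or pseudocount <= 0:
            raise ValueError(
                "profile contains zero frequencies; pass a positive pseudocount to regularise"
            )
        pi = pi + pseudocount
        pi = pi / pi.sum()
    return pi

def _log_ratio(pi, lam):
    """t_XY = ln(lambda_X pi_Y / (lambda_Y pi_X)); equals 4Ne(m_Y - m_X) at equilibrium."""
    lp = np.log(pi) - np.log(lam)
    return lp[None, :] - lp[:, None]


def rate_from_frequencies(pi, mutation: MutationModel, *, pseudocount=None) -> SiteRateMatrix:
    """Substitution rates expressed through stationary frequencies.

    Algebraically identical to the fitness form: substituting the Boltzmann
    stationary profile makes the log-frequency ratio equal the scaled
    selection coefficient.  When the ratio is 1 the stable neutral limit
    ``Q_XY = v_XY`` is returned.  The result satisfies detailed balance with
    respect to ``pi`` by construction.
    """
    pi = _prepare_pi(pi, pseudocount)
    Q = mutation.v * fixation_factor(_log_ratio(pi, mutation.lam))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SiteRateMatrix(Q, pi)


def f81_approximation(pi, mutation: MutationModel, *, pseudocount=None) -> SiteRateMatrix:
    """First-order (ln x ~= x - 1) reduction: Q_XY = vS_XY pi_Y.

    An amino acid version of the Felsenstein 81 model with site-specific
    frequencies; exact in the limit pi -> lambda.
    """
    pi = _prepare_pi(pi, pseudocount)
    Q = mutation.vS * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SiteRateMatrix(Q, pi)
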