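"""Evolution of a codon sequence under selection for folding stability.

A protein is modelled as a native contact map plus an ensemble of decoy
folds; the energy of a sequence in any fold is a sum of pairwise contact
energies.  The free energy of the non-native state is estimated from the
decoy energy statistics by a Gaussian (random-energy) approximation for a
much larger ensemble of unfolded conformations, giving a folding free
energy dG for every sequence.  Fitness is the Boltzmann probability of
being folded,

    f = exp(-dG/kT) / (1 + exp(-dG/kT)),

and substitution dynamics follow a Gillespie algorithm over all
single-nucleotide codon changes, each accepted at the mutation rate times
the Kimura fixation factor of the population-scaled fitness difference
4 Ne * (ln f_mut - ln f_wt).  Because fitness couples every site through
the contact energies, the acceptability of an amino acid at one site drifts
as the rest of the protein evolves ("evolutionary Stokes shift"), producing
temporal as well as spatial rate heterogeneity; the simulation exposes the
instantaneous per-site equilibrium profiles, the effective number of
acceptable amino acids Omega_L(t) and the relative rate omega_L(t)
throughout the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .genetic_code import (
    AA_ALPHABET,
    AA_INDEX,
    GeneticCodeTable,
    MutationModel,
    NUCLEOTIDES,
    build_genetic_code,
    k80_nucleotide_rates,
)
from .heterogeneity import effective_n_amino_acids, relative_rates
from .mutsel import SiteProfile, fixation_factor

__all__ = [
    "ContactStructure",
    "StabilityModel",
    "Trajectory",
    "load_contact_potential",
    "contact_energy",
    "folding_free_energy",
    "fitness_from_dG",
    "scaled_unfolded_entropy",
    "simulate",
    "burn_in",
    "NotConvergedError",
    "instantaneous_site_profile",
    "sf_statistics",
    "SFStatistics",
    "stokes_shift",
    "StokesShiftResult",
]

#: log ensemble size of unfolded conformations used in the reference setup
#: (10^160 conformations for a 300-residue protein).
DEFAULT_LOG_N_UNFOLDED = 160.0 * np.log(10.0)


@dataclass(frozen=True)
class ContactStructure:
    """A set of unordered residue-residue contacts (|i - j| >= 2)."""

    n_residues: int
    contacts: np.ndarray  # (m, 2) with i < j

    def __post_init__(self):
        c = np.asarray(self.contacts, dtype=int).reshape(-1, 2)
        c = np.sort(c, axis=1)
        order = np.lexsort((c[:, 1], c[:, 0]))
        c = c[order]
        object.__setattr__(self, "contacts", c)
        if len(c) and (c.min() < 0 or c.max() >= self.n_residues):
            raise ValueError("contact indices out of range")
        if np.any(c[:, 1] - c[:, 0] < 2):
            raise ValueError("contacts must satisfy |i - j| >= 2")
        if len(c) != len({tuple(p) for p in c}):
            raise ValueError("duplicate contacts")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact_key(self) -> frozenset:
        return frozenset(map(tuple, self.contacts))


def load_contact_potential(path=None):
    """Load a 20x20 pairwise contact potential (kT units) from TSV.

    With no path, loads the bundled SYNTHETIC stand-in potential: a
    Miyazawa-Jernigan-style table constructed from the standardized Miyazawa
    one-body contact-energy scale, a charge-charge term and a frozen random
    pairwise coupling.  It reproduces the statistical character of a
    knowledge-based potential (hydrophobic residues favoured in contacts,
    like charges penalised, genuinely pairwise epistatic terms) but is not a
    published table.
    """
    if path is None:
        ref = resources.files("mutselhet.data") / "synthetic_contact_potential.tsv"
        with resources.as_file(ref) as p:
            return load_contact_potential(p)
    rows = {}
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts[-20:]
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    perm = [header.index(a) for a in AA_ALPHABET]
    E = np.array([[rows[a][j] for j in perm] for a in AA_ALPHABET])
    if np.max(np.abs(E - E.T)) > 1e-9:
        raise ValueError("contact potential must be symmetric")
    return (E + E.T) / 2.0


@dataclass(frozen=True)
class StabilityModel:
    """Contact potential + native fold + decoy ensemble + unfolded-state size."""

    potential: np.ndarray
    native: ContactStructure
    decoys: tuple
    log_n_unfolded: float = DEFAULT_LOG_N_UNFOLDED
    kT: float = 1.0

    def __post_init__(self):
        pot = np.asarray(self.potential, dtype=float)
        if pot.shape != (20, 20) or np.max(np.abs(pot - pot.T)) > 1e-9:
            raise ValueError("potential must be a symmetric 20x20 matrix")
        object.__setattr__(self, "potential", pot)
        object.__setattr__(self, "decoys", tuple(self.decoys))
        for d in self.decoys:
            if d.n_residues != self.native.n_residues:
                raise ValueError("decoys must share n_residues with the native fold")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_residues(self) -> int:
        return self.native.n_residues


def scaled_unfolded_entropy(n_residues: int, reference_n: int = 300) -> float:
    """Unfolded-ensemble log-size scaled linearly with chain length.

    The reference setup uses ln(10^160) for a 300-residue protein
    (~1.23 kT of conformational entropy per residue); reduced-scale
    simulations keep the per-residue entropy constant.
    """
    return DEFAULT_LOG_N_UNFOLDED * n_residues / reference_n


def _seq_to_idx(seq) -> np.ndarray:
    if isinstance(seq, str):
        try:
            return np.array([AA_INDEX[a] for a in seq])
        except KeyError as exc:
            raise ValueError(f"invalid amino acid {exc.args[0]!r}") from None
    return np.asarray(seq, dtype=int)


def contact_energy(seq, structure: ContactStructure, potential) -> float:
    """Sum of pairwise contact energies of a sequence threaded on a fold."""
    idx = _seq_to_idx(seq)
    if len(idx) != structure.n_residues:
        raise ValueError("sequence length does not match the structure")
    if structure.n_contacts == 0:
        return 0.0
    pot = np.asarray(potential, dtype=float)
    return float(pot[idx[structure.contacts[:, 0]], idx[structure.contacts[:, 1]]].sum())


def _alt_free_energy(decoy_energies: np.ndarray, log_n: float, kT: float) -> float:
    """Gaussian (random-energy) free energy of the non-native ensemble."""
    mu = decoy_energies.mean()
    var = decoy_energies.var()  # population variance over the decoy set
    return mu - kT * log_n - var / (2.0 * kT)


def folding_free_energy(seq, model: StabilityModel) -> float:
    """dG = E_native - G_alt, with G_alt estimated from the decoy ensemble."""
    if len(model.decoys) < 2:
        raise ValueError("need at least 2 decoys to estimate the energy spread")
    idx = _seq_to_idx(seq)
    e_nat = contact_energy(idx, model.native, model.potential)
    e_dec = np.array([contact_energy(idx, d, model.potential) for d in model.decoys])
    return e_nat - _alt_free_energy(e_dec, model.log_n_unfolded, model.kT)


def fitness_from_dG(dG, kT: float = 1.0):
    """Probability of being folded at equilibrium (saturates stably)."""
    from scipy.special import expit

    return expit(-np.asarray(dG, dtype=float) / kT)


def log_fitness_from_dG(dG, kT: float = 1.0):
    """ln f, computed without underflow for very unstable sequences."""
    return -np.logaddexp(0.0, np.asarray(dG, dtype=float) / kT)


# ---------------------------------------------------------------------------
# Fitness landscape machinery


class StabilityLandscape:
    """Efficient per-site fitness/profile evaluations for a StabilityModel."""

    def __init__(self, model: StabilityModel):
        self.model = model
        self.L = model.n_residues
        self.structures = (model.native,) + model.decoys
        self.edges = [s.contacts for s in self.structures]
        # adjacency lists per structure for single-site queries
        self.partners = []
        for s in self.structures:
            adj = [[] for _ in range(self.L)]
            for i, j in s.contacts:
                adj[i].append(j)
                adj[j].append(i)
            self.partners.append([np.asarray(a, dtype=int) for a in adj])

    def total_energies(self, aa: np.ndarray) -> np.ndarray:
        """Energy of the sequence in every structure (native first)."""
        pot = self.model.potential
        return np.array(
            [pot[aa[e[:, 0]], aa[e[:, 1]]].sum() if len(e) else 0.0 for e in self.edges]
        )

    def _site_energy_matrices(self, aa: np.ndarray, energies: np.ndarray):
        """cand[s][L, X]: total energy in structure s with site L mutated to X."""
        pot = self.model.potential
        out = np.empty((len(self.structures), self.L, 20))
        for s, e in enumerate(self.edges):
            G = np.zeros((self.L, 20))
            if len(e):
                np.add.at(G, e[:, 0], pot[:, aa[e[:, 1]]].T)
                np.add.at(G, e[:, 1], pot[:, aa[e[:, 0]]].T)
            cur = G[np.arange(self.L), aa]
            out[s] = energies[s] + G - cur[:, None]
        return out

    def _dG_from_cand(self, cand: np.ndarray) -> np.ndarray:
        kT = self.model.kT
        e_nat = cand[0]
        mu = cand[1:].mean(axis=0)
        var = cand[1:].var(axis=0)
        return e_nat - (mu - kT * self.model.log_n_unfolded - var / (2.0 * kT))

    def site_log_fitness(self, aa: np.ndarray, energies=None) -> np.ndarray:
        """ln f(sequence with site L mutated to X), an (L, 20) matrix."""
        if energies is None:
            energies = self.total_energies(aa)
        cand = self._site_energy_matrices(aa, energies)
        return log_fitness_from_dG(self._dG_from_cand(cand), self.model.kT)

    def site_log_fitness_one(self, aa: np.ndarray, site: int, energies=None) -> np.ndarray:
        """ln f over the 20 amino acids at one site, rest of sequence fixed."""
        if energies is None:
            energies = self.total_energies(aa)
        pot = self.model.potential
        cand = np.empty((len(self.structures), 20))
        for s, adj in enumerate(self.partners):
            p = adj[site]
            if len(p):
                g = pot[:, aa[p]].sum(axis=1)
                cand[s] = energies[s] + g - g[aa[site]]
            else:
                cand[s] = energies[s]
        return log_fitness_from_dG(self._dG_from_cand(cand[:, None, :])[0], self.model.kT)

    def delta_g(self, aa: np.ndarray) -> float:
        e = self.total_energies(aa)
        return float(e[0] - _alt_free_energy(e[1:], self.model.log_n_unfolded, self.model.kT))


def _profiles_from_log_fitness(log_f: np.ndarray, scaled_Ne: float, lam: np.ndarray) -> np.ndarray:
    """Boltzmann profiles pi_X prop. to lambda_X exp(4Ne m_X), row-wise."""
    x = scaled_Ne * log_f + np.log(lam)[None, :]
    x = x - x.max(axis=1, keepdims=True)
    p = np.exp(x)
    return p / p.sum(axis=1, keepdims=True)


def instantaneous_site_profile(seq, site: int, model: StabilityModel,
                               mutation: MutationModel, scaled_Ne: float) -> SiteProfile:
    """Instantaneous equilibrium profile at one site given the current background.

    For each amino acid X placed at ``site`` (the rest of the sequence
    fixed), the marginal Malthusian fitness is m_X = ln f; the profile is the
    Boltzmann equilibrium with the code factors lambda.
    """
    aa = _seq_to_idx(seq)
    land = StabilityLandscape(model)
    log_f = land.site_log_fitness_one(aa, site)
    return SiteProfile(_profiles_from_log_fitness(log_f[None, :], scaled_Ne, mutation.lam)[0])


# ---------------------------------------------------------------------------
# Gillespie simulation


@dataclass
class Trajectory:
    """Record of a stability-selection simulation run.

    Events are (time, site, from_codon, to_codon) with strictly increasing
    times; ``sample_*`` arrays hold the state sampled at fixed time
    intervals (instantaneous per-site profiles and the current dG).
    """

    start_codons: tuple
    event_times: np.ndarray
    event_sites: np.ndarray
    event_from: np.ndarray   # codon indices
    event_to: np.ndarray
    sample_times: np.ndarray
    sample_profiles: np.ndarray  # (n_samples, L, 20)
    sample_dG: np.ndarray
    duration: float
    rate_integral: float     # integral of the total substitution rate over the run
    config: dict = field(default_factory=dict)
    _codons: tuple = ()      # codon string list (cached from the code table)

    @property
    def n_substitutions(self) -> int:
        return len(self.event_times)

    @property
    def n_residues(self) -> int:
        return len(self.start_codons)

    def iter_events(self):
        for t, s, f, to in zip(self.event_times, self.event_sites, self.event_from, self.event_to):
            yield float(t), int(s), self._codons[f], self._codons[to]

    def codon_state_after(self, k: int) -> np.ndarray:
        """Codon-index state after the first k events (k=0: start state)."""
        lut = {c: i for i, c in enumerate(self._codons)}
        state = np.array([lut[c] for c in self.start_codons])
        for e in range(k):
            state[self.event_sites[e]] = self.event_to[e]
        return state


def _codon_tables(code: GeneticCodeTable, nuc_rates: dict):
    """Neighbour tables: for each codon, up to 9 single-nucleotide sense targets."""
    pos = {c: i for i, c in enumerate(code.codons)}
    n = len(code.codons)
    nb_codon = np.zeros((n, 9), dtype=int)
    nb_rate = np.zeros((n, 9))
    for i, c in enumerate(code.codons):
        k = 0
        for p in range(3):
            for nt in NUCLEOTIDES:
                if nt == c[p]:
                    continue
                j = pos.get(c[: p] + nt + c[p + 1 :])
                if j is None:
                    continue  # mutations to stop codons are excluded
                nb_codon[i, k] = j
                nb_rate[i, k] = nuc_rates[(c[p], nt)]
                k += 1
    return nb_codon, nb_rate


def simulate(
    start_codons,
    model: StabilityModel,
    mutation: MutationModel,
    scaled_Ne: float,
    duration: float | None = None,
    sample_interval: float = 0.1,
    seed: int | None = None,
    *,
    n_substitutions: int | None = None,
    kappa: float | None = None,
) -> Trajectory:
    """Gillespie simulation of codon-sequence evolution under stability selection.

    Every single-nucleotide change of every codon is a candidate event with
    rate = nucleotide mutation rate x fixation_factor(4Ne * (ln f_mut -
    ln f_wt)); mutations to stop codons are excluded.  Time advances by
    exponential waiting times based on the total rate; the realised event is
    drawn proportionally to the candidate rates.  The run stops at
    ``duration`` (model time) or after ``n_substitutions`` events, whichever
    is given (at least one is required).  The state (per-site instantaneous
    profiles, dG) is sampled every ``sample_interval`` time units.

    ``scaled_Ne`` is the single population-scaled selection parameter 4 Ne;
    setting it to 0 gives neutral evolution.  The nucleotide model is K80
    with ``kappa`` taken from ``mutation`` unless overridden.
    """
    if duration is None and n_substitutions is None:
        raise ValueError("give a duration and/or a substitution-count stop")
    if duration is not None and duration <= 0:
        raise ValueError("duration must be positive")
    kappa = kappa if kappa is not None else (mutation.kappa or 2.0)
    code = build_genetic_code("standard")
    nuc_rates = k80_nucleotide_rates(kappa)
    nb_codon, nb_rate = _codon_tables(code, nuc_rates)
    aa_of_codon = code.aa_index_of_codon()

    lut = {c: i for i, c in enumerate(code.codons)}
    try:
        state = np.array([lut[c] for c in start_codons])
    except KeyError as exc:
        raise ValueError(f"start codon {exc.args[0]!r} is not a sense codon") from None
    if len(state) != model.n_residues:
        raise ValueError("start sequence length does not match the model")

    land = StabilityLandscape(model)
    rng = np.random.default_rng(seed)
    L = len(state)
    site_idx = np.arange(L)

    times, sites, frm, to = [], [], [], []
    sample_times, sample_profiles, sample_dG = [], [], []
    t = 0.0
    next_sample = 0.0
    rate_integral = 0.0
    log_lam = np.log(mutation.lam)

    while True:
        aa = aa_of_codon[state]
        energies = land.total_energies(aa)
        dG = energies[0] - _alt_free_energy(energies[1:], model.log_n_unfolded, model.kT)
        if scaled_Ne != 0.0:
            log_f = land.site_log_fitness(aa, energies)
            m0 = log_f[site_idx, aa]
            S = scaled_Ne * (log_f - m0[:, None])
            fix = fixation_factor(S)
        else:
            log_f = np.zeros((L, 20))
            fix = np.ones((L, 20))

        cand_rates = nb_rate[state] * fix[site_idx[:, None], aa_of_codon[nb_codon[state]]]
        total = cand_rates.sum()
        assert total > 0, "total substitution rate vanished"
        dt = rng.exponential(1.0 / total)

        # emit samples falling strictly before the next event (or the horizon)
        horizon = t + dt if duration is None else min(t + dt, duration)
        while next_sample <= horizon + 1e-12:
            x = scaled_Ne * log_f + log_lam[None, :]
            x = x - x.max(axis=1, keepdims=True)
            p = np.exp(x)
            sample_profiles.append(p / p.sum(axis=1, keepdims=True))
            sample_times.append(next_sample)
            sample_dG.append(dG)
            next_sample += sample_interval

        if duration is not None and t + dt > duration:
            rate_integral += total * (duration - t)
            t = duration
            break
        rate_integral += total * dt
        t += dt

        flat = rng.choice(L * 9, p=(cand_rates / total).ravel())
        site, k = divmod(flat, 9)
        new_codon = nb_codon[state[site], k]
        times.append(t)
        sites.append(site)
        frm.append(state[site])
        to.append(new_codon)
        state[site] = new_codon
        if n_substitutions is not None and len(times) >= n_substitutions:
            break

    return Trajectory(
        start_codons=tuple(start_codons),
        event_times=np.asarray(times),
        event_sites=np.asarray(sites, dtype=int),
        event_from=np.asarray(frm, dtype=int),
        event_to=np.asarray(to, dtype=int),
        sample_times=np.asarray(sample_times),
        sample_profiles=np.asarray(sample_profiles).reshape(-1, L, 20),
        sample_dG=np.asarray(sample_dG),
        duration=t,
        rate_integral=rate_integral,
        config={
            "seed": seed,
            "scaled_Ne": scaled_Ne,
            "kappa": kappa,
            "sample_interval": sample_interval,
            "n_residues": L,
            "n_decoys": len(model.decoys),
            "log_n_unfolded": model.log_n_unfolded,
            "kT": model.kT,
        },
        _codons=code.codons,
    )


class NotConvergedError(RuntimeError):
    """The burn-in criterion was not reached within the trajectory."""


def burn_in(trajectory: Trajectory, criterion: str = "substitutions",
            *, factor: int = 10, alpha: float = 0.05) -> float:
    """Time after which the run is declared at drift-selection balance.

    ``substitutions`` (default): the time of substitution number
    ``factor * n_residues``.  ``trend``: the earliest sample time from which
    the remaining dG trace shows no significant linear trend (two-sided
    p > alpha); scanned in 5%-of-samples steps.
    """
    if criterion == "substitutions":
        needed = factor * trajectory.n_residues
        if trajectory.n_substitutions < needed:
            raise NotConvergedError(
                f"burn-in needs {needed} substitutions, trajectory has {trajectory.n_substitutions}"
            )
        return float(trajectory.event_times[needed - 1])
    if criterion == "trend":
        from scipy.stats import linregress

        ts, ys = trajectory.sample_times, trajectory.sample_dG
        n = len(ts)
        if n < 10:
            raise NotConvergedError("too few samples for a trend test")
        for start in range(0, n // 2 + 1, max(1, n // 20)):
            seg_t, seg_y = ts[start:], ys[start:]
            if np.ptp(seg_y) == 0:  # flat trace is trivially stationary
                return float(seg_t[0])
            res = linregress(seg_t, seg_y)
            if res.pvalue > alpha:
                return float(seg_t[0])
        raise NotConvergedError("dG trace still shows a significant trend")
    raise ValueError(f"unknown burn-in criterion {criterion!r}")


# ---------------------------------------------------------------------------
# Heterogeneity statistics of a trajectory


@dataclass(frozen=True)
class SFStatistics:
    """(Omega, omega) under three levels of averaging of one simulation.

    ``sf_*`` are per-sample per-site instantaneous values; ``sft_*`` come
    from the per-site time-averaged profiles; ``sfts_*`` from the single
    profile averaged over both time and sites.
    """

    sf_omega: np.ndarray        # (n_samples, L)
    sf_rate: np.ndarray
    sft_omega: np.ndarray       # (L,)
    sft_rate: np.ndarray
    sfts_omega: float
    sfts_rate: float
    sample_times: np.ndarray


def sf_statistics(trajectory: Trajectory, mutation: MutationModel,
                  *, burn_in_time: float = 0.0, pseudocount: float = 1e-10) -> SFStatistics:
    """Compute instantaneous, time-averaged and time-and-site-averaged statistics.

    Samples are equally spaced in time, so the time average of the profiles
    is dwell-weighted by construction.
    """
    keep = trajectory.sample_times >= burn_in_time
    if keep.sum() < 2:
        raise ValueError("need at least 2 post-burn-in samples")
    P = trajectory.sample_profiles[keep]          # (S, L, 20)
    S_, L, _ = P.shape

    flatP = P.reshape(-1, 20)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(flatP > 0, flatP * np.log(flatP), 0.0), axis=1)
    sf_omega = np.exp(ent).reshape(S_, L)
    sf_rate = relative_rates(flatP, mutation, pseudocount=pseudocount).reshape(S_, L)

    Pt = P.mean(axis=0)                            # (L, 20) time-averaged
    sft_omega = np.array([effective_n_amino_acids(p) for p in Pt])
    sft_rate = relative_rates(Pt, mutation, pseudocount=pseudocount)

    Pts = Pt.mean(axis=0)
    sfts_omega = effective_n_amino_acids(Pts)
    sfts_rate = float(relative_rates(Pts[None, :], mutation, pseudocount=pseudocount)[0])

    return SFStatistics(
        sf_omega=sf_omega, sf_rate=sf_rate,
        sft_omega=sft_omega, sft_rate=sft_rate,
        sfts_omega=sfts_omega, sfts_rate=sfts_rate,
        sample_times=trajectory.sample_times[keep],
    )


@dataclass(frozen=True)
class StokesShiftResult:
    """Propensity of newly fixed residues immediately after versus long after fixation."""

    freq_after: np.ndarray
    freq_later: np.ndarray
    n_pairs: int
    n_increased: int
    p_value: float


def stokes_shift(trajectory: Trajectory, model: StabilityModel, mutation: MutationModel,
                 scaled_Ne: float, *, lag: int = 50, burn_in_time: float = 0.0) -> StokesShiftResult:
    """Test whether a site's propensity for its new residue grows after fixation.

    For every post-burn-in substitution fixing a new amino acid X at site L,
    the instantaneous equilibrium frequency pi_L,X is evaluated immediately
    after the event and again ``lag`` amino-acid-changing substitutions
    later, restricted to events where X is still resident at L (the shift is
    a property of the protein adapting around a resident amino acid; the lag
    is counted in amino-acid replacements because synonymous events leave
    the fitness background unchanged).  A one-sided sign test gives the
    p-value for the frequencies increasing over the lag.
    """
    land = StabilityLandscape(model)
    code = build_genetic_code("standard")
    aa_of_codon = code.aa_index_of_codon()
    log_lam = np.log(mutation.lam)

    n_ev = trajectory.n_substitutions
    first = int(np.searchsorted(trajectory.event_times, burn_in_time))

    def profile_at(aa_state, energies, site):
        log_f = land.site_log_fitness_one(aa_state, site, energies)
        x = scaled_Ne * log_f + log_lam
        x -= x.max()
        p = np.exp(x)
        return p / p.sum()

    # replay the trajectory once, maintaining amino acid state + total energies
    aa = aa_of_codon[trajectory.codon_state_after(0)]
    energies = land.total_energies(aa)
    queries = {}   # origin replacement index -> (site, new amino acid)
    after = {}
    later = {}
    n_replacements = 0

    pot = model.potential
    for e in range(n_ev):
        site = trajectory.event_sites[e]
        new_aa = aa_of_codon[trajectory.event_to[e]]
        old_aa = aa[site]
        if new_aa == old_aa:
            aa[site] = new_aa
            continue
        for s, adj in enumerate(land.partners):
            p = adj[site]
            if len(p):
                energies[s] += pot[new_aa, aa[p]].sum() - pot[old_aa, aa[p]].sum()
        aa[site] = new_aa
        n_replacements += 1
        if e >= first:
            after[n_replacements] = profile_at(aa, energies, site)[new_aa]
            queries[n_replacements] = (site, new_aa)
        origin = n_replacements - lag
        if origin in queries:
            s_o, x_o = queries[origin]
            if aa[s_o] == x_o:  # residue still resident
                later[origin] = profile_at(aa, energies, s_o)[x_o]

    keys = sorted(set(after) & set(later))
    if len(keys) < 5:
        raise ValueError("too few resident substitution pairs for a sign test")
    fa = np.array([after[k] for k in keys])
    fl = np.array([later[k] for k in keys])
    diff = fl - fa
    nz = diff != 0
    n_inc = int(np.sum(diff[nz] > 0))
    from scipy.stats import binomtest

    p = binomtest(n_inc, int(nz.sum()), 0.5, alternative="greater").pvalue
    return StokesShiftResult(freq_after=fa, freq_later=fl, n_pairs=int(nz.sum()),
                             n_increased=n_inc, p_value=float(p))
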