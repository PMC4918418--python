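# Methods

## Mutation model

The nucleotide process is K80: transversions at rate 1, transitions at rate
κ (default 2).  Setting the transversion rate to 1 defines the package's
time unit, which makes "rate relative to neutral" well defined everywhere.
Amino-acid-level mutation rates are codon averages over the standard nuclear
code (61 sense codons; mutations to stop codons are excluded everywhere):

    v_XY = Σ_{c∈X} w_c Σ_{c'∈Y, |c−c'|=1} μ(c, c') / Σ_{c∈X} w_c

with uniform codon usage `w_c = 1/61` by default, so the code weights reduce
to `λ_X = d_X/61` with `d_X` the codon degeneracy.  `v_XY = 0` exactly for
pairs not connected by a single nucleotide change, and all pair statistics
(the relative rate ω, exchangeability comparisons) are restricted to
single-step-accessible pairs: a continuous-time single-nucleotide process
cannot make the others instantaneously.

Non-uniform codon usage is supported through a square-root parameterisation,
`μ_w(c, c') = μ(c, c')·√(w_{c'}/w_c)`, which makes the codon process
reversible with respect to `w` and therefore preserves the amino-acid-level
reversibility identity `v_XY λ_X = v_YX λ_Y` for arbitrary positive weights.
A naive weighted average would break that identity (the K80 moves are
symmetric, so codon-level detailed balance fails for non-uniform `w`); with
uniform weights the two definitions coincide.

Amino acids and nucleotides are ordered alphabetically by one-letter code in
all in-memory arrays; PAML-format files keep the PAML convention
(A R N D C Q E G H I L K M F P S T W Y V) for interchange.

## Site rates and equilibria

`fixation_factor(S) = S/(1 − e^{−S})` is evaluated with a series branch for
|S| < 1e−4 (the expression is 0/0 at neutrality) and exponent-shifted
branches elsewhere, so it is finite and monotone over the whole real line.
Equilibrium profiles use max-shifted exponentials and cannot overflow.
The frequency form of the rates,

    Q_XY = v_XY · ln(λ_X π_Y / (λ_Y π_X)) / (1 − λ_Y π_X / (λ_X π_Y)),

is algebraically the fixation form with the Boltzmann stationary profile
substituted; an oracle test checks entrywise agreement to 1e−9 over random
fitness landscapes.  Empirical profiles may contain zeros; a flag-controlled
pseudocount (default 1e−10 where a default is needed) is added and the
profile renormalised before taking logs.

The reduced model `Q_XY = v^S_XY π_Y` (an amino acid Felsenstein-81 with
site-specific frequencies) is **not** a pointwise approximation of the exact
rates — the log-linearisation step behind it treats λπ products of order
1/400 as if they were near 1 — and we make no such claim in tests.  Its role
is structural: it is the per-site model whose exact flux average produces
the covariance-corrected site-averaged rates below, and the process used to
evolve synthetic alignments.

## Site averaging and heterogeneity statistics

Given site profiles, the averaged rates are computed in covariance form,
`Q̂_XY = v^S_XY (1 + Cov_XY/(π̂_X π̂_Y)) π̂_Y`, with the **population**
covariance (divisor N): the average is an exact identity over the given
sites, not an inference.  A brute-force flux-averaging oracle pins the form
(including the `π̂_X π̂_Y` denominator) to 1e−10.  Entries driven negative by
extreme anticorrelation are floored at zero with a logged warning; rates
cannot be negative, and such values only arise as smoothing artifacts.
The covariance-only exchangeability `S_XY = 1 + Cov_XY/(π̂_X π̂_Y)` is
reported with the diagonal masked and, by default, normalised so the implied
rate matrix has one expected substitution per unit time at `π̂` — the same
normalisation applied to published matrices before comparison.

`Ω = exp(−Σ π ln π)` uses the convention 0·ln 0 = 0.  The relative rate

    ω = Σ_pairs π_X Q_XY / Σ_pairs λ_X v_XY

uses ordered-pair sums in both numerator and denominator over the
single-step pairs, so the ordered/unordered convention cancels; the
denominator is the stationary flux of the neutral process (`π = λ`,
`Q = v`), which makes ω(λ) = 1 exactly.  Mixture models report the
weight-averaged per-class Ω and ω.

## Alignment profiles

Sequence weights follow the position-based scheme of Henikoff & Henikoff:
within each column every residue receives 1/(r·s) (r = distinct residues,
s = multiplicity); gaps and ambiguous residues ('X', mapped from any
non-standard character) contribute nothing.  Alignments with fewer than 100
columns or 100 sequences (configurable) are rejected with an explicit
reason; columns whose weighted gap-or-missing fraction strictly exceeds 0.5
are dropped.  Per-column frequencies are weighted counts over the 20 amino
acids, optionally pseudocounted for downstream log-frequency rates.

## Stability model and simulator

A sequence threaded on a fold scores `E = Σ_{(i,j)∈contacts} e(A_i, A_j)`.
The bundled potential (`synthetic_contact_potential.tsv`) is a **synthetic**
stand-in for a knowledge-based pair potential, constructed as
`−0.6(h_X + h_Y) + 0.6 q_X q_Y + G_XY − 2` in kT units, where h is the
standardized Miyazawa one-body contact-energy scale, q is net charge, and G
is a frozen random symmetric coupling (sd 0.5).  The random coupling is
essential: a purely additive potential has no epistasis and therefore no
Stokes shift.  Any symmetric 20×20 table can be supplied instead.

The non-native free energy is a Gaussian (random-energy) estimate from the
decoy ensemble: with decoy energy mean μ_d and variance σ_d² for the current
sequence,

    ΔG = E_native − μ_d + σ_d²/(2kT) + kT·ln N_unfolded.

`ln N_unfolded` defaults to ln(10^160) — the reference unfolded-ensemble
size for a 300-residue protein — and `scaled_unfolded_entropy(n)` scales it
linearly in chain length (~1.23 kT of conformational entropy per residue)
for reduced chains.  Fitness is the folding probability
`f = 1/(1 + e^{ΔG/kT})` and the Malthusian fitness entering the fixation
factor is `m = ln f`.  Population size enters only as the single scalar
4N_e.

Dynamics are exact Gillespie: every single-nucleotide change of every codon
is a candidate with rate = nucleotide rate × fixation factor; waiting times
are exponential in the total rate; the realised event is drawn
proportionally.  The state (per-site instantaneous equilibrium profiles,
ΔG) is sampled at fixed time intervals rather than at every event, for cost
control; equal spacing makes the time average of sampled profiles
dwell-weighted by construction.  Burn-in is declared after 10·n_residues
substitutions by default, or by the absence of a significant linear trend in
the sampled ΔG trace (two-sided regression p > 0.05, scanned from the start
in 5% steps); failure to meet either criterion raises an explicit
not-converged error.

**Selection scaling.**  The effective strength 4N_e·Δln f is the one
simulator parameter with no published value.  We calibrate 4N_e = 30 for
reduced-scale runs (50 residues, 10 decoys, contact density 2 per residue):
at that value the run equilibrates at marginal stability and the realised
statistics sit in the biologically plausible band (instantaneous ω of order
0.01–0.1, instantaneous Ω of order 1–3), while much larger values freeze the
amino acid state entirely (realised nonsynonymous rates below 1e−4 of
neutral) and make temporal statistics unobservable at feasible run lengths.
The parameter is a plain argument; nothing depends on the default.

**SF / SF-T / SF-TS.**  From post-burn-in samples: SF is the per-sample
per-site (Ω, ω) of the instantaneous profiles; SF-T applies (Ω, ω) to each
site's time-averaged profile; SF-TS to the single site-and-time-averaged
profile.  Entropy concavity forces mean SF Ω ≤ SF-T Ω ≤ SF-TS Ω, with strict
gaps whenever temporal/spatial heterogeneity is present.

**Stokes shift.**  For each post-burn-in amino acid replacement, the site's
instantaneous equilibrium frequency for the new residue is compared
immediately after fixation and after a lag counted in amino-acid-changing
substitutions (synonymous events leave the fitness background bit-identical,
so a raw event lag measures nothing under strong selection), restricted to
replacements whose residue is still resident at the later time — the shift
is a statement about the protein adapting around a resident amino acid.
A one-sided sign test summarises the direction.

## Synthetic data

Site profiles are drawn from Dirichlet distributions around class centres
(concentration 50 by default; every amino acid keeps base mass ε = 1e−3 so
log-frequency rates stay finite).  Two class constructions are provided:
six hard physicochemical subsets (aliphatic/aromatic/polar/basic/acidic/
small–special), useful for sign and recovery tests with known block
structure, and twenty graded classes anchored at each amino acid through a
Gaussian kernel (bandwidth τ = 1.0) in standardized (hydropathy, volume,
charge) space.  The kernel classes are the realistic default for
exchangeability work: empirical site profiles carry smoothly graded
covariance between physicochemically similar residues, and hard blocks
understate it.  The resulting rank correlations with the bundled empirical
matrices are insensitive to τ over [0.7, 1.5] and to the concentration over
[20, 50].

Alignments are evolved per site under the F81-style per-site process
(normalised to one expected substitution per unit time, so branch lengths
are in substitutions per site) down a star or balanced binary tree, sampling
endpoint states from the matrix exponential; the root is drawn from the site
profile, so the per-site stationary law is the input profile.  Gaps are not
simulated.  Contact structures are uniform random draws of
`round(density·n/2)` pairs with |i−j| ≥ 2 (the standard contact-map
convention excluding chain neighbours); decoys share the native's contact
count and are resampled until distinct from it.  Random contact maps lack
the core/surface organisation of real folds; spatial heterogeneity in the
simulator comes from the degree distribution alone, so passing tests
demonstrate the averaging and Stokes-shift phenomenology, not the
site-by-site statistics of any real protein.

## What the synthetic data do and do not show

The generators reproduce the structural features the analyses rely on —
heterogeneous, physicochemically correlated site profiles; phylogenetic
redundancy; a rugged but foldable energy landscape — but not database
composition biases, indels, functional (as opposed to stability) selection,
or real fold geometry.  Quantities that depend only on internal consistency
(rate-form equivalence, averaging identities, normalisations) transfer to
real data directly; quantities reported from synthetic inputs
(correlation magnitudes, SF point positions) are qualitative
reproductions of the phenomena, not predictions for any particular protein
family.

## Problem sizes

Default test and example scales: 300–500 sites and ~150 sequences for
profile work; 50 residues, 10 decoys, 4000 substitution events for
simulation runs (burn-in 500 events, ≥3000 post-burn-in).  These sizes give
sub-minute runs while leaving every qualitative contrast (covariance signs,
correlation strengths, heterogeneity orderings, Stokes-shift direction)
decisively resolved.
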