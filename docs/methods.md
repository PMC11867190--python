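# Methods

## Model and probability system

The protracted birth–death (PBD) process starts at forward time 0 with one
good lineage and runs to the present at time T (time in Myr throughout).
Good lineages initiate incipient lineages at rate λ₁ and die at rate μ₁;
incipient lineages complete speciation at rate λ₂, initiate further incipient
lineages at rate λ₃, and die at rate μ₂. An incipient lineage is conspecific
with its parent species until it completes, at which point it founds a new
species.

For a single ancestor observed over a horizon *t*, the first-event
probabilities (extinction of the whole potential clade, completion somewhere
in it, or speciation of a good lineage) satisfy renewal equations over the
time of the ancestor's first event. Differentiating them collapses the system
to the four ODEs given in the README: two copies of the same Riccati flow for
the incipient quantities — pEI rising from 0 and q = 1 − pCI falling from 1,
both converging to the stable root π of μ₂ − Λx + λ₃x² — and two linear ODEs
driven by them for pEG and pSG. The reduction was re-derived by hand and is
verified in the test suite against an independent product-integration solver
of the original integral equations (exponential-kernel Volterra stepping with
Richardson extrapolation), to 1e-6 across random parameter sets.

The solver integrates all four curves jointly (`scipy.integrate.solve_ivp`,
LSODA, rtol 1e-10, atol 1e-12). The tight tolerances matter because the
equivalent-rate formulas later divide by pNG = 1 − pSG − pEG, which decays to
0. Curve derivatives are taken as the exact ODE right-hand sides evaluated at
the solution — never finite differences. The closed-form solution of the
incipient Riccati flow (through the roots x± = (Λ±k)/(2λ₃), k = √(Λ²−4μ₂λ₃),
pinned by pEI(0) = 0) serves as an analytic cross-check; the ODE path is the
source of truth, and the critical case k = 0 falls back to it.

Degenerate parameters are handled as continuous limits, not errors: λ₃ = 0
makes the Riccati linear (π = μ₂/(λ₂+μ₂)); μ₂ = 0 gives π = 0; all incipient
rates zero give π = 0 by convention. π and k are evaluated in rationalised,
ratio-based forms (π = 2μ₂ / (Λ(1+√(1−4μ₂λ₃/Λ²)))) so that very small or
very large rates neither underflow nor cancel. One boundary subtlety: when
λ₂ = 0 and λ₃ > μ₂ the incipient clade is supercritical and can survive
forever without ever completing; the closed form then tracks the stable root
μ₂/λ₃ rather than the true non-completion probability 1. We keep the
closed-form (stable-root) definition, which is the quantity the equivalent
rates are built from.

## Equivalent rates

Matching the good-lineage probability dynamics with a time-varying BD
process and solving the resulting 2×2 linear system yields the symmetric
pair of formulas in the README, with the identity
λ̂ + μ̂ = (pSG′ + pEG′)/pNG as an internal consistency check. At the present
(h = 0): λ̂ = 0 exactly and μ̂ = μ₁ exactly. The death rate is nearly
constant over time, with a modest dip (≈ −17% at the rate-curve defaults)
followed by recovery to μ₁ right at the present; the birth rate's variation
is an order of magnitude larger.

As the horizon grows, both numerator and denominator of the rate formulas
vanish. Where pNG drops below a guard of 1e-10 the analytic limit — the
constant equivalent rates λ̃ = (1−π)λ₁, μ̃ = μ₁ — is substituted and the
grid point flagged (`fallback_flag` in the TSV output).

**Limitation (slow incipient mode).** The deep-past limit of λ̂ equals λ̃
only when the incipient relaxation constant k exceeds ν = λ̃ + μ̃. When
k < ν (strong good-lineage turnover combined with slowly equilibrating
incipient dynamics) the slow incipient transient dominates the 0/0 limit and
λ̂ converges to min(k, ν)·λ̃/ν instead; the package reproduces this exactly
(a unit test encodes the formula), and users comparing λ̂(deep past) with λ̃
should first check k > ν. All default parameter sets used in this package
satisfy k > ν comfortably.

Discretisation of a trajectory into piecewise-constant rates (default 200
intervals, matching the grid on which the tree-comparison study was
designed) evaluates the rates exactly at each interval midpoint via one
extra ODE solve rather than interpolating the stored grid.

## Influence decomposition

λ̃ = (1−π)λ₁ is differentiated analytically (chain rule through π; verified
against central finite differences to 1e-4 relative over random parameter
sets). The relative influence of a parameter is its absolute partial
derivative divided by the sum of absolute partials; signs are kept
separately (initiation and completion act positively on λ̃, incipient
extinction negatively, and μ₁ has exactly zero effect). The simplified
three-factor variant ties λ₁ = λ₃ and μ₁ = μ₂ and sums the tied partials.
Limiting-factor maps label each grid cell by the dominant factor; because a
continuous colour blend needs a discrete rule, a factor is *dominant* only
if it leads the runner-up by ≥ 5 percentage points, otherwise all factors
within that margin are reported together. Default maps use 101×101
log-spaced grids on [1e-3, 2] with off-axis factors fixed at 0.1.

## Simulators

`simulate_pbd` is an exact Gillespie algorithm: total event rate
n_good·(λ₁+μ₁) + n_incipient·(λ₂+λ₃+μ₂), exponential waiting times, event
and lineage chosen proportionally to rates, full event history recorded.
Species labels are minted at completion (and for the root, which starts
good); incipient lineages inherit their parent's current label. A replicate
exceeding 10⁶ standing lineages aborts with an explicit error — protection
for supercritical corners of parameter sweeps.

The reconstructed tree of extant species places one tip per species with at
least one member lineage alive at T (so a species whose completed founder
died survives through its conspecific incipient members — the "buffering"
effect; a stricter variant requiring the good lineage itself to survive is
available). Each species is represented by its oldest member lineage by
default (youngest available as an option); divergence times are the
initiation times at which the representatives' paths separate in the full
genealogy, so the extracted tree is ultrametric and binary by construction.
Tip labels s1, s2, … follow the order of species founding.

`simulate_bd` handles arbitrary piecewise-constant rates. Each event
consumes a single unit-exponential hazard draw that is carried across
interval boundaries, so a constant-rate trajectory and its piecewise-cut
copy produce bit-identical trees from the same seed. Conditioning retries a
replicate (up to 100 attempts) until at least 2 lineages survive;
exhausted replicates are recorded as invalid rather than silently dropped.
Batches derive per-replicate generators from one root seed via
`numpy.random.SeedSequence`, making them reproducible and order-independent.

The three-model comparison simulates matched batches under PBD, under the
discretised time-varying equivalent rates (varBD), and under the constant
equivalent rates (BD), with shared batch settings. The default study uses
T = 15 Myr, 200 intervals, 200 replicates, conditioning on 2 survivors.

What the synthetic batches emulate — and what they do not: they are exact
draws from the stated processes, so statistical claims about PBD-vs-BD tree
shape are tested at their source. They contain no incomplete sampling,
fossil tips, rate heterogeneity across lineages, or measurement error in
branch lengths; conclusions about those aspects of real phylogenies are out
of scope, and a test passing here says nothing about them.

## Tree statistics

- γ is computed from internode intervals g_k (duration with k lineages),
  standardised so that pure-birth trees have mean 0; defined for ≥ 3 tips on
  ultrametric trees (tolerance 1e-6 relative), invariant to time rescaling.
- stairs2 is the mean over internal nodes of the smaller-to-larger child
  subtree tip-count ratio — topology only, in (0, 1], 1 for a cherry.
- DR is the inverse equal-splits measure: the pendant edge carries weight 1
  and each step rootward halves the weight; the per-tree summary is the
  median over tips. Tips within 1e-9·T of the present count as extant.

## Constant-rate BD fitting and truncation

The likelihood is the classical reconstructed-process density on branching
times with incomplete sampling, written through
H(t) = ρλ(1−e^{−rt})/r + e^{−rt} (r = λ−μ): p₀ = 1 − ρ/H, p₁ = ρe^{−rt}/H².
Evaluation is log-space safe on both sides of criticality (for r < 0 the
factorisation H = e^{st}(1 + ρλ(1−e^{−st})/s), s = −r, keeps every term
bounded; |rt| → 0 uses the series limit), so λ = μ needs no special-casing.

Slicing a tree at age τ turns every lineage crossing τ into a tip; the
sliced tree is fitted with the sampling fraction set to the probability that
a lineage at age τ leaves extant descendants, ρ = (λ−μ)/(λ − μe^{−(λ−μ)τ}).
Slices compose: cutting at τ₁ then τ₂ equals cutting once at τ₁+τ₂.

Conditioning options: none, survival (≥1 observed tip), at least two
observed tips (default — it matches simulations conditioned on two
survivors from a known stem origin), or the observed tip count (Nee-style).
The choice matters in finite samples: the extinction-rate MLE is strongly
right-skewed, and with survival-type conditioning its median exceeds the
truth by ~15% at a few hundred tips (reference implementations agree to
three decimals on the same trees), converging from above as trees grow;
tip-count conditioning removes that skew but overshoots below the truth.
Parameter-recovery checks in the test suite therefore use trees deep enough
(25 Myr, ~1500 tips) for the default conditioning to place median estimates
within 10% of the generating rates. λ estimates are far better behaved
(medians within ~1% at every size tried).

Optimisation runs Nelder–Mead in (log λ, log μ) with μ floored at 1e-8,
from four deterministic starting points seeded by log(n)/t₀, tolerance 1e-8
on the log-likelihood; estimates at an effective bound or non-converged
runs are flagged, and flagged fits are excluded from sweep summaries. The
truncation sweep reports median and quartile estimates per slice age and
counts replicates dropped for having fewer than two lineages at the slice.

## Problem sizes

Defaults were chosen to mirror the study design at a scale a laptop handles
comfortably: probability grids of 100–600 points; 200-replicate batches for
tree-statistic medians; 50 random parameter sets for the quadrature and
asymptote properties; 200 trees for parameter recovery; 80 trees × 9 slice
ages for the truncation profile. The experiment drivers accept `--full`
(500 replicates) and arbitrary overrides; every run writes a manifest from
which its tables re-generate byte-identically.

## Known limitations

- The equivalent BD process is memoryless while PBD is not: a good species
  that has accumulated incipient members is harder to kill than a fresh one,
  so the equivalent death rate overestimates extinction — visible as smaller,
  less tip-light trees under the equivalent models when λ₃ is large.
- λ̂'s deep-past convergence to λ̃ requires k > λ̃+μ̃ (see above).
- The BD fitting module is constant-rate only; time-varying or
  lineage-heterogeneous fitting, incomplete taxon sampling and fossil data
  are out of scope.
- Trees are strictly binary and ultrametric; polytomies and non-ultrametric
  inputs are rejected rather than coerced.
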