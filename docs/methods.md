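# Methods

## The phenotype decision network

The decision switch is an approximate-majority consensus network over
three species: s and r (votes for the sensitive and resistant
phenotype) and a transient facilitator b. We use the symmetric
five-reaction family

| reaction | rate constant | default |
|---|---|---|
| s + r → r + b | `demote_s` | 1 |
| s + r → s + b | `demote_r` | 1 |
| s + r → b + b | `demote_both` | 0.5 |
| b + s → s + s | `recruit_s` | 1 |
| b + r → r + r | `recruit_r` | 1 |

which contains the two canonical demotion variants of the
approximate-majority family as limits (`demote_both = 0`: each
cross-encounter demotes one participant; `demote_s = demote_r = 0`:
both). Every reaction conserves the total count, b starts and ends at
zero, and the absorbing states are the two consensus pools. One other
dead state exists — an all-b pool, reachable only through the
both-demotion channel once the network has drained to a single molecule
of each species. It is exactly s↔r symmetric and is resolved as a
fair-coin tie in every engine.

**Calibration.** Absorption probabilities of the embedded jump chain are
invariant to the recruitment/demotion rate *ratio* (each b molecule's
fate depends only on the s:r composition when it is recruited), so for a
fixed demotion variant the rate constants do not move the switch's
operating points at all. The mix of the two demotion channels does.
`demote_both/demote_s = 0.5` was chosen so that the 100-molecule switch
reproduces the reference operating points of the bet-hedging model —
P(all-s | 53s/47r) = 0.7532, P(all-r | 46s/54r) = 0.8194, and, forced by
symmetry, exactly 1/2 at 50s/50r (all exact values from the linear solve
below). Rates are s↔r symmetric throughout; asymmetric rates would break
the 50/50 coin flip.

**Engines.** Three independent routes compute the same chain:

1. `resolve_crn` — a per-event Gillespie direct-method loop (exponential
   waiting times from the total mass-action propensity), optionally
   recording the full trajectory;
2. `resolve_crn_batch` — a numba-compiled kernel (numpy-vectorised
   fallback when numba is absent) that simulates the embedded jump chain
   for many replicates; the jump chain fully determines winners and
   event counts, so waiting times are not drawn on this path;
3. `exact_phenotype_probability` — exhaustive enumeration of the
   conserved-total lattice ((n+1)(n+2)/2 states) and a sparse first-step
   linear solve; practical to a few hundred molecules.

The test suite cross-checks all three (Monte Carlo vs exact solve within
3 binomial standard errors, plus an independently coded dense-solve
oracle in the tests themselves). Monte-Carlo probability estimates carry
Wilson score intervals. A guard (default 10⁷ events) bounds every
resolution; expected event counts are O(n log n), ~10³ for n = 100.

## The bet-hedging population model

Discrete-time scheduler, default step Δt = 1. Per step and per cell, in
order: (1) therapy kill with probability `kill_probability_S` if the
cell is S and the drug is on; (2) baseline death (default 0.01); (3)
division with phenotype-dependent probability (defaults p_S = 0.3,
p_R = 0.1 — "fast-growing" vs "slow-growing") scaled by the logistic
factor max(0, 1 − N/K), default capacity K = 5000. A dividing parent is
replaced by two daughters, each phenotyped by an independent network
resolution. All of a step's resolutions are executed in one batch kernel
call, which is what makes 20-seed preset sweeps cheap.

**Memory.** After a daughter's network absorbs, the whole absorbed pool
(g_s + g_r + inherited molecules, all of the winning species) becomes
the daughter's molecular store. At the parent's next division the store
is decayed by binomial thinning with survival exp(−rate × age) (age =
time since birth; thinning is applied lazily at division, which is
equivalent to per-step decay and order-independent), split as
⌊n/2⌋/⌈n/2⌉ with the odd molecule assigned uniformly, and each half is
added to the genotype votes of one daughter. The store therefore
compounds above g_s + g_r under slow decay; we accept this literal
reading — it is precisely what makes memory strengthen in fast-dividing
lineages. With memory disabled (or decay → ∞) the model collapses to
the memoryless limit, which the tests verify distributionally.

**Therapy** is a deterministic pulse train: `n_pulses` pulses of
`pulse_duration` separated by `inter_pulse_gap`, starting at
`start_time`; the drug kills only S cells. Defaults: 6 pulses × 10
steps, gap 20, kill probability 0.9 per step. "100 % sensitive" is
interpreted as susceptible-only (high per-step kill), not instant
eradication, so partial-kill dynamics within a pulse remain visible.

**Regime taxonomy.** `classify_regime` applies deterministic rules in
order: *extinct* if the census ever reaches zero; *hybrid growth* if the
inter-pulse recovery peaks are non-decreasing (5 % tolerance) and the
treatment window ends ≥1.5× above the pre-treatment census — the
within-pulse transient is not held against monotone growth, since any
effective pulse dips the census; *tissue preservation* if the
on-treatment minimum stays above half the pre-treatment census;
*persister* otherwise.

**Presets.** The six shipped configurations realise the regime gallery.
Decay rates are "slow" or "fast" *relative to the phenotype's division
timescale* (off-treatment S cells divide every ~3 steps, R cells every
~10, and both only every ~1/death ≈ 100 steps at carrying capacity), so
the numeric values differ between presets:

- `fig11c` (53s/47r, no memory): persister.
- `fig11d` (46s/54r, no memory): tissue preservation.
- `fig12b` (53s/47r, decay s 0.3 / r 2.0): micro-persister — troughs of
  ~10 cells, survival through the R rump that the genotype leak
  replenishes during each inter-pulse regrowth, rapid post-treatment
  recovery.
- `fig12c` (53s/47r, decay s 0.5 / r 0.01, death 0.03, p_R 0.15,
  therapy from t = 250): R-memory compounds at the capacity churn, the
  standing population becomes resistant-rich (~2/3) during a long
  equilibration, and therapy removes less than half of it.
- `fig12d` (57s/43r, decay 0.01 both, K = 50 000, therapy from t = 0):
  hybrid growth — treatment during the growth phase; after the first
  pulse the memory-locked resistant lineage grows monotonically through
  the remaining pulses, comparably on and off drug.
- `fig12e` (60s/40r, decay 0.5 both): extinction — the resistant
  phenotype is produced too rarely (P(R) ≈ 1.1 %) and erodes during
  pulses (resistant parents without memory mostly produce sensitive
  daughters), so the pulse train eradicates the population.

Preset parameters were fixed by forward simulation over 20 seeds per
candidate; each shipped preset yields its regime label in ≥80 % of 20
seeds (in current runs, 20/20 each). The figure-level dynamics are
qualitative reproductions: division/kill/decay constants are modelling
choices, not measured quantities.

## Landscape dynamics

One state-space coordinate x on a bounded domain, default [−2, 2] with
401 nodes; benchmark potential V(x) = a(x² − 1)² with barrier height a
(presets: "normal" a = 2, "cancer" a = 0.5), constant noise intensity D
(default 0.4 for transition experiments).

The density equation ∂N/∂t = ∂x[D ∂x N − F N] + g N is discretised in
flux form with exponentially fitted (Scharfetter–Gummel) face fluxes:
J = (D/h)[B(w) N_right − B(−w) N_left], w = −ΔV/D, B(w) = w/(e^w − 1).
For constant D this makes exp(−V/D) *exactly* stationary on the grid and
conserves the cell sum to round-off under the no-flux boundary
condition. Time stepping is explicit Euler with guard
dt ≤ h²/(2 max D) (0.9 safety factor; a violating dt raises an error
carrying the suggested value). The growth term is applied as the exact
pointwise factor exp(g dt) each step, so constant-γ mass growth matches
exp(γt) to the conservation error. Growth breaks normalisation by
design; `DensityField.normalized()` provides the per-time renormalised
view for probability readouts, and raw densities are always available.

`simulate_langevin` integrates dx = F dt + √(2D) dW by Euler–Maruyama
with reflecting walls; drift is −dV/dx by central difference (h = 10⁻⁶).
The particle histogram and the PDE density are two independent
discretisations of the same dynamics and are required to agree to
L1 < 0.05 at 5 × 10⁴ particles in the tests.

`transition_probability` initialises a narrow Gaussian (σ = 3 grid
steps) truncated to the start well at that well's potential minimum,
evolves it with g ≡ 0, and reports the mass fraction inside the target
well. It is exactly 0 at t = 0, increases strictly as the barrier is
lowered at fixed t and D, and approaches the Boltzmann mass ratio at
long times (1/2 for half-domain wells around a symmetric barrier).

## The two-gene circuit

dx_i/dt = θ [ a x_i^n/(K^n + x_i^n) + b K^n/(K^n + x_j^n) ] − k x_i,
with self-activation a = 0.25, mutual inhibition b = 1, Hill n = 4,
threshold K = 0.5, degradation k = 1. The production scale θ is the
bifurcation control: at θ = 1 the circuit is bistable — two asymmetric
attractors (one gene high) and a symmetric saddle — and as θ decreases
the attractors destabilize and merge with the saddle in a supercritical
pitchfork at θ_c ≈ 0.430 (located by bisection on the stable-state
count), below which a single symmetric state remains. The leading
Jacobian eigenvalue λ* of the tracked attractor rises continuously to
zero at θ_c; the Jacobian is analytic, with a finite-difference
cross-check in the tests. θ scales both production terms rather than
self-activation alone because the θ = 0 limit must be monostable for a
bifurcation to exist within the scan; with the inhibition term left
unscaled the circuit would remain a bistable toggle at θ = 0.

Fixed points are found by `scipy.optimize.root` (hybr) from a 12 × 12
grid of starts over the invariant box [0, θ(a+b)/k]², deduplicated at
10⁻⁵ and classified by Jacobian eigenvalues.

**Snapshots.** Cells are independent Euler–Maruyama realisations
(dt = 0.01, additive noise σ, reflection at zero) started *at* the
selected attractor and integrated for a burn-in (default 50 time units;
the relaxation time is 1/|λ*| ≈ 1–10 over the scanned range, so the
default is several relaxation times except asymptotically close to
θ_c). Observed expression of gene g in cell j is
max(0, c + W_g · x_j + ε), with m × 2 mixing weights W drawn once per
experiment from a seeded standard normal, basal offset c = 1 (keeps
typical readouts positive so clipping rarely distorts the covariance
structure), and readout noise ε of scale 0.05. Defaults m = 20 genes,
σ = 0.05.

What the generator emulates: a unimodal cloud of cells in one basin
whose dispersion and correlation structure respond to attractor
stability. What it does not: transcript counts, technical dropout,
library-size variation, multimodal mixtures, or more than two latent
dimensions — so passing tests demonstrate the statistical mechanism,
not performance on real single-cell data.

## Snapshot statistics

`mean_abs_pairwise_correlation` averages |Pearson r| over all unordered
vector pairs, excluding (and counting) pairs that involve a
zero-variance vector; if no usable pair remains it raises. The
destabilization index is the ratio of the gene-pair mean to the
cell-pair mean. Orientation: gene correlations in the numerator, cell
correlations in the denominator — the orientation under which the index
*increases* as an attractor destabilizes (cells disperse, so cell-pair
correlation falls; fluctuations align with the soft eigen-direction, so
gene-pair correlation rises). Correlations are computed on raw values —
Pearson is already invariant to per-vector affine rescaling, which the
tests assert as a stronger property. Above a pair-count cap (default
10⁶) pairs are uniformly subsampled with the supplied generator; below
it the computation is exact and is checked against a brute-force double
loop to 10⁻¹².

In the bifurcation scan (10 θ values from 1.0 down to 0.45, 200 cells,
20 observed genes, 20 seeds per point) the median index rises
monotonically (~0.18 to ~0.60) with Spearman rank correlation +1 against
proximity to θ_c, the gene-pair mean |r| rises, and the cell-pair mean
|r| falls — the package's operational early-warning claim, reproduced
by the acceptance-style test at exactly these problem sizes.

`svd_statespace` mean-centres gene-wise, takes the SVD, and returns the
leading left singular vectors as orthonormal eigengene axes (sign
convention: each axis's largest-magnitude gene weight is positive),
singular values, explained-variance ratios and cell projections; `project`
maps new samples into the stored space after removing the stored
centering. Snapshot sets are concatenated cell-wise before
decomposition.

## Reproducibility and problem sizes

Every stochastic routine takes a `numpy.random.Generator`; the CLI
derives a named child stream per subcommand from the root `--seed` via
`SeedSequence(entropy, spawn_key=hash(name))`, so adding a subcommand
never perturbs existing streams, and identical seeds give byte-identical
outputs on a platform. The compiled network kernel is seeded with one
integer drawn from the caller's generator (kept below 2³¹); the numpy
fallback consumes the generator directly, so the two engines are
statistically — not bitwise — equivalent, and which one runs is fixed by
the environment, not by data.

Default experiment sizes (20 000 network replicates per probability
estimate; 20 seeds per preset regime; 5 × 10⁴ Langevin particles;
200-cell snapshots) keep each headline check to seconds-to-minutes on
one core while leaving Monte-Carlo standard errors well inside the
asserted tolerances.

## Known limitations

- The population model is non-spatial and ignores microenvironmental
  signalling ("environmental memory"), mutation of the genotype, and
  more than two phenotypes.
- The landscape solver is 1-D; multi-dimensional densities and
  estimation of a landscape from data are out of scope.
- The circuit is the minimal two-gene exemplar; no network inference is
  attempted.
- Figure-level population dynamics are qualitative: vital rates, kill
  rates, pulse timing and decay constants are unpublished modelling
  choices, and only the decision network's operating points are
  quantitative claims.
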