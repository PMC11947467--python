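# Methods

## Model

Two cell-cycle compartments of a migrating monolayer are tracked as
densities on a line or a radially symmetric disc: ρ₁ (G0/G1 together with
post-mitotic cells, which FUCCI leaves dark) and ρ₂ (S/G2/M). Motility is
linear diffusion with one shared constant D; the G1→S transition fires at
rate k₁f(ρ) and division at k₂g(ρ), where the crowding functions f, g are
nonincreasing, equal 1 at ρ = 0, and encode contact inhibition through the
total density ρ = ρ₁ + ρ₂. Division removes one ρ₂ cell and creates two ρ₁
cells, so net growth comes only from the division column of the 2×2 local
reaction matrix; its dominant eigenvalue λ(ρ) is the local net growth rate.

Assumptions worth keeping in mind: movement is unbiased diffusion (no
cell–cell adhesion or pressure-driven advection); stage durations are
exponentially distributed at fixed density; both compartments share D; the
populations are well described after radial averaging (local spatial
correlations between cell phases are ignored).

Three crowding variants are supported per transition: `linear`
(1 − ρ/K)₊ — the calibrated default; `heaviside` H(K − ρ) — the reduced
model used for closed-form wave analysis; `constant` — no density
dependence, giving the exponential-growth submodel valid at low density.
Convention: H(0) = 0, i.e. the transition shuts off exactly at the
threshold, matching the linear variant's zero at ρ = K and making the
carrying capacity absorbing.

### Parameters

| parameter | meaning | units | reference value |
|---|---|---|---|
| D | cell diffusivity | μm²/h | 1300 |
| k₁ | intrinsic G1→S rate | 1/h | 0.612 |
| k₂ | intrinsic division rate | 1/h | 0.457 |
| K₁ | crowding threshold of G1→S | cells/mm² | 4965 |
| K₂ | crowding threshold of division | cells/mm² | 5435 |

The reference values (`POSTERIOR_MODES`) are the calibrated marginal
posterior modes for expanding MDCK tissue. K₁ < K₂ — crowding bites the
G1→S transition first — is a finding of that calibration, not an enforced
constraint. Densities enter the model only through the ratios ρ/K, so no
mm²↔μm² conversion is ever applied to them; the tests assert invariance
under joint rescaling of (ρ, K₁, K₂).

`doubling_time` is defined as ln 2 / λ(ρ), the doubling of the dominant
growth mode at fixed density. Other definitions (e.g. the sum of the two
stage durations) differ by up to tens of percent at high density; at
4000 cells/mm² the two give ≈ 14.0 h and ≈ 16.7 h respectively. Infinite
durations (a crowding factor at zero) are returned as `math.inf`, never as
an overflow.

## Numerical solution

Method of lines on a uniform cell-centred grid (nodes at (i+½)Δx).
Diffusion is discretised in conservative flux form with second-order
central differences; the radial operator (1/r)∂ᵣ(r∂ᵣ·) uses face radii, so
the flux through the r = 0 face vanishes identically and no-flux walls and
exact mass conservation hold by construction (reaction-free mass drift in
the tests is ~10⁻¹² relative). For both geometries the interior stencil
weights sum to 2/Δx², so the Cartesian diffusive CFL bound applies
unchanged.

Two integrators:

- `adaptive` (default): scipy RK45 with rtol 10⁻⁶ / atol 10⁻⁹ — the
  reactions are non-stiff at the biological rates.
- `fixed`: classical RK4 with Δt = 0.9·min(Δx²/2D, 1/(4(k₁+k₂))),
  JIT-compiled with numba (a pure-numpy fallback is used if numba is
  unavailable). This path is ~100× faster and powers the thousands of
  forward solves inside the MCMC likelihood; against the adaptive solver it
  agrees to ~10⁻⁵ relative on the expansion problem.

Sharp initial steps are applied as given on the grid, without smoothing
(an optional half-cosine ramp is a scenario parameter). Negative
undershoots below 10⁻⁶ of the field scale are clamped to zero at output;
anything larger raises an integration error carrying the failure time
(pinning the clamp at the literal solver atol of 10⁻⁹ would misclassify
harmless ~10⁻³ cells/mm² undershoots of the adaptive scheme near sharp
steps as failures). Default grids: radial L = 5000 μm, N = 500; Cartesian
L = 3000 μm, N = 300. Front positions are threshold crossings (outermost,
linearly interpolated; default threshold 1% of K₂), and expansion speed is
the least-squares slope of the edge trajectory over a window (default: the
final half of the output times).

## Traveling-wave analysis

Low-density initial data develop pulled fronts: speed set by the
linearisation about ρ = 0, c_min = 2√(D λ(0)), independent of K₁, K₂ and
of the crowding shapes. When 4r/(k₁+k₂) ≪ 1 (r = k₁k₂/(k₁+k₂)) this
reduces to the single-rate Fisher–KPP-style √(2Dr). At the reference
parameters 4r/(k₁+k₂) ≈ 0.98, so the two-stage correction matters: 33.6 vs
26.1 μm/h.

For Heaviside crowding the wake composition has closed forms in κ = k₁/k₂
and K₁/K₂ alone: with α_κ = 2/(√(κ²+6κ+1) − κ + 1), the invaded bulk keeps
ρ₂bulk/K₂ = (K₁/K₂)/α_κ − 1 when K₁/K₂ > α_κ (else 0), the edge peak is
ρ₂edge/K₂ = (K₁/K₂)(1−α_κ)/α_κ, and the excess ρ₂edge − ρ₂bulk collapses
to K₂ − K₁ on the supercritical branch. These are asymptotic edge
estimates: in full simulations of the Heaviside model (L = 8000 μm,
N = 1600, 200 h horizon; the switching layer needs Δx ≈ 5 μm to converge)
the bulk ρ₂ averaged over the trailing 20% of the invaded region sits
≈ 15% below the closed form — the reduced model is quantitative only to
that level, and coarser grids widen the gap. The measured front speed at
the same settings is within 2% of c_min and moves by < 0.5% when both
thresholds are halved or doubled.

## Bayesian calibration

Likelihood: the earliest observed profile pair initialises the PDE (and is
excluded from the residuals — it is consumed, not fitted); all later
(time, position) points of both compartments contribute iid Gaussian
residuals with a single inferred scale σ, computed on the
replicate-averaged profiles (per-replicate fitting is possible by passing
the unaveraged set). Predictions are linearly interpolated from the solver
grid (default N = 150–250) to the observation positions. Solver failures
propagate as −∞ (rejected proposals).

Priors are independent uniform boxes: D ∈ [10, 5000] μm²/h,
k₁, k₂ ∈ [0.01, 3] /h, K₁, K₂ ∈ [1000, 10000] cells/mm²,
σ ∈ [1, 2000] cells/mm². Sampling uses the affine-invariant ensemble
sampler (emcee), seeded for bit-reproducible chains. Initialisation is a
real design point on this likelihood surface:

- `map` — seeded differential evolution in unit-box coordinates (the raw
  scales span five orders of magnitude) followed by a Nelder–Mead polish;
  walkers start in a tight ball around the optimum. Plain multistart local
  optimisation reliably stalls in local optima of the 6-D surface.
- `prior` — pure prior scatter (used for the posterior≈prior sanity test).
- `prior_best` — the best n_walkers points out of a large prior sample:
  walkers start spread across flat (non-identified) directions while
  already near the ridge of the identified ones, which is the right
  structure for practical-identifiability runs; raw prior scatter leaves
  most walkers stuck (acceptance ≈ 0.1) for the whole budget.

Diagnostics: mean acceptance fraction and split-chain potential scale
reduction per parameter (each walker chain halved; warn above 1.05).
Marginal summaries report the KDE mode (Gaussian KDE, 512-point grid; a
second peak within 5% of the maximum flags multimodality), mean, sd and
equal-tailed 95% interval. Practical identifiability is the posterior/prior
sd ratio: < 0.3 identifiable, > 0.75 non-identifiable, else marginal.

An optional reporting floor (`reporting_floor_frac`, default off) treats
densities below a fraction of the dataset's peak as empty when seeding the
PDE and dead-bands residuals where both data and prediction are below it —
useful for data whose measurement noise does not vanish in empty regions,
where a spurious noise floor would otherwise grow exponentially.

### Identifiability at low density

In the low-density regime only the products k₁f(ρ̄) and k₂g(ρ̄) are
constrained, so the full model's rates trade off against the thresholds
(k₁ ↔ K₁, k₂ ↔ K₂) and even D, k₁, k₂ carry wide full-model marginals
under these priors; the crisp statement of the design lesson is that
K₁, K₂ stay prior-wide (sd ratio > 0.75) while the exponential submodel
(f = g = 1, parameters D, k₁, k₂, σ) recovers the kinetics to within a few
percent. High-density expansion data, in contrast, identify all five
parameters.

## Synthetic data

The generator forward-simulates a scenario at known truth parameters,
samples the observation schedule, and adds measurement noise. Scenarios:

- **expansion** (radial): plateau 3500 cells/mm² (split 70/30 between
  G1/post-M and S/G2/M — the composition is a modelling choice; only the
  total is constrained by the emulated experiments) of initial radius
  1700 μm with a 100 μm half-cosine edge, simulated 46 h; the profile 10 h
  in becomes observation time zero (discarding the seeding transient) and
  later profiles follow every 9 h; 11 replicates, noise scale
  150 cells/mm².
- **colonization** (1-D): sharp block ρ₁ = 4800 cells/mm² for x < 850 μm,
  ρ₂ = 0, domain 3000 μm — the barrier-release geometry; noiseless single
  replicate by default. A low-density variant (ρ₁ = ρ₂ = 500) serves the
  traveling-wave studies.
- **scratch** (1-D): two 400 cells/mm² blocks (300/100 split) flanking a
  500 μm cell-free gap, observed every 16 h over two days, with
  constant-crowding truth kinetics D = 400 μm²/h, k₁ = 0.08 /h,
  k₂ = 0.04 /h (melanoma-like: mean cycle 1/k₁ + 1/k₂ = 37.5 h, one to two
  cycles per experiment, peak density staying below a quarter of K₁);
  3 replicates, noise 20 cells/mm².

Noise model: additive Gaussian per replicate/point/compartment with
constant scale in the tissue bulk, truncated at zero; no noise where the
noiseless truth is below 1 cell/mm² (counting nuclei in empty space yields
exactly zero), and the sd tapers linearly below 10% of the peak total
density. The taper matters: a constant scale clipped at zero would paint a
systematically positive ≈ 0.4σ density "floor" over the near-empty front
tail; consumed as the likelihood's initial condition, that floor grows at
λ(0) ≈ 0.22/h and biases D by ≈ −18% and k₁ by ≈ −9% in recovery
experiments. It also matches the qualitative behaviour of nucleus-counting
noise, whose spread shrinks with the number of cells counted.
`noise_on_first=False` generates an exact earliest profile; see below.

What the generator does **not** emulate: imaging/segmentation error
structure, spatially or temporally correlated noise, replicate-to-replicate
biological variability of the parameters, the post-stencil transient of
real tissue (real initial profiles are rougher), or local cell-phase
correlations. Passing recovery tests therefore demonstrates that the
inference machinery is correct and well calibrated under the stated noise
model — not that real data meet these assumptions.

## Calibration checks and problem sizes

The test suite runs three heavier end-to-end experiments (sizes chosen to
keep the full suite a few minutes long):

- **Expansion recovery**: data at the reference truth (default scenario,
  N = 500 generation grid), fitted with the full model on a N = 250
  likelihood grid, 16 walkers × 400 steps. Marginal modes land within ~1%
  of truth (asserted tolerance: 10%) with K₁ < K₂ recovered.
- **Identifiability contrast**: the default scratch dataset fitted with
  the full model (`prior_best`, 32 × 600) and the exponential submodel
  (`map`, 16 × 400) on a N = 100 grid.
- **Coverage**: five scratch datasets (exact earliest profile,
  `noise_on_first=False`; matched N = 100 grids), exponential submodel;
  95% intervals cover the truth for ≥ 80% of parameter–dataset pairs.
  With a noisy earliest profile this calibration check necessarily fails:
  the likelihood conditions on that profile as exact, so its noise shifts
  each posterior by ~1% while the intervals are ~±0.3% wide — an inherent
  cost of the measured-initial-condition design, not a sampler defect.
  Short tight-ball chains also under-disperse intervals slightly; the
  coverage experiment uses converged settings.

## Known limitations

- The reduced-model composition formulas are edge asymptotics (~15% off
  the converged PDE wake at the reference parameters).
- Credible intervals quantify uncertainty conditional on the measured
  initial profile and the iid Gaussian noise model; they do not propagate
  initial-condition noise.
- The 2-D solver assumes radial symmetry; no adhesion, pressure or
  cross-diffusion terms; single-stage exponential clocks per compartment
  (no age structure or multistage cycles).
- The doubling-time definition is a package choice (ln 2 / λ); measured
  population doubling times at high density are definition-sensitive.
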