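# Methods

`krtecon` evaluates the economics of kidney transplantation against
maintenance dialysis on a sparse cross-country panel: 14 countries observed
at two calendar years (2019 and 2023).  This note records the models, the
synthetic data-generating process, the numerical choices, and the design
decisions taken where the problem was genuinely open.

## Cost–benefit model

Per patient and country-year, with `C_dial` the annual cost of in-centre
haemodialysis, `C_post` the annual post-transplant maintenance cost and
`C_tx` the initial transplant episode cost (all constant USD):

- annual saving `S = C_dial − C_post`;
- break-even time `BE = C_tx / S` (years; undefined when `S ≤ 0`, reported
  as an explicit no-payback condition, never a silent division);
- net present value over horizon `T` at discount rate `r`
  (end-of-year discounting, upfront cost undiscounted at t = 0):
  `NPV = Σ_{t=1..T} S/(1+r)^t − C_tx`.

Defaults: `r = 0.03`, `T = 10`.  Cumulative cash-flow trajectories
`S(t) = −C_tx + S·t` are deliberately **undiscounted**: their "valley"
metrics (minimum, number of years below zero) describe the financing gap a
payer must bridge, which is a liquidity question, not a present-value one.
Break-even is reported as a real number of years, not rounded to budget
cycles.

Budget impact of scaling transplant volume by a multiplier `φ ≥ 1`:
`ΔS(φ) = (φ−1)·Vol0·S·s1`, where `Vol0` is baseline annual volume and `s1`
one-year graft/patient survival (patients who do not survive the first year
generate no maintenance-phase savings).  The increment is exactly linear in
`(φ−1)` and in each factor; the cumulative figure discounts the constant
annual increment over the horizon.  `s1` has no authoritative source value;
it is an explicit input (default 0.95) and results are reported conditional
on it.

## Cost–utility model

Utility weights 0.82 (transplant) and 0.56 (dialysis) give an annual gain of
0.26 QALY.  Cumulative incremental QALYs adjust for survival:
`ΔQALY = Σ_{t=1..T} [S_Tx(t)·0.82 − S_dial(t)·0.56]`, undiscounted (a
discount switch exists but defaults off, matching the additive form above).
`ICER = ΔCost/ΔQALY`; ΔCost is taken as the negative of the 10-year
discounted net saving from the cost-benefit engine — the operational
definition had to be fixed somewhere, and this choice makes the
cost-effectiveness plane consistent with the NPV results.  Quadrants follow
the sign pattern of (ΔCost, ΔQALY); dominant results (Quadrant I) report the
raw negative ratio alongside the dominance flag because negative
cost-per-QALY values are informative about the size of the saving.
Willingness-to-pay default: $50,000/QALY, binding only in Quadrant II.

## Synthetic panel generator

Real registry cost panels are not redistributable, so the generator emulates
the *statistical* structure of the study sample; no attempt is made to
impersonate actual countries.  Calibration targets are pooled moments:
annual saving mean $37,471 (SD $12,845), break-even mean 3.12 y (SD 1.24,
range 0.5–6.8), living-donor split 6 countries above / 8 at-or-below 20%,
transplant volume mean 2,847 (SD 1,923).  Choices:

- **Lognormal components.**  Costs are positive and right-skewed; lognormals
  also serve directly as the PSA sampling distributions.  Break-even and the
  annual saving are drawn lognormally with moment-matched parameters and
  `C_tx = BE·S` pins the episode cost; the post-transplant cost is an
  independent lognormal (mean $25,000, SD $6,000 — a mid-range European
  maintenance figure) and `C_dial = C_post + S` guarantees economic
  dominance in the default regime.
- **Living-donor coupling.**  The log break-even carries a −0.42 loading on
  the standardized LD share (faster payback where living donation is
  common) and the saving gap a +0.30 loading, so the subgroup contrast and
  the negative LD/BE correlation are recoverable from generated panels.
- **Economic features.**  d = 3 (GDP per capita, health-expenditure ratio,
  capacity index), drawn normally and standardized to zero mean and unit
  variance before any kernel use; log break-even loads 0.45 on the first
  feature so the similarity graph carries signal about the state.
- **Survival.**  Exponential hazards per modality (simplest monotone
  family; registry Kaplan–Meier curves are not available).  Defaults
  `h_tx = 0.03`, `h_dial = 0.1579` are calibrated so the 10-year
  survival-adjusted incremental QALY equals 4.38 at the default weights.
- **2019 → 2023 dynamics.**  Each of the saving gap, episode cost,
  maintenance cost and volume is multiplied by
  `exp(drift + amplitude·g(state) + η)`.  The maps `g` are smooth tanh
  functions of the standardized 2019 state: the saving gap widens where
  payback is slow and episode costs fall there (cost rationalization under
  fiscal stress), producing smooth, strongly mean-reverting break-even
  dynamics — strong enough that the cross-sectional ordering partly
  reverses over the window, consistent with the churn the cluster
  transition analysis is designed to detect.  This state-dependent
  evolution is what an additive two-way fixed-effects model cannot
  represent, which is precisely the regime the neural ODE is meant to
  capture.  Acting on the *saving gap* rather than on the dialysis cost
  avoids denominator leverage (small cost shocks exploding the break-even
  of low-margin systems into unlearnable outliers).  Shocks `η` are
  zero-mean with covariance `noise_scale²·A` (Cholesky of the similarity
  kernel): graph-close countries move together.  Defaults:
  amplitude 0.45, noise 0.02, drift 0 — year-over-year cost factors of
  roughly ±40%, consistent with the large 2019→2023 (pandemic-era) swings
  the two-point design is meant to absorb.  Zero amplitude and noise
  reproduce the first year exactly.

What the generator does **not** emulate: per-country realism (the study's
pooled moments are the only constraints), deceased-donor programmes,
modality mix within dialysis, currency/inflation adjustment, and more than
two observation times.  Passing tests therefore demonstrate correctness of
the machinery and recoverability of the designed structure, not fidelity to
any particular country's registry values.

## Graph-regularized neural ODE

State per country: `x = (log BE, log C_dial, log C_post, log C_tx,
log Vol)`, the cost/volume components standardized by first-year mean/SD
(shared across years); log break-even stays on its natural scale and the
readout is its exponential, guaranteeing positive predictions.  Dynamics
`dx/dt = f_θ(x, t)` with `f_θ` an MLP `(n+1) → 32 → 32 → n`, tanh hidden
activations, linear output.  Time is normalized: 2019 ↦ 0, 2023 ↦ 1 (the
4-year gap is absorbed into the scale of `f_θ`).

Training loss: `L_total = L_data + λ_graph·L_graph + λ_curv·L_curv` with

- `L_data`: MSE of the log break-even component against both observation
  times (the t = 0 residual is identically zero since the 2019 state is the
  initial condition; it is still included in the averaging so the loss is
  "across all countries and time points");
- `L_graph = Σ_ij A_ij‖x_i − x_j‖²` averaged along the solver grid, with
  `A_ij = exp(−‖z_i − z_j‖²/σ²)`, `σ = 0.5`;
- `L_curv`: mean squared second-order central difference of the trajectory
  on the solver grid (`λ_curv = 0.01`), suppressing oscillatory solutions.
  Finite differences avoid nested automatic differentiation.

Numerics: fixed-step RK4 (default 16 steps) over [0, 1]; exact hand-derived
reverse-mode gradients through the unrolled solver and MLP (validated
against central finite differences to 1e−4 in the tests); Adam
(lr 1e−2, default 2000 epochs) with decoupled weight decay 1e−2 on the
weight matrices — with 14 training countries the decay meaningfully
improves held-out extrapolation.  The output layer is initialized at 1/10
scale so training starts from near-constant trajectories.  All replicated
fits (cross-validation folds, bootstrap replicates, ensemble members) are
mathematically independent but share one batched computation for speed.

`λ_graph` is not identified a priori and its usefulness is panel-dependent
(the kernel graph can be nearly empty, or can weld a close pair of
countries together); it is selected per panel by leave-one-country-out
cross-validation over the grid {0.001, 0.01, 0.1, 1} — the same protocol
that motivates the default of 0.1.  LOCO-CV holds each country out of
`L_data` while keeping its graph edges (the penalty needs the node present
to propagate information); held-out predictions average a small ensemble of
random initializations (default 3) to reduce fit-to-fit variance.
Bootstrap confidence intervals for RMSE resample countries with
replacement (B = 1000 by default) and refit from scratch.

The architecture's parameter count follows the stated counting rule,
`(n·32+32) + (32·32+32) + (32·m+32) = 1312` at `n = 5, m = 1`.

## Baselines and model comparison

The static linear predictor applies the break-even identity with first-year
costs frozen — exact in 2019, wrong in 2023 by exactly the realized cost
drift.  The two-way fixed-effects regression `BE_it = α_i + γ_t + βX_it +
ε_it` uses reference-level encoding (first country/year dropped) and OLS;
covariates default to none because the generator's economic features are
time-invariant and would be collinear with the country effects.  Rank
deficiency is detected and reported with the offending columns named.

RMSE squares residuals before averaging (the conventional definition).
AIC/BIC use the Gaussian concentrated-likelihood forms
`K·ln(RSS/K) + 2k` and `K·ln(RSS/K) + k·ln K`; printed AIC/BIC values from
the study are treated as report inputs for worked examples, not as
refitting targets, since their likelihood convention is unrecoverable.  For
the neural ODE, `k` defaults to the raw 1312 count with an
effective-degrees-of-freedom override, because penalized fits have far
fewer effective parameters than raw ones.

In the comparison report the neural ODE's RMSE is its LOCO-CV RMSE while
the baselines report fit RMSE — a deliberately conservative asymmetry
(held-out versus in-sample) under which the ordering
GR-NODE < fixed effects < linear CBA is still expected on default panels.

## Cluster dynamics

Fixed break-even thresholds with half-open intervals: [0, 2.5) → A,
[2.5, 4.0) → B, [4.0, ∞) → C.  (Tertile re-estimation is out of scope; the
fixed printed thresholds are used, configurably.)  Cohen's κ uses the
standard `p0`, `pe` from the transition matrix marginals.  "Deterioration"
is any move to a later letter.  The permutation stability test shuffles the
second-year labels uniformly (preserving their multiset and hence both
marginals), M = 10,000 by default; under this scheme the analytic null mean
of the stability rate is `Σ_i r_i c_i / N²`, which the test suite verifies
to within 3 standard errors.  The one-tailed p-value is the plain
proportion of null stability rates at or above the observed rate.

## Heterogeneity and sensitivity

Cochran `Q = Σ w_i (BE_i − BE_w)²` with inverse-variance weights (Q scales
linearly with the weight scale — weights must be true inverse variances);
`I² = max{0, (Q−df)/Q}·100`; DerSimonian–Laird
`τ² = max{0, (Q−df)/C}`, `C = Σw − Σw²/Σw`.  The prediction interval for a
new country is `μ ± 1.96·√(σ² + τ²)` with `σ²` the mean within-country
variance; the formula's printed source is ambiguous about the square root
and about σ², and its printed interval is not reproducible from its printed
τ² — the formula is implemented as read and this is simply documented.
Country-level BE variances are not observable from a cost table; in the
pipeline they come from each country's Monte-Carlo cost uncertainty
(lognormal, CV 0.10 by default); equal weights are the fallback.

The country-level analyses — heterogeneity, the living-donor subgroup
contrast, and the LD/break-even correlation — summarize each country by its
mean break-even across the two observation years: the stratifying variables
are country attributes, and with strongly mean-reverting dynamics a
single-year snapshot would understate (or even invert) the cross-sectional
gradients the panel as a whole carries.  The subgroup contrast (LD share
> 20% versus ≤ 20%) uses Welch's unequal-variance t with the
Welch–Satterthwaite fractional df; group CIs are t-based.  The PSA samples the three cost parameters (lognormal by
default, normal optionally) and propagates them through the cost-benefit
identities; draws with non-positive dialysis cost or non-positive saving
are rejected and resampled with the rejection count reported.  The tornado
analysis re-evaluates NPV one parameter at a time (±20% dialysis cost,
discount rate ∈ {0, 5%}, ±20% episode cost by default), ordered by absolute
swing.  No multiple-testing correction is applied anywhere (none is used in
the source analysis).

## Pipeline and problem sizes

`run_pipeline` sequences generation → per-record economics → heterogeneity/
subgroup/correlation → cluster transitions → PSA/tornado → model
benchmarking → budget scenarios, writes CSV/JSON outputs in stable layouts
and records a manifest (config hash + per-file SHA-256); identical
configurations give identical bundles.  Stage seeds derive from the master
seed by fixed offsets (+1 models, +2 permutation, +3 PSA).

The test suite runs the statistical machinery at reduced problem sizes
chosen to keep the full suite comfortably on one CPU: neural-ODE tests use
4 RK4 steps and a few hundred epochs (the training dynamics are insensitive
to solver resolution at this smoothness), the model-ordering replication
uses the 3-point λ grid with a 2-member ensemble, permutation and PSA
calibration checks use reduced replicate counts where only calibration —
not precision — is at stake.  Defaults in the library remain at the
full-scale values (16 steps, 2000 epochs, M = 10,000, B = 1000).

## Known limitations

- Two observation times cannot identify trajectory shape between the
  endpoints; the curvature penalty imposes smoothness rather than inferring
  it.
- The LOCO comparison at N = 14 has high fold-to-fold variance; on a few
  seeds the held-out RMSE of the neural ODE approaches or exceeds the
  in-sample fixed-effects RMSE even under favourable dynamics.
- The ICER's ΔCost definition is a package convention (see above); other
  operationalizations shift the plane's x-axis but not the dominance
  classification on default panels.
- Heterogeneity weights from Monte-Carlo cost uncertainty understate true
  registry sampling variance; Q and τ² from the pipeline are therefore
  internally consistent but not comparable to registry-based values.
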