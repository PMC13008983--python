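# krtecon

Health-economic evaluation of kidney transplantation versus maintenance
dialysis across countries: per-patient cost–benefit and cost–utility
engines, a graph-regularized neural ODE for sparse two-point panels with
linear and fixed-effects baselines, cluster-transition dynamics,
meta-analytic heterogeneity statistics, probabilistic sensitivity analysis
and budget-impact scenarios — all driven by a seeded synthetic
country-panel generator, so every stage is testable without registry
downloads.

**Who it is for.**  Health economists and biostatisticians studying kidney
replacement therapy (KRT) policy: when does a transplant programme pay for
itself, how fast, how does that vary across systems, and what does scaling
volume buy?

## The models

Per patient, with annual dialysis cost `C_dial`, annual post-transplant
cost `C_post` and initial transplant episode cost `C_tx`:

```
Annual saving   S   = C_dial − C_post
Break-even      BE  = C_tx / S                      (years)
NPV(T)              = Σ_{t=1..T} S/(1+r)^t − C_tx   (r = 3%, T = 10 default)
ΔQALY(T)            = Σ_{t=1..T} [S_Tx(t)·u_Tx − S_dial(t)·u_dial]
ICER                = ΔCost / ΔQALY
```

with utility weights `u_Tx = 0.82`, `u_dial = 0.56` and modality-specific
survival `S_Tx, S_dial`.  Countries are clustered by break-even speed
(A < 2.5 y ≤ B < 4.0 y ≤ C) and their 2019→2023 transitions analysed with
Cohen's κ and a permutation stability test.  Cross-country heterogeneity
uses Cochran Q, I², DerSimonian–Laird τ² and a prediction interval.

The panel model is a neural ODE `dx_i/dt = f_θ(x_i, t)` over a
5-dimensional economic state per country, trained with a graph-smoothness
penalty `Σ_ij A_ij‖x_i−x_j‖²` on the exponential-kernel similarity of
economic feature vectors (`A_ij = exp(−‖z_i−z_j‖²/σ²)`, σ = 0.5) and a
trajectory-curvature penalty.  It is benchmarked against a static
break-even predictor and a two-way fixed-effects regression by RMSE,
AIC/BIC and leave-one-country-out R².  See `docs/methods.md` for the full
specification and design rationale.

## Worked example

```python
from krtecon import cba, cua

saving = cba.annual_saving(62_000, 25_000)          # 37000.0 USD/year
be     = cba.break_even(117_000, saving)            # 3.162 years
npv    = cba.npv(saving, cba.CBAParams(), 117_000)  # 198617.50 USD

traj = cba.cash_flow_trajectory(117_000, saving, 10)
print(traj.valley_depth, traj.valley_duration)      # -117000.0 4

gain = cua.annual_utility_gain(cua.UtilityWeights())  # 0.26 QALY/year
res  = cua.icer(-npv, 4.38)
print(res.quadrant, round(res.icer))                # I -45346
```

A patient whose system spends $62k/year on dialysis and $25k/year on
post-transplant care saves $37k annually; a $117k transplant episode pays
for itself in 3.16 years and returns ~$199k discounted over 10 years.
Cumulative cash flow is negative in years 0–3 (the "valley of death",
$117k deep at year 0).  With 4.38 QALYs gained the strategy is dominant
(Quadrant I): better outcomes at lower cost, ICER ≈ −$45k/QALY.

Full pipeline from the shell:

```bash
krt simulate --seed 1 --out panel.csv
krt cba --panel panel.csv --out outcomes.csv
krt all --seed 1 --outdir results/   # every stage + manifest
```

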