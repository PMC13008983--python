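"""Cross-country heterogeneity, subgroup contrasts, and sensitivity analyses.

Heterogeneity of break-even times across countries is quantified with the
meta-analytic toolkit: the Cochran statistic Q = sum_i w_i (BE_i - BE_w)^2
with inverse-variance weights and weighted mean BE_w; the inconsistency
I^2 = max{0, (Q - df)/Q} x 100 %; the DerSimonian-Laird moment estimator of
the between-country variance tau^2; and a prediction interval for a new
country, mu +/- 1.96 * sqrt(sigma^2 + tau^2) with sigma^2 the typical
(mean) within-country variance.

Subgroup analysis contrasts countries above versus at-or-below a 20 %
living-donor share with Welch's unequal-variance t-test; the continuous
association is a Pearson correlation.  Probabilistic sensitivity analysis
draws all three cost parameters from configurable (lognormal by default)
distributions and propagates them through the cost-benefit engine;
deterministic one-way sensitivity produces tornado-style NPV swings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cba import CBAParams, annuity_factor

__all__ = [
    "HeterogeneityResult",
    "SubgroupResult",
    "PSAResult",
    "CostDistribution",
    "PSADistributions",
    "cochran_q",
    "i_squared",
    "tau_squared_and_prediction_interval",
    "heterogeneity_summary",
    "subgroup_welch",
    "ld_correlation",
    "monte_carlo_psa",
    "tornado_analysis",
]


def cochran_q(be_values, weights) -> tuple[float, int]:
    """Cochran heterogeneity statistic and its degrees of freedom N - 1.

    Q = sum_i w_i (BE_i - BE_w)^2 around the weighted mean
    BE_w = sum_i w_i BE_i / sum_i w_i.  Q is *not* invariant to rescaling
    the weights — it scales linearly with them — so weights must be true
    inverse variances for the chi-square calibration to hold.
    """
    be = np.asarray(be_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if be.shape != w.shape:
        raise ValueError("be_values and weights must have equal length")
    if be.size < 2:
        raise ValueError("need at least 2 countries")
    if np.any(w <= 0):
        raise ValueError("all weights must be > 0")
    be_w = np.sum(w * be) / np.sum(w)
    q = float(np.sum(w * (be - be_w) ** 2))
    return q, be.size - 1


def i_squared(Q: float, df: int) -> float:
    """Inconsistency I^2 = max{0, (Q - df)/Q} * 100, in percent.

    Values near 100 % mean essentially all dispersion is genuine
    between-country difference rather than sampling error.  Clamped to
    [0, 100]; Q = 0 returns 0.
    """
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q == 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q * 100.0))


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    i2: float
    i2_rounded: int
    tau2: float
    tau2_clamped: bool
    mu: float
    prediction_interval: tuple[float, float]


def tau_squared_and_prediction_interval(
    be_values, weights, mu: float | None = None
) -> tuple[float, tuple[float, float], bool]:
    """DerSimonian-Laird tau^2 and the new-country prediction interval.

    tau^2 = max{0, (Q - df) / C} with C = sum w - sum w^2 / sum w; negative
    moment estimates are clamped to zero and flagged.  The interval is
    mu +/- 1.96 * sqrt(sigma^2 + tau^2), where sigma^2 is the mean
    within-country variance (the mean of 1/w_i) and mu defaults to the
    inverse-variance weighted mean.
    """
    be = np.asarray(be_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if be.size < 3:
        raise ValueError("need at least 3 countries")
    q, df = cochran_q(be, w)
    sw = np.sum(w)
    c = sw - np.sum(w**2) / sw
    raw = (q - df) / c if c > 0 else 0.0
    clamped = raw < 0
    tau2 = max(0.0, float(raw))
    if mu is None:
        mu = float(np.sum(w * be) / sw)
    sigma2 = float(np.mean(1.0 / w))
    half = 1.96 * np.sqrt(sigma2 + tau2)
    return tau2, (float(mu - half), float(mu + half)), clamped


def heterogeneity_summary(be_values, weights) -> HeterogeneityResult:
    q, df = cochran_q(be_values, weights)
    i2 = i_squared(q, df)
    tau2, interval, clamped = tau_squared_and_prediction_interval(be_values, weights)
    w = np.asarray(weights, dtype=float)
    be = np.asarray(be_values, dtype=float)
    mu = float(np.sum(w * be) / np.sum(w))
    return HeterogeneityResult(
        Q=q, df=df, i2=i2, i2_rounded=int(round(i2)), tau2=tau2,
        tau2_clamped=clamped, mu=mu, prediction_interval=interval,
    )


@dataclass(frozen=True)
class SubgroupResult:
    mean_high: float
    mean_low: float
    n_high: int
    n_low: int
    ci_high: tuple[float, float]
    ci_low: tuple[float, float]
    difference: float  # mean_high - mean_low
    t: float
    welch_df: float
    p: float


def _group_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    se = x.std(ddof=1) / np.sqrt(len(x))
    tcrit = stats.t.ppf(0.5 + level / 2, df=len(x) - 1)
    return float(x.mean() - tcrit * se), float(x.mean() + tcrit * se)


def subgroup_welch(be_high, be_low) -> SubgroupResult:
    """Welch unequal-variance contrast of high- vs low-living-donor groups.

    The reported difference is mean(high) - mean(low); with faster payback
    in high-LD systems it is negative.  The Welch-Satterthwaite df is
    fractional and never exceeds n1 + n2 - 2.
    """
    high = np.asarray(be_high, dtype=float)
    low = np.asarray(be_low, dtype=float)
    if len(high) < 2 or len(low) < 2:
        raise ValueError("both subgroups need at least 2 countries")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    v1, v2 = high.var(ddof=1) / len(high), low.var(ddof=1) / len(low)
    if v1 + v2 == 0:
        welch_df = float(len(high) + len(low) - 2)
        t, p = 0.0, 1.0
    else:
        welch_df = (v1 + v2) ** 2 / (
            v1**2 / (len(high) - 1) + v2**2 / (len(low) - 1)
        )
    return SubgroupResult(
        mean_high=float(high.mean()), mean_low=float(low.mean()),
        n_high=len(high), n_low=len(low),
        ci_high=_group_ci(high), ci_low=_group_ci(low),
        difference=float(high.mean() - low.mean()),
        t=float(t), welch_df=float(welch_df), p=float(p),
    )


def ld_correlation(ld_shares, be_values) -> tuple[float, float]:
    """Pearson correlation of living-donor share and break-even, with p-value."""
    ld = np.asarray(ld_shares, dtype=float)
    be = np.asarray(be_values, dtype=float)
    if len(ld) < 3:
        raise ValueError("need at least 3 observations")
    if ld.std() == 0 or be.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(ld, be)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Probabilistic and deterministic sensitivity


@dataclass(frozen=True)
class CostDistribution:
    """Sampling distribution of one cost parameter (lognormal or normal)."""

    mean: float
    sd: float
    family: str = "lognormal"

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        if self.family == "lognormal":
            sigma2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=size)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size=size)
        raise ValueError(f"unknown distribution family: {self.family}")


@dataclass(frozen=True)
class PSADistributions:
    c_dialysis: CostDistribution
    c_post_tx: CostDistribution
    c_tx_initial: CostDistribution


@dataclass(frozen=True)
class PSAResult:
    M: int
    npv_mean: float
    npv_ci: tuple[float, float]
    prob_npv_positive: float
    be_mean: float
    be_ci: tuple[float, float]
    n_rejected: int
    seed: int
    npv_draws: np.ndarray = field(repr=False)
    be_draws: np.ndarray = field(repr=False)


def monte_carlo_psa(
    distributions: PSADistributions,
    params: CBAParams = CBAParams(),
    M: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo propagation of cost-parameter uncertainty.

    Each iteration samples the three cost parameters, then computes NPV and
    break-even via the cost-benefit identities.  Draws with non-positive
    dialysis cost, negative other costs, or non-positive annual saving
    (break-even undefined) are rejected and resampled, with the rejection
    count reported.  Interval estimates are 2.5/97.5 empirical percentiles.
    """
    if M < 1000:
        raise ValueError("M must be >= 1000")
    rng = np.random.default_rng(seed)
    npv_draws = np.empty(M)
    be_draws = np.empty(M)
    filled = 0
    rejected = 0
    annuity = annuity_factor(params.discount_rate, params.horizon)
    for _ in range(1000):
        need = M - filled
        if need == 0:
            break
        cd = distributions.c_dialysis.sample(rng, need)
        cp = distributions.c_post_tx.sample(rng, need)
        ct = distributions.c_tx_initial.sample(rng, need)
        saving = cd - cp
        ok = (cd > 0) & (cp >= 0) & (ct >= 0) & (saving > 0)
        rejected += int(need - ok.sum())
        k = int(ok.sum())
        npv_draws[filled:filled + k] = saving[ok] * annuity - ct[ok]
        be_draws[filled:filled + k] = ct[ok] / saving[ok]
        filled += k
    if filled < M:
        raise ValueError("sampling distributions reject almost all draws")
    npv_ci = np.percentile(npv_draws, [2.5, 97.5])
    be_ci = np.percentile(be_draws, [2.5, 97.5])
    return PSAResult(
        M=M,
        npv_mean=float(npv_draws.mean()),
        npv_ci=(float(npv_ci[0]), float(npv_ci[1])),
        prob_npv_positive=float(np.mean(npv_draws > 0)),
        be_mean=float(be_draws.mean()),
        be_ci=(float(be_ci[0]), float(be_ci[1])),
        n_rejected=rejected,
        seed=seed,
        npv_draws=npv_draws,
        be_draws=be_draws,
    )


DEFAULT_TORNADO = [
    ("c_dialysis -20%", {"c_dialysis": 0.8}, {}),
    ("c_dialysis +20%", {"c_dialysis": 1.2}, {}),
    ("discount_rate 0%", {}, {"discount_rate": 0.0}),
    ("discount_rate 5%", {}, {"discount_rate": 0.05}),
    ("c_tx_initial -20%", {"c_tx_initial": 0.8}, {}),
    ("c_tx_initial +20%", {"c_tx_initial": 1.2}, {}),
]


def tornado_analysis(
    base: dict[str, float],
    params: CBAParams = CBAParams(),
    perturbations: list[tuple[str, dict, dict]] | None = None,
) -> pd.DataFrame:
    """One-way NPV sensitivity: each row perturbs one parameter, others at base.

    ``base`` holds c_dialysis, c_post_tx, c_tx_initial.  Each perturbation is
    (label, cost multipliers, CBAParams overrides).  Rows are ordered by the
    absolute NPV swing from the base case.
    """
    perturbations = DEFAULT_TORNADO if perturbations is None else perturbations
    if not perturbations:
        raise ValueError("perturbation list must be non-empty")

    def npv_at(mult: dict, overrides: dict) -> float:
        cd = base["c_dialysis"] * mult.get("c_dialysis", 1.0)
        cp = base["c_post_tx"] * mult.get("c_post_tx", 1.0)
        ct = base["c_tx_initial"] * mult.get("c_tx_initial", 1.0)
        p = CBAParams(
            discount_rate=overrides.get("discount_rate", params.discount_rate),
            horizon=overrides.get("horizon", params.horizon),
        )
        return (cd - cp) * annuity_factor(p.discount_rate, p.horizon) - ct

    base_npv = npv_at({}, {})
    rows = []
    for label, mult, overrides in perturbations:
        npv = npv_at(mult, overrides)
        rows.append({"parameter": label, "npv": npv, "delta": npv - base_npv})
    df = pd.DataFrame(rows)
    df["abs_swing"] = df["delta"].abs()
    df = df.sort_values("abs_swing", ascending=False, ignore_index=True)
    df.attrs["base_npv"] = base_npv
    return df
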