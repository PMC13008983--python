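"""End-to-end orchestration: panel -> economics -> models -> dynamics -> reports.

``run_pipeline`` sequences every analysis stage on one panel (synthetic by
default, or a CSV supplied by the caller), writes the tabular outputs in
stable layouts, and records a manifest with the config hash and per-file
checksums so identical configurations reproduce identical bundles.

Stage order: panel generation, per-country-year economics (cost-benefit and
cost-utility), heterogeneity and subgroup statistics, cluster transition
dynamics, probabilistic/deterministic sensitivity, model benchmarking
(neural ODE vs baselines, optional — it dominates runtime), and
budget-impact scenarios.  Each random stage derives its seed from the master
seed by a fixed offset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, cba, clusters, cua, grnode, heterogeneity as het
from .panel import (
    PanelConfig,
    generate_panel,
    generate_survival_curves,
    read_panel_csv,
    write_panel_csv,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "RunManifest",
    "run_pipeline",
    "economic_outcomes",
    "read_panel_csv",
]

# fixed seed offsets for the random stages
_SEED_GRNODE = 1
_SEED_PERMUTATION = 2
_SEED_PSA = 3


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and carries the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    panel: PanelConfig = field(default_factory=PanelConfig)
    cba_params: cba.CBAParams = field(default_factory=cba.CBAParams)
    utilities: cua.UtilityWeights = field(default_factory=cua.UtilityWeights)
    thresholds: tuple[float, float] = clusters.DEFAULT_THRESHOLDS
    grnode: grnode.GRNODEConfig = field(default_factory=grnode.GRNODEConfig)
    phis: tuple[float, ...] = (1.10, 1.25, 1.50)
    psa_m: int = 10_000
    psa_cv: float = 0.10  # coefficient of variation of the PSA cost distributions
    permutation_m: int = 10_000
    run_models: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict[str, dict[str, str]]


@dataclass
class PipelineResult:
    panel: pd.DataFrame
    outcomes: pd.DataFrame
    summary: pd.DataFrame
    heterogeneity: het.HeterogeneityResult
    subgroup: het.SubgroupResult
    correlation: tuple[float, float]
    transition: clusters.TransitionMatrix
    kappa: clusters.KappaResult
    transition_stats: clusters.TransitionStats
    stability_test: clusters.StabilityTestResult
    psa: het.PSAResult
    tornado: pd.DataFrame
    budget: list[cba.BudgetImpactResult]
    comparison: baselines.ComparisonReport | None
    grnode_fit: grnode.FitResult | None
    loco: grnode.LocoCVResult | None
    manifest: RunManifest | None = None


def economic_outcomes(
    panel: pd.DataFrame,
    params: cba.CBAParams,
    utilities: cua.UtilityWeights,
    survival_curves,
    thresholds=clusters.DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-country-year derived economics: saving, BE, NPV, dQALY, ICER, cluster.

    The incremental cost on the cost-effectiveness plane is the negative of
    the discounted net saving (transplant minus avoided dialysis spending
    over the horizon), so a positive NPV maps to dCost < 0.
    """
    rows = []
    dqaly = cua.cumulative_delta_qaly(utilities, survival_curves, params.horizon)
    for _, rec in panel.iterrows():
        saving = cba.annual_saving(rec["c_dialysis"], rec["c_post_tx"])
        be = cba.break_even(rec["c_tx_initial"], saving)
        npv_value = cba.npv(saving, params, rec["c_tx_initial"])
        ce = cua.icer(-npv_value, dqaly)
        rows.append({
            "country_id": rec["country_id"],
            "year": rec["year"],
            "annual_saving": saving,
            "break_even": be,
            "npv": npv_value,
            "delta_qaly": dqaly,
            "delta_cost": ce.delta_cost,
            "icer": ce.icer,
            "quadrant": ce.quadrant,
            "cost_effective": ce.cost_effective,
            "cluster": clusters.assign_cluster(be, thresholds),
            "ld_share": rec["ld_share"],
            "volume_ld": rec["volume_ld"],
        })
    return pd.DataFrame(rows)


def _summary_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    cols = {
        "Annual saving (USD)": "annual_saving",
        "Break-even time (years)": "break_even",
        "10-Year NPV (USD)": "npv",
        "Incremental QALY (10-year)": "delta_qaly",
        "Annual transplant volume (living donor)": "volume_ld",
    }
    rows = []
    for label, col in cols.items():
        x = outcomes[col].to_numpy(dtype=float)
        rows.append({"Variable": label, "Mean": x.mean(), "SD": x.std(ddof=1),
                     "Min": x.min(), "Max": x.max()})
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
    panel: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every stage; write the output bundle when ``outdir`` is given."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage '{name}' failed: {err}") from err

    if panel is None:
        panel = stage("generate_panel", generate_panel, config.panel)
    curves = stage(
        "survival", generate_survival_curves,
        config.panel.survival_spec, config.cba_params.horizon,
    )
    outcomes = stage(
        "economics", economic_outcomes,
        panel, config.cba_params, config.utilities, curves, config.thresholds,
    )
    summary = _summary_table(outcomes)

    years = sorted(outcomes["year"].unique())
    latest = outcomes[outcomes["year"] == years[-1]].set_index("country_id")
    # Country-level analyses (heterogeneity, subgroup, correlation) use each
    # country's mean break-even across the observation years: the stratifying
    # characteristics are country attributes, and the panel mean is the
    # country-level summary the cross-sectional statistics describe.
    country = outcomes.groupby("country_id").agg(
        break_even=("break_even", "mean"), ld_share=("ld_share", "first")
    )

    # Heterogeneity: inverse-variance weights from each country's Monte-Carlo
    # cost uncertainty at the configured CV.
    def _heterogeneity():
        be = country["break_even"]
        variances = []
        mean_costs = panel.groupby("country_id")[
            ["c_dialysis", "c_post_tx", "c_tx_initial"]
        ].mean()
        for cid in be.index:
            rec = mean_costs.loc[cid]
            dists = het.PSADistributions(
                c_dialysis=het.CostDistribution(rec["c_dialysis"], config.psa_cv * rec["c_dialysis"]),
                c_post_tx=het.CostDistribution(rec["c_post_tx"], config.psa_cv * rec["c_post_tx"]),
                c_tx_initial=het.CostDistribution(rec["c_tx_initial"], config.psa_cv * rec["c_tx_initial"]),
            )
            res = het.monte_carlo_psa(dists, config.cba_params, M=1000,
                                      seed=config.seed + _SEED_PSA)
            variances.append(np.var(res.be_draws))
        weights = 1.0 / np.asarray(variances)
        return het.heterogeneity_summary(be.to_numpy(), weights)

    heterogeneity_result = stage("heterogeneity", _heterogeneity)

    def _subgroup():
        high = country.loc[country["ld_share"] > 20.0, "break_even"]
        low = country.loc[country["ld_share"] <= 20.0, "break_even"]
        return het.subgroup_welch(high, low)

    subgroup = stage("subgroup", _subgroup)
    correlation = stage(
        "correlation", het.ld_correlation,
        country["ld_share"], country["break_even"],
    )

    def _clusters():
        first = outcomes[outcomes["year"] == years[0]].set_index("country_id")
        a1 = first["cluster"]
        a2 = latest["cluster"]
        tm = clusters.transition_matrix(a1, a2)
        return (
            tm,
            clusters.cohen_kappa(tm),
            clusters.transition_stats(tm),
            clusters.permutation_stability_test(
                a1, a2, M=config.permutation_m,
                seed=config.seed + _SEED_PERMUTATION,
            ),
        )

    tm, kappa, tstats, stability = stage("clusters", _clusters)

    def _sensitivity():
        mean_cd = panel["c_dialysis"].mean()
        mean_cp = panel["c_post_tx"].mean()
        mean_ct = panel["c_tx_initial"].mean()
        dists = het.PSADistributions(
            c_dialysis=het.CostDistribution(mean_cd, config.psa_cv * mean_cd),
            c_post_tx=het.CostDistribution(mean_cp, config.psa_cv * mean_cp),
            c_tx_initial=het.CostDistribution(mean_ct, config.psa_cv * mean_ct),
        )
        psa = het.monte_carlo_psa(dists, config.cba_params, M=config.psa_m,
                                  seed=config.seed + _SEED_PSA)
        tornado = het.tornado_analysis(
            {"c_dialysis": mean_cd, "c_post_tx": mean_cp, "c_tx_initial": mean_ct},
            config.cba_params,
        )
        return psa, tornado

    psa, tornado = stage("sensitivity", _sensitivity)

    comparison = grnode_fit = loco = None
    if config.run_models:
        def _models():
            from dataclasses import replace
            gcfg = replace(config.grnode, seed=config.seed + _SEED_GRNODE)
            fit = grnode.train(panel, gcfg)
            loco_res = grnode.loco_cv(panel, gcfg)
            obs = baselines.observed_break_even(panel)
            lin_pred = baselines.linear_cba_predict(panel)
            # the economic features are time-invariant, hence collinear with
            # the country effects; the FE baseline runs without covariates
            fe = baselines.fit_fixed_effects(panel)
            K = len(panel)
            lin_rss = float(np.sum((obs - lin_pred) ** 2))
            node_obs = fit.states.be_observed_2023
            node_pred = fit.predicted_be_2023.to_numpy()
            node_rss = float(np.sum((node_obs - node_pred) ** 2))
            n_eff = grnode.count_parameters(
                fit.states.x0.shape[1], 1, config.grnode.hidden
            )
            metrics = {
                "Linear CBA": dict(
                    rmse=baselines.rmse(obs, lin_pred),
                    aic=baselines.information_criteria(lin_rss, K, 1)[0],
                    bic=baselines.information_criteria(lin_rss, K, 1)[1],
                    loocv_r2=grnode.r_squared(obs, lin_pred),
                ),
                "Fixed Effects Panel": dict(
                    rmse=baselines.rmse(obs, fe.predictions),
                    aic=baselines.information_criteria(fe.rss, K, fe.n_params)[0],
                    bic=baselines.information_criteria(fe.rss, K, fe.n_params)[1],
                    loocv_r2=grnode.r_squared(obs, fe.predictions),
                ),
                "GR-NODE": dict(
                    rmse=loco_res.rmse,
                    aic=baselines.information_criteria(node_rss, len(node_obs), n_eff)[0],
                    bic=baselines.information_criteria(node_rss, len(node_obs), n_eff)[1],
                    loocv_r2=loco_res.r2,
                ),
            }
            return baselines.comparison_report(metrics), fit, loco_res

        comparison, grnode_fit, loco = stage("models", _models)

    def _budget():
        vol0 = float(panel.loc[panel["year"] == years[-1], "volume_ld"].sum())
        saving = float(
            outcomes.loc[outcomes["year"] == years[-1], "annual_saving"].mean()
        )
        s1 = float(curves.s_tx[0])
        results = []
        for phi in config.phis:
            scenario = cba.ScenarioConfig(phi=phi, vol0=vol0,
                                          annual_saving=saving, s1=s1)
            results.append(cba.budget_impact(scenario, config.cba_params))
        return results

    budget = stage("budget", _budget)

    result = PipelineResult(
        panel=panel, outcomes=outcomes, summary=summary,
        heterogeneity=heterogeneity_result, subgroup=subgroup,
        correlation=correlation, transition=tm, kappa=kappa,
        transition_stats=tstats, stability_test=stability,
        psa=psa, tornado=tornado, budget=budget,
        comparison=comparison, grnode_fit=grnode_fit, loco=loco,
    )
    if outdir is not None:
        result.manifest = export_tables(result, config, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# Export


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def export_tables(result: PipelineResult, config: PipelineConfig,
                  outdir: Path) -> RunManifest:
    """Write the output bundle (CSV/JSON, stable layouts) and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["panel"] = outdir / "panel.csv"
    write_panel_csv(result.panel, paths["panel"])

    paths["outcomes"] = outdir / "outcomes.csv"
    result.outcomes.to_csv(paths["outcomes"], index=False, float_format="%.17g")

    paths["summary"] = outdir / "summary_statistics.csv"
    result.summary.to_csv(paths["summary"], index=False, float_format="%.2f")

    paths["transition"] = outdir / "transition_matrix.csv"
    result.transition.to_frame().to_csv(paths["transition"])

    het_payload = {
        "cochran_q": result.heterogeneity.Q,
        "df": result.heterogeneity.df,
        "i_squared_percent": result.heterogeneity.i2,
        "i_squared_rounded": result.heterogeneity.i2_rounded,
        "tau_squared": result.heterogeneity.tau2,
        "prediction_interval_years": list(result.heterogeneity.prediction_interval),
        "kappa": result.kappa.kappa,
        "kappa_interpretation": result.kappa.interpretation,
        "stability": {
            "observed": result.stability_test.observed,
            "null_mean": result.stability_test.null_mean,
            "null_sd": result.stability_test.null_sd,
            "z": result.stability_test.z,
            "p_one_tailed": result.stability_test.p_one_tailed,
            "M": result.stability_test.M,
        },
    }
    paths["heterogeneity"] = outdir / "heterogeneity.json"
    paths["heterogeneity"].write_text(
        json.dumps(het_payload, indent=2, default=_json_default)
    )

    sub = result.subgroup
    subgroup_payload = {
        "high_ld": {"mean_be": sub.mean_high, "n": sub.n_high, "ci": list(sub.ci_high)},
        "low_ld": {"mean_be": sub.mean_low, "n": sub.n_low, "ci": list(sub.ci_low)},
        "difference_high_minus_low": sub.difference,
        "welch_t": sub.t, "welch_df": sub.welch_df, "p": sub.p,
        "pearson_r": result.correlation[0], "pearson_p": result.correlation[1],
    }
    paths["subgroup"] = outdir / "subgroup.json"
    paths["subgroup"].write_text(
        json.dumps(subgroup_payload, indent=2, default=_json_default)
    )

    psa_payload = {
        "M": result.psa.M,
        "npv_mean": result.psa.npv_mean,
        "npv_ci": list(result.psa.npv_ci),
        "prob_npv_positive": result.psa.prob_npv_positive,
        "be_mean": result.psa.be_mean,
        "be_ci": list(result.psa.be_ci),
    }
    paths["sensitivity"] = outdir / "sensitivity.json"
    paths["sensitivity"].write_text(
        json.dumps(psa_payload, indent=2, default=_json_default)
    )
    paths["tornado"] = outdir / "tornado.csv"
    result.tornado.to_csv(paths["tornado"], index=False, float_format="%.6g")

    budget_payload = [
        {"phi": b.phi, "annual_increment_usd": b.annual_increment,
         "cumulative_discounted_usd": b.cumulative_discounted}
        for b in result.budget
    ]
    paths["budget"] = outdir / "budget_impact.json"
    paths["budget"].write_text(
        json.dumps(budget_payload, indent=2, default=_json_default)
    )

    if result.comparison is not None:
        paths["model_comparison"] = outdir / "model_comparison.csv"
        result.comparison.metrics.to_csv(paths["model_comparison"],
                                         float_format="%.6g")
        paths["loss_trace"] = outdir / "grnode_loss_trace.csv"
        result.grnode_fit.loss_trace.to_csv(paths["loss_trace"],
                                            index_label="epoch",
                                            float_format="%.10g")

    outputs = {}
    for name, path in paths.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        outputs[name] = {"path": str(path), "sha256": digest}
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, outputs=outputs
    )
    (outdir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2)
    )
    return manifest
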