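"""End-to-end staged model building for censored concentration surveys.

The workflow mirrors how such analyses are done in practice: decluster the
sites into quasi-independent subsets, fit a deliberately overfitted
comprehensive model, check residual diagnostics and the Weibull
probability plot, tabulate adjusted-LR significance of every factor group,
eliminate insignificant groups backwards (largest adjusted p first,
re-testing after each deletion), and report the final model with
multiplicative effects.  Held-out validation data are scored with the
frozen calibration design metadata — never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import PRE_HOLOCENE_CODES, Dataset
from .design_matrix import ModelSpec, build_design
from .robust_inference import sandwich_covariance, term_deletion_table
from .spatial_blocks import ClusterAssignment, decluster_sites, residual_variogram
from .weibull_grm import (
    WeibullFit,
    deviance_residuals,
    fit_weibull_grm,
    generalized_r2,
    multiplicative_effect,
    weibull_probability_points,
)

__all__ = ["PipelineOptions", "PipelineReport", "run_grm_pipeline",
           "regional_subset", "score_validation"]


@dataclass(frozen=True)
class PipelineOptions:
    link_threshold_km: float = 25.0
    max_subset_size: int = 50
    drop_p_threshold: float = 0.05
    borderline_p: float = 0.10            # blocks with p below this may be kept
    keep_borderline: tuple[str, ...] = () # factor names protected when borderline
    variogram_bin_km: float = 5.0
    variogram_max_lag_km: float = 100.0
    metric: str = "haversine"
    max_elimination_rounds: int = 30


@dataclass
class PipelineReport:
    clusters: ClusterAssignment
    comprehensive_fit: WeibullFit
    final_fit: WeibullFit
    final_spec: ModelSpec
    lr_table: pd.DataFrame                 # comprehensive-model deletion table
    final_lr_table: pd.DataFrame
    effects: pd.DataFrame                  # per-term multiplicative effects
    residual_summary: dict
    probability_plot_slope: float
    variogram: pd.DataFrame
    generalized_r2: float
    dropped: list[str] = field(default_factory=list)
    validation_summary: dict | None = None


def regional_subset(ds: Dataset, excluded_geology=PRE_HOLOCENE_CODES) -> Dataset:
    """Restrict a survey to the high-concentration (Holocene) geology by
    excluding the listed units (defaults: rb, rm, br)."""
    geo = ds.joined()["geology"]
    mask = ~geo.isin(set(excluded_geology))
    if not mask.any():
        raise ValueError("no observations left after geology exclusion")
    return ds.subset(mask.to_numpy())


def _residual_stats(resid: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(resid)),
        "sd": float(np.std(resid, ddof=1)),
        "fraction_within_2": float(np.mean(np.abs(resid) <= 2.0)),
        "n": int(len(resid)),
    }


def score_validation(fit: WeibullFit, validation: Dataset) -> dict:
    """Deviance-residual summary of held-out data under a frozen fit."""
    design = build_design(
        fit.spec, validation,
        bbox=fit.design.bbox,
        category_levels=fit.design.category_levels,
        validate_rank=False,
    )
    t, delta, _ = validation.response
    mu = np.exp(design.X @ fit.beta)
    scoring_fit = WeibullFit(
        beta=fit.beta, alpha_hat=fit.alpha_hat, loglik=np.nan,
        naive_cov=fit.naive_cov, design=design, fitted_mu=mu,
        convergence=fit.convergence, spec=fit.spec,
    )
    resid = deviance_residuals(scoring_fit, t, delta)
    out = _residual_stats(resid)
    out["residuals"] = resid
    return out


def _effect_table(fit: WeibullFit) -> pd.DataFrame:
    """Per-unit multiplicative effects for every continuous main effect,
    reporting both percent conventions."""
    rows = []
    blocks = fit.design.term_blocks
    for term, idx in blocks.items():
        if term == "intercept" or ":" in term or len(idx) != 1:
            continue
        b = float(fit.beta[idx[0]])
        eff = multiplicative_effect(b)
        rows.append({
            "term": term, "coef": b, "factor": eff["factor"],
            "percent_exact": eff["percent_change_exact"],
            "percent_abs_beta": eff["percent_change_abs_beta"],
            "direction": eff["direction"],
        })
    return pd.DataFrame(rows)


def run_grm_pipeline(
    data: Dataset,
    spec: ModelSpec,
    validation: Dataset | None = None,
    clusters: ClusterAssignment | None = None,
    options: PipelineOptions = PipelineOptions(),
) -> PipelineReport:
    """Run decluster → fit → diagnostics → deletion table → backward
    elimination → final effects, returning a :class:`PipelineReport`.

    When ``clusters`` is omitted they are computed from the data
    coordinates; sites removed by declustering are dropped from the
    calibration fit (they remain available to the caller for validation).
    """
    opt = options
    sv = data.survey
    if clusters is None:
        clusters = decluster_sites(
            sv["site_id"], sv["lon"], sv["lat"],
            link_threshold_km=opt.link_threshold_km,
            max_subset_size=opt.max_subset_size,
            metric=opt.metric,
        )
    retained = sv["site_id"].isin(clusters.labels.index).to_numpy()
    cal = data.subset(retained) if not retained.all() else data

    # comprehensive fit + robust covariance
    fit_full = fit_weibull_grm(spec, cal)
    sw = sandwich_covariance(fit_full, cal, clusters)

    # diagnostics
    t, delta, _ = cal.response
    resid = deviance_residuals(fit_full, t, delta)
    res_stats = _residual_stats(resid)
    _, _, pp_slope = weibull_probability_points(t, delta)
    vg = residual_variogram(
        resid, cal.survey["lon"], cal.survey["lat"],
        bin_width_km=opt.variogram_bin_km,
        max_lag_km=opt.variogram_max_lag_km,
        metric=opt.metric,
    ).to_frame()
    null_fit = fit_weibull_grm(ModelSpec(name="null"), cal)
    r2 = generalized_r2(fit_full.loglik, null_fit.loglik, len(cal))

    # factor significance on the comprehensive model
    lr_table = term_deletion_table(spec, cal, clusters,
                                   fit_full=fit_full, sandwich=sw)

    # backward elimination: drop the least significant group, re-test
    cur_spec, cur_fit, cur_table = spec, fit_full, lr_table
    dropped: list[str] = []
    for _ in range(opt.max_elimination_rounds):
        ok = cur_table[cur_table["status"] == "ok"]
        weak = ok[ok["p_adjusted"] > opt.drop_p_threshold]
        weak = weak[~(
            weak["factor"].isin(opt.keep_borderline)
            & (weak["p_adjusted"] < opt.borderline_p)
        )]
        if weak.empty:
            break
        factor = weak.sort_values("p_adjusted", ascending=False)["factor"].iloc[0]
        block = factor.split(" and ")[0] if " and " in factor else factor
        cur_spec = cur_spec.drop_block(block)
        if not (cur_spec.continuous_terms or cur_spec.categorical_terms
                or cur_spec.spatial_poly_degree or cur_spec.seasonal):
            cur_fit = fit_weibull_grm(cur_spec, cal)
            cur_table = cur_table.iloc[0:0]
            dropped.append(factor)
            break
        cur_fit = fit_weibull_grm(cur_spec, cal)
        cur_sw = sandwich_covariance(cur_fit, cal, clusters)
        cur_table = term_deletion_table(cur_spec, cal, clusters,
                                        fit_full=cur_fit, sandwich=cur_sw)
        dropped.append(factor)

    report = PipelineReport(
        clusters=clusters,
        comprehensive_fit=fit_full,
        final_fit=cur_fit,
        final_spec=cur_spec,
        lr_table=lr_table,
        final_lr_table=cur_table,
        effects=_effect_table(cur_fit),
        residual_summary=res_stats,
        probability_plot_slope=pp_slope,
        variogram=vg,
        generalized_r2=r2,
        dropped=dropped,
    )
    if validation is not None:
        report.validation_summary = score_validation(cur_fit, validation)
    return report
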