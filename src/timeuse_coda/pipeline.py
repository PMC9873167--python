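"""End-to-end analysis: person-day table in, estimates and CIs out.

Mirrors the published analysis flow: exclude zero-part days, combine
population weights with day-of-week uniformisation factors, fit one
compositional regression per survey wave, derive whole-sample compositional
means and per-category least-squares means, between-wave changes in min/day,
covariate x wave interaction p-values, and percentile bootstrap confidence
intervals that re-run the whole reweight-and-fit pipeline on every resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda_core import (
    DAY_HOURS,
    DEFAULT_BASIS,
    PART_COLUMNS,
    IlrBasis,
    VariationMatrix,
    compositional_mean,
    variation_matrix,
)
from .diary import ExclusionReport, apply_exclusions
from .regression import (
    DEFAULT_MARGINS,
    DEFAULT_PREDICTORS,
    BootstrapResult,
    RegressionModel,
    bootstrap_cis,
    fit,
    interaction_test,
    wave_difference,
)
from .weighting import uniformise_day_of_week

logger = logging.getLogger(__name__)

WHOLE_SAMPLE = "whole_sample"


@dataclass
class AnalysisResults:
    """Everything the reporting layer needs, as plain DataFrames."""

    means: pd.DataFrame           # wave x parts (+ CI columns when bootstrapped)
    ls_means: pd.DataFrame        # variable, category, wave, n, pct, parts (+ CIs)
    changes: pd.DataFrame         # scope rows, per-part d min/day (+ CIs), interaction p
    interactions: pd.DataFrame    # variable, statistic, value, p
    variation: dict[object, VariationMatrix]
    exclusions: ExclusionReport
    models: dict[object, RegressionModel] = field(repr=False, default_factory=dict)
    bootstrap: BootstrapResult | None = field(repr=False, default=None)
    summary: dict = field(default_factory=dict)


def _estimate_frame(
    data: pd.DataFrame,
    predictors,
    variables,
    basis: IlrBasis,
    dow_uniform: bool,
    total: float,
    margins: str = DEFAULT_MARGINS,
) -> tuple[list[str], np.ndarray, dict[object, RegressionModel]]:
    """One pass of reweight + fit + back-transform; fixed estimand layout."""
    weighted = uniformise_day_of_week(data, enabled=dow_uniform)
    waves = sorted(pd.unique(weighted["wave"]))
    names: list[str] = []
    values: list[float] = []
    models: dict[object, RegressionModel] = {}
    means: dict[object, np.ndarray] = {}
    ls: dict[tuple[str, str, object], np.ndarray] = {}

    for w in waves:
        sub = weighted[weighted["wave"] == w]
        means[w] = compositional_mean(
            sub[list(PART_COLUMNS)].to_numpy(), sub["final_weight"].to_numpy(), total=total
        )
        models[w] = fit(sub, predictors, basis=basis, wave=w, total=total)
        for col, v in zip(PART_COLUMNS, means[w]):
            names.append(f"mean|{w}|{col}")
            values.append(v)
    for var in variables:
        for w in waves:
            for cat in models[w].levels[var]:
                comp = models[w].ls_mean_composition(var, cat, margins)
                ls[(var, cat, w)] = comp
                for col, v in zip(PART_COLUMNS, comp):
                    names.append(f"ls|{var}|{cat}|{w}|{col}")
                    values.append(v)
    if len(waves) == 2:
        w0, w1 = waves
        d = wave_difference(means[w0], means[w1], total=total)
        for col, v in zip(PART_COLUMNS, d):
            names.append(f"d|{WHOLE_SAMPLE}||{col}")
            values.append(v)
        for var in variables:
            for cat in models[w0].levels[var]:
                d = wave_difference(ls[(var, cat, w0)], ls[(var, cat, w1)], total=total)
                for col, v in zip(PART_COLUMNS, d):
                    names.append(f"d|{var}|{cat}|{col}")
                    values.append(v)
    return names, np.asarray(values), models


def analyze_person_days(
    person_days: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    variables=None,
    basis: IlrBasis = DEFAULT_BASIS,
    B: int = 0,
    seed: int | None = None,
    dow_uniform: bool = True,
    statistic: str = "pillai",
    margins: str = DEFAULT_MARGINS,
    total: float = DAY_HOURS,
) -> AnalysisResults:
    """Run the full analysis.

    ``B >= 2`` adds percentile bootstrap CIs (participant resampling within
    wave, reweighting and refitting inside each replicate); ``B = 0`` skips
    them.  ``variables`` defaults to all predictors.
    """
    variables = list(variables if variables is not None else predictors)
    retained, report = apply_exclusions(person_days)

    def statistic_fn(df: pd.DataFrame):
        names, values, _ = _estimate_frame(df, predictors, variables, basis, dow_uniform, total, margins)
        return names, values

    names, values, models = _estimate_frame(
        retained, predictors, variables, basis, dow_uniform, total, margins
    )
    est = dict(zip(names, values))

    boot = None
    ci: dict[str, tuple[float, float]] = {}
    if B >= 2:
        boot = bootstrap_cis(statistic_fn, retained, B=B, seed=seed)
        ci = {n: (lo, hi) for n, lo, hi in zip(boot.names, boot.ci_low, boot.ci_high)}

    weighted = uniformise_day_of_week(retained, enabled=dow_uniform)
    waves = sorted(pd.unique(weighted["wave"]))
    variation = {
        w: variation_matrix(
            weighted.loc[weighted["wave"] == w, list(PART_COLUMNS)].to_numpy(),
            weighted.loc[weighted["wave"] == w, "final_weight"].to_numpy(),
        )
        for w in waves
    }

    inter_rows = []
    if len(waves) == 2:
        for var in variables:
            t = interaction_test(weighted, var, predictors, basis=basis, statistic=statistic)
            inter_rows.append(
                {"variable": var, "statistic": t.statistic, "value": t.value,
                 "f_value": t.f_value, "df1": t.df1, "df2": t.df2, "p_value": t.p_value}
            )
    interactions = pd.DataFrame(inter_rows)
    inter_p = {r["variable"]: r["p_value"] for r in inter_rows}

    def _with_ci(prefix: str, row: dict) -> dict:
        for col in PART_COLUMNS:
            key = f"{prefix}|{col}"
            row[col] = est[key]
            if key in ci:
                row[f"{col}_ci_low"], row[f"{col}_ci_high"] = ci[key]
        return row

    means = pd.DataFrame([_with_ci(f"mean|{w}", {"wave": w}) for w in waves])

    ls_rows = []
    for var in variables:
        for w in waves:
            sub = weighted[weighted["wave"] == w]
            wtot = sub.groupby(var)["final_weight"].sum()
            for cat in models[w].levels[var]:
                row = {
                    "variable": var,
                    "category": cat,
                    "wave": w,
                    "n": int((sub[var] == cat).sum()),
                    "pct": float(100.0 * wtot.get(cat, 0.0) / wtot.sum()),
                }
                ls_rows.append(_with_ci(f"ls|{var}|{cat}|{w}", row))
    ls_means = pd.DataFrame(ls_rows)

    change_rows = []
    if len(waves) == 2:
        change_rows.append(
            _change_row(WHOLE_SAMPLE, "", est, ci, interaction_p=None)
        )
        for var in variables:
            for cat in models[waves[0]].levels[var]:
                change_rows.append(_change_row(var, cat, est, ci, inter_p.get(var)))
    changes = pd.DataFrame(change_rows)

    summary = {
        "n_input": int(len(person_days)),
        "n_retained": int(report.n_retained),
        "waves": [int(w) if isinstance(w, (int, np.integer)) else w for w in waves],
        "predictors": list(predictors),
        "variables": variables,
        "basis": basis.name,
        "B": int(B),
        "seed": seed,
        "dow_uniform": bool(dow_uniform),
        "interaction_statistic": statistic,
        "ls_mean_margins": margins,
        "total_variance": {str(w): variation[w].total_variance for w in waves},
    }
    return AnalysisResults(
        means=means,
        ls_means=ls_means,
        changes=changes,
        interactions=interactions,
        variation=variation,
        exclusions=report,
        models=models,
        bootstrap=boot,
        summary=summary,
    )


def _change_row(scope_var, scope_cat, est, ci, interaction_p):
    row = {"variable": scope_var, "category": scope_cat}
    prefix = f"d|{scope_var}|{scope_cat}"
    for col in PART_COLUMNS:
        key = f"{prefix}|{col}"
        part = col.removesuffix("_h")
        row[f"d_{part}_min"] = est[key]
        if key in ci:
            row[f"d_{part}_ci_low"], row[f"d_{part}_ci_high"] = ci[key]
    row["interaction_p"] = interaction_p if interaction_p is not None else np.nan
    return row
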