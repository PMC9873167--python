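"""Compositional regression: ilr outcomes on categorical predictors.

The inferential engine behind the descriptive tables: per survey wave, a
weighted multivariate least-squares regression of the two ilr coordinates on
the sociodemographic covariates (main effects only, treatment coding).
From a fitted model:

* :func:`ls_means` — adjusted (least-squares) means per category: the
  predicted ilr pair with every *other* factor averaged over its levels —
  by default at the observed weighted level shares (proportional margins,
  the convention the published adjusted means follow; classical
  equal-weight margins are available via ``margins="equal"``) — then
  back-transformed and closed to 24 h;
* :func:`wave_difference` — per-behaviour change between waves in min/day
  (the three parts sum to zero by the closed 24 h budget);
* :func:`interaction_test` — Pillai's-trace test (Wilks optional) of the
  covariate x wave interaction on a pooled two-wave fit;
* :func:`bootstrap_cis` — percentile confidence intervals from resampling
  person-days with replacement, stratified by wave, re-running the whole
  pipeline (including day-of-week reweighting) on each replicate.

All reported quantities are invariant to the ilr basis choice; the test
suite asserts this across random bases.

Weights are treated as frequency/precision weights: point estimates use
weighted least squares, residual scatter matrices are weight-normalised, and
error degrees of freedom count observations (not weight mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda_core import (
    DAY_HOURS,
    DEFAULT_BASIS,
    PART_COLUMNS,
    PART_LABELS,
    IlrBasis,
    ilr,
    ilr_inverse,
)
from .errors import BootstrapError, EstimationError, UsageError
from .vocab import COVARIATES, COVARIATE_ORDER

DEFAULT_PREDICTORS: tuple[str, ...] = COVARIATE_ORDER


def factor_levels(df: pd.DataFrame, predictors) -> dict[str, tuple[str, ...]]:
    """Observed levels per predictor, in canonical vocabulary order where known.

    The first level is the reference.  A predictor observed at fewer than
    two levels cannot be estimated and raises.
    """
    levels: dict[str, tuple[str, ...]] = {}
    for var in predictors:
        if var not in df.columns:
            raise UsageError(f"predictor {var!r} not in data")
        observed = [str(v) for v in pd.unique(df[var])]
        canonical = COVARIATES.get(var)
        if canonical and set(observed) <= set(canonical):
            obs = tuple(l for l in canonical if l in observed)
        else:
            obs = tuple(observed)
        if len(obs) < 2:
            raise EstimationError(f"predictor {var!r} has fewer than 2 observed levels")
        levels[var] = obs
    return levels


def build_design(df: pd.DataFrame, levels: dict[str, tuple[str, ...]]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept.

    Columns: intercept, then for each factor a dummy per non-reference
    level, named ``factor[level]``.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for var, lv in levels.items():
        vals = df[var].astype(str).to_numpy()
        for level in lv[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"{var}[{level}]")
    return np.column_stack(cols), names


def _check_rank(xw: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(xw, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(xw.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise EstimationError(f"rank-deficient design; aliased columns: {bad}")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, names: list[str]):
    sw = np.sqrt(w)
    xw = x * sw[:, None]
    _check_rank(xw, names)
    coef, *_ = np.linalg.lstsq(xw, y * sw[:, None], rcond=None)
    resid = y - x @ coef
    return coef, resid


#: how the levels of the *other* factors are averaged in an LS mean:
#: "observed" weights them by their weighted sample shares (the convention
#: the published adjusted means follow), "equal" weights every level equally
#: (the classical textbook LS mean).
DEFAULT_MARGINS = "observed"


@dataclass
class RegressionModel:
    """Fitted weighted multivariate regression of ilr coordinates."""

    wave: object
    levels: dict[str, tuple[str, ...]]
    columns: list[str]
    coef: np.ndarray  # (k, 2)
    resid_cov: np.ndarray  # (2, 2), weight-normalised
    n_obs: int
    weighted_n: float
    basis: IlrBasis
    total: float = DAY_HOURS
    # weighted observed share of each level, per factor (margin weights)
    level_shares: dict[str, np.ndarray] = field(repr=False, default=None)
    # sandwich kernel A^-1 (X'W^2 X) A^-1 with A = X'WX, for margin SEs
    cov_kernel: np.ndarray = field(repr=False, default=None)

    def margin_vector(self, variable: str, category: str, margins: str = DEFAULT_MARGINS) -> np.ndarray:
        """Design-space vector of the LS-mean margin for ``variable=category``."""
        if variable not in self.levels:
            raise UsageError(f"variable {variable!r} not in the model")
        if category not in self.levels[variable]:
            raise UsageError(f"unknown category {category!r} for {variable!r}")
        if margins not in ("equal", "observed"):
            raise UsageError(f"margins must be 'equal' or 'observed', got {margins!r}")
        m = np.zeros(len(self.columns))
        m[0] = 1.0
        for var, lv in self.levels.items():
            shares = (
                self.level_shares[var]
                if margins == "observed"
                else np.full(len(lv), 1.0 / len(lv))
            )
            for i, level in enumerate(lv):
                if i == 0:
                    continue  # reference level has no column
                j = self.columns.index(f"{var}[{level}]")
                if var == variable:
                    m[j] = 1.0 if level == category else 0.0
                else:
                    m[j] = shares[i]
        return m

    def ls_mean_ilr(self, variable: str, category: str, margins: str = DEFAULT_MARGINS) -> np.ndarray:
        return self.margin_vector(variable, category, margins) @ self.coef

    def ls_mean_composition(
        self, variable: str, category: str, margins: str = DEFAULT_MARGINS
    ) -> np.ndarray:
        return ilr_inverse(self.ls_mean_ilr(variable, category, margins), self.basis, self.total)

    def margin_ilr_covariance(
        self, variable: str, category: str, margins: str = DEFAULT_MARGINS
    ) -> np.ndarray:
        """Approximate 2x2 sampling covariance of the LS-mean ilr pair."""
        m = self.margin_vector(variable, category, margins)
        return float(m @ self.cov_kernel @ m) * self.resid_cov


def fit(
    data: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    basis: IlrBasis = DEFAULT_BASIS,
    weight_col: str = "final_weight",
    wave: object = None,
    total: float = DAY_HOURS,
) -> RegressionModel:
    """Weighted least squares of the ilr coordinates on categorical predictors.

    Both coordinates share one design matrix, so this is equivalently a
    multivariate WLS; with an empty predictor list it is the intercept-only
    model, whose back-transformed intercept equals the weighted
    compositional mean of the data.
    """
    if len(data) == 0:
        raise EstimationError("cannot fit on an empty dataset")
    levels = factor_levels(data, predictors)
    x, names = build_design(data, levels)
    y = ilr(data[list(PART_COLUMNS)].to_numpy(), basis)
    w = data[weight_col].to_numpy(dtype=float) if weight_col in data.columns else np.ones(len(data))
    if np.any(w <= 0):
        raise EstimationError("analysis weights must be strictly positive")
    coef, resid = _wls(x, y, w, names)
    wsum = w.sum()
    resid_cov = (resid * w[:, None]).T @ resid / wsum
    a_inv = np.linalg.inv(x.T @ (x * w[:, None]))
    cov_kernel = a_inv @ (x.T @ (x * (w**2)[:, None])) @ a_inv
    level_shares = {
        var: np.array([w[(data[var].astype(str) == lvl).to_numpy()].sum() / wsum for lvl in lv])
        for var, lv in levels.items()
    }
    return RegressionModel(
        wave=wave if wave is not None else (data["wave"].iloc[0] if "wave" in data.columns else None),
        levels=levels,
        columns=names,
        coef=coef,
        resid_cov=resid_cov,
        n_obs=len(data),
        weighted_n=float(wsum),
        basis=basis,
        total=total,
        level_shares=level_shares,
        cov_kernel=cov_kernel,
    )


def ls_means(model: RegressionModel, variable: str, margins: str = DEFAULT_MARGINS) -> pd.DataFrame:
    """LS-mean compositions (h/day) for every category of ``variable``.

    ``margins`` picks the averaging convention for the other factors (see
    :data:`DEFAULT_MARGINS`); the one-factor model is unaffected.
    """
    rows = []
    for category in model.levels.get(variable) or _raise_unknown(variable):
        comp = model.ls_mean_composition(variable, category, margins)
        rows.append(
            {
                "variable": variable,
                "category": category,
                "wave": model.wave,
                **dict(zip(PART_COLUMNS, comp)),
            }
        )
    return pd.DataFrame(rows)


def _raise_unknown(variable: str):
    raise UsageError(f"variable {variable!r} not in the model")


def wave_difference(comp_first, comp_second, total: float = DAY_HOURS) -> np.ndarray:
    """Per-part change between two closed compositions, in min/day.

    ``(second - first) * 60``; the three parts sum to zero exactly because
    both compositions are closed to the same 24 h total.
    """
    a = np.asarray(comp_first, dtype=float)
    b = np.asarray(comp_second, dtype=float)
    for name, c in (("first", a), ("second", b)):
        if abs(c.sum() - total) > 1e-6:
            raise UsageError(f"{name} composition does not sum to {total}: {c.sum()}")
    return (b - a) * 60.0


@dataclass(frozen=True)
class InteractionTest:
    """Multivariate test of a covariate x wave interaction."""

    variable: str
    statistic: str
    value: float
    f_value: float
    df1: float
    df2: float
    p_value: float


def _pillai_f(h: np.ndarray, e: np.ndarray, q: int, v_e: int) -> tuple[float, float, float, float, float]:
    p = h.shape[0]
    eig = np.linalg.eigvals(np.linalg.solve(h + e, h))
    v = float(np.real(eig).sum())
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n2 = (v_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n2 + s + 1)
    f = (df2 / df1) * v / (s - v)
    pval = float(stats.f.sf(f, df1, df2))
    return v, f, df1, df2, pval


def _wilks_f(h: np.ndarray, e: np.ndarray, q: int, v_e: int) -> tuple[float, float, float, float, float]:
    p = h.shape[0]
    lam = float(np.linalg.det(e) / np.linalg.det(h + e))
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = t * (v_e - (p - q + 1) / 2.0) - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return lam, f, df1, df2, pval


def interaction_test(
    data: pd.DataFrame,
    variable: str,
    predictors=DEFAULT_PREDICTORS,
    basis: IlrBasis = DEFAULT_BASIS,
    weight_col: str = "final_weight",
    wave_col: str = "wave",
    statistic: str = "pillai",
) -> InteractionTest:
    """P-value for the ``variable x survey-wave`` interaction.

    Fits the pooled two-wave multivariate model with and without the
    interaction columns and compares the nested fits with Pillai's trace
    (or Wilks' lambda) using the standard F approximation.  The p-value is
    invariant to the ilr basis.
    """
    if statistic not in ("pillai", "wilks"):
        raise UsageError(f"unknown statistic {statistic!r}; use 'pillai' or 'wilks'")
    if variable not in predictors:
        raise UsageError(f"variable {variable!r} is not among the predictors")
    cells = pd.crosstab(data[variable], data[wave_col])
    empty = [(str(i), str(c)) for i in cells.index for c in cells.columns if cells.loc[i, c] == 0]
    if empty or cells.shape[0] < 2 or cells.shape[1] < 2:
        raise EstimationError(f"interaction {variable!r} x wave inestimable; empty cells: {empty}")

    levels = factor_levels(data, predictors)
    wave_levels = factor_levels(data, [wave_col])[wave_col]
    x_main, names = build_design(data, {**levels, wave_col: wave_levels})

    var_vals = data[variable].astype(str).to_numpy()
    wave_vals = data[wave_col].astype(str).to_numpy()
    inter_cols, inter_names = [], []
    for lv in levels[variable][1:]:
        for wl in wave_levels[1:]:
            inter_cols.append(((var_vals == lv) & (wave_vals == wl)).astype(float))
            inter_names.append(f"{variable}[{lv}]:{wave_col}[{wl}]")
    x_full = np.column_stack([x_main] + inter_cols)
    full_names = names + inter_names

    y = ilr(data[list(PART_COLUMNS)].to_numpy(), basis)
    w = data[weight_col].to_numpy(dtype=float) if weight_col in data.columns else np.ones(len(data))

    _, resid_red = _wls(x_main, y, w, names)
    _, resid_full = _wls(x_full, y, w, full_names)
    e_red = (resid_red * w[:, None]).T @ resid_red
    e_full = (resid_full * w[:, None]).T @ resid_full
    h = e_red - e_full
    q = len(inter_names)
    v_e = len(data) - x_full.shape[1]
    fn = _pillai_f if statistic == "pillai" else _wilks_f
    value, f, df1, df2, pval = fn(h, e_full, q, v_e)
    return InteractionTest(variable, statistic, value, f, df1, df2, pval)


@dataclass
class BootstrapResult:
    """Percentile bootstrap output: replicate estimates and 95% bounds."""

    names: list[str]
    estimate: np.ndarray
    replicates: np.ndarray  # (B_kept, m)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_dropped: int

    def interval(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.ci_low[i]), float(self.ci_high[i])


def bootstrap_cis(
    statistic,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    wave_col: str = "wave",
    level: float = 0.95,
    max_dropped_frac: float = 0.10,
) -> BootstrapResult:
    """Percentile bootstrap CIs for an arbitrary pipeline statistic.

    ``statistic(df)`` must return ``(names, values)`` with a fixed layout.
    Person-days are resampled with replacement, stratified by wave, and the
    statistic (which should re-run reweighting and fitting) is evaluated on
    each resample.  Replicates on which estimation fails (e.g. an empty
    category) are dropped with a tally; more than ``max_dropped_frac`` of B
    dropped aborts with :class:`BootstrapError`.  Reproducible under a fixed
    seed.
    """
    if B < 2:
        raise UsageError(f"B must be >= 2, got {B}")
    if rng is None:
        rng = np.random.default_rng(seed)
    names, est = statistic(data)
    est = np.asarray(est, dtype=float)

    if wave_col in data.columns:
        strata = [np.flatnonzero((data[wave_col] == w).to_numpy()) for w in pd.unique(data[wave_col])]
    else:
        strata = [np.arange(len(data))]

    reps = []
    dropped = 0
    for _ in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        sample = data.take(idx)
        try:
            _, vals = statistic(sample)
        except (EstimationError, UsageError) as err:
            dropped += 1
            if dropped > max_dropped_frac * B:
                raise BootstrapError(
                    f"{dropped}/{B} bootstrap replicates failed (last: {err})"
                ) from None
            continue
        reps.append(np.asarray(vals, dtype=float))
    replicates = np.vstack(reps)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(replicates, 100 * alpha, axis=0)
    hi = np.percentile(replicates, 100 * (1 - alpha), axis=0)
    return BootstrapResult(
        names=list(names), estimate=est, replicates=replicates, ci_low=lo, ci_high=hi, n_dropped=dropped
    )
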