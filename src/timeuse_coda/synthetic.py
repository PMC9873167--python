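"""Synthetic survey generator with exported ground truth.

The survey microdata behind the published Thai time-use analysis are not
public, so every pipeline stage is exercised on synthetic populations drawn
from the model under which the analysis is exactly correctly specified: the
logistic-normal.  Covariates are drawn categorically with wave-specific
prevalences, the ilr coordinate pair is Normal(design x B, Sigma), and the
composition is the inverse-ilr closed to 24 h.  Population weights,
non-uniform day-of-week sampling and a small number of planted zero-part
days (which the pipeline must exclude) complete the emulation.

:func:`GeneratorConfig.thai_like` calibrates the generator to the published
margins: category prevalences from the printed counts, per-category effects
from differences of the printed adjusted means, wave centres equal to the
printed whole-sample compositional means, and the residual covariance scaled
so the marginal total variance matches the reported 1.85.  This is a
resemblance to the study conditions, not a replication of its data.

:func:`generate_diaries` expands person-days back into 10-minute diary
slots (largest-remainder apportionment, exact 144 slots) for round-trip
testing of the classification stage, and :func:`table1_fixture` re-exports
the printed descriptive table for arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _table1
from ._table1 import (  # noqa: F401  (re-exported fixture API)
    EXCLUSION_COUNTS,
    INPUT_N,
    RETAINED_N,
    TOTAL_VARIANCE,
    WHOLE_SAMPLE_MEANS,
    table1_fixture,
)
from .coda_core import DAY_HOURS, DEFAULT_BASIS, PART_COLUMNS, IlrBasis, ilr, ilr_inverse
from .diary import CATEGORY_COLUMNS, PA, SB, SLEEP, SLOTS_PER_DAY, ActivityMap
from .errors import ConfigurationError
from .vocab import COVARIATES, DAYS_OF_WEEK, WAVES

#: exclusion reason -> zeroed part column, in the tie-break order sleep -> PA -> SB
ZERO_PART_ORDER: tuple[tuple[str, str], ...] = (
    ("no_sleep", "sleep_h"),
    ("no_pa", "pa_h"),
    ("no_sb", "sb_h"),
)


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: levels, prevalences and ilr effects.

    ``prevalence[wave]`` sums to one over levels; ``effects[wave]`` is an
    (L, 2) matrix of absolute ilr effects per level, with the first
    (reference) level conventionally zero.  ``derived_from_day_of_week``
    marks day type, whose level follows the sampled diary day rather than an
    independent draw.
    """

    name: str
    levels: tuple[str, ...]
    prevalence: dict[int, np.ndarray]
    effects: dict[int, np.ndarray]
    derived_from_day_of_week: bool = False

    def validate(self, waves) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError(f"covariate {self.name!r} needs >= 2 levels")
        for w in waves:
            p = np.asarray(self.prevalence[w], dtype=float)
            if p.shape != (len(self.levels),) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"covariate {self.name!r}, wave {w}: bad prevalence vector")
            e = np.asarray(self.effects[w], dtype=float)
            if e.shape != (len(self.levels), 2):
                raise ConfigurationError(f"covariate {self.name!r}, wave {w}: effects must be (L, 2)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic two-wave survey."""

    n_per_wave: dict[int, int]
    intercepts: dict[int, np.ndarray]
    covariates: tuple[CovariateSpec, ...] = ()
    sigma: np.ndarray = dc_field(default_factory=lambda: np.eye(2) * 0.3)
    waves: tuple[int, ...] = WAVES
    zero_counts: dict[int, dict[str, int]] | None = None
    zero_rates: dict[int, dict[str, float]] | None = None
    weight_sigma: float = 0.5
    dow_probs: dict[int, np.ndarray] | None = None
    basis: IlrBasis = DEFAULT_BASIS
    total: float = DAY_HOURS

    def validate(self) -> None:
        for w in self.waves:
            if self.n_per_wave[w] < 1:
                raise ConfigurationError(f"wave {w}: n must be >= 1")
            if np.asarray(self.intercepts[w]).shape != (2,):
                raise ConfigurationError(f"wave {w}: intercept must be a 2-vector")
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (2, 2) or not np.allclose(s, s.T) or np.any(np.linalg.eigvalsh(s) <= 0):
            raise ConfigurationError("sigma must be symmetric positive definite 2x2")
        for spec in self.covariates:
            spec.validate(self.waves)
        if self.weight_sigma < 0:
            raise ConfigurationError("weight_sigma must be >= 0")
        if self.dow_probs is not None:
            for w in self.waves:
                p = np.asarray(self.dow_probs[w], dtype=float)
                if p.shape != (7,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
                    raise ConfigurationError(f"wave {w}: day-of-week probabilities invalid")
        for rates in (self.zero_rates or {}).values():
            if any(not (0 <= r < 1) for r in rates.values()):
                raise ConfigurationError("zero-part rates must be in [0, 1)")

    def planted_zero_counts(self, wave: int) -> dict[str, int]:
        """Zero-part days to plant in ``wave`` (explicit counts win over rates)."""
        if self.zero_counts and wave in self.zero_counts:
            return {r: int(k) for r, k in self.zero_counts[wave].items()}
        if self.zero_rates and wave in self.zero_rates:
            n = self.n_per_wave[wave]
            return {r: int(round(rate * n)) for r, rate in self.zero_rates[wave].items()}
        return {}

    def day_type_prevalence(self, wave: int) -> np.ndarray:
        """(weekday, weekend) probability implied by the day-of-week sampling."""
        if self.dow_probs is None:
            return np.array([5.0 / 7.0, 2.0 / 7.0])
        p = np.asarray(self.dow_probs[wave], dtype=float)
        weekend = p[5:].sum()
        return np.array([1.0 - weekend, weekend])

    # ------------------------------------------------------------------ #

    @classmethod
    def thai_like(cls, n_per_wave: dict[int, int] | None = None, plant_zero_rates: bool = True) -> "GeneratorConfig":
        """Generator calibrated to the published survey margins (see module docs)."""
        n_per_wave = dict(n_per_wave or _table1.INPUT_N)
        basis = DEFAULT_BASIS
        tbl = table1_fixture()

        dow_probs = {}
        for w in WAVES:
            weekday_share = float(
                tbl.query("variable == 'day_type' and category == 'weekday' and wave == @w")["pct"].iloc[0]
            ) / 100.0
            wd = np.array([1.10, 1.05, 1.00, 0.95, 0.90])
            we = np.array([1.05, 0.95])
            dow_probs[w] = np.concatenate(
                [wd / wd.sum() * weekday_share, we / we.sum() * (1.0 - weekday_share)]
            )

        covariates: list[CovariateSpec] = []
        for var, levels in COVARIATES.items():
            sub = tbl[tbl["variable"] == var].set_index(["category", "wave"])
            prevalence, effects = {}, {}
            for w in WAVES:
                counts = np.array([sub.loc[(l, w), "n"] for l in levels], dtype=float)
                prevalence[w] = counts / counts.sum()
                gs = np.array(
                    [[sub.loc[(l, w), c] for c in PART_COLUMNS] for l in levels], dtype=float
                )
                z = ilr(gs, basis)
                effects[w] = z - z[0]
            if var == "day_type":
                for w in WAVES:
                    prevalence[w] = None  # replaced below by dow-implied values
            covariates.append(
                CovariateSpec(
                    name=var,
                    levels=levels,
                    prevalence=prevalence,
                    effects=effects,
                    derived_from_day_of_week=(var == "day_type"),
                )
            )

        # day-type prevalence follows the day-of-week sampling probabilities
        for i, spec in enumerate(covariates):
            if spec.derived_from_day_of_week:
                prev = {}
                for w in WAVES:
                    weekend = dow_probs[w][5:].sum()
                    prev[w] = np.array([1.0 - weekend, weekend])
                covariates[i] = CovariateSpec(
                    name=spec.name,
                    levels=spec.levels,
                    prevalence=prev,
                    effects=spec.effects,
                    derived_from_day_of_week=True,
                )

        # intercept so the population mean ilr equals the printed whole-sample mean
        intercepts = {}
        for w in WAVES:
            target = ilr(np.array(WHOLE_SAMPLE_MEANS[w]), basis)
            shift = np.zeros(2)
            for spec in covariates:
                shift += spec.prevalence[w] @ spec.effects[w]
            intercepts[w] = target - shift

        # residual covariance so the marginal total variance matches the report:
        # total variance = D * (trace(Sigma) + trace of between-covariate ilr variance)
        traces = []
        for w in WAVES:
            between = 0.0
            for spec in covariates:
                e, p = spec.effects[w], spec.prevalence[w]
                centred = e - p @ e
                between += float(p @ (centred**2).sum(axis=1))
            traces.append(_table1.TOTAL_VARIANCE[w] / 3.0 - between)
        target_trace = float(np.mean(traces))
        if target_trace <= 0.01:
            raise ConfigurationError("between-covariate variance exceeds the target total variance")
        shape = np.array([[0.60, -0.10], [-0.10, 0.40]])
        sigma = shape * (target_trace / np.trace(shape))

        zero_rates = None
        if plant_zero_rates:
            zero_rates = {
                w: {r: k / _table1.INPUT_N[w] for r, k in _table1.EXCLUSION_COUNTS[w].items()}
                for w in WAVES
            }

        cfg = cls(
            n_per_wave=n_per_wave,
            intercepts=intercepts,
            covariates=tuple(covariates),
            sigma=sigma,
            waves=WAVES,
            zero_rates=zero_rates,
            dow_probs=dow_probs,
            basis=basis,
        )
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of a generated population, for recovery tests.

    LS means are provided under both margin conventions: ``observed``
    averages the other factors at their population prevalences, ``equal``
    weights every level equally (keys are ``(variable, level, wave)``).
    """

    mean_ilr: dict[int, np.ndarray]
    mean_composition: dict[int, np.ndarray]
    ls_mean_ilr: dict[tuple[str, str, int], np.ndarray]
    ls_mean_composition: dict[tuple[str, str, int], np.ndarray]
    ls_mean_ilr_equal: dict[tuple[str, str, int], np.ndarray]
    interaction_present: dict[str, bool]
    zero_counts: dict[int, dict[str, int]]
    sigma: np.ndarray

    def ls_mean(self, variable: str, category: str, wave: int) -> np.ndarray:
        return self.ls_mean_composition[(variable, category, wave)]


def _ground_truth(config: GeneratorConfig) -> GroundTruth:
    mean_ilr, mean_comp = {}, {}
    ls_ilr, ls_comp, ls_ilr_eq = {}, {}, {}
    for w in config.waves:
        mu = np.asarray(config.intercepts[w], dtype=float).copy()
        for spec in config.covariates:
            mu += spec.prevalence[w] @ spec.effects[w]
        mean_ilr[w] = mu
        mean_comp[w] = ilr_inverse(mu, config.basis, config.total)
        for spec in config.covariates:
            others_obs, others_eq = np.zeros(2), np.zeros(2)
            for other in config.covariates:
                if other.name != spec.name:
                    others_obs += other.prevalence[w] @ other.effects[w]
                    others_eq += other.effects[w].mean(axis=0)
            for i, level in enumerate(spec.levels):
                z = config.intercepts[w] + spec.effects[w][i] + others_obs
                ls_ilr[(spec.name, level, w)] = z
                ls_comp[(spec.name, level, w)] = ilr_inverse(z, config.basis, config.total)
                ls_ilr_eq[(spec.name, level, w)] = (
                    config.intercepts[w] + spec.effects[w][i] + others_eq
                )
    interaction = {
        spec.name: not all(
            np.allclose(spec.effects[w] - spec.effects[w][0],
                        spec.effects[config.waves[0]] - spec.effects[config.waves[0]][0])
            for w in config.waves
        )
        for spec in config.covariates
    }
    zero = {w: config.planted_zero_counts(w) for w in config.waves}
    return GroundTruth(
        mean_ilr=mean_ilr,
        mean_composition=mean_comp,
        ls_mean_ilr=ls_ilr,
        ls_mean_composition=ls_comp,
        ls_mean_ilr_equal=ls_ilr_eq,
        interaction_present=interaction,
        zero_counts=zero,
        sigma=np.asarray(config.sigma, dtype=float),
    )


def generate_person_days(
    config: GeneratorConfig, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic person-day table and its ground truth.

    Deterministic under a fixed seed.  Planted zero-part days overwrite one
    part with zero and re-close the remainder to 24 h; their bookkeeping is
    exported so exclusion counts can be checked exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(np.asarray(config.sigma, dtype=float))
    frames = []
    for w in config.waves:
        n = config.n_per_wave[w]
        dow_p = (
            np.asarray(config.dow_probs[w], dtype=float)
            if config.dow_probs is not None
            else np.full(7, 1.0 / 7.0)
        )
        dow_idx = rng.choice(7, size=n, p=dow_p)
        cols: dict[str, np.ndarray] = {
            "participant_id": np.array([f"{w}-{i:06d}" for i in range(n)]),
            "wave": np.full(n, w),
            "day_of_week": np.array(DAYS_OF_WEEK)[dow_idx],
        }
        mu = np.tile(np.asarray(config.intercepts[w], dtype=float), (n, 1))
        for spec in config.covariates:
            if spec.derived_from_day_of_week:
                idx = (dow_idx >= 5).astype(int)
            else:
                idx = rng.choice(len(spec.levels), size=n, p=spec.prevalence[w])
            cols[spec.name] = np.array(spec.levels)[idx]
            mu += spec.effects[w][idx]
        z = mu + rng.standard_normal((n, 2)) @ chol.T
        parts = ilr_inverse(z, config.basis, config.total)
        cols["weight"] = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)

        planted = config.planted_zero_counts(w)
        if planted:
            k_total = sum(planted.values())
            if k_total > n:
                raise ConfigurationError(f"wave {w}: cannot plant {k_total} zero days in n={n}")
            chosen = rng.permutation(n)[:k_total]
            offset = 0
            for reason, part_col in ZERO_PART_ORDER:
                k = planted.get(reason, 0)
                rows = chosen[offset : offset + k]
                offset += k
                j = PART_COLUMNS.index(part_col)
                parts[rows, j] = 0.0
                keep = [jj for jj in range(3) if jj != j]
                sub = parts[np.ix_(rows, keep)]
                parts[np.ix_(rows, keep)] = sub * (config.total / sub.sum(axis=1, keepdims=True))
        for j, col in enumerate(PART_COLUMNS):
            cols[col] = parts[:, j]
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    return df, _ground_truth(config)


def largest_remainder(values, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``values``.

    Floors each share and hands remaining units to the largest fractional
    parts, ties broken by position — deterministic and exact.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0) or v.sum() <= 0:
        raise ConfigurationError("apportionment needs non-negative values with a positive sum")
    quota = v * (total / v.sum())
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.lexsort((np.arange(len(v)), -(quota - base)))
    base[order[:short]] += 1
    return base


def generate_diaries(
    person_days: pd.DataFrame,
    activity_map: ActivityMap | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expand person-days into 144-slot diaries that classify back to them.

    Each behaviour receives ``round-to-apportionment(hours x 6)`` slots
    (largest remainder, exactly 144 total), coded with a directly-mapped
    code for its category; slot order is shuffled per day (sequencing within
    the day is arbitrary).  Classify-and-aggregate round-trips the input
    composition to within one slot (1/12 h) per part.
    """
    amap = activity_map or ActivityMap.default()
    code_of = {}
    for cat in (PA, SB, SLEEP):
        codes = amap.codes_for(cat)
        if not codes:
            raise ConfigurationError(f"activity map has no directly-mapped code for {cat}")
        code_of[cat] = codes[0]
    rng = np.random.default_rng(seed)
    pids, slots, codes_out = [], [], []
    cats = (PA, SB, SLEEP)
    for row in person_days.itertuples(index=False):
        hours = np.array([getattr(row, CATEGORY_COLUMNS[c]) for c in cats])
        counts = largest_remainder(hours * 6.0, SLOTS_PER_DAY)
        day_codes = np.repeat([code_of[c] for c in cats], counts)
        rng.shuffle(day_codes)
        pids.append(np.full(SLOTS_PER_DAY, row.participant_id))
        slots.append(np.arange(SLOTS_PER_DAY))
        codes_out.append(day_codes)
    return pd.DataFrame(
        {
            "participant_id": np.concatenate(pids),
            "slot_index": np.concatenate(slots),
            "activity_code": np.concatenate(codes_out),
            "location": None,
            "occupation_code": None,
        }
    )
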