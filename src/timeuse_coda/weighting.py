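"""Analysis weights: survey population weights x day-of-week uniformisation.

Each person-day carries a population weight supplied with the survey (the
sampling design is consumed, never re-derived here).  Because diary days are
not sampled uniformly over the week, an additional factor rescales the
weighted mass so each day of the week carries exactly 1/7 of the total —
computed separately per survey wave, since waves are analysed as separate
regressions.  The factors are mass-preserving: the summed final weight per
wave equals the summed population weight.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import WeightingError
from .vocab import DAYS_OF_WEEK

logger = logging.getLogger(__name__)


def day_of_week_factors(
    days: pd.DataFrame,
    weight_col: str = "weight",
    dow_col: str = "day_of_week",
    wave_col: str = "wave",
) -> pd.Series:
    """Per-(wave, day-of-week) factor (W_total/7) / W_day.

    Requires every day of the week to be present in every wave; otherwise
    uniformisation is impossible and a :class:`WeightingError` is raised.
    """
    if dow_col not in days.columns:
        raise WeightingError(f"no {dow_col!r} column: cannot uniformise days of the week")
    mass = days.groupby([wave_col, dow_col], observed=True)[weight_col].sum()
    factors = {}
    for wave, wave_mass in mass.groupby(level=0):
        present = set(wave_mass.index.get_level_values(1))
        missing = [d for d in DAYS_OF_WEEK if d not in present]
        if missing:
            raise WeightingError(f"wave {wave!r}: day(s) of week absent: {missing}")
        total = wave_mass.sum()
        for (w, d), m in wave_mass.items():
            if m <= 0:
                raise WeightingError(f"wave {wave!r}: non-positive weight mass on {d!r}")
            factors[(w, d)] = (total / 7.0) / m
    out = pd.Series(factors, name="dow_factor")
    out.index.names = [wave_col, dow_col]
    return out


def combine_weights(
    days: pd.DataFrame,
    factors: pd.Series | None = None,
    weight_col: str = "weight",
    dow_col: str = "day_of_week",
    wave_col: str = "wave",
    out_col: str = "final_weight",
) -> pd.DataFrame:
    """Attach ``final_weight = population weight x day-of-week factor``.

    With ``factors=None`` they are computed from ``days`` itself.
    """
    if factors is None:
        factors = day_of_week_factors(days, weight_col, dow_col, wave_col)
    keys = pd.MultiIndex.from_frame(days[[wave_col, dow_col]])
    try:
        f = factors.reindex(keys).to_numpy()
    except KeyError as err:  # pragma: no cover - reindex fills NaN instead
        raise WeightingError(str(err)) from None
    if pd.isna(f).any():
        missing = sorted({tuple(k) for k, v in zip(keys, f) if pd.isna(v)})
        raise WeightingError(f"no day-of-week factor for {missing[:5]}")
    out = days.copy()
    out[out_col] = out[weight_col].to_numpy() * f
    return out


def uniformise_day_of_week(
    days: pd.DataFrame,
    enabled: bool = True,
    weight_col: str = "weight",
    dow_col: str = "day_of_week",
    wave_col: str = "wave",
    out_col: str = "final_weight",
) -> pd.DataFrame:
    """Convenience wrapper used by the pipeline.

    When disabled, or when the input has no day-of-week column
    (pre-aggregated data), the population weight is carried through
    unchanged with a logged notice.
    """
    if not enabled or dow_col not in days.columns:
        if enabled:
            logger.info("no %r column; skipping day-of-week uniformisation", dow_col)
        out = days.copy()
        out[out_col] = out[weight_col]
        return out
    return combine_weights(days, None, weight_col, dow_col, wave_col, out_col)
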