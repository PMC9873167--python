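"""Classify 10-minute time-use diary slots into PA / SB / sleep person-days.

Diaries record one activity code (Trial-ICATUS dialect) per 10-minute slot,
144 slots per day.  Codes are resolved to a behaviour category through an
:class:`ActivityMap`: a direct code-to-category lookup plus ordered
MET-informed rules for work- and travel-related codes, where the category
depends on the metabolic cost of the participant's occupation or mode of
travel (sedentary at or below the MET threshold, physically active above it).
Sleep — overnight sleep and naps alike — is only ever assigned through the
direct map.

The shipped default map is a small documented stand-in, not the authentic
published lookup tables; a complete user-supplied map is accepted in the same
format.

After aggregation the three behaviour totals sum to 24 h exactly.  Days that
report no sleep, no active wake time, or no sedentary behaviour are removed
by :func:`apply_exclusions`, which tallies each reason per survey wave (a day
with several zero parts is counted once, under the first zero in the order
sleep -> PA -> SB).
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .coda_core import PART_COLUMNS
from .errors import ClassificationError, ConfigurationError, MalformedDiaryError
from .vocab import COVARIATE_ORDER

logger = logging.getLogger(__name__)

PA, SB, SLEEP = "PA", "SB", "SLEEP"
CATEGORIES: tuple[str, str, str] = (PA, SB, SLEEP)
SLOTS_PER_DAY = 144
SLOT_HOURS = 10.0 / 60.0

#: category -> hours column in the person-day table
CATEGORY_COLUMNS = {PA: "pa_h", SB: "sb_h", SLEEP: "sleep_h"}


@dataclass(frozen=True)
class DiarySlot:
    """One 10-minute diary entry."""

    slot_index: int
    activity_code: str
    location: str | None = None
    occupation_code: str | None = None


@dataclass(frozen=True)
class MetRule:
    """MET assignment for a code pattern, optionally qualified.

    ``pattern`` is a glob matched against the activity code; ``field`` (one
    of ``occupation``/``location`` or None) together with ``value`` restricts
    the rule to slots with that qualifier.  First matching rule wins, so rule
    order is part of the configuration.
    """

    pattern: str
    met: float
    field: str | None = None
    value: str | None = None

    def __post_init__(self) -> None:
        if self.field not in (None, "occupation", "location"):
            raise ConfigurationError(f"MET rule field must be occupation/location, got {self.field!r}")
        if self.met <= 0:
            raise ConfigurationError(f"MET value must be positive, got {self.met}")

    def matches(self, code: str, location: str | None, occupation: str | None) -> bool:
        if not fnmatch.fnmatchcase(code, self.pattern):
            return False
        if self.field is None:
            return True
        qualifier = occupation if self.field == "occupation" else location
        return qualifier == self.value


@dataclass(frozen=True)
class ActivityMap:
    """Activity-code classification config.

    ``direct`` maps codes straight to a category; ``met_rules`` resolve the
    remaining (work/travel) codes through MET values: SB when the assigned
    MET is at or below ``met_threshold`` (default 1.5 MET, the conventional
    sedentary boundary), PA otherwise.  In strict mode an unresolvable code
    raises; in lenient mode it falls back to ``fallback`` with a warning.
    """

    direct: dict[str, str] = field(default_factory=dict)
    met_rules: tuple[MetRule, ...] = ()
    met_threshold: float = 1.5
    strict: bool = True
    fallback: str = SB

    def __post_init__(self) -> None:
        for code, cat in self.direct.items():
            if cat not in CATEGORIES:
                raise ConfigurationError(f"direct map {code!r} -> {cat!r}: unknown category")
        if self.fallback not in CATEGORIES:
            raise ConfigurationError(f"unknown fallback category {self.fallback!r}")
        if self.met_threshold <= 0:
            raise ConfigurationError("met_threshold must be positive")

    def classify(self, code: str, location: str | None = None, occupation: str | None = None) -> str:
        if not code:
            raise ClassificationError("empty activity code")
        cat = self.direct.get(code)
        if cat is not None:
            return cat
        for rule in self.met_rules:
            if rule.matches(code, location, occupation):
                return SB if rule.met <= self.met_threshold else PA
        if self.strict:
            raise ClassificationError(f"unmapped activity code {code!r}")
        logger.warning("unmapped activity code %r; falling back to %s", code, self.fallback)
        return self.fallback

    def codes_for(self, category: str) -> list[str]:
        """Directly-mapped codes for a category (used by the diary generator)."""
        return [c for c, cat in self.direct.items() if cat == category]

    def with_mode(self, strict: bool) -> "ActivityMap":
        return replace(self, strict=strict)

    @classmethod
    def from_dict(cls, spec: dict) -> "ActivityMap":
        rules = tuple(
            MetRule(
                pattern=str(r["pattern"]),
                met=float(r["met"]),
                field=r.get("field"),
                value=r.get("value"),
            )
            for r in spec.get("met_rules", [])
        )
        return cls(
            direct={str(k): str(v).upper() for k, v in spec.get("direct", {}).items()},
            met_rules=rules,
            met_threshold=float(spec.get("met_threshold", 1.5)),
            strict=bool(spec.get("strict", True)),
            fallback=str(spec.get("fallback", SB)).upper(),
        )

    @classmethod
    def from_yaml(cls, path) -> "ActivityMap":
        with open(path, "r", encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
        if not isinstance(spec, dict):
            raise ConfigurationError(f"activity map {path} is not a mapping")
        return cls.from_dict(spec)

    @classmethod
    def default(cls) -> "ActivityMap":
        """The small default map shipped with the package."""
        text = resources.files("timeuse_coda.data").joinpath("default_activity_map.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def classify_slot(slot: DiarySlot, activity_map: ActivityMap) -> str:
    """Category of one diary slot under the given map."""
    return activity_map.classify(slot.activity_code, slot.location, slot.occupation_code)


def _validate_indices(indices: np.ndarray) -> None:
    if len(indices) != SLOTS_PER_DAY:
        raise MalformedDiaryError(f"expected {SLOTS_PER_DAY} slots, got {len(indices)}")
    uniq = np.unique(indices)
    if len(uniq) != SLOTS_PER_DAY or uniq[0] != 0 or uniq[-1] != SLOTS_PER_DAY - 1:
        raise MalformedDiaryError("slot indices must be the integers 0..143, each exactly once")


def aggregate_day(slots, activity_map: ActivityMap) -> dict[str, float]:
    """Aggregate one participant's 144 slots into behaviour hours.

    Returns ``{"pa_h": ..., "sb_h": ..., "sleep_h": ...}``; sleep hours are
    set by subtraction so the three parts sum to 24.0 exactly.
    """
    slots = list(slots)
    _validate_indices(np.array([s.slot_index for s in slots]))
    counts = {cat: 0 for cat in CATEGORIES}
    for s in slots:
        counts[classify_slot(s, activity_map)] += 1
    pa_h = counts[PA] * SLOT_HOURS
    sb_h = counts[SB] * SLOT_HOURS
    return {"pa_h": pa_h, "sb_h": sb_h, "sleep_h": 24.0 - pa_h - sb_h}


def classify_diaries(
    slots_df: pd.DataFrame,
    participants_df: pd.DataFrame,
    activity_map: ActivityMap,
) -> pd.DataFrame:
    """Build the person-day composition table from long-format diary slots.

    ``slots_df`` has one row per slot (participant_id, slot_index,
    activity_code, optional location / occupation_code); ``participants_df``
    one row per participant (participant_id, wave, weight, covariates,
    optional day_of_week).  Classification is a pure function of
    (code, location, occupation, config), so slot order is irrelevant.
    """
    df = slots_df.copy()
    for col in ("location", "occupation_code"):
        if col not in df.columns:
            df[col] = None
        else:  # CSV round trips turn missing qualifiers into NaN floats
            df[col] = df[col].astype(object).where(df[col].notna(), None)

    combos = df[["activity_code", "location", "occupation_code"]].drop_duplicates()
    cat_of = {
        (c, l, o): activity_map.classify(str(c), l, o)
        for c, l, o in combos.itertuples(index=False)
    }
    df["category"] = [
        cat_of[(c, l, o)]
        for c, l, o in zip(df["activity_code"], df["location"], df["occupation_code"])
    ]

    for pid, grp in df.groupby("participant_id", sort=False):
        try:
            _validate_indices(grp["slot_index"].to_numpy())
        except MalformedDiaryError as err:
            raise MalformedDiaryError(f"participant {pid!r}: {err}") from None

    counts = (
        df.groupby(["participant_id", "category"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    out = pd.DataFrame(index=counts.index)
    out["pa_h"] = counts[PA] * SLOT_HOURS
    out["sb_h"] = counts[SB] * SLOT_HOURS
    out["sleep_h"] = 24.0 - out["pa_h"] - out["sb_h"]
    out = participants_df.merge(out.reset_index(), on="participant_id", how="inner")
    return out


@dataclass(frozen=True)
class WaveExclusions:
    """Exclusion tally for one survey wave."""

    n_input: int
    n_no_sleep: int
    n_no_pa: int
    n_no_sb: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_no_sleep - self.n_no_pa - self.n_no_sb


@dataclass(frozen=True)
class ExclusionReport:
    """Per-wave exclusion counts for zero-part days."""

    per_wave: dict[object, WaveExclusions]

    @property
    def n_retained(self) -> int:
        return sum(w.n_retained for w in self.per_wave.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "wave": wave,
                "n_input": w.n_input,
                "n_no_sleep": w.n_no_sleep,
                "n_no_pa": w.n_no_pa,
                "n_no_sb": w.n_no_sb,
                "n_retained": w.n_retained,
            }
            for wave, w in sorted(self.per_wave.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows)


def apply_exclusions(days: pd.DataFrame, wave_col: str = "wave") -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop zero-part person-days and report counts per wave.

    A day with several zero parts is counted once, under the first zero in
    the order sleep -> PA -> SB.  Idempotent: on already-retained data the
    report shows zero exclusions.
    """
    sleep0 = days["sleep_h"].to_numpy() <= 0.0
    pa0 = days["pa_h"].to_numpy() <= 0.0
    sb0 = days["sb_h"].to_numpy() <= 0.0
    reason = np.where(sleep0, "no_sleep", np.where(pa0, "no_pa", np.where(sb0, "no_sb", "keep")))

    per_wave: dict[object, WaveExclusions] = {}
    waves = days[wave_col] if wave_col in days.columns else pd.Series(["all"] * len(days))
    for wave in pd.unique(waves):
        mask = (waves == wave).to_numpy()
        r = reason[mask]
        per_wave[wave] = WaveExclusions(
            n_input=int(mask.sum()),
            n_no_sleep=int((r == "no_sleep").sum()),
            n_no_pa=int((r == "no_pa").sum()),
            n_no_sb=int((r == "no_sb").sum()),
        )
    retained = days.loc[reason == "keep"].copy()
    report = ExclusionReport(per_wave=per_wave)
    if retained.empty:
        logger.warning("apply_exclusions removed every person-day")
    return retained, report


PERSON_DAY_COLUMNS: tuple[str, ...] = (
    ("participant_id", "wave", "weight") + COVARIATE_ORDER + ("day_of_week",) + PART_COLUMNS
)
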