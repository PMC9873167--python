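"""Published descriptive results used as a static arithmetic fixture.

Adjusted (least-squares) mean hours per day in PA, SB and sleep per
sociodemographic category and survey wave, with category counts, plus the
whole-sample compositional means.  These printed values serve two roles:

* inputs for arithmetic checks (row closure to 24 h, min/day contrasts);
* calibration of the "thai-like" synthetic generator (category prevalences
  and effect sizes that resemble the study margins).

No quantity here is ever computed by the package; it is a transcription of
reported results.
"""

from __future__ import annotations

import pandas as pd

# variable, category, n09, pct09, n15, pct15,
#   pa09, pa15, sb09, sb15, sleep09, sleep15, interaction_p
_ROWS = [
    ("sex", "female", 33877, 51.2, 35826, 51.4, 10.35, 9.42, 4.82, 5.52, 8.83, 9.06, "<0.001"),
    ("sex", "male", 32311, 48.8, 33810, 48.6, 9.09, 8.17, 5.56, 6.23, 9.36, 9.60, "<0.001"),
    ("household_area", "rural", 45573, 68.9, 38341, 55.1, 9.67, 8.74, 5.23, 5.89, 9.11, 9.37, "0.035"),
    ("household_area", "urban", 20615, 31.1, 31295, 44.9, 9.84, 8.89, 5.08, 5.82, 9.08, 9.29, "0.035"),
    ("age_group", "10-17", 9303, 14.1, 8380, 12.0, 11.44, 10.55, 4.30, 5.02, 8.26, 8.43, "<0.001"),
    ("age_group", "18-24", 8146, 12.3, 7959, 11.4, 10.11, 9.65, 4.80, 5.22, 9.09, 9.13, "<0.001"),
    ("age_group", "25-39", 18606, 28.1, 17670, 25.4, 9.99, 9.14, 4.92, 5.55, 9.09, 9.31, "<0.001"),
    ("age_group", "40-59", 21367, 32.3, 23706, 34.0, 9.72, 8.77, 5.36, 5.99, 8.93, 9.23, "<0.001"),
    ("age_group", "60-74", 6491, 9.8, 8940, 12.8, 8.12, 7.45, 6.22, 6.78, 9.66, 9.77, "<0.001"),
    ("age_group", "75-84", 1832, 2.8, 2409, 3.5, 5.27, 5.36, 7.71, 7.79, 11.03, 10.85, "<0.001"),
    ("age_group", "85+", 443, 0.7, 572, 0.8, 3.34, 3.29, 8.24, 8.83, 12.42, 11.88, "<0.001"),
    ("education", "primary_or_below", 39893, 60.3, 35913, 51.6, 9.52, 8.68, 5.19, 5.84, 9.29, 9.48, "<0.001"),
    ("education", "secondary_high_school", 17674, 26.7, 21366, 30.7, 10.10, 9.02, 5.05, 5.72, 8.85, 9.26, "<0.001"),
    ("education", "college_university_higher", 8494, 12.8, 12073, 17.3, 9.89, 8.78, 5.37, 6.20, 8.74, 9.02, "<0.001"),
    ("employment", "employed", 44451, 67.2, 44931, 64.5, 11.06, 10.17, 4.38, 5.01, 8.57, 8.82, "0.190"),
    ("employment", "unemployed", 16290, 24.6, 20187, 29.0, 6.79, 6.06, 7.20, 7.89, 10.01, 10.05, "0.190"),
    ("marital", "never_married", 14902, 22.5, 17350, 24.9, 9.11, 8.25, 5.62, 6.27, 9.27, 9.48, "<0.001"),
    ("marital", "currently_married", 39441, 59.6, 39197, 56.3, 10.00, 9.07, 5.02, 5.71, 8.98, 9.22, "<0.001"),
    ("marital", "formerly_married", 6401, 9.7, 8021, 11.5, 9.44, 8.71, 5.16, 5.75, 9.40, 9.55, "<0.001"),
    ("region", "bangkok", 6483, 9.8, 9141, 13.1, 9.93, 8.89, 5.20, 5.70, 8.87, 9.41, "<0.001"),
    ("region", "central", 15751, 23.8, 20115, 28.9, 9.84, 8.95, 5.03, 5.83, 9.13, 9.23, "<0.001"),
    ("region", "north", 12344, 18.6, 12017, 17.3, 9.73, 8.78, 4.97, 5.64, 9.30, 9.58, "<0.001"),
    ("region", "north_east", 22562, 34.1, 19174, 27.5, 9.67, 8.67, 5.26, 6.02, 9.08, 9.31, "<0.001"),
    ("region", "south", 9048, 13.7, 9189, 13.2, 9.50, 8.72, 5.53, 6.06, 8.97, 9.22, "<0.001"),
    ("day_type", "weekday", 46415, 70.1, 49646, 71.3, 9.95, 9.17, 5.06, 5.64, 8.99, 9.19, "<0.001"),
    ("day_type", "weekend", 19773, 29.9, 19990, 28.7, 9.20, 7.92, 5.45, 6.41, 9.35, 9.66, "<0.001"),
]

#: whole-sample compositional means (h/day), by wave
WHOLE_SAMPLE_MEANS: dict[int, tuple[float, float, float]] = {
    2009: (9.50, 5.30, 9.20),
    2015: (8.60, 5.96, 9.44),
}

#: sample sizes: included after exclusions, per wave
RETAINED_N: dict[int, int] = {2009: 66188, 2015: 69636}
#: participants entering the exclusion step, per wave
INPUT_N: dict[int, int] = {2009: 66652, 2015: 69922}
#: zero-part exclusion counts per wave, in the order sleep -> PA -> SB
EXCLUSION_COUNTS: dict[int, dict[str, int]] = {
    2009: {"no_sleep": 367, "no_pa": 69, "no_sb": 28},
    2015: {"no_sleep": 184, "no_pa": 80, "no_sb": 22},
}

#: reported total variance of the composition, by wave
TOTAL_VARIANCE: dict[int, float] = {2009: 1.85, 2015: 1.85}


def table1_fixture() -> pd.DataFrame:
    """The per-category adjusted means as a long DataFrame.

    One row per (variable, category, wave) with columns ``n``, ``pct``,
    ``pa_h``, ``sb_h``, ``sleep_h`` and the printed interaction p-value.
    """
    rows = []
    for var, cat, n09, p09, n15, p15, pa09, pa15, sb09, sb15, sl09, sl15, ip in _ROWS:
        rows.append(
            dict(variable=var, category=cat, wave=2009, n=n09, pct=p09,
                 pa_h=pa09, sb_h=sb09, sleep_h=sl09, interaction_p=ip)
        )
        rows.append(
            dict(variable=var, category=cat, wave=2015, n=n15, pct=p15,
                 pa_h=pa15, sb_h=sb15, sleep_h=sl15, interaction_p=ip)
        )
    return pd.DataFrame(rows)
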