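"""Controlled vocabularies for the person-day table.

Covariate levels follow the sociodemographic taxonomy of the Thai national
time-use surveys: sex, household area, seven age groups, three education
levels, employment, marital status, five regions and day type.  The first
level of each variable is the reference level in regression designs.
"""

WAVES: tuple[int, int] = (2009, 2015)

COVARIATES: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "household_area": ("rural", "urban"),
    "age_group": ("10-17", "18-24", "25-39", "40-59", "60-74", "75-84", "85+"),
    "education": ("primary_or_below", "secondary_high_school", "college_university_higher"),
    "employment": ("employed", "unemployed"),
    "marital": ("never_married", "currently_married", "formerly_married"),
    "region": ("bangkok", "central", "north", "north_east", "south"),
    "day_type": ("weekday", "weekend"),
}

COVARIATE_ORDER: tuple[str, ...] = tuple(COVARIATES)

DAYS_OF_WEEK: tuple[str, ...] = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
WEEKEND_DAYS: tuple[str, str] = ("sat", "sun")
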