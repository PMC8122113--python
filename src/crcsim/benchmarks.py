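"""Shipped regional benchmark parameter sets.

Four complete model parameterizations — Western, Eastern, Northern and
Southern Europe — serve as starting points for country adjustment.
They are plausible defaults constructed here in code: the lesion
progression core (shared across regions, since between-country
incidence differences are attributed to differences in disease onset)
plus region-scaled onset hazards, a European-style life table and
population pyramid, stage mix, stage-specific relative survival, test
characteristics for gFOBT/FIT/FS/colonoscopy, and a biennial-FIT
programme history.  Every benchmark passes the template quality checks.
"""

from __future__ import annotations

import numpy as np

from .params import (
    LifeTable,
    LesionStateSpace,
    ModelParams,
    OnsetHazard,
    PopulationPyramid,
    ProgrammeDesign,
    ScreeningTest,
    StageSurvival,
    SurveillanceProtocol,
)

REGIONS = ("western", "eastern", "northern", "southern")

# Region-level onset scaling: Eastern Europe carries the highest CRC
# burden, Northern the lowest, with Western as the reference.
_REGION_ONSET_SCALE = {"western": 1.0, "eastern": 1.2, "northern": 0.85, "southern": 0.9}


def default_life_table(terminal_age: int = 100) -> LifeTable:
    """Gompertz-style all-cause (minus CRC) mortality, life expectancy ~81."""
    age = np.arange(terminal_age + 1)
    qx = 5e-5 * np.exp(0.095 * age) + 5e-4
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(age=age, qx=qx)


def default_pyramid(base_year: int = 2018, scale: float = 100_000.0) -> PopulationPyramid:
    """A mildly ageing population pyramid (counts per year of age)."""
    age = np.arange(101)
    shape = np.ones(101)
    shape[:30] = 0.95
    shape[30:50] = 1.05
    shape[50:70] = 1.10
    shape[70:] = np.maximum(0.0, 1.10 * np.exp(-0.06 * (age[70:] - 70)))
    count = shape / shape.sum() * scale * 101
    return PopulationPyramid(age=age, count=count, base_year=base_year)


def default_onset_hazard(region: str = "western") -> OnsetHazard:
    """Adenoma-onset hazard per person-year: zero before 20, rising
    roughly linearly to a plateau in old age.  Cumulative hazard to age
    60 is ~0.3, giving realistic adenoma prevalence."""
    age = np.arange(100)
    haz = np.zeros(100)
    rise = (age >= 20) & (age < 60)
    haz[rise] = 6.0e-4 * (age[rise] - 20)
    late = age >= 60
    haz[late] = 0.024 + 4.0e-4 * np.minimum(age[late] - 60, 30)
    return OnsetHazard(age=age, hazard=haz * _REGION_ONSET_SCALE[region])


def default_lesion_space() -> LesionStateSpace:
    """The region-invariant progression core of the adenoma--carcinoma
    sequence.  Mean onset-to-invasion time for progressive adenomas is
    ~14 years; the preclinical sojourn averages ~2.5 years."""
    return LesionStateSpace(
        progression_rates={
            "adenoma_small": 0.20,
            "adenoma_medium": 0.20,
            "adenoma_large": 0.25,
            "preclinical_I": 0.60,
            "preclinical_II": 0.60,
            "preclinical_III": 0.50,
        },
        surfacing_rates={
            "preclinical_I": 0.25,
            "preclinical_II": 0.45,
            "preclinical_III": 0.70,
            "preclinical_IV": 1.00,
        },
        p_progressive=0.07,
    )


def default_stage_survival() -> StageSurvival:
    """Cumulative relative survival 0..10 years since diagnosis."""
    years = np.arange(11.0)
    def curve(s5, s10):
        # geometric interpolation to 5y, flattening to the 10y value
        a = np.empty(11)
        a[:6] = s5 ** (np.arange(6) / 5.0)
        a[6:] = s5 * (s10 / s5) ** (np.arange(1, 6) / 5.0)
        return a
    return StageSurvival(
        years=years,
        survival={
            "I": curve(0.97, 0.95),
            "II": curve(0.89, 0.84),
            "III": curve(0.70, 0.60),
            "IV": curve(0.15, 0.10),
        },
    )


DEFAULT_STAGE_DISTRIBUTION = np.array([0.18, 0.24, 0.31, 0.27])


def default_tests() -> dict:
    """Operating characteristics per modality (per-lesion sensitivity)."""
    return {
        "gFOBT": ScreeningTest(
            name="gFOBT",
            sensitivity_by_state={
                "adenoma_small": 0.01,
                "adenoma_medium": 0.03,
                "adenoma_large": 0.10,
                "preclinical_I": 0.35,
                "preclinical_II": 0.40,
                "preclinical_III": 0.45,
                "preclinical_IV": 0.50,
            },
            specificity=0.975,
        ),
        "FIT": ScreeningTest(
            name="FIT",
            cutoff_label="47 ug Hb/g",
            sensitivity_by_state={
                "adenoma_small": 0.04,
                "adenoma_medium": 0.10,
                "adenoma_large": 0.32,
                "preclinical_I": 0.70,
                "preclinical_II": 0.78,
                "preclinical_III": 0.84,
                "preclinical_IV": 0.88,
            },
            specificity=0.97,
        ),
        "FS": ScreeningTest(
            name="FS",
            sensitivity_by_state={
                "adenoma_small": 0.40,
                "adenoma_medium": 0.50,
                "adenoma_large": 0.60,
                "preclinical_I": 0.60,
                "preclinical_II": 0.62,
                "preclinical_III": 0.64,
                "preclinical_IV": 0.66,
            },
            specificity=0.97,
            complication_probs={"serious": 0.0001, "cardiovascular": 0.0001, "other": 0.001},
        ),
        "colonoscopy": ScreeningTest(
            name="colonoscopy",
            sensitivity_by_state={
                "adenoma_small": 0.77,
                "adenoma_medium": 0.87,
                "adenoma_large": 0.95,
                "preclinical_I": 0.95,
                "preclinical_II": 0.97,
                "preclinical_III": 0.98,
                "preclinical_IV": 0.98,
            },
            specificity=1.0,
            complication_probs={"serious": 0.002, "cardiovascular": 0.001, "other": 0.012},
            is_direct_visualization=True,
        ),
    }


def default_programme_history() -> tuple:
    """Biennial FIT 55-75 since 2014, 71.3% participation."""
    return (
        ProgrammeDesign(
            test_name="FIT",
            start_age=55,
            stop_age=75,
            interval=2,
            participation=0.713,
            invitation_coverage=1.0,
            followup_adherence=0.85,
            start_year=2014,
            end_year=None,
        ),
    )


def benchmark_model(region: str = "western") -> ModelParams:
    """One of the four shipped regional benchmark parameter sets."""
    region = region.lower()
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    return ModelParams(
        life_table=default_life_table(),
        pyramid=default_pyramid(),
        onset=default_onset_hazard(region),
        lesion_space=default_lesion_space(),
        survival=default_stage_survival(),
        stage_distribution=DEFAULT_STAGE_DISTRIBUTION.copy(),
        tests=default_tests(),
        programme_history=default_programme_history(),
        surveillance=SurveillanceProtocol(),
        base_year=2018,
    )
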