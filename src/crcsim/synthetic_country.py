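"""Synthetic country templates with known ground truth.

The generator emulates what a national screening registry would upload:
a population pyramid, a life table, age-band CRC incidence, stage mix,
stage-specific relative survival, and the running FIT programme.  The
incidence section is computed from the ground-truth parameter set via
the deterministic incidence oracle, so benchmark adjustment has an
exact fixed point and calibration recovery can be tested against known
onset multipliers.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .benchmarks import benchmark_model
from .country_template import CountryTemplate, IncidenceTable, write_template
from .natural_history import cohort_oracle
from .params import (
    STAGES,
    LifeTable,
    ModelParams,
    PopulationPyramid,
    ProgrammeDesign,
    StageSurvival,
)

__all__ = ["SyntheticSpec", "generate_synthetic_country", "make_fixture"]

_LEVEL_SCALE = {"low": 0.7, "medium": 1.0, "high": 1.4}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic country.

    ``onset_multipliers`` scales the regional benchmark onset hazard per
    5-year age band (length 20, bands 0-4 .. 95-99); if None, a flat
    profile at the ``incidence_level`` scale is used.  Participation
    defaults to 0.713, mirroring a typical organised FIT programme.
    """

    seed: int = 0
    region: str = "western"
    base_population: float = 10_000_000.0
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.095
    background_mortality: float = 5e-4
    onset_multipliers: tuple | None = None
    incidence_level: str = "medium"
    participation: float = 0.713
    invitation_coverage: float = 1.0
    followup_adherence: float = 0.85
    programme: ProgrammeDesign = field(
        default_factory=lambda: ProgrammeDesign(
            test_name="FIT",
            start_age=55,
            stop_age=75,
            interval=2,
            participation=0.713,
            invitation_coverage=1.0,
            followup_adherence=0.85,
            start_year=2014,
        )
    )


def _synthetic_life_table(spec: SyntheticSpec) -> LifeTable:
    age = np.arange(101)
    qx = spec.gompertz_a * np.exp(spec.gompertz_b * age) + spec.background_mortality
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(age=age, qx=qx)


def _synthetic_pyramid(spec: SyntheticSpec, rng: np.random.Generator) -> PopulationPyramid:
    age = np.arange(101)
    shape = np.where(age < 45, 1.0, np.exp(-0.022 * (age - 45)))
    shape = shape * (1.0 + 0.05 * np.sin(age / 9.0)) * (1.0 + rng.normal(0, 0.01, size=101))
    shape = np.maximum(shape, 0.0)
    count = shape / shape.sum() * spec.base_population
    return PopulationPyramid(age=age, count=count, base_year=2018)


def _band_profile_to_age_factors(multipliers: np.ndarray, n_ages: int) -> np.ndarray:
    factors = np.ones(n_ages)
    for i, m in enumerate(multipliers):
        lo, hi = 5 * i, min(5 * (i + 1), n_ages)
        if lo >= n_ages:
            break
        factors[lo:hi] = m
    return factors


def _jitter_survival(base: StageSurvival, rng: np.random.Generator) -> StageSurvival:
    """Plausibly perturbed stage survival: jitter the 10-year level per
    stage, preserve monotonicity and the I >= II >= III >= IV ordering."""
    new = {}
    prev = None
    for s in STAGES:
        v = base.survival[s].copy()
        f = float(np.clip(1.0 + rng.normal(0, 0.03), 0.9, 1.1))
        # exponent-tilt the whole curve (keeps S(0)=1 and monotonicity)
        v = v ** f
        if prev is not None:
            v = np.minimum(v, prev)
        v = np.minimum.accumulate(v)
        new[s] = v
        prev = v
    return StageSurvival(years=base.years.copy(), survival=new)


def _jitter_stage_distribution(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = base * np.exp(rng.normal(0, 0.08, size=4))
    return w / w.sum()


def generate_synthetic_country(spec: SyntheticSpec) -> tuple:
    """Generate (CountryTemplate, ground-truth ModelParams).

    The template's incidence equals the oracle incidence of the returned
    ground-truth parameters (numerically, per 5-year band), so the
    calibration has an exact fixed point; the template always passes the
    quality checks with zero errors.
    """
    rng = np.random.default_rng(int(spec.seed))
    bench = benchmark_model(spec.region)
    life_table = _synthetic_life_table(spec)
    pyramid = _synthetic_pyramid(spec, rng)

    if spec.onset_multipliers is not None:
        mult = np.asarray(spec.onset_multipliers, dtype=float)
    else:
        mult = np.full(20, _LEVEL_SCALE[spec.incidence_level])
    factors = _band_profile_to_age_factors(mult, len(bench.onset.hazard))

    programme = replace(
        spec.programme,
        participation=spec.participation,
        invitation_coverage=spec.invitation_coverage,
        followup_adherence=spec.followup_adherence,
    )
    truth = replace(
        bench,
        life_table=life_table,
        pyramid=pyramid,
        onset=bench.onset.scaled(factors),
        survival=_jitter_survival(bench.survival, rng),
        stage_distribution=_jitter_stage_distribution(bench.stage_distribution, rng),
        programme_history=(programme,),
    )

    inc_by_age = cohort_oracle(truth, max_age=100, dt=0.02)
    lo = np.arange(0, 100, 5)
    hi = lo + 4
    rates = np.array([inc_by_age[a : a + 5].mean() for a in lo])
    incidence = IncidenceTable(age_low=lo, age_high=hi, rate_per_100k=rates)

    template = CountryTemplate(
        incidence=incidence,
        screening_history=(programme,),
        participation=spec.participation,
        invitation_coverage=spec.invitation_coverage,
        followup_adherence=spec.followup_adherence,
        pyramid=pyramid,
        life_table=life_table,
        stage_distribution=truth.stage_distribution,
        survival=truth.survival,
        supplied=frozenset(
            (
                "incidence",
                "screening_history",
                "participation",
                "population",
                "lifetable",
                "stage_distribution",
                "relative_survival",
            )
        ),
    )
    return template, truth


def make_fixture(spec: SyntheticSpec, out_dir) -> tuple:
    """Generate a synthetic country and write its canonical CSV template
    directory; returns (template, ground-truth params)."""
    template, truth = generate_synthetic_country(spec)
    write_template(template, out_dir)
    return template, truth
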