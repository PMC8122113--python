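"""Scenario comparison engine.

No-screening / current / alternative screening scenarios run over one
shared simulated population: the latent natural histories are realized
once per (seed, cohort) and reused by every scenario (common random
numbers), so scenario differences reflect the intervention rather than
Monte Carlo noise.  Persons are simulated as birth cohorts covering
ages 40-100 over the 2018-2050 reporting window; screening before the
switch year follows the uploaded programme history identically across
screening scenarios, and outcome counts are tallied per calendar year,
5-year age band and birth cohort, then scaled to the country population
via per-cohort scaling factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .natural_history import Cohort, _rng_for, generate_cohort
from .params import STAGES, LifeTable, ModelParams, PopulationPyramid, ProgrammeDesign
from .screening import simulate_person_screening

__all__ = [
    "Scenario",
    "AnnualOutcomes",
    "RawOutcomes",
    "ScalingFactors",
    "METRICS",
    "run_comparison",
    "scale_to_population",
    "person_years_projection",
]

METRICS = (
    "crc_cases",
    "crc_deaths",
    "tests_gFOBT",
    "tests_FIT",
    "tests_FS",
    "tests_colonoscopy",
    "positives",
    "false_positives",
    "followup_colonoscopies",
    "surveillance_colonoscopies",
    "adenomas_detected",
    "cancers_detected",
    "complications_serious",
    "complications_cardiovascular",
    "complications_other",
)
_METRIC_INDEX = {m: i for i, m in enumerate(METRICS)}

_EVENT_TO_METRIC = {
    "positive": "positives",
    "false_positive": "false_positives",
    "followup_colonoscopy": "followup_colonoscopies",
    "surveillance_colonoscopy": "surveillance_colonoscopies",
    "adenoma_detected": "adenomas_detected",
    "cancer_detected": "cancers_detected",
    "complication_serious": "complications_serious",
    "complication_cardiovascular": "complications_cardiovascular",
    "complication_other": "complications_other",
}


@dataclass(frozen=True)
class Scenario:
    """One screening scenario: a post-switch-year programme design (or
    None for no screening at all).  Changes are implemented at the
    switch year; earlier screening follows the uploaded history."""

    label: str
    design: ProgrammeDesign | None
    switch_year: int = 2018

    @classmethod
    def no_screening(cls, label: str = "No screening") -> "Scenario":
        return cls(label=label, design=None)

    @classmethod
    def current_programme(cls, params: ModelParams, label: str = "Current programme", switch_year: int = 2018) -> "Scenario":
        """Continue the latest uploaded programme unchanged after the switch."""
        if not params.programme_history:
            raise ValueError("no uploaded programme history to continue")
        last = params.programme_history[-1]
        return cls(label=label, design=replace(last, start_year=switch_year, end_year=None), switch_year=switch_year)

    def programmes(self, params: ModelParams) -> list:
        """History clipped at the switch year plus the scenario design.

        The no-screening scenario is the fully unscreened counterfactual
        (no historical screening either)."""
        if self.design is None:
            return []
        out = []
        for d in params.programme_history:
            end = self.switch_year - 1 if d.end_year is None else min(d.end_year, self.switch_year - 1)
            if end >= d.start_year:
                out.append(replace(d, end_year=end))
        out.append(replace(self.design, start_year=max(self.design.start_year, self.switch_year)))
        return out


@dataclass
class ScalingFactors:
    """Per-birth-cohort ratio of real population count to simulated
    persons; counts scale linearly."""

    birth_years: np.ndarray
    factors: np.ndarray

    def __post_init__(self):
        if np.any(self.factors <= 0):
            raise ValueError("scaling factors must be positive")


@dataclass
class RawOutcomes:
    """Unscaled per-cohort tallies: metric -> (n_cohorts, n_years, n_bands)."""

    years: np.ndarray
    band_edges: np.ndarray
    birth_years: np.ndarray
    n_per_cohort: int
    counts: dict


@dataclass
class AnnualOutcomes:
    """Per-calendar-year, per-age-band outcome counts (population scale
    after ``scale_to_population``).  ``person_years`` comes from the
    demographic projection and is scenario-invariant."""

    years: np.ndarray
    band_edges: np.ndarray
    counts: dict
    person_years: np.ndarray | None = None

    def band_slice(self, age_lo: int, age_hi: int) -> slice:
        """Bands covering inclusive ages [age_lo, age_hi]; edges must align."""
        edges = self.band_edges
        lo = int(np.searchsorted(edges, age_lo))
        if edges[lo] != age_lo:
            raise ValueError(f"age {age_lo} does not align with band edges")
        if age_hi + 1 >= edges[-2]:
            # window closing inside the open-ended last band (e.g. 100+)
            return slice(lo, len(edges) - 1)
        hi = int(np.searchsorted(edges, age_hi + 1))
        if edges[hi] != age_hi + 1:
            raise ValueError(f"age {age_hi} does not align with band edges")
        return slice(lo, hi)

    def total(self, metric: str, age_lo: int = 0, age_hi: int = 104, years=None) -> float:
        sl = self.band_slice(age_lo, min(age_hi, int(self.band_edges[-1]) - 1))
        arr = self.counts[metric][:, sl]
        if years is not None:
            y0, y1 = years
            mask = (self.years >= y0) & (self.years <= y1)
            arr = arr[mask]
        return float(arr.sum())

    def per_year(self, metric: str, age_lo: int = 0, age_hi: int = 104) -> np.ndarray:
        sl = self.band_slice(age_lo, min(age_hi, int(self.band_edges[-1]) - 1))
        return self.counts[metric][:, sl].sum(axis=1)

    def person_years_per_year(self, age_lo: int = 40, age_hi: int = 100) -> np.ndarray:
        if self.person_years is None:
            raise ValueError("person-years not attached")
        sl = self.band_slice(age_lo, min(age_hi, int(self.band_edges[-1]) - 1))
        return self.person_years[:, sl].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (year, age_band, metric, value) table."""
        rows = []
        labels = [
            f"{int(self.band_edges[i])}-{int(self.band_edges[i + 1]) - 1}"
            for i in range(len(self.band_edges) - 1)
        ]
        metrics = dict(self.counts)
        if self.person_years is not None:
            metrics["person_years"] = self.person_years
        for metric, arr in metrics.items():
            for yi, year in enumerate(self.years):
                for bi, lab in enumerate(labels):
                    rows.append((int(year), lab, metric, float(arr[yi, bi])))
        return pd.DataFrame(rows, columns=["year", "age_band", "metric", "value"])

    def equals(self, other: "AnnualOutcomes") -> bool:
        """Bitwise equality of all counts (common-random-number checks)."""
        if set(self.counts) != set(other.counts):
            return False
        return all(np.array_equal(self.counts[m], other.counts[m]) for m in self.counts)


# ---------------------------------------------------------------------------

def person_years_projection(
    pyramid: PopulationPyramid,
    life_table: LifeTable,
    years: tuple = (2018, 2050),
    band_edges: np.ndarray | None = None,
) -> np.ndarray:
    """Person-years per (calendar year, age band) from a deterministic
    cohort-component projection of the base-year pyramid (closed to
    migration, deaths uniform within the year).  Scenario-invariant by
    construction: the projection uses demography only."""
    if band_edges is None:
        band_edges = np.arange(0, 110, 5)
    band_edges = np.asarray(band_edges)
    y0, y1 = years
    n_years = y1 - y0 + 1
    max_age = life_table.terminal_age
    n = np.zeros(max_age + 1)
    ages = pyramid.age
    n[ages[ages <= max_age]] = pyramid.count[ages <= max_age]
    out = np.zeros((n_years, len(band_edges) - 1))
    band_of = np.clip(np.searchsorted(band_edges, np.arange(max_age + 1), side="right") - 1, 0, len(band_edges) - 2)
    for yi in range(n_years):
        deaths = n * life_table.qx[: max_age + 1]
        py = n - 0.5 * deaths
        np.add.at(out[yi], band_of, py)
        nxt = np.zeros_like(n)
        nxt[1:] = (n - deaths)[:-1]
        n = nxt
    return out


def scale_to_population(raw: RawOutcomes, factors: ScalingFactors, person_years: np.ndarray | None = None) -> AnnualOutcomes:
    """Multiply every cohort's counts by its scaling factor and sum —
    exact linearity in the factors."""
    if not np.array_equal(raw.birth_years, factors.birth_years):
        raise ValueError("scaling factors do not cover the simulated cohorts")
    counts = {m: np.tensordot(factors.factors, arr, axes=1) for m, arr in raw.counts.items()}
    return AnnualOutcomes(
        years=raw.years.copy(),
        band_edges=raw.band_edges.copy(),
        counts=counts,
        person_years=person_years,
    )


# ---------------------------------------------------------------------------

def _latent_dx(cohort: Cohort) -> tuple:
    """(dx_age, stage) of the first clinical surfacing per person under
    no screening; inf/0 where no lesion ever surfaces."""
    n = cohort.n
    les = cohort.lesions
    dx_age = cohort.first_surface_age
    stage = np.zeros(n, dtype=np.int64)
    has = np.isfinite(dx_age)
    if len(les):
        order = np.lexsort((les.surface_age, les.person_idx))
        pid = les.person_idx[order]
        first = np.unique(pid, return_index=True)
        stage_first = les.clinical_stage[order][first[1]]
        stage[first[0]] = np.where(has[first[0]], stage_first, 0)
    return dx_age, stage


def _crc_death_ages(params: ModelParams, dx_age: np.ndarray, stage: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Age at CRC death (inf if cured) from the shared survival uniforms."""
    out = np.full(len(dx_age), np.inf)
    for k, s in enumerate(STAGES, start=1):
        m = stage == k
        if m.any():
            t = params.survival.inverse_cdf(s, u[m])
            out[m] = dx_age[m] + t
    return out


class _CohortTally:
    """Accumulates screening events into (metric, year, band) arrays for
    a fixed cohort."""

    def __init__(self, arr: np.ndarray, cohort_idx: int, birth_time: float, y0: int, y1: int):
        self.arr = arr
        self.c = cohort_idx
        self.birth_time = birth_time
        self.y0 = y0
        self.y1 = y1

    def __call__(self, time: float, event: str, test_name: str = "", count: int = 1):
        year = int(np.floor(time))
        if year < self.y0 or year > self.y1:
            return
        metric = f"tests_{test_name}" if event == "test" else _EVENT_TO_METRIC[event]
        age = int(np.floor(time - self.birth_time))
        band = min(age // 5, self.arr.shape[3] - 1)
        self.arr[_METRIC_INDEX[metric], self.c, year - self.y0, band] += count


def _tally_cases_deaths(
    arr: np.ndarray,
    cohort_idx: int,
    birth_time: float,
    dx_age: np.ndarray,
    death_crc_age: np.ndarray,
    death_other_age: np.ndarray,
    y0: int,
    y1: int,
) -> None:
    n_bands = arr.shape[3]

    def add(metric, age_events):
        t = birth_time + age_events
        year = np.floor(t).astype(int)
        ok = (year >= y0) & (year <= y1)
        if not ok.any():
            return
        age = np.floor(age_events[ok]).astype(int)
        band = np.minimum(age // 5, n_bands - 1)
        np.add.at(arr[_METRIC_INDEX[metric], cohort_idx], (year[ok] - y0, band), 1)

    has_dx = np.isfinite(dx_age)
    add("crc_cases", dx_age[has_dx])
    died = np.isfinite(death_crc_age) & (death_crc_age < death_other_age)
    add("crc_deaths", death_crc_age[died])


def run_comparison(
    params: ModelParams,
    scenarios: list,
    n_sim: int,
    master_seed: int,
    years: tuple = (2018, 2050),
    cohort_ages: tuple = (40, 100),
    progress: bool = False,
) -> tuple:
    """Simulate all scenarios over a shared population.

    Returns ({label: RawOutcomes}, ScalingFactors).  ``n_sim`` persons
    are split evenly over the birth cohorts that pass through ages
    ``cohort_ages`` during ``years``; each cohort's natural histories
    are generated once and shared by every scenario.
    """
    labels = [sc.label for sc in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    y0, y1 = years
    base = params.base_year
    birth_years = np.arange(y0 - cohort_ages[1], y1 - cohort_ages[0] + 1)
    n_cohorts = len(birth_years)
    n_c = max(1, int(n_sim) // n_cohorts)
    band_edges = np.arange(0, 110, 5)
    n_years = y1 - y0 + 1
    n_bands = len(band_edges) - 1

    pyr_count = np.zeros(n_cohorts)
    for i, b in enumerate(birth_years):
        age = base - b
        idx = np.flatnonzero(params.pyramid.age == age)
        pyr_count[i] = params.pyramid.count[idx[0]] if len(idx) else 0.0
    factors = ScalingFactors(birth_years=birth_years, factors=np.maximum(pyr_count, 1e-12) / n_c)

    arrays = {
        sc.label: np.zeros((len(METRICS), n_cohorts, n_years, n_bands)) for sc in scenarios
    }
    scenario_programmes = {sc.label: sc.programmes(params) for sc in scenarios}

    iterator = enumerate(birth_years)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(list(iterator), desc="cohorts")
        except ImportError:
            pass

    for ci, b in iterator:
        min_age = max(0.0, base - (b + 0.5))
        if min_age > params.life_table.terminal_age:
            continue  # cohort extinct by the base year (pyramid count ~0)
        cohort = generate_cohort(
            params, int(b), n_c, master_seed, cohort_key=ci, condition_alive_age=min_age
        )
        latent_age, latent_stage = _latent_dx(cohort)
        death_other = cohort.death_age_other
        birth_time = cohort.birth_time
        les = cohort.lesions

        for si, sc in enumerate(scenarios):
            arr = arrays[sc.label]
            progs = scenario_programmes[sc.label]
            if not progs:
                dx_age, stage = latent_age.copy(), latent_stage.copy()
                dx_age[dx_age >= death_other] = np.inf
            else:
                dx_age = np.full(cohort.n, np.inf)
                stage = np.zeros(cohort.n, dtype=np.int64)
                tally = _CohortTally(arr, ci, birth_time, y0, y1)
                rng_pre = _rng_for(master_seed, ci, 4)
                rng_post = _rng_for(master_seed, ci, 5, si)
                any_invite_age = min(
                    (d.start_age for d in progs), default=np.inf
                )
                for i in range(cohort.n):
                    lo, hi = les.slices[i]
                    d_other = birth_time + death_other[i]
                    if hi == lo and death_other[i] <= any_invite_age:
                        continue  # no lesions, dies before first invitation
                    out = simulate_person_screening(
                        birth_time,
                        d_other,
                        les.onset_age[lo:hi],
                        les.entry_ages[lo:hi],
                        les.surface_age[lo:hi],
                        les.clinical_stage[lo:hi],
                        progs,
                        params,
                        sc.switch_year,
                        rng_pre,
                        rng_post,
                        tally,
                    )
                    if out.dx_time is not None:
                        stage[i] = out.dx_stage
                        if out.clinical_lesion is not None:
                            # exact surfacing age of the diagnosing lesion, so
                            # an untouched person matches the latent path bitwise
                            dx_age[i] = les.surface_age[lo + out.clinical_lesion]
                        else:
                            dx_age[i] = out.dx_time - birth_time
            death_crc = _crc_death_ages(params, dx_age, stage, cohort.u_survival)
            death_crc[~np.isfinite(dx_age)] = np.inf
            _tally_cases_deaths(
                arr, ci, birth_time, dx_age, death_crc, death_other, y0, y1
            )

    raws = {
        sc.label: RawOutcomes(
            years=np.arange(y0, y1 + 1),
            band_edges=band_edges,
            birth_years=birth_years,
            n_per_cohort=n_c,
            counts={m: arrays[sc.label][i] for i, m in enumerate(METRICS)},
        )
        for sc in scenarios
    }
    return raws, factors
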