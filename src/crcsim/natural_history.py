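"""Colorectal cancer natural-history simulation.

One simulated life is: a draw of other-cause death from the life table;
adenoma onsets from a nonhomogeneous Poisson process with an age-specific
hazard (times a birth-cohort multiplier); per-lesion growth through the
adenoma size classes; for the progressive subset, invasion to preclinical
cancer stages I--IV with competing clinical surfacing; and, after the
first clinical diagnosis, a CRC death time drawn from the stage-specific
relative-survival table (10-year cure point).  The first clinical cancer
ends natural-history simulation for that person; the reported death is
whichever of CRC and other-cause death comes first.

Two equivalent routes exist to age-specific clinical incidence:

* Monte Carlo over individual histories (`generate_cohort`), and
* a deterministic oracle (`cohort_oracle`) that convolves the onset
  intensity with the phase-type density of time from adenoma onset to
  clinical surfacing, obtained from the matrix exponential of the lesion
  chain's sub-generator.

Because adenoma onsets are Poisson and lesions evolve independently, the
hazard of *first* clinical diagnosis at age a equals the unthinned
surfacing intensity at a, so the oracle is exact for incidence per
at-risk (alive and undiagnosed) person-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.signal import fftconvolve

from .params import (
    N_STATES,
    STAGES,
    LifeTable,
    LesionStateSpace,
    ModelParams,
    OnsetHazard,
    StageSurvival,
)

__all__ = [
    "Lesion",
    "PersonHistory",
    "LesionSet",
    "Cohort",
    "sample_other_cause_death",
    "sample_death_ages",
    "sample_adenoma_onsets",
    "progress_lesion",
    "surface_clinical",
    "sample_crc_death",
    "simulate_lesion_batch",
    "generate_cohort",
    "cohort_oracle",
    "expected_band_cases",
]


# ---------------------------------------------------------------------------
# Person-level containers

@dataclass
class Lesion:
    """One lesion's realized trajectory (ages, not calendar years).

    ``entry_ages[i]`` is the age at entry into lesion state i
    (adenoma_small .. preclinical_IV); ``inf`` marks states never
    reached.  ``surface_age`` is the age of clinical surfacing (``inf``
    if the lesion never surfaces), ``surface_stage`` the mechanistic
    stage 1-4 at surfacing, and ``clinical_stage`` the stage assigned to
    a clinical diagnosis (drawn from the stage-at-diagnosis
    distribution when one is supplied, else the mechanistic stage).
    """

    onset_age: float
    progressive: bool
    entry_ages: np.ndarray
    surface_age: float = np.inf
    surface_stage: int = 0
    clinical_stage: int = 0

    def state_at(self, age: float) -> int | None:
        """Lesion state index at ``age``; None before onset or after surfacing."""
        if age < self.onset_age or age >= self.surface_age:
            return None
        k = int(np.searchsorted(self.entry_ages, age, side="right")) - 1
        return k if k >= 0 else None


@dataclass
class PersonHistory:
    """One simulated life history in calendar time."""

    birth_year: int
    birth_time: float  # continuous calendar time of birth (mid-year)
    death_time_other: float  # calendar time of other-cause death
    lesions: list = field(default_factory=list)
    clinical_dx: tuple | None = None  # (calendar time, stage 1-4)
    crc_death_time: float | None = None
    screen_detected: bool = False

    @property
    def death_time(self) -> float:
        if self.crc_death_time is not None:
            return min(self.death_time_other, self.crc_death_time)
        return self.death_time_other

    def age_at(self, t: float) -> float:
        return t - self.birth_time


# ---------------------------------------------------------------------------
# Elementary sampling operations

def sample_death_ages(
    life_table: LifeTable, n: int, rng: np.random.Generator, min_age: float = 0.0
) -> np.ndarray:
    """Draw n continuous ages at other-cause death, conditional on being
    alive at ``min_age``; deaths are uniform within their year of age."""
    qx = life_table.qx
    t = life_table.terminal_age
    if min_age >= t + 1:
        raise ValueError("min_age beyond terminal age")
    s = life_table.survival()  # S at exact integer ages 0..t+1
    a0 = int(np.floor(max(min_age, 0.0)))
    frac = max(min_age, 0.0) - a0
    # P(death in [a, a+1)) for a >= a0, adjusted for the partial first year.
    pmf = s[a0 : t + 1] * qx[a0:]
    pmf = pmf.copy()
    pmf[0] *= 1.0 - frac  # only the remaining part of the first year
    alive = s[a0] * (1.0 - qx[a0] * frac)
    if alive <= 0:
        raise ValueError("life table assigns zero probability of being alive at min_age")
    pmf /= alive
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0  # qx terminal = 1 guarantees sum 1 up to rounding
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    ages = a0 + idx.astype(float)
    w = rng.random(n)
    lo = np.where(idx == 0, frac, 0.0)
    return ages + lo + w * (1.0 - lo)


def sample_other_cause_death(
    life_table: LifeTable, birth_year: int, rng: np.random.Generator, min_age: float = 0.0
) -> float:
    """Calendar time of other-cause death for one person born mid-year."""
    age = sample_death_ages(life_table, 1, rng, min_age=min_age)[0]
    return birth_year + 0.5 + float(age)


def sample_adenoma_onsets(
    onset: OnsetHazard,
    lifespan: float,
    rng: np.random.Generator,
    multiplier: float = 1.0,
) -> np.ndarray:
    """Onset ages from the nonhomogeneous Poisson process, truncated at
    ``lifespan``; the hazard is piecewise constant per year of age."""
    if lifespan <= 0:
        return np.empty(0)
    haz = onset.hazard * multiplier
    ages = onset.age
    exposure = np.clip(lifespan - ages, 0.0, 1.0)
    rates = haz * exposure
    counts = rng.poisson(rates)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    base = np.repeat(ages.astype(float), counts)
    width = np.repeat(exposure, counts)
    times = base + rng.random(total) * width
    return np.sort(times)


def simulate_lesion_batch(
    space: LesionStateSpace,
    onset_ages: np.ndarray,
    rng: np.random.Generator,
    progressive: np.ndarray | None = None,
) -> dict:
    """Simulate the lesion Markov chain for a batch of onsets.

    Returns arrays: progressive (bool), entry_ages (m, 7) with inf for
    unreached states, surface_age (m,), surface_stage (m,) in 0..4
    (0 = never surfaces).  Growth through the adenoma size classes uses
    the shared progression rates; only progressive lesions may take the
    large-adenoma -> preclinical transition, and at each preclinical
    stage progression and clinical surfacing compete exponentially.
    """
    m = len(onset_ages)
    prog_rates = space.progression_array()  # exits for states 0..5
    surf_rates = space.surfacing_array()  # surfacing for states 3..6
    if progressive is None:
        progressive = rng.random(m) < space.p_progressive
    progressive = np.asarray(progressive, dtype=bool)

    entry = np.full((m, N_STATES), np.inf)
    entry[:, 0] = onset_ages
    surface_age = np.full(m, np.inf)
    surface_stage = np.zeros(m, dtype=np.int64)

    t = np.asarray(onset_ages, dtype=float).copy()
    active = np.ones(m, dtype=bool)
    for s in range(N_STATES):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        if s < 3:
            rate = prog_rates[s]
            if s == 2:
                # only progressive lesions leave the large-adenoma state
                idx = idx[progressive[idx]]
                active[:] = False
                active[idx] = True
                if len(idx) == 0:
                    break
            if rate <= 0.0:
                break  # absorbing: nothing ever leaves this state
            dwell = rng.exponential(1.0 / rate, size=len(idx))
            t[idx] = t[idx] + dwell
            entry[idx, s + 1] = t[idx]
        else:
            k = s - 3  # preclinical stage index 0..3
            rho = prog_rates[s] if s < N_STATES - 1 else 0.0
            sigma = surf_rates[k]
            total = rho + sigma
            if total <= 0.0:
                break
            dwell = rng.exponential(1.0 / total, size=len(idx))
            t[idx] = t[idx] + dwell
            surf = rng.random(len(idx)) < sigma / total
            sid = idx[surf]
            surface_age[sid] = t[sid]
            surface_stage[sid] = k + 1
            active[sid] = False
            nid = idx[~surf]
            if s == N_STATES - 1:
                active[nid] = False  # rho = 0 there, so nid is empty anyway
            else:
                entry[nid, s + 1] = t[nid]
    return {
        "progressive": progressive,
        "entry_ages": entry,
        "surface_age": surface_age,
        "surface_stage": surface_stage,
    }


def progress_lesion(
    onset_age: float,
    space: LesionStateSpace,
    censor_age: float,
    rng: np.random.Generator,
    progressive: bool | None = None,
) -> Lesion:
    """Simulate a single lesion trajectory from onset, truncated at
    ``censor_age`` (entries after the censor time are discarded)."""
    if onset_age >= censor_age:
        raise ValueError("lesion onset must precede the censoring time")
    out = simulate_lesion_batch(
        space,
        np.array([onset_age]),
        rng,
        progressive=None if progressive is None else np.array([progressive]),
    )
    entry = out["entry_ages"][0]
    entry = np.where(entry <= censor_age, entry, np.inf)
    surface = float(out["surface_age"][0])
    stage = int(out["surface_stage"][0])
    if surface > censor_age:
        surface, stage = np.inf, 0
    return Lesion(
        onset_age=float(onset_age),
        progressive=bool(out["progressive"][0]),
        entry_ages=entry,
        surface_age=surface,
        surface_stage=stage,
        clinical_stage=stage,
    )


def surface_clinical(person: PersonHistory) -> tuple | None:
    """Earliest clinical surfacing among the person's lesions before
    other-cause death: (calendar diagnosis time, stage), or None."""
    best_t, best_stage = np.inf, 0
    for les in person.lesions:
        t = person.birth_time + les.surface_age
        if t < best_t:
            best_t = t
            best_stage = les.clinical_stage if les.clinical_stage else les.surface_stage
    if best_t < person.death_time_other:
        return best_t, best_stage
    return None


def sample_crc_death(
    dx: tuple,
    survival: StageSurvival,
    other_cause_death: float,
    rng: np.random.Generator,
) -> float | None:
    """CRC death time for a diagnosis (time, stage 1-4), or None if the
    person is cured (survives the 10-year horizon) or dies of other
    causes first."""
    dx_time, stage = dx
    if dx_time >= other_cause_death:
        raise ValueError("diagnosis must precede other-cause death")
    u = rng.random()
    t = survival.inverse_cdf(STAGES[stage - 1], u)[0]
    if not np.isfinite(t):
        return None
    crc = dx_time + float(t)
    return crc if crc < other_cause_death else None


# ---------------------------------------------------------------------------
# Vectorized cohort generation

@dataclass
class LesionSet:
    """Flat arrays describing all lesions of a cohort, grouped by person.

    ``slices[i] = (lo, hi)`` indexes person i's lesions.
    """

    person_idx: np.ndarray
    onset_age: np.ndarray
    progressive: np.ndarray
    entry_ages: np.ndarray  # (m, 7)
    surface_age: np.ndarray
    surface_stage: np.ndarray
    clinical_stage: np.ndarray
    slices: np.ndarray  # (n, 2)

    def __len__(self) -> int:
        return len(self.onset_age)


@dataclass
class Cohort:
    """A birth cohort of simulated persons with latent (no-screening)
    natural histories; screening scenarios overlay on these shared
    realizations (common random numbers)."""

    birth_year: int
    n: int
    death_age_other: np.ndarray  # (n,) continuous ages
    u_survival: np.ndarray  # (n,) uniform draw reused for CRC survival
    lesions: LesionSet
    first_surface_age: np.ndarray  # (n,) min surfacing age, inf if none

    @property
    def birth_time(self) -> float:
        return self.birth_year + 0.5

    def person(self, i: int) -> PersonHistory:
        """Materialize one person as a PersonHistory (no-screening view)."""
        lo, hi = self.lesions.slices[i]
        lesions = [
            Lesion(
                onset_age=float(self.lesions.onset_age[j]),
                progressive=bool(self.lesions.progressive[j]),
                entry_ages=self.lesions.entry_ages[j],
                surface_age=float(self.lesions.surface_age[j]),
                surface_stage=int(self.lesions.surface_stage[j]),
                clinical_stage=int(self.lesions.clinical_stage[j]),
            )
            for j in range(lo, hi)
        ]
        return PersonHistory(
            birth_year=self.birth_year,
            birth_time=self.birth_time,
            death_time_other=self.birth_time + float(self.death_age_other[i]),
            lesions=lesions,
        )


def _rng_for(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)))


def generate_cohort(
    params: ModelParams,
    birth_year: int,
    n: int,
    master_seed: int,
    cohort_key: int = 0,
    condition_alive_age: float = 0.0,
    immortal: bool = False,
) -> Cohort:
    """Generate a birth cohort's latent natural histories.

    ``condition_alive_age`` conditions other-cause death on survival to
    that age (used for cohorts already alive at the base year, whose
    earlier mortality is embodied in the population pyramid).
    ``immortal`` suppresses other-cause death entirely (validation runs
    against the incidence oracle).  Deterministic given
    (master_seed, cohort_key, params).
    """
    rng_demo = _rng_for(master_seed, cohort_key, 0)
    rng_onset = _rng_for(master_seed, cohort_key, 1)
    rng_prog = _rng_for(master_seed, cohort_key, 2)
    rng_surv = _rng_for(master_seed, cohort_key, 3)

    max_age = float(params.life_table.terminal_age + 1)
    if immortal:
        death_age = np.full(n, max_age)
    else:
        death_age = sample_death_ages(params.life_table, n, rng_demo, min_age=condition_alive_age)
    mult = params.onset.multiplier(birth_year)

    # Onset counts per (person, age-year), truncated at death.
    ages = params.onset.age
    haz = params.onset.hazard * mult
    exposure = np.clip(death_age[:, None] - ages[None, :], 0.0, 1.0)
    counts = rng_onset.poisson(haz[None, :] * exposure)
    per_person = counts.sum(axis=1)
    total = int(per_person.sum())
    base = np.repeat(np.tile(ages.astype(float), n), counts.ravel())
    width = np.repeat(exposure.ravel(), counts.ravel())
    onset_age = base + rng_onset.random(total) * width
    person_idx = np.repeat(np.arange(n), per_person)

    traj = simulate_lesion_batch(params.lesion_space, onset_age, rng_prog)
    clinical_stage = rng_surv.choice(4, size=total, p=params.stage_distribution / params.stage_distribution.sum()) + 1
    clinical_stage = clinical_stage.astype(np.int64)
    u_survival = rng_surv.random(n)

    lo = np.concatenate([[0], np.cumsum(per_person)])
    slices = np.stack([lo[:-1], lo[1:]], axis=1)
    lesions = LesionSet(
        person_idx=person_idx,
        onset_age=onset_age,
        progressive=traj["progressive"],
        entry_ages=traj["entry_ages"],
        surface_age=traj["surface_age"],
        surface_stage=traj["surface_stage"],
        clinical_stage=clinical_stage,
        slices=slices,
    )
    first_surface = np.full(n, np.inf)
    np.minimum.at(first_surface, person_idx, traj["surface_age"])
    return Cohort(
        birth_year=birth_year,
        n=n,
        death_age_other=death_age,
        u_survival=u_survival,
        lesions=lesions,
        first_surface_age=first_surface,
    )


# ---------------------------------------------------------------------------
# Deterministic incidence oracle

def _surfacing_density(space: LesionStateSpace, dt: float, n_steps: int) -> np.ndarray:
    """Density g(t) of time from (progressive) adenoma onset to clinical
    surfacing, on the grid t = 0, dt, ..., n_steps*dt, via iterated
    matrix exponentials of the chain's sub-generator."""
    q = space.generator_matrix()
    step = expm(q * dt)
    sigma = space.surfacing_array()
    occ = np.zeros(N_STATES)
    occ[0] = 1.0
    g = np.empty(n_steps + 1)
    occ_hist = np.empty((n_steps + 1, N_STATES))
    for i in range(n_steps + 1):
        occ_hist[i] = occ
        g[i] = float(occ[3:] @ sigma)
        occ = occ @ step
    # mass check: occupancy remaining + surfaced mass must be ~1
    surfaced = np.trapezoid(g, dx=dt)
    mass = occ_hist[-1].sum() + surfaced
    if abs(mass - 1.0) > 1e-3:
        raise RuntimeError(
            f"surfacing-density mass check failed (total {mass:.5f}); reduce the step size"
        )
    return g


def cohort_oracle(
    params: ModelParams,
    max_age: int = 100,
    dt: float = 0.02,
    cohort_multiplier: float = 1.0,
) -> np.ndarray:
    """Expected clinical CRC incidence per 100,000 at-risk person-years,
    by single year of age 0..max_age-1, with no Monte Carlo noise.

    The hazard of first clinical diagnosis at age a is
    p_progressive * integral of onset(s) * g(a - s) ds, where g is the
    onset-to-surfacing phase-type density; by the Poisson thinning
    property this equals the incidence rate among persons alive and
    undiagnosed, independent of other-cause mortality.
    """
    steps_per_year = int(round(1.0 / dt))
    if abs(steps_per_year * dt - 1.0) > 1e-12:
        raise ValueError("dt must divide one year evenly")
    n_steps = max_age * steps_per_year
    # midpoint sampling of the piecewise-constant hazard: exact across
    # its year-boundary jumps, leaving only O(dt^2) error from g
    mid_ages = (np.arange(n_steps) + 0.5) * dt
    idx = np.minimum(mid_ages.astype(int), len(params.onset.hazard) - 1)
    haz = np.where(
        mid_ages < len(params.onset.hazard), params.onset.hazard[idx] * cohort_multiplier, 0.0
    )
    g = _surfacing_density(params.lesion_space, dt, n_steps)
    # rate at midpoint t_k = (k+1/2) dt: sum_m haz_mid[m] * g((k-m) dt) * dt
    conv = fftconvolve(haz, g[:n_steps])[:n_steps] * dt
    rate = params.lesion_space.p_progressive * conv
    per_year = rate.reshape(max_age, steps_per_year).mean(axis=1) * 1e5
    # FFT convolution leaves O(1e-12) noise where the rate is exactly zero
    per_year[np.abs(per_year) < 1e-9] = 0.0
    return per_year


def expected_band_cases(
    incidence_per_100k: np.ndarray, at_risk_py_by_age: np.ndarray, bands: list
) -> np.ndarray:
    """Expected case counts per age band given observed at-risk exposure."""
    rate = incidence_per_100k / 1e5
    out = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        out[i] = float(np.sum(rate[lo:hi] * at_risk_py_by_age[lo:hi]))
    return out
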