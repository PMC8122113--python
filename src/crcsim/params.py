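"""Parameter containers for the colorectal cancer screening microsimulator.

The natural-history model is an adenoma--carcinoma multistate process:
adenomas arise as a nonhomogeneous Poisson process in each person, grow
through three size classes, and a progressive subset invades to become
preclinical (screen-detectable) cancer in stages I--IV, from which the
cancer can surface clinically.  All dwell times are exponential, so a
lesion's life is a continuous-time Markov chain.  The containers below
hold the rates and tables that drive that process, plus the screening
test characteristics and programme designs layered on top.

Everything round-trips losslessly through plain dictionaries / YAML so a
calibrated parameter set can be archived next to its run outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

# Ordered lesion states of the adenoma--carcinoma sequence.  Indices are
# used throughout the simulator; "clinical" is a terminal pseudo-state.
LESION_STATES = (
    "adenoma_small",
    "adenoma_medium",
    "adenoma_large",
    "preclinical_I",
    "preclinical_II",
    "preclinical_III",
    "preclinical_IV",
)
N_STATES = len(LESION_STATES)
STATE_INDEX = {s: i for i, s in enumerate(LESION_STATES)}
PRECLINICAL_STATES = LESION_STATES[3:]
ADENOMA_STATES = LESION_STATES[:3]
STAGES = ("I", "II", "III", "IV")

COMPLICATION_CLASSES = ("serious", "cardiovascular", "other")


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause mortality probabilities qx by completed age.

    Ages must be contiguous from 0 to the terminal age, where qx = 1
    (everyone dies within the terminal year).
    """

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        age = np.asarray(self.age, dtype=int)
        qx = _as_float_array(self.qx)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "qx", qx)
        if age.shape != qx.shape or age.ndim != 1 or len(age) == 0:
            raise ParameterError("life table: age and qx must be equal-length 1-d arrays")
        if age[0] != 0 or np.any(np.diff(age) != 1):
            raise ParameterError("life table: ages must be contiguous from 0")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ParameterError("life table: qx outside [0, 1]")
        if qx[-1] != 1.0:
            raise ParameterError("life table: terminal-age qx must be 1")

    @property
    def terminal_age(self) -> int:
        return int(self.age[-1])

    def survival(self) -> np.ndarray:
        """S(a) = P(alive at exact age a) for a = 0 .. terminal+1."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])

    def to_dict(self) -> dict:
        return {"age": self.age.tolist(), "qx": self.qx.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LifeTable":
        return cls(age=np.asarray(d["age"]), qx=np.asarray(d["qx"]))


@dataclass(frozen=True)
class OnsetHazard:
    """Adenoma-onset intensity per person-year by single year of age.

    ``hazard[a]`` applies on the age interval [a, a+1).  The per-birth-
    cohort multiplier scales the whole curve for a given cohort; cohorts
    not listed default to 1.  Hazards need not be monotone: calibration
    is free to bend the curve.
    """

    age: np.ndarray
    hazard: np.ndarray
    cohort_multiplier: dict = field(default_factory=dict)

    def __post_init__(self):
        age = np.asarray(self.age, dtype=int)
        hazard = _as_float_array(self.hazard)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "hazard", hazard)
        if age.shape != hazard.shape or age.ndim != 1 or len(age) == 0:
            raise ParameterError("onset hazard: age and hazard must match")
        if age[0] != 0 or np.any(np.diff(age) != 1):
            raise ParameterError("onset hazard: ages must be contiguous from 0")
        if np.any(hazard < 0):
            raise ParameterError("onset hazard: negative hazard")

    @property
    def max_age(self) -> int:
        return int(self.age[-1]) + 1

    def multiplier(self, birth_year: int) -> float:
        return float(self.cohort_multiplier.get(int(birth_year), 1.0))

    def scaled(self, factors: np.ndarray) -> "OnsetHazard":
        """Return a copy with per-age multiplicative factors applied."""
        factors = _as_float_array(factors)
        if factors.shape != self.hazard.shape:
            raise ParameterError("onset hazard: factor shape mismatch")
        return replace(self, hazard=self.hazard * factors)

    def to_dict(self) -> dict:
        return {
            "age": self.age.tolist(),
            "hazard": self.hazard.tolist(),
            "cohort_multiplier": {int(k): float(v) for k, v in self.cohort_multiplier.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OnsetHazard":
        return cls(
            age=np.asarray(d["age"]),
            hazard=np.asarray(d["hazard"]),
            cohort_multiplier={int(k): float(v) for k, v in d.get("cohort_multiplier", {}).items()},
        )


@dataclass(frozen=True)
class LesionStateSpace:
    """Rates of the lesion continuous-time Markov chain.

    ``progression_rates`` holds the exit-to-next-state rate for every
    non-terminal lesion state (adenoma_small .. preclinical_III); the
    large-adenoma exit applies only to progressive lesions (decided by a
    single Bernoulli(p_progressive) draw at lesion birth).  Preclinical
    stages additionally surface clinically at ``surfacing_rates``,
    competing with stage progression; preclinical_IV can only surface.
    Nonprogressive adenomas may still grow to adenoma_large but never
    leave the adenoma states.
    """

    progression_rates: dict
    surfacing_rates: dict
    p_progressive: float

    def __post_init__(self):
        prog = {s: float(self.progression_rates[s]) for s in LESION_STATES[:-1]}
        surf = {s: float(self.surfacing_rates[s]) for s in PRECLINICAL_STATES}
        object.__setattr__(self, "progression_rates", prog)
        object.__setattr__(self, "surfacing_rates", surf)
        if any(r < 0 for r in prog.values()) or any(r < 0 for r in surf.values()):
            raise ParameterError("lesion state space: negative rate")
        if not 0.0 <= self.p_progressive <= 1.0:
            raise ParameterError("lesion state space: p_progressive outside [0, 1]")

    def progression_array(self) -> np.ndarray:
        """Exit-to-next rates for states 0..5 (preclinical_IV has none)."""
        return np.array([self.progression_rates[s] for s in LESION_STATES[:-1]])

    def surfacing_array(self) -> np.ndarray:
        """Clinical surfacing rates for preclinical I..IV."""
        return np.array([self.surfacing_rates[s] for s in PRECLINICAL_STATES])

    def generator_matrix(self) -> np.ndarray:
        """Sub-generator over the 7 transient states for progressive lesions.

        Clinical surfacing is the absorbing exit; its per-stage intensity
        is recoverable as occupancy x surfacing rate.
        """
        q = np.zeros((N_STATES, N_STATES))
        prog = self.progression_array()
        surf = self.surfacing_array()
        for i in range(N_STATES - 1):
            q[i, i + 1] = prog[i]
        for k in range(4):
            i = 3 + k
            q[i, i] -= surf[k]
        for i in range(N_STATES):
            q[i, i] -= prog[i] if i < N_STATES - 1 else 0.0
        return q

    def to_dict(self) -> dict:
        return {
            "progression_rates": dict(self.progression_rates),
            "surfacing_rates": dict(self.surfacing_rates),
            "p_progressive": float(self.p_progressive),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LesionStateSpace":
        return cls(
            progression_rates=d["progression_rates"],
            surfacing_rates=d["surfacing_rates"],
            p_progressive=d["p_progressive"],
        )


@dataclass(frozen=True)
class StageSurvival:
    """Cumulative stage-specific relative survival over 0..10 years.

    Relative (net) survival: observed survival of cases divided by the
    expected survival of a disease-free population — used here as the
    cause-specific survival from which CRC death times are drawn by
    inverse-CDF with linear interpolation.  Patients alive past the
    10-year horizon are treated as cured.
    """

    years: np.ndarray
    survival: dict  # stage label -> cumulative relative survival array

    def __post_init__(self):
        years = _as_float_array(self.years)
        surv = {s: _as_float_array(self.survival[s]) for s in STAGES}
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "survival", surv)
        if years[0] != 0 or years[-1] < 10:
            raise ParameterError("stage survival: table must cover years 0..10 since diagnosis")
        if np.any(np.diff(years) <= 0):
            raise ParameterError("stage survival: years must be increasing")
        for s, v in surv.items():
            if v.shape != years.shape:
                raise ParameterError(f"stage survival: stage {s} length mismatch")
            if abs(v[0] - 1.0) > 1e-9:
                raise ParameterError(f"stage survival: stage {s} must start at 1 at diagnosis")
            if np.any(np.diff(v) > 1e-12) or np.any(v < 0) or np.any(v > 1):
                raise ParameterError(f"stage survival: stage {s} must be nonincreasing in [0, 1]")
        for a, b in zip(STAGES[:-1], STAGES[1:]):
            if np.any(surv[a] < surv[b] - 1e-9):
                warnings.warn(
                    f"stage survival: stage {a} curve dips below stage {b}; "
                    "check the survival table ordering",
                    stacklevel=2,
                )

    def inverse_cdf(self, stage: str, u: np.ndarray) -> np.ndarray:
        """Time to CRC death for uniform draws u; inf means cured.

        P(T > t) = S(t); draws with u <= S(10) survive the horizon and
        never die of CRC.
        """
        u = np.atleast_1d(_as_float_array(u))
        s = self.survival[stage]
        # S is nonincreasing; interpolate t(S) on the reversed arrays.
        t = np.interp(u, s[::-1], self.years[::-1])
        out = np.where(u <= s[-1] + 1e-15, np.inf, t)
        return out

    def to_dict(self) -> dict:
        return {
            "years": self.years.tolist(),
            "survival": {s: v.tolist() for s, v in self.survival.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageSurvival":
        return cls(years=np.asarray(d["years"]), survival={s: np.asarray(v) for s, v in d["survival"].items()})


@dataclass(frozen=True)
class ScreeningTest:
    """A screening modality and its operating characteristics.

    ``sensitivity_by_state`` maps every detectable lesion state
    (adenoma_small .. preclinical_IV) to a per-lesion detection
    probability; ``specificity`` is the probability a lesion-free
    attendee tests negative.  Direct-visualization tests (colonoscopy)
    find and manage lesions in the same procedure, so a positive result
    needs no separate diagnostic follow-up.  ``complication_probs``
    apply per procedure of this modality.
    """

    name: str
    cutoff_label: str = ""
    sensitivity_by_state: dict = field(default_factory=dict)
    specificity: float = 1.0
    complication_probs: dict = field(default_factory=dict)
    is_direct_visualization: bool = False

    def __post_init__(self):
        sens = {s: float(self.sensitivity_by_state.get(s, 0.0)) for s in LESION_STATES}
        comp = {c: float(self.complication_probs.get(c, 0.0)) for c in COMPLICATION_CLASSES}
        object.__setattr__(self, "sensitivity_by_state", sens)
        object.__setattr__(self, "complication_probs", comp)
        probs = list(sens.values()) + list(comp.values()) + [self.specificity]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError(f"screening test {self.name}: probability outside [0, 1]")
        arr = self.sensitivity_array()
        if np.any(np.diff(arr) < -1e-12):
            warnings.warn(
                f"screening test {self.name}: sensitivity decreases with lesion severity",
                stacklevel=2,
            )

    def sensitivity_array(self) -> np.ndarray:
        return np.array([self.sensitivity_by_state[s] for s in LESION_STATES])

    def complication_array(self) -> np.ndarray:
        return np.array([self.complication_probs[c] for c in COMPLICATION_CLASSES])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoff_label": self.cutoff_label,
            "sensitivity_by_state": dict(self.sensitivity_by_state),
            "specificity": float(self.specificity),
            "complication_probs": dict(self.complication_probs),
            "is_direct_visualization": bool(self.is_direct_visualization),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningTest":
        return cls(**d)


@dataclass(frozen=True)
class ProgrammeDesign:
    """An organised screening programme over a calendar period.

    Invitations go out at ages start_age, start_age + interval, ... up
    to stop_age (inclusive), restricted to calendar years in
    [start_year, end_year].  ``invitation_coverage`` is the fraction of
    the target population actually invited, ``participation`` the
    fraction of invitees attending, ``followup_adherence`` the fraction
    of positives undergoing diagnostic colonoscopy.
    """

    test_name: str
    start_age: int
    stop_age: int
    interval: int
    participation: float
    invitation_coverage: float = 1.0
    followup_adherence: float = 1.0
    start_year: int = 2018
    end_year: int | None = None

    def __post_init__(self):
        if self.start_age > self.stop_age:
            raise ParameterError("programme: start_age > stop_age")
        if self.interval < 1:
            raise ParameterError("programme: interval must be >= 1 year")
        for p in (self.participation, self.invitation_coverage, self.followup_adherence):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("programme: fraction outside [0, 1]")

    def invitation_ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.stop_age + 1, self.interval)

    def operates_in(self, year: int) -> bool:
        if year < self.start_year:
            return False
        return self.end_year is None or year <= self.end_year

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "start_age": int(self.start_age),
            "stop_age": int(self.stop_age),
            "interval": int(self.interval),
            "participation": float(self.participation),
            "invitation_coverage": float(self.invitation_coverage),
            "followup_adherence": float(self.followup_adherence),
            "start_year": int(self.start_year),
            "end_year": None if self.end_year is None else int(self.end_year),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProgrammeDesign":
        return cls(**d)


@dataclass(frozen=True)
class SurveillanceProtocol:
    """Post-polypectomy surveillance rules (template-settable, fixed in runs).

    Findings with >= ``high_risk_count`` adenomas or any adenoma at or
    beyond ``high_risk_state`` are high risk and trigger a surveillance
    colonoscopy after ``interval_high_risk`` years (attended with
    probability ``participation``); low-risk findings return the person
    to the routine invitation schedule.
    """

    high_risk_count: int = 3
    high_risk_state: str = "adenoma_large"
    interval_high_risk: int = 3
    participation: float = 0.8

    def __post_init__(self):
        if self.interval_high_risk < 1:
            raise ParameterError("surveillance: interval must be >= 1 year")
        if not 0.0 <= self.participation <= 1.0:
            raise ParameterError("surveillance: participation outside [0, 1]")
        if self.high_risk_state not in LESION_STATES:
            raise ParameterError("surveillance: unknown trigger state")

    def to_dict(self) -> dict:
        return {
            "high_risk_count": int(self.high_risk_count),
            "high_risk_state": self.high_risk_state,
            "interval_high_risk": int(self.interval_high_risk),
            "participation": float(self.participation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurveillanceProtocol":
        return cls(**d)


@dataclass(frozen=True)
class PopulationPyramid:
    """Population count per single year of age in the base calendar year."""

    age: np.ndarray
    count: np.ndarray
    base_year: int = 2018

    def __post_init__(self):
        age = np.asarray(self.age, dtype=int)
        count = _as_float_array(self.count)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "count", count)
        if age.shape != count.shape or age.ndim != 1:
            raise ParameterError("pyramid: age/count mismatch")
        if age[0] != 0 or np.any(np.diff(age) != 1):
            raise ParameterError("pyramid: ages must be contiguous from 0")
        if np.any(count < 0):
            raise ParameterError("pyramid: negative count")

    def to_dict(self) -> dict:
        return {"age": self.age.tolist(), "count": self.count.tolist(), "base_year": int(self.base_year)}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationPyramid":
        return cls(age=np.asarray(d["age"]), count=np.asarray(d["count"]), base_year=d.get("base_year", 2018))


@dataclass(frozen=True)
class ModelParams:
    """Complete calibrated parameter set driving the simulator."""

    life_table: LifeTable
    pyramid: PopulationPyramid
    onset: OnsetHazard
    lesion_space: LesionStateSpace
    survival: StageSurvival
    stage_distribution: np.ndarray  # fractions I..IV at clinical diagnosis
    tests: dict  # name -> ScreeningTest
    programme_history: tuple = ()  # ProgrammeDesign periods before the switch year
    surveillance: SurveillanceProtocol = field(default_factory=SurveillanceProtocol)
    base_year: int = 2018

    def __post_init__(self):
        sd = _as_float_array(self.stage_distribution)
        object.__setattr__(self, "stage_distribution", sd)
        object.__setattr__(self, "programme_history", tuple(self.programme_history))
        if sd.shape != (4,) or np.any(sd < 0) or abs(sd.sum() - 1.0) > 1e-3:
            raise ParameterError("stage distribution: four nonnegative fractions summing to 1")
        for d in self.programme_history:
            if d.test_name not in self.tests:
                raise ParameterError(f"programme references unknown test {d.test_name!r}")

    def to_dict(self) -> dict:
        return {
            "life_table": self.life_table.to_dict(),
            "pyramid": self.pyramid.to_dict(),
            "onset": self.onset.to_dict(),
            "lesion_space": self.lesion_space.to_dict(),
            "survival": self.survival.to_dict(),
            "stage_distribution": self.stage_distribution.tolist(),
            "tests": {k: t.to_dict() for k, t in self.tests.items()},
            "programme_history": [d.to_dict() for d in self.programme_history],
            "surveillance": self.surveillance.to_dict(),
            "base_year": int(self.base_year),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            life_table=LifeTable.from_dict(d["life_table"]),
            pyramid=PopulationPyramid.from_dict(d["pyramid"]),
            onset=OnsetHazard.from_dict(d["onset"]),
            lesion_space=LesionStateSpace.from_dict(d["lesion_space"]),
            survival=StageSurvival.from_dict(d["survival"]),
            stage_distribution=np.asarray(d["stage_distribution"]),
            tests={k: ScreeningTest.from_dict(t) for k, t in d["tests"].items()},
            programme_history=[ProgrammeDesign.from_dict(p) for p in d.get("programme_history", [])],
            surveillance=SurveillanceProtocol.from_dict(d.get("surveillance", {})),
            base_year=d.get("base_year", 2018),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
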