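"""Screening overlay on simulated life histories.

Invitations follow the programme's age grid restricted to operating
calendar years; attendance is an independent Bernoulli per round
(invitation coverage x participation).  At an attended test every
prevalent lesion is detected independently with the test's per-state
sensitivity; a lesion-free attendee turns falsely positive with
probability 1 - specificity.  Positive stool/FS tests go to diagnostic
colonoscopy with the follow-up adherence probability; colonoscopy
(including primary colonoscopy screening, which visualizes the bowel
directly and needs no separate follow-up) removes detected adenomas,
screen-detects preclinical cancer at its current (earlier) stage — the
stage shift that carries the survival benefit — and triggers
post-polypectomy surveillance for high-risk adenoma findings.
Complications are independent Bernoulli draws per colonoscopy/FS
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    COMPLICATION_CLASSES,
    ModelParams,
    ProgrammeDesign,
    ScreeningTest,
    SurveillanceProtocol,
    STATE_INDEX,
)
from .natural_history import PersonHistory

__all__ = [
    "TestResult",
    "ScreeningEvent",
    "ScreeningEventLog",
    "build_invitation_schedule",
    "simulate_attendance",
    "apply_test",
    "resolve_positive",
    "sample_complications",
    "classify_findings",
    "simulate_person_screening",
    "PersonScreeningOutcome",
]

_PRECLINICAL_MIN = STATE_INDEX["preclinical_I"]


@dataclass
class TestResult:
    """Outcome of one applied screening test."""

    positive: bool
    detected: np.ndarray  # bool per prevalent lesion (parallel to input states)
    false_positive: bool  # positive with zero detected lesions


@dataclass(frozen=True)
class ScreeningEvent:
    time: float
    event: str
    test_name: str = ""
    count: int = 1


@dataclass
class ScreeningEventLog:
    """Per-person chronological log of screening events."""

    events: list = field(default_factory=list)

    def add(self, time: float, event: str, test_name: str = "", count: int = 1):
        self.events.append(ScreeningEvent(time, event, test_name, count))

    def count(self, event: str) -> int:
        return sum(e.count for e in self.events if e.event == event)


def build_invitation_schedule(design: ProgrammeDesign, person: PersonHistory) -> list:
    """Calendar invitation times for one person under one programme.

    Invitations occur when the person reaches ages start_age,
    start_age + interval, ... <= stop_age, restricted to calendar years
    in which the programme operates, and never after death or after a
    clinical CRC diagnosis.
    """
    last = person.death_time
    if person.clinical_dx is not None:
        last = min(last, person.clinical_dx[0])
    out = []
    for age in design.invitation_ages():
        t = person.birth_time + float(age)
        if t >= last:
            break
        if design.operates_in(int(np.floor(t))):
            out.append(t)
    return out


def simulate_attendance(
    invitations: list, design: ProgrammeDesign, rng: np.random.Generator
) -> list:
    """Subset of invitations attended; each round is an independent
    Bernoulli(invitation_coverage x participation)."""
    p = design.invitation_coverage * design.participation
    return [t for t in invitations if rng.random() < p]


def apply_test(
    lesion_states: np.ndarray, test: ScreeningTest, rng: np.random.Generator
) -> TestResult:
    """Apply a test to a person with the given prevalent lesion states.

    Each lesion is detected independently with the per-state
    sensitivity; the person is positive iff >= 1 lesion is detected, or
    (no detection) on a false-positive draw with probability
    1 - specificity.  The false-positive flag is set only when positive
    with zero detected lesions.
    """
    states = np.asarray(lesion_states, dtype=int)
    sens = test.sensitivity_array()
    detected = rng.random(len(states)) < sens[states] if len(states) else np.zeros(0, dtype=bool)
    if detected.any():
        return TestResult(positive=True, detected=detected, false_positive=False)
    fp = rng.random() < 1.0 - test.specificity
    return TestResult(positive=fp, detected=detected, false_positive=fp)


def sample_complications(
    n_procedures: int, test: ScreeningTest, rng: np.random.Generator
) -> dict:
    """Complication counts by class over n procedures (independent
    Bernoulli per procedure per class; additive across persons/years)."""
    probs = test.complication_array()
    return {
        c: int(rng.binomial(n_procedures, p)) if n_procedures else 0
        for c, p in zip(COMPLICATION_CLASSES, probs)
    }


def classify_findings(
    adenoma_states: np.ndarray, protocol: SurveillanceProtocol
) -> str | None:
    """Adenoma findings class: 'high', 'low', or None for no adenomas."""
    states = np.asarray(adenoma_states, dtype=int)
    if len(states) == 0:
        return None
    if len(states) >= protocol.high_risk_count:
        return "high"
    if np.any(states >= STATE_INDEX[protocol.high_risk_state]):
        return "high"
    return "low"


@dataclass
class PersonScreeningOutcome:
    """Scenario-specific fate of one person."""

    dx_time: float | None = None
    dx_stage: int = 0
    screen_detected: bool = False
    removed: np.ndarray | None = None  # which lesions were resected
    clinical_lesion: int | None = None  # local index of the surfacing lesion


def _colonoscopy_procedure(
    t: float,
    prevalent: np.ndarray,
    states: np.ndarray,
    colo: ScreeningTest,
    rng: np.random.Generator,
    record,
) -> tuple:
    """Shared mechanics of any colonoscopy: per-lesion detection with
    the colonoscopy's sensitivity, per-procedure complication draws.

    Returns (detected mask over `prevalent`, detected adenoma states,
    most advanced detected preclinical stage or 0)."""
    for c, p in zip(COMPLICATION_CLASSES, colo.complication_array()):
        if p > 0 and rng.random() < p:
            record(t, f"complication_{c}", colo.name)
    sens = colo.sensitivity_array()
    detected = rng.random(len(states)) < sens[states] if len(states) else np.zeros(0, dtype=bool)
    det_states = states[detected]
    cancer_stage = 0
    if np.any(det_states >= _PRECLINICAL_MIN):
        cancer_stage = int(det_states.max() - _PRECLINICAL_MIN + 1)
    adenoma_states = det_states[det_states < _PRECLINICAL_MIN]
    return detected, adenoma_states, cancer_stage


def resolve_positive(
    t: float,
    prevalent_idx: np.ndarray,
    states: np.ndarray,
    design: ProgrammeDesign,
    colonoscopy: ScreeningTest,
    surveillance: SurveillanceProtocol,
    rng: np.random.Generator,
    record,
    direct_result: TestResult | None = None,
) -> tuple:
    """Resolve a positive screen.

    For stool/FS tests a diagnostic colonoscopy happens with probability
    followup_adherence and re-examines every prevalent lesion with the
    colonoscopy's sensitivity; for direct-visualization tests the
    positive result *is* the colonoscopy finding (``direct_result``).
    Detected adenomas are resected (their trajectories terminate);
    detected preclinical cancer becomes screen-detected at its current
    stage.  Returns (removed_lesion_indices, cancer_stage, findings
    class or None).  A positive without follow-up changes nothing.
    """
    if direct_result is not None:
        detected = direct_result.detected
        det_states = states[detected]
        cancer_stage = 0
        if np.any(det_states >= _PRECLINICAL_MIN):
            cancer_stage = int(det_states.max() - _PRECLINICAL_MIN + 1)
        adenoma_states = det_states[det_states < _PRECLINICAL_MIN]
    else:
        if rng.random() >= design.followup_adherence:
            return np.empty(0, dtype=int), 0, None
        record(t, "followup_colonoscopy", colonoscopy.name)
        detected, adenoma_states, cancer_stage = _colonoscopy_procedure(
            t, prevalent_idx, states, colonoscopy, rng, record
        )
    if cancer_stage:
        record(t, "cancer_detected", colonoscopy.name)
    n_adenoma = int(len(adenoma_states))
    if n_adenoma:
        record(t, "adenoma_detected", colonoscopy.name, count=n_adenoma)
    removed = prevalent_idx[detected & (states < _PRECLINICAL_MIN)] if len(states) else np.empty(0, dtype=int)
    findings = classify_findings(adenoma_states, surveillance) if cancer_stage == 0 else None
    return removed, cancer_stage, findings


def simulate_person_screening(
    birth_time: float,
    death_other: float,
    lesion_onset: np.ndarray,
    lesion_entry: np.ndarray,  # (k, 7)
    lesion_surface: np.ndarray,
    lesion_clinical_stage: np.ndarray,
    programmes: list,
    params: ModelParams,
    switch_year: int,
    rng_pre: np.random.Generator,
    rng_post: np.random.Generator,
    record,
) -> PersonScreeningOutcome:
    """Run the full screening overlay for one person.

    The latent lesion trajectories are shared across scenarios (common
    random numbers); screening only censors them: resected adenomas
    never progress, and a screen-detected cancer preempts its clinical
    surfacing.  Events before the switch year draw from ``rng_pre``
    (shared across screening scenarios) and later events from
    ``rng_post`` (scenario-specific).
    """
    k = len(lesion_onset)
    removed = np.zeros(k, dtype=bool)
    colo = params.tests["colonoscopy"]
    surveillance = params.surveillance

    # static invitation schedule: (time, design), chronological
    invites = []
    for d in programmes:
        for age in d.invitation_ages():
            t = birth_time + float(age)
            if t < death_other and d.operates_in(int(np.floor(t))):
                invites.append((t, d))
    invites.sort(key=lambda x: x[0])

    outcome = PersonScreeningOutcome(removed=removed)
    pending_surv: float | None = None
    i = 0

    def next_clinical() -> tuple:
        act = ~removed
        if not act.any():
            return np.inf, 0, -1
        j = np.flatnonzero(act)
        jj = int(j[np.argmin(lesion_surface[j])])
        return birth_time + lesion_surface[jj], int(lesion_clinical_stage[jj]), jj

    def prevalent_at(t: float) -> tuple:
        age = t - birth_time
        idx, states = [], []
        for j in range(k):
            if removed[j] or age < lesion_onset[j] or age >= lesion_surface[j]:
                continue
            s = int(np.searchsorted(lesion_entry[j], age, side="right")) - 1
            if s >= 0:
                idx.append(j)
                states.append(s)
        return np.asarray(idx, dtype=int), np.asarray(states, dtype=int)

    while True:
        # next screening contact: pending surveillance preempts routine
        if pending_surv is not None:
            t_next, kind = pending_surv, "surveillance"
        elif i < len(invites):
            t_next, kind = invites[i][0], "invite"
        else:
            t_next = np.inf
            kind = ""
        t_clin, stage_clin, j_clin = next_clinical()
        if t_clin <= t_next:
            if t_clin < death_other:
                outcome.dx_time, outcome.dx_stage = t_clin, stage_clin
                outcome.clinical_lesion = j_clin
            return outcome
        if not np.isfinite(t_next) or t_next >= death_other:
            return outcome

        rng = rng_pre if int(np.floor(t_next)) < switch_year else rng_post
        if kind == "invite":
            t, design = invites[i]
            i += 1
            test = params.tests[design.test_name]
            if rng.random() >= design.invitation_coverage * design.participation:
                continue
            record(t, "test", test.name)
            idx, states = prevalent_at(t)
            result = apply_test(states, test, rng)
            if test.is_direct_visualization:
                # the screen itself is a colonoscopy procedure
                for c, p in zip(COMPLICATION_CLASSES, colo.complication_array()):
                    if p > 0 and rng.random() < p:
                        record(t, f"complication_{c}", test.name)
            elif test.name == "FS":
                for c, p in zip(COMPLICATION_CLASSES, test.complication_array()):
                    if p > 0 and rng.random() < p:
                        record(t, f"complication_{c}", test.name)
            if not result.positive:
                continue
            record(t, "positive", test.name)
            if result.false_positive:
                record(t, "false_positive", test.name)
            if test.is_direct_visualization:
                if result.false_positive:
                    continue  # a lesion-free positive colonoscopy finds nothing
                rem, cancer_stage, findings = resolve_positive(
                    t, idx, states, design, colo, surveillance, rng, record, direct_result=result
                )
            else:
                # diagnostic colonoscopy re-examines every prevalent lesion,
                # including those the stool/FS test missed (and may find
                # nothing after a false positive)
                rem, cancer_stage, findings = resolve_positive(
                    t, idx, states, design, colo, surveillance, rng, record
                )
            removed[rem] = True
            if cancer_stage:
                outcome.dx_time, outcome.dx_stage = t, cancer_stage
                outcome.screen_detected = True
                return outcome
            if findings == "high":
                pending_surv = t + surveillance.interval_high_risk
        else:  # surveillance colonoscopy
            t = pending_surv
            pending_surv = None
            while i < len(invites) and invites[i][0] <= t:
                i += 1  # routine rounds suppressed while under surveillance
            if rng.random() >= surveillance.participation:
                continue
            record(t, "surveillance_colonoscopy", colo.name)
            idx, states = prevalent_at(t)
            detected, adenoma_states, cancer_stage = _colonoscopy_procedure(
                t, idx, states, colo, rng, record
            )
            if cancer_stage:
                record(t, "cancer_detected", colo.name)
                outcome.dx_time, outcome.dx_stage = t, cancer_stage
                outcome.screen_detected = True
                return outcome
            if len(adenoma_states):
                record(t, "adenoma_detected", colo.name, count=int(len(adenoma_states)))
                removed[idx[detected]] = True
            if classify_findings(adenoma_states, surveillance) == "high":
                pending_surv = t + surveillance.interval_high_risk
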