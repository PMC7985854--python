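"""Caries detection and the mapping from detections to treatment actions.

Two exam types run on fixed schedules: a visual-tactile assessment every
cycle (it cannot see initial proximal lesions at all) and a bitewing
radiograph every other cycle, read either by dentists alone or with AI
assistance.  Each due method fires independently given the true surface
state; a diseased surface counts as detected if any method fires, at its
true stage (no depth misgrading is modelled).  A sound surface can be
false-positively read as an initial lesion with one minus the method's
initial-stage specificity.

Detected initial lesions (including false positives) receive the policy's
initial-lesion action — resin infiltration in the base case, restoration in
the all-restorative sensitivity analysis.  Detected advanced lesions are
always restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import LesionStage, ParameterSet, ScenarioConfig

__all__ = [
    "TestProfile",
    "ExamSchedule",
    "DetectionOutcome",
    "TreatmentPolicy",
    "exams_due",
    "apply_tests",
    "decide_treatment",
    "build_test_profiles",
]

VISUAL_TACTILE = "visual_tactile"
RADIOGRAPH = "radiograph"


@dataclass(frozen=True)
class TestProfile:
    """Realized per-stage sensitivity/specificity of one detection method.

    Keys are the accuracy-table stage columns ``E2``, ``D1``, ``D2``;
    D3 lesions are graded with the D2 ("advanced") column.
    """

    method: str
    sensitivity: dict
    specificity: dict

    __test__ = False  # not a test class, despite the name

    def __post_init__(self) -> None:
        for d in (self.sensitivity, self.specificity):
            for stage, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{self.method} {stage}: {v} outside [0, 1]")

    def sensitivity_for(self, truth: LesionStage) -> float:
        key = "D2" if truth.is_advanced else truth.name
        return self.sensitivity[key]

    @property
    def sound_specificity(self) -> float:
        """Specificity applied to a sound surface (initial-lesion grade)."""
        return self.specificity["E2"]


@dataclass(frozen=True)
class ExamSchedule:
    """Cycle schedule of the two exam types (intervals in annual cycles)."""

    vt_interval: int = 1
    bw_interval: int = 2
    offset: int = 0

    def __post_init__(self) -> None:
        if self.vt_interval < 1 or self.bw_interval < 1:
            raise ValueError("exam intervals must be >= 1")

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig) -> "ExamSchedule":
        return cls(scenario.vt_interval, scenario.bw_interval, scenario.exam_offset)


@dataclass(frozen=True)
class DetectionOutcome:
    detected_stage: LesionStage | None
    truth: LesionStage
    is_false_positive: bool

    def __post_init__(self) -> None:
        expected_fp = self.truth == LesionStage.SOUND and self.detected_stage is not None
        if self.is_false_positive != expected_fp:
            raise ValueError("is_false_positive inconsistent with truth/detection")


@dataclass(frozen=True)
class TreatmentPolicy:
    """Maps the detected lesion grade to a treatment.  Advanced lesions are
    always restored; the initial-lesion action is the policy lever."""

    initial_lesion_action: str = "infiltrate"  # "infiltrate" | "restore"

    def __post_init__(self) -> None:
        if self.initial_lesion_action not in ("infiltrate", "restore"):
            raise ValueError(f"unknown action {self.initial_lesion_action!r}")


def exams_due(cycle_index: int, schedule: ExamSchedule) -> frozenset:
    """The exam types due at a cycle: an exam runs when its interval divides
    the cycle index relative to the schedule offset."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    rel = cycle_index - schedule.offset
    due = set()
    if rel >= 0:
        if rel % schedule.vt_interval == 0:
            due.add(VISUAL_TACTILE)
        if rel % schedule.bw_interval == 0:
            due.add(RADIOGRAPH)
    return frozenset(due)


def apply_tests(
    truth: LesionStage,
    methods: frozenset | set,
    profiles: dict,
    rng: np.random.Generator,
) -> DetectionOutcome:
    """Run every due method against the true surface state.

    Methods err independently given the truth.  True positives are graded at
    the true stage; false positives on sound surfaces are graded as initial
    (E2) lesions.
    """
    missing = [m for m in methods if m not in profiles]
    if missing:
        raise KeyError(f"no test profile configured for {missing}")
    # Fixed method order keeps the RNG stream deterministic.
    ordered = sorted(methods)
    if truth == LesionStage.SOUND:
        fired = any(
            rng.random() < 1.0 - profiles[m].sound_specificity for m in ordered
        )
        if fired:
            return DetectionOutcome(LesionStage.E2, truth, True)
        return DetectionOutcome(None, truth, False)
    fired = any(
        rng.random() < profiles[m].sensitivity_for(truth) for m in ordered
    )
    return DetectionOutcome(truth if fired else None, truth, False)


def decide_treatment(outcome: DetectionOutcome, policy: TreatmentPolicy) -> str:
    """Map a detection outcome to ``"none"``, ``"infiltrate"`` or ``"restore"``.

    False positives are graded initial and therefore receive the policy's
    initial-lesion action: money spent with no effectiveness gain under the
    infiltration policy, and an unnecessary restoration under the
    all-restorative policy.
    """
    if outcome.detected_stage is None:
        return "none"
    if outcome.detected_stage.is_advanced:
        return "restore"
    return policy.initial_lesion_action


def build_test_profiles(
    params: ParameterSet, scenario: ScenarioConfig
) -> dict:
    """Build the per-method TestProfile map active in a scenario, using the
    tooth's realized accuracy draws.  The generic ``radiograph`` slot is the
    AI-assisted profile in the test strategy and the configured dentists'
    profile in the control strategy."""
    radiograph_source = scenario.radiograph_method
    return {
        VISUAL_TACTILE: TestProfile(
            VISUAL_TACTILE,
            params.sensitivity[VISUAL_TACTILE],
            params.specificity[VISUAL_TACTILE],
        ),
        RADIOGRAPH: TestProfile(
            radiograph_source,
            params.sensitivity[radiograph_source],
            params.specificity[radiograph_source],
        ),
    }
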