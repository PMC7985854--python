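"""Epidemiological model inputs: lesion stages, hazard functions, PSA sampling.

This module houses every transition-probability input of the decision model
as typed data: stage-specific caries prevalence for low- and high-risk
populations, the diagnostic accuracy of each detection method, age-dependent
hazard functions for lesion development and progression, and the annual
failure/allocation tables of the restorative-endodontic-prosthetic cascade.

Hazard functions come in two parametric families:

* lesion development on sound surfaces (exponential decay in attained age):
  ``p(alpha) = m * a * base**(-b * 2*alpha)``
* lesion progression (power law in attained age):
  ``p(alpha) = m * c * (2*alpha)**(-k)``

where ``alpha`` is the tooth bearer's attained age in years (12 at the start
of the simulation) and ``m`` collects the sampled/fixed multipliers.  The
doubled-age argument ``2*alpha`` and the decay base 2.7 are implemented
verbatim as published for the source model and are configurable
(``age_factor``, ``base``) for anyone who wants the ``e``-based reading.

Probabilistic sensitivity analysis (PSA) draws one realization of every
distributed parameter per simulated tooth.  Symmetric published ranges are
sampled uniformly; parameters published as a point estimate with a
confidence interval or an asymmetric range are sampled from a triangular
distribution with the mode at the point estimate.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "LesionStage",
    "INITIAL_STAGES",
    "ADVANCED_STAGES",
    "ParameterDistribution",
    "DevelopmentHazard",
    "ProgressionHazard",
    "TransitionRow",
    "ModelParameters",
    "ParameterSet",
    "ScenarioConfig",
    "load_table1",
    "sample_parameter_set",
    "development_probability",
    "progression_probability",
    "prevalence",
]


class LesionStage(enum.IntEnum):
    """Radiographic proximal-lesion depth, strictly ordered by severity.

    ``SOUND < E2 < D1 < D2 < D3``.  E2: inner third of enamel (E1 is folded
    into E2 — the model carries no separate outer-enamel state); D1/D2/D3:
    outer/middle/inner third of dentin.  E2 and D1 are "initial" lesions,
    presumed noncavitated and manageable by resin infiltration; D2 and D3
    are "advanced" and require restorative care.
    """

    SOUND = 0
    E2 = 1
    D1 = 2
    D2 = 3
    D3 = 4

    @property
    def is_initial(self) -> bool:
        return self in INITIAL_STAGES

    @property
    def is_advanced(self) -> bool:
        return self in ADVANCED_STAGES


INITIAL_STAGES = (LesionStage.E2, LesionStage.D1)
ADVANCED_STAGES = (LesionStage.D2, LesionStage.D3)

#: Stages that can be present at baseline / arise by development.
PREVALENT_STAGES = (LesionStage.E2, LesionStage.D1, LesionStage.D2)


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDistribution:
    """A point, uniform or triangular sampling distribution for one input."""

    kind: str  # "point" | "uniform" | "triangular"
    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("point", "uniform", "triangular"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"require low <= mode <= high, got "
                f"({self.low}, {self.mode}, {self.high})"
            )
        if self.kind == "point" and not (self.low == self.mode == self.high):
            raise ValueError("point distribution requires low == mode == high")

    @classmethod
    def point(cls, value: float) -> "ParameterDistribution":
        return cls("point", value, value, value)

    @classmethod
    def uniform(cls, low: float, high: float) -> "ParameterDistribution":
        return cls("uniform", low, 0.5 * (low + high), high)

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "ParameterDistribution":
        return cls("triangular", low, mode, high)

    def sample(self, rng: np.random.Generator | None) -> float:
        """Draw one realization; point distributions consume no randomness."""
        if self.kind == "point" or self.low == self.high:
            return self.mode
        if rng is None:  # PSA off: use the point estimate / mode
            return self.mode
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(rng.triangular(self.low, self.mode, self.high))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "low": self.low, "mode": self.mode, "high": self.high}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterDistribution":
        return cls(d["kind"], float(d["low"]), float(d["mode"]), float(d["high"]))


# ---------------------------------------------------------------------------
# Hazard functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DevelopmentHazard:
    """Exponential-decay incidence of a new lesion on a sound surface.

    ``p(alpha) = m * a * base**(-b * age_factor * alpha)``, clamped to [0, 1].
    """

    a: float
    b: float
    base: float = 2.7

    def value(self, age: float, multiplier: float, age_factor: float = 2.0) -> float:
        return _clamp01(multiplier * self.a * self.base ** (-self.b * age_factor * age))

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "base": self.base}


@dataclass(frozen=True)
class ProgressionHazard:
    """Power-law per-cycle probability of progressing one lesion stage.

    ``p(alpha) = m * c * (age_factor * alpha)**(-k)``, clamped to [0, 1].
    """

    c: float
    k: float

    def value(self, age: float, multiplier: float, age_factor: float = 2.0) -> float:
        return _clamp01(multiplier * self.c * (age_factor * age) ** (-self.k))

    def to_dict(self) -> dict:
        return {"c": self.c, "k": self.k}


# ---------------------------------------------------------------------------
# Transition tables (restorative / endodontic / prosthetic cascade)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionRow:
    """Annual failure probability of a health state plus the allocation map
    distributing failures over follow-up events.  Allocation probabilities
    must sum to 1 exactly (within float round-off)."""

    probability: ParameterDistribution
    allocation: tuple[tuple[str, float], ...]  # ordered (outcome, probability)

    def __post_init__(self) -> None:
        total = math.fsum(p for _, p in self.allocation)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"allocation probabilities must sum to 1, got {total!r} "
                f"for {dict(self.allocation)!r}"
            )
        if any(p < 0 for _, p in self.allocation):
            raise ValueError("allocation probabilities must be non-negative")

    def to_dict(self) -> dict:
        return {
            "probability": self.probability.to_dict(),
            "allocation": {k: v for k, v in self.allocation},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionRow":
        return cls(
            ParameterDistribution.from_dict(d["probability"]),
            tuple((k, float(v)) for k, v in d["allocation"].items()),
        )


# ---------------------------------------------------------------------------
# Full model parameterization
# ---------------------------------------------------------------------------

_STAGE_KEYS = ("E2", "D1", "D2")
_METHODS = ("visual_tactile", "radiograph", "radiograph_ai", "radiograph_primary_study")


@dataclass(frozen=True)
class ModelParameters:
    """The complete, validated epidemiological input set of the model."""

    prevalence_low: dict  # stage key -> probability
    prevalence_high_multipliers: dict  # stage key -> multiplier on low risk
    development: dict  # stage key -> DevelopmentHazard
    development_multiplier: dict  # stage key -> ParameterDistribution
    progression_untreated: dict  # from-stage key -> ProgressionHazard
    progression_multiplier: dict  # from-stage key -> ParameterDistribution
    risk_multiplier: dict  # "low"/"high" -> float (applies to E2->D1, D1->D2)
    d2_to_d3_multiplier: float  # fixed, replaces the risk multiplier for D2->D3
    progression_infiltrated: dict  # from-stage ("E2","D1") -> ProgressionHazard
    infiltrated_multiplier: dict  # from-stage -> ParameterDistribution
    accuracy: dict  # method -> {"sensitivity"/"specificity" -> {stage -> dist}}
    transitions: dict  # row name -> TransitionRow
    clinical: dict  # scalar clinical constants
    age_factor: float = 2.0  # the literal "2 alpha" in the published hazards

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = math.fsum(self.prevalence_low.values())
        if any(v < 0 for v in self.prevalence_low.values()) or total > 1.0:
            raise ValueError("prevalences must be >= 0 and sum to <= 1")
        high = [
            self.prevalence_low[s] * self.prevalence_high_multipliers[s]
            for s in _STAGE_KEYS
        ]
        if math.fsum(high) > 1.0:
            raise ValueError("high-risk prevalences sum to > 1")
        for s in _STAGE_KEYS:
            if s not in self.development or s not in self.development_multiplier:
                raise ValueError(f"missing development hazard for stage {s}")
            if s not in self.progression_untreated or s not in self.progression_multiplier:
                raise ValueError(f"missing progression hazard for stage {s}")
        for s in ("E2", "D1"):
            if s not in self.progression_infiltrated:
                raise ValueError(f"missing infiltrated-progression hazard for {s}")
        for m in _METHODS:
            acc = self.accuracy[m]
            for metric in ("sensitivity", "specificity"):
                for s in _STAGE_KEYS:
                    dist = acc[metric][s]
                    if not (0.0 <= dist.low and dist.high <= 1.0):
                        raise ValueError(f"{m} {metric} {s} outside [0, 1]")
        for key, value in self.clinical.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"clinical constant {key} outside [0, 1]")
        # TransitionRow validates its own allocation sums on construction.

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "prevalence": {
                "low": dict(self.prevalence_low),
                "high_multipliers": dict(self.prevalence_high_multipliers),
            },
            "development": {
                "hazards": {s: h.to_dict() for s, h in self.development.items()},
                "multipliers": {
                    s: d.to_dict() for s, d in self.development_multiplier.items()
                },
            },
            "progression": {
                "untreated": {
                    s: h.to_dict() for s, h in self.progression_untreated.items()
                },
                "untreated_multipliers": {
                    s: d.to_dict() for s, d in self.progression_multiplier.items()
                },
                "risk_multiplier": dict(self.risk_multiplier),
                "d2_to_d3_multiplier": self.d2_to_d3_multiplier,
                "infiltrated": {
                    s: h.to_dict() for s, h in self.progression_infiltrated.items()
                },
                "infiltrated_multipliers": {
                    s: d.to_dict() for s, d in self.infiltrated_multiplier.items()
                },
            },
            "accuracy": {
                m: {
                    metric: {s: d.to_dict() for s, d in stages.items()}
                    for metric, stages in acc.items()
                }
                for m, acc in self.accuracy.items()
            },
            "transitions": {k: row.to_dict() for k, row in self.transitions.items()},
            "clinical": dict(self.clinical),
            "age_factor": self.age_factor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        dev = d["development"]
        prog = d["progression"]
        return cls(
            prevalence_low={k: float(v) for k, v in d["prevalence"]["low"].items()},
            prevalence_high_multipliers={
                k: float(v) for k, v in d["prevalence"]["high_multipliers"].items()
            },
            development={
                s: DevelopmentHazard(**h) for s, h in dev["hazards"].items()
            },
            development_multiplier={
                s: ParameterDistribution.from_dict(x)
                for s, x in dev["multipliers"].items()
            },
            progression_untreated={
                s: ProgressionHazard(**h) for s, h in prog["untreated"].items()
            },
            progression_multiplier={
                s: ParameterDistribution.from_dict(x)
                for s, x in prog["untreated_multipliers"].items()
            },
            risk_multiplier={k: float(v) for k, v in prog["risk_multiplier"].items()},
            d2_to_d3_multiplier=float(prog["d2_to_d3_multiplier"]),
            progression_infiltrated={
                s: ProgressionHazard(**h) for s, h in prog["infiltrated"].items()
            },
            infiltrated_multiplier={
                s: ParameterDistribution.from_dict(x)
                for s, x in prog["infiltrated_multipliers"].items()
            },
            accuracy={
                m: {
                    metric: {
                        s: ParameterDistribution.from_dict(x)
                        for s, x in stages.items()
                    }
                    for metric, stages in acc.items()
                }
                for m, acc in d["accuracy"].items()
            },
            transitions={
                k: TransitionRow.from_dict(row) for k, row in d["transitions"].items()
            },
            clinical={k: float(v) for k, v in d["clinical"].items()},
            age_factor=float(d.get("age_factor", 2.0)),
        )


def load_table1(source: str | dict | None = None) -> ModelParameters:
    """Load and validate the base parameter file.

    ``source`` may be a path to a JSON file, an already-parsed dict, or
    ``None`` to load the packaged base file (``data/table1_base.json``).
    """
    if source is None:
        text = resources.files("cariesim").joinpath("data/table1_base.json").read_text()
        return ModelParameters.from_dict(json.loads(text))
    if isinstance(source, dict):
        return ModelParameters.from_dict(source)
    with open(source) as fh:
        return ModelParameters.from_dict(json.load(fh))


def prevalence(model: ModelParameters, risk: str) -> dict:
    """Baseline stage prevalences for a risk profile; SOUND is the remainder."""
    if risk == "low":
        return dict(model.prevalence_low)
    if risk == "high":
        return {
            s: model.prevalence_low[s] * model.prevalence_high_multipliers[s]
            for s in _STAGE_KEYS
        }
    raise ValueError(f"unknown risk profile {risk!r} (expected 'low' or 'high')")


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One complete, runnable scenario.

    ``strategy`` selects which radiographic test profile the biennial
    bitewing exam uses: ``"ai"`` for the neural-network-assisted reading
    (plus a per-use AI fee) and ``"control"`` for unassisted dentists.
    ``control_profile`` picks the source of the dentists' accuracy:
    ``"radiograph"`` (meta-analytic pooled values, the base case) or
    ``"radiograph_primary_study"`` (the seven dentists who read the same
    test images as the network).
    """

    name: str = "base_case"
    risk: str = "low"  # low | high
    strategy: str = "ai"  # ai | control
    policy: str = "infiltrate"  # treatment of detected initial lesions
    control_profile: str = "radiograph"
    horizon: int = 65  # annual cycles; age 12 -> 77
    start_age: float = 12.0
    discount_rate: float = 0.03
    ai_fee: float = 8.0  # euro per analyzed bitewing pair
    replacement: float = 0.8  # probability an extracted tooth gets an implant
    vt_interval: int = 1  # visual-tactile exam, every cycle
    bw_interval: int = 2  # bitewing radiograph, every 2 years
    exam_offset: int = 0
    shared_divisor: int = 16  # teeth sharing radiograph/AI/assessment fees
    refp_repeat: bool = False  # re-bill repeat false positives on one surface
    psa: bool = True

    def __post_init__(self) -> None:
        if self.risk not in ("low", "high"):
            raise ValueError(f"unknown risk {self.risk!r}")
        if self.strategy not in ("ai", "control"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.policy not in ("infiltrate", "restore"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.control_profile not in ("radiograph", "radiograph_primary_study"):
            raise ValueError(f"unknown control profile {self.control_profile!r}")
        if self.vt_interval < 1 or self.bw_interval < 1:
            raise ValueError("exam intervals must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if not (0.0 <= self.replacement <= 1.0):
            raise ValueError("replacement probability must lie in [0, 1]")
        if self.shared_divisor < 1:
            raise ValueError("shared-cost divisor must be >= 1")
        if self.discount_rate <= -1.0:
            raise ValueError("discount rate must exceed -1")

    @property
    def radiograph_method(self) -> str:
        """Name of the radiographic test profile active in this scenario."""
        return "radiograph_ai" if self.strategy == "ai" else self.control_profile

    def with_(self, **overrides) -> "ScenarioConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# Sampled parameter sets
# ---------------------------------------------------------------------------

_TRANSITION_ORDER = (
    "composite",
    "direct_capping",
    "crown_vital",
    "rct",
    "crown_nonvital",
    "nonsurg_retreat",
    "surg_retreat",
    "implant",
)


@dataclass
class ParameterSet:
    """One realization of all distributed inputs for a single simulated tooth.

    With PSA on, every distributed parameter is drawn independently; point
    parameters pass through unchanged.  All realized probabilities are
    clamped to [0, 1].  The realized multipliers are combined with the
    hazard coefficients of ``model`` at evaluation time.
    """

    model: ModelParameters
    risk: str
    dev_multiplier: dict  # stage -> float
    prog_multiplier: dict  # from-stage -> float
    infil_multiplier: dict  # from-stage -> float
    sensitivity: dict  # method -> {stage key -> float}
    specificity: dict
    failure: dict  # transition row -> float
    pulp_exposure_d3: float
    pulp_exposure_rerestoration: float
    capping_fraction: float
    replacement: float

    def development_probability(self, age: float, target_stage: LesionStage) -> float:
        if target_stage not in PREVALENT_STAGES:
            raise ValueError(
                f"lesions develop only at stages E2/D1/D2, got {target_stage!r}"
            )
        key = target_stage.name
        return self.model.development[key].value(
            age, self.dev_multiplier[key], self.model.age_factor
        )

    def progression_probability(
        self, age: float, from_stage: LesionStage, infiltrated: bool = False
    ) -> float:
        if from_stage not in PREVALENT_STAGES:
            raise ValueError(
                f"progression is defined for E2/D1/D2 lesions, got {from_stage!r}"
            )
        key = from_stage.name
        if infiltrated:
            if from_stage == LesionStage.D2:
                raise ValueError("infiltrated progression is undefined for D2 lesions")
            return self.model.progression_infiltrated[key].value(
                age, self.infil_multiplier[key], self.model.age_factor
            )
        if from_stage == LesionStage.D2:
            m = self.model.d2_to_d3_multiplier * self.prog_multiplier[key]
        else:
            m = self.model.risk_multiplier[self.risk] * self.prog_multiplier[key]
        return self.model.progression_untreated[key].value(
            age, m, self.model.age_factor
        )


def sample_parameter_set(
    model: ModelParameters,
    scenario: ScenarioConfig,
    rng: np.random.Generator | None,
) -> ParameterSet:
    """Draw one ParameterSet; with ``scenario.psa`` off, point values are used.

    The draw order is fixed (development, progression, infiltration
    multipliers; every accuracy value of every method; every transition row)
    so that paired runs with common random numbers stay aligned regardless of
    which strategy consumes the set.
    """
    psa_rng = rng if scenario.psa else None
    dev = {s: model.development_multiplier[s].sample(psa_rng) for s in _STAGE_KEYS}
    prog = {s: model.progression_multiplier[s].sample(psa_rng) for s in _STAGE_KEYS}
    infil = {s: model.infiltrated_multiplier[s].sample(psa_rng) for s in ("E2", "D1")}
    sens: dict = {}
    spec: dict = {}
    for m in _METHODS:
        sens[m] = {
            s: _clamp01(model.accuracy[m]["sensitivity"][s].sample(psa_rng))
            for s in _STAGE_KEYS
        }
        spec[m] = {
            s: _clamp01(model.accuracy[m]["specificity"][s].sample(psa_rng))
            for s in _STAGE_KEYS
        }
    failure = {
        k: _clamp01(model.transitions[k].probability.sample(psa_rng))
        for k in _TRANSITION_ORDER
        if k in model.transitions
    }
    c = model.clinical
    return ParameterSet(
        model=model,
        risk=scenario.risk,
        dev_multiplier=dev,
        prog_multiplier=prog,
        infil_multiplier=infil,
        sensitivity=sens,
        specificity=spec,
        failure=failure,
        pulp_exposure_d3=c["pulp_exposure_d3"],
        pulp_exposure_rerestoration=c["pulp_exposure_rerestoration"],
        capping_fraction=c["capping_fraction"],
        replacement=scenario.replacement,
    )


# -- module-level operation wrappers ----------------------------------------

def development_probability(
    age: float, target_stage: LesionStage, params: ParameterSet
) -> float:
    """Per-cycle probability that a sound surface develops a lesion arriving
    directly at ``target_stage`` (E2, D1 or D2), at attained age ``age``."""
    return params.development_probability(age, target_stage)


def progression_probability(
    age: float,
    from_stage: LesionStage,
    params: ParameterSet,
    infiltrated: bool = False,
) -> float:
    """Per-cycle probability that a lesion at ``from_stage`` deepens by one
    stage.  Untreated initial lesions carry the risk-profile multiplier;
    D2->D3 uses a fixed multiplier instead; infiltrated lesions use their own
    (much flatter) hazards and no risk multiplier."""
    return params.progression_probability(age, from_stage, infiltrated)
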