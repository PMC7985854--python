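"""Shared oracles and reduced-model builders used by several test modules."""

from __future__ import annotations

import numpy as np

from cariesim.engine import StateKind, ToothState, simulate_tooth, step_tooth
from cariesim.fixtures import build_table1_config
from cariesim.parameters import (
    ParameterDistribution,
    ScenarioConfig,
    load_table1,
    sample_parameter_set,
)


def zero_hazard_model():
    """No disease, no failures, no false positives: a tooth can only ever
    accrue exam costs."""
    cfg = build_table1_config()
    for h in cfg["development"]["hazards"].values():
        h["a"] = 0.0
    cfg["prevalence"]["low"] = {"E2": 0.0, "D1": 0.0, "D2": 0.0}
    zero = ParameterDistribution.point(0.0).to_dict()
    one = ParameterDistribution.point(1.0).to_dict()
    for row in cfg["transitions"].values():
        row["probability"] = zero
    for acc in cfg["accuracy"].values():
        acc["specificity"] = {"E2": one, "D1": one, "D2": one}
    return load_table1(cfg)


def three_state_chain_model(p_develop: float, p_fail: float):
    """Collapse the engine to a SOUND -> RESTORED -> EXTRACTED chain.

    Development arrives only at E2 with a constant (age-independent) hazard,
    detection is certain every cycle, detected lesions are restored
    (all-restorative policy), and a failed restoration is always extracted.
    The per-cycle transition matrix is then exactly

        [[1-p_develop, p_develop, 0],
         [0,           1-p_fail,  p_fail],
         [0,           0,         1]]

    because a restoration placed in a cycle cannot fail in that cycle.
    """
    cfg = build_table1_config()
    cfg["prevalence"]["low"] = {"E2": 0.0, "D1": 0.0, "D2": 0.0}
    cfg["development"]["hazards"]["E2"] = {"a": p_develop, "b": 0.0, "base": 2.7}
    cfg["development"]["hazards"]["D1"]["a"] = 0.0
    cfg["development"]["hazards"]["D2"]["a"] = 0.0
    one = ParameterDistribution.point(1.0).to_dict()
    cfg["development"]["multipliers"] = {s: one for s in ("E2", "D1", "D2")}
    for h in cfg["progression"]["untreated"].values():
        h["c"] = 0.0
    for h in cfg["progression"]["infiltrated"].values():
        h["c"] = 0.0
    cfg["accuracy"]["radiograph_ai"]["sensitivity"] = {
        "E2": one, "D1": one, "D2": one
    }
    cfg["accuracy"]["radiograph_ai"]["specificity"] = {
        "E2": one, "D1": one, "D2": one
    }
    cfg["transitions"]["composite"] = {
        "probability": ParameterDistribution.point(p_fail).to_dict(),
        "allocation": {"extraction": 1.0},
    }
    return load_table1(cfg)


def chain_scenario(horizon: int) -> ScenarioConfig:
    return ScenarioConfig(
        name="chain",
        strategy="ai",
        policy="restore",
        horizon=horizon,
        replacement=0.0,
        bw_interval=1,
        psa=False,
    )


def chain_occupancy(model, scenario, n: int, seed: int) -> np.ndarray:
    """Simulated occupancy of (SOUND, RESTORED, EXTRACTED) after each cycle."""
    occ = np.zeros((scenario.horizon, 3))
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        params = sample_parameter_set(model, scenario, rng)
        state = ToothState(age=scenario.start_age)
        extracted = False
        for t in range(scenario.horizon):
            if not extracted:
                step_tooth(state, t, params, scenario, rng)
                if not state.natural_tooth_present:
                    extracted = True
            if extracted:
                occ[t, 2] += 1
            elif state.kind == StateKind.RESTORED:
                occ[t, 1] += 1
            else:
                occ[t, 0] += 1
    return occ / n


def chain_closed_form(p_develop: float, p_fail: float, horizon: int) -> np.ndarray:
    """Matrix-power occupancy of the three-state chain (independent oracle)."""
    M = np.array(
        [
            [1 - p_develop, p_develop, 0.0],
            [0.0, 1 - p_fail, p_fail],
            [0.0, 0.0, 1.0],
        ]
    )
    out = np.zeros((horizon, 3))
    v = np.array([1.0, 0.0, 0.0])
    for t in range(horizon):
        v = v @ M
        out[t] = v
    return out
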