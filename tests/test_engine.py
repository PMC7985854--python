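"""Microsimulation engine: determinism, conservation laws, reduced-model
oracles, and stochastic orderings."""

import numpy as np
import pytest

from cariesim.engine import run_cohort, initial_state
from cariesim.fixtures import build_table1_config, scenario
from cariesim.parameters import LesionStage, ScenarioConfig, load_table1
from helpers import (
    chain_closed_form,
    chain_occupancy,
    chain_scenario,
    three_state_chain_model,
    zero_hazard_model,
)


class TestInitialState:
    def test_low_risk_prevalence_reproduced(self, model):
        rng = np.random.default_rng(0)
        sc = ScenarioConfig(risk="low")
        n = 40000
        counts = {s: 0 for s in ("E2", "D1", "D2", "SOUND")}
        for _ in range(n):
            st = initial_state(model, sc, rng)
            counts[st.stage.name if st.stage != LesionStage.SOUND else "SOUND"] += 1
        for key, p in (("E2", 0.14), ("D1", 0.025), ("D2", 0.005), ("SOUND", 0.83)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 4 * se
        assert initial_state(model, sc, rng).age == 12.0

    def test_zero_prevalence_always_sound(self):
        model = zero_hazard_model()
        rng = np.random.default_rng(1)
        sc = ScenarioConfig()
        for _ in range(100):
            assert initial_state(model, sc, rng).stage == LesionStage.SOUND


class TestDeterminismAndInvariants:
    def test_same_seed_reproduces_cohort_exactly(self, model, schedule):
        sc = scenario("base_case", strategy="ai")
        a = run_cohort(sc, n=60, seed=123, model=model, cost_schedule=schedule)
        b = run_cohort(sc, n=60, seed=123, model=model, cost_schedule=schedule)
        assert np.array_equal(a.effectiveness, b.effectiveness)
        assert np.array_equal(a.cost_discounted, b.cost_discounted)
        c = run_cohort(sc, n=60, seed=124, model=model, cost_schedule=schedule)
        assert not np.array_equal(a.cost_discounted, c.cost_discounted)

    def test_cohort_is_order_independent(self, model, schedule):
        """Tooth i's outcome depends only on (seed, i), not on cohort size."""
        sc = scenario("base_case", strategy="control")
        small = run_cohort(sc, n=30, seed=9, model=model, cost_schedule=schedule)
        large = run_cohort(sc, n=60, seed=9, model=model, cost_schedule=schedule)
        assert np.array_equal(small.effectiveness, large.effectiveness[:30])
        assert np.array_equal(small.cost_discounted, large.cost_discounted[:30])

    def test_retention_bounded_and_costs_nonnegative(self, model, schedule):
        sc = scenario("base_case", strategy="ai")
        c = run_cohort(sc, n=300, seed=7, model=model, cost_schedule=schedule)
        assert np.all(c.effectiveness >= 0)
        assert np.all(c.effectiveness <= sc.horizon)
        assert np.all(c.cost_discounted >= 0)
        assert np.all(c.cost_discounted <= c.cost_undiscounted + 1e-9)
        assert np.all(c.effectiveness_discounted <= c.effectiveness + 1e-9)

    def test_event_ledger_conservation(self, model, schedule):
        """Extraction is unique and terminal for the natural tooth; implants
        only follow extractions; no caries treatment after crown/extraction;
        events are time-ordered."""
        sc = scenario("base_case", strategy="ai")
        cohort = run_cohort(
            sc, n=400, seed=11, model=model, cost_schedule=schedule,
            keep_histories=True,
        )
        n_extracted = 0
        for hist in cohort.histories:
            kinds = [e.kind for e in hist.events]
            cycles = [e.cycle for e in hist.events]
            assert cycles == sorted(cycles)
            assert kinds.count("extraction") <= 1
            if "extraction" in kinds:
                n_extracted += 1
                t_ext = hist.events[kinds.index("extraction")].cycle
                assert hist.retention_years == t_ext
            else:
                assert hist.retention_years == sc.horizon
            if "implant_iscrown" in kinds:
                assert kinds.index("extraction") < kinds.index("implant_iscrown")
            if "reimplant" in kinds:
                assert "implant_iscrown" in kinds
            first_crown = kinds.index("crown") if "crown" in kinds else None
            if first_crown is not None:
                later = kinds[first_crown + 1:]
                assert "restoration" not in later
                assert "infiltration" not in later
        assert n_extracted > 0  # the base case does lose some teeth


class TestReducedModelOracles:
    def test_zero_hazards_give_full_retention_and_exam_only_costs(self, schedule):
        model = zero_hazard_model()
        sc = scenario("base_case", strategy="ai")
        cohort = run_cohort(sc, n=20, seed=3, model=model, cost_schedule=schedule)
        assert np.all(cohort.effectiveness == sc.horizon)
        # closed-form exam cost: visual-tactile yearly, bitewing + AI biennial,
        # all shared over 16 teeth and discounted at 3%
        vt = schedule.fees["exam_vt"] / 16
        bw = (schedule.fees["exam_bw"] + sc.ai_fee) / 16
        expected = sum(
            (vt + (bw if t % 2 == 0 else 0.0)) * 1.03 ** (-t)
            for t in range(sc.horizon)
        )
        assert np.allclose(cohort.cost_discounted, expected, rtol=1e-12)
        control = scenario("base_case", strategy="control")
        cohort_c = run_cohort(control, n=5, seed=3, model=model, cost_schedule=schedule)
        bw_c = schedule.fees["exam_bw"] / 16
        expected_c = sum(
            (vt + (bw_c if t % 2 == 0 else 0.0)) * 1.03 ** (-t)
            for t in range(sc.horizon)
        )
        assert np.allclose(cohort_c.cost_discounted, expected_c, rtol=1e-12)

    def test_three_state_chain_matches_closed_form(self):
        """With constant development, certain detection, restore-everything
        and failure->extraction, engine occupancy must match the matrix-power
        solution of the 3-state Markov chain within 3 standard errors."""
        p1, p2, horizon, n = 0.10, 0.08, 20, 1500
        model = three_state_chain_model(p1, p2)
        sc = chain_scenario(horizon)
        occ = chain_occupancy(model, sc, n, seed=17)
        exact = chain_closed_form(p1, p2, horizon)
        for t in (4, 9, 19):
            for j in range(3):
                p = exact[t, j]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(occ[t, j] - p) < 3 * se + 1e-9, (t, j, occ[t, j], p)


class TestStochasticOrderings:
    def test_retention_monotone_in_restoration_failure_rate(self, schedule):
        """Doubling the composite failure probability cannot raise mean
        retention beyond Monte-Carlo noise (common random numbers)."""
        base_cfg = build_table1_config()
        harsh_cfg = build_table1_config()
        harsh_cfg["transitions"]["composite"]["probability"] = {
            "kind": "point", "low": 0.032, "mode": 0.032, "high": 0.032,
        }
        sc = scenario("base_case", strategy="control")
        base = run_cohort(sc, n=4000, seed=21, model=load_table1(base_cfg),
                          cost_schedule=schedule)
        harsh = run_cohort(sc, n=4000, seed=21, model=load_table1(harsh_cfg),
                           cost_schedule=schedule)
        assert harsh.effectiveness.mean() <= base.effectiveness.mean() + 0.05

    def test_ai_assisted_detection_not_less_effective(self, model, schedule):
        """Under the infiltration policy the more sensitive radiographic
        profile retains at least as many tooth-years as the control."""
        ai = run_cohort(scenario("base_case", strategy="ai"), n=4000, seed=22,
                        model=model, cost_schedule=schedule)
        ctrl = run_cohort(scenario("base_case", strategy="control"), n=4000,
                          seed=22, model=model, cost_schedule=schedule)
        assert ai.effectiveness.mean() >= ctrl.effectiveness.mean()

    def test_replacement_probability_does_not_affect_retention(self, model, schedule):
        """Implants replace lost teeth but never count as retention, so the
        replacement probability must leave effectiveness untouched."""
        a = run_cohort(scenario("replace_0"), n=500, seed=5, model=model,
                       cost_schedule=schedule)
        b = run_cohort(scenario("replace_100"), n=500, seed=5, model=model,
                       cost_schedule=schedule)
        assert np.array_equal(a.effectiveness, b.effectiveness)
        assert a.cost_discounted.mean() < b.cost_discounted.mean()


def test_cohort_argument_validation(model):
    with pytest.raises(ValueError):
        run_cohort(ScenarioConfig(), n=0, seed=1, model=model)
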