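"""Hazard functions, distributions, and parameter-file validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cariesim.fixtures import build_table1_config
from cariesim.parameters import (
    LesionStage,
    ParameterDistribution,
    ScenarioConfig,
    TransitionRow,
    development_probability,
    load_table1,
    prevalence,
    progression_probability,
    sample_parameter_set,
)

AGES = np.arange(12, 121)


def point_params(model, risk="low"):
    """ParameterSet at point estimates (PSA off)."""
    sc = ScenarioConfig(risk=risk, psa=False)
    return sample_parameter_set(model, sc, np.random.default_rng(0))


class TestHazardFormulas:
    """The published hazard forms, evaluated with the doubled-age argument
    they were printed with, against independently computed values."""

    @pytest.mark.parametrize(
        "stage, expected",
        [
            # m * a * 2.7**(-b * 2*age) at age 12, m = 1.26
            (LesionStage.E2, 1.26 * 0.57252 * 2.7 ** (-0.1472 * 24)),
            (LesionStage.D1, 1.26 * 0.0426 * 2.7 ** (-0.0521 * 24)),
            (LesionStage.D2, 1.26 * 0.57 * 0.0426 * 2.7 ** (-0.0521 * 24)),
        ],
    )
    def test_development_at_baseline_age(self, model_doubled_age, stage, expected):
        p = point_params(model_doubled_age)
        assert development_probability(12, stage, p) == pytest.approx(expected, rel=1e-9)
        # the first two printed to the usual 3 significant figures
        if stage == LesionStage.E2:
            assert p.development_probability(12, stage) == pytest.approx(0.0216, abs=5e-4)
        if stage == LesionStage.D1:
            assert p.development_probability(12, stage) == pytest.approx(0.0155, abs=5e-4)

    @pytest.mark.parametrize(
        "stage, infiltrated, expected",
        [
            (LesionStage.E2, False, 2.13 * 3.0984 * 24 ** (-1.343)),  # ~0.0925
            (LesionStage.D1, False, 2.13 * 161.52 * 24 ** (-2.078)),  # ~0.466
            (LesionStage.D2, False, 1.32 * 161.52 * 24 ** (-2.078)),  # ~0.289
            (LesionStage.E2, True, 0.4289 * 24 ** (-1.391)),  # ~0.0052
            (LesionStage.D1, True, 68.869 * 24 ** (-2.078)),
        ],
    )
    def test_progression_at_baseline_age(self, model_doubled_age, stage, infiltrated, expected):
        p = point_params(model_doubled_age, risk="low")
        got = progression_probability(12, stage, p, infiltrated=infiltrated)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_high_risk_multiplier_applies_to_initial_stages_only(self, model_doubled_age):
        lo = point_params(model_doubled_age, "low")
        hi = point_params(model_doubled_age, "high")
        for age in (12, 30, 60):
            assert progression_probability(age, LesionStage.E2, hi) == pytest.approx(
                progression_probability(age, LesionStage.E2, lo) * 2.63 / 2.13
            )
            # D2 -> D3 carries the fixed 1.32 multiplier, no risk dependence
            assert progression_probability(age, LesionStage.D2, hi) == pytest.approx(
                progression_probability(age, LesionStage.D2, lo)
            )

    def test_hazards_decay_to_zero_with_age(self, model):
        p = point_params(model)
        assert p.development_probability(500, LesionStage.E2) < 1e-12
        assert p.progression_probability(10_000, LesionStage.D1) < 1e-3

    @pytest.mark.parametrize("which_model", ["model", "model_doubled_age"])
    def test_all_hazards_are_probabilities_over_age_grid(self, which_model, request):
        p = point_params(request.getfixturevalue(which_model))
        for age in AGES:
            for stage in (LesionStage.E2, LesionStage.D1, LesionStage.D2):
                assert 0.0 <= p.development_probability(age, stage) <= 1.0
                assert 0.0 <= p.progression_probability(age, stage) <= 1.0
            for stage in (LesionStage.E2, LesionStage.D1):
                assert 0.0 <= p.progression_probability(age, stage, True) <= 1.0

    def test_monotone_in_age_and_orderings(self, model, model_doubled_age):
        """Hazards never increase with age (strictly decrease where not
        clamped); high risk >= low risk; infiltrated <= untreated."""
        for m, strict in ((model, False), (model_doubled_age, True)):
            lo, hi = point_params(m, "low"), point_params(m, "high")
            for stage in (LesionStage.E2, LesionStage.D1, LesionStage.D2):
                dev = [lo.development_probability(a, stage) for a in AGES]
                prog = [lo.progression_probability(a, stage) for a in AGES]
                for seq in (dev, prog):
                    diffs = np.diff(seq)
                    assert np.all(diffs <= 0)
                    if strict:
                        assert np.all(diffs < 0)
                for a in AGES:
                    assert hi.progression_probability(a, stage) >= (
                        lo.progression_probability(a, stage)
                    )
            for stage in (LesionStage.E2, LesionStage.D1):
                for a in AGES:
                    assert lo.progression_probability(a, stage, True) <= (
                        lo.progression_probability(a, stage, False)
                    )

    def test_stage_domain_errors(self, model):
        p = point_params(model)
        with pytest.raises(ValueError):
            development_probability(12, LesionStage.D3, p)
        with pytest.raises(ValueError):
            progression_probability(12, LesionStage.D3, p)
        with pytest.raises(ValueError):
            # infiltrated progression is undefined for D2 lesions
            progression_probability(12, LesionStage.D2, p, infiltrated=True)


class TestDistributions:
    def test_point_returns_exact_value(self):
        d = ParameterDistribution.point(0.016)
        assert d.sample(np.random.default_rng(0)) == 0.016

    def test_degenerate_triangular(self):
        d = ParameterDistribution.triangular(0.4, 0.4, 0.4)
        assert d.sample(np.random.default_rng(0)) == 0.4

    def test_uniform_sample_mean(self):
        d = ParameterDistribution("uniform", 1.24, 1.26, 1.29)
        rng = np.random.default_rng(42)
        xs = np.array([d.sample(rng) for _ in range(100_000)])
        se = (1.29 - 1.24) / np.sqrt(12) / np.sqrt(xs.size)
        assert abs(xs.mean() - 1.265) < 3 * se

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterDistribution("uniform", 1.3, 1.3, 1.2)
        with pytest.raises(ValueError):
            ParameterDistribution("point", 0.1, 0.2, 0.2)
        with pytest.raises(ValueError):
            ParameterDistribution("lognormal", 0, 1, 2)

    @settings(max_examples=50, deadline=None)
    @given(
        lo=st.floats(0, 1),
        spread=st.floats(0, 1),
        frac=st.floats(0, 1),
        kind=st.sampled_from(["uniform", "triangular"]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_samples_stay_in_bounds(self, lo, spread, frac, kind, seed):
        hi = lo + spread
        mode = lo + frac * spread
        d = ParameterDistribution(kind, lo, mode, hi)
        x = d.sample(np.random.default_rng(seed))
        assert lo <= x <= hi


class TestParameterFile:
    def test_allocation_maps_sum_to_one_and_reject_violations(self):
        cfg = build_table1_config()
        for row in cfg["transitions"].values():
            assert sum(row["allocation"].values()) == pytest.approx(1.0, abs=1e-12)
        cfg["transitions"]["composite"]["allocation"]["crown"] = 0.11
        with pytest.raises(ValueError, match="sum to 1"):
            load_table1(cfg)

    def test_prevalence_validation(self):
        cfg = build_table1_config()
        cfg["prevalence"]["low"]["E2"] = 0.999
        with pytest.raises(ValueError):
            load_table1(cfg)

    def test_high_risk_prevalence(self, model):
        low = prevalence(model, "low")
        high = prevalence(model, "high")
        assert low == {"E2": 0.14, "D1": 0.025, "D2": 0.005}
        assert high["E2"] == pytest.approx(2.14 * 0.14)
        assert high["D1"] == pytest.approx(1.66 * 0.025)
        with pytest.raises(ValueError):
            prevalence(model, "medium")

    def test_psa_draws_are_clamped_probabilities(self, model):
        sc = ScenarioConfig(psa=True)
        rng = np.random.default_rng(5)
        for _ in range(50):
            ps = sample_parameter_set(model, sc, rng)
            for method in ps.sensitivity:
                for v in ps.sensitivity[method].values():
                    assert 0.0 <= v <= 1.0
                for v in ps.specificity[method].values():
                    assert 0.0 <= v <= 1.0
            for v in ps.failure.values():
                assert 0.0 <= v <= 1.0

    def test_point_failure_probabilities_pass_through(self, model):
        ps = point_params(model)
        assert ps.failure["composite"] == 0.016
        assert ps.failure["surg_retreat"] == 0.061
        assert ps.pulp_exposure_d3 == 0.3
        assert ps.capping_fraction == 0.95

    def test_transition_row_allocation_order_preserved(self):
        row = TransitionRow(
            ParameterDistribution.point(0.5),
            (("a", 0.5), ("b", 0.5)),
        )
        assert [k for k, _ in row.allocation] == ["a", "b"]
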