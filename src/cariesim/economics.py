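"""Costing, discounting and cost-effectiveness statistics.

Every clinical event recorded by the engine is priced from a fee schedule
(euro, price year 2020).  Fees that a practice incurs once per patient visit
— the bitewing pair, the AI analysis of that pair, and the assessment/advice
of the visual-tactile exam — are divided by the number of teeth sharing them
(16 posterior teeth covered by one pair of bitewings by default).  Costs in
cycle ``t`` are discounted by ``(1 + r)**-t`` (start-of-cycle convention,
3 %/a by default).

The comparison layer computes the summary statistics of a two-strategy
cost-effectiveness analysis: incremental cost-effectiveness ratio (ICER) on
cohort means, the per-sample incremental cloud and its cost-effectiveness
plane quadrant fractions, net-monetary-benefit acceptability curves over a
willingness-to-pay grid, and a univariate sensitivity table over named
scenario variants.  Effectiveness (tooth retention years) enters these
statistics undiscounted; see the methods note for the rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CohortResult, ToothHistory
from .parameters import ScenarioConfig

__all__ = [
    "EVENT_KINDS",
    "SHARED_KINDS",
    "CostSchedule",
    "CEResult",
    "default_cost_schedule",
    "load_cost_schedule",
    "discount_factor",
    "cost_of_event",
    "price_history",
    "icer",
    "quadrant_fractions",
    "acceptability_curve",
    "compare",
    "sensitivity_table",
]

#: Every costable event kind the engine can emit.
EVENT_KINDS = (
    "exam_vt",
    "exam_bw",
    "ai_analysis",
    "infiltration",
    "restoration",
    "re_restoration",
    "repair",
    "direct_capping",
    "rct",
    "recement",
    "recrown",
    "crown",
    "nonsurg_retreat",
    "surg_retreat",
    "extraction",
    "implant_iscrown",
    "reimplant",
    "refix",
)

#: Fees incurred per visit/patient and shared across the covered teeth.
SHARED_KINDS = frozenset({"exam_vt", "exam_bw", "ai_analysis"})


@dataclass(frozen=True)
class CostSchedule:
    """Per-event fees (euro 2020) plus the shared-cost rules.

    ``ai_fee`` is the per-use charge for analyzing one pair of bitewings
    (8 euro base case; 4 and 12 in sensitivity analyses) and overrides any
    ``ai_analysis`` entry in ``fees``.  ``synthetic`` marks a placeholder
    schedule whose fee levels are not taken from the official German
    BEMA/GOZ catalogues.
    """

    fees: dict
    shared_divisor: int = 16
    ai_fee: float = 8.0
    currency: str = "EUR-2020"
    synthetic: bool = True

    def __post_init__(self) -> None:
        if self.shared_divisor < 1:
            raise ValueError("shared-cost divisor must be >= 1")
        if self.ai_fee < 0:
            raise ValueError("AI fee must be >= 0")
        bad = {k: v for k, v in self.fees.items() if v < 0}
        if bad:
            raise ValueError(f"negative fees: {bad}")

    def fee(self, kind: str) -> float:
        if kind == "ai_analysis":
            return self.ai_fee
        try:
            return self.fees[kind]
        except KeyError:
            raise KeyError(
                f"no fee configured for event kind {kind!r}; "
                f"known kinds: {sorted(self.fees)}"
            ) from None

    def with_overrides(
        self, ai_fee: float | None = None, shared_divisor: int | None = None
    ) -> "CostSchedule":
        out = self
        if ai_fee is not None:
            out = replace(out, ai_fee=ai_fee)
        if shared_divisor is not None:
            out = replace(out, shared_divisor=shared_divisor)
        return out

    def to_dict(self) -> dict:
        return {
            "currency": self.currency,
            "synthetic": self.synthetic,
            "shared_divisor": self.shared_divisor,
            "ai_fee_per_bitewing_pair": self.ai_fee,
            "fees": dict(self.fees),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostSchedule":
        return cls(
            fees={k: float(v) for k, v in d["fees"].items()},
            shared_divisor=int(d.get("shared_divisor", 16)),
            ai_fee=float(d.get("ai_fee_per_bitewing_pair", 8.0)),
            currency=d.get("currency", "EUR-2020"),
            synthetic=bool(d.get("synthetic", True)),
        )


def load_cost_schedule(path: str) -> CostSchedule:
    with open(path) as fh:
        return CostSchedule.from_dict(json.load(fh))


def default_cost_schedule() -> CostSchedule:
    """The packaged synthetic placeholder schedule (``synthetic: true``)."""
    text = resources.files("cariesim").joinpath("data/costs_placeholder.json").read_text()
    return CostSchedule.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Pricing
# ---------------------------------------------------------------------------

def discount_factor(year: int | float, rate: float) -> float:
    """Present-value multiplier ``(1 + rate)**-year`` for a cost in ``year``
    (0 = simulation start)."""
    if year < 0:
        raise ValueError("year must be >= 0")
    if rate <= -1.0:
        raise ValueError("rate must exceed -1")
    return (1.0 + rate) ** (-year)


def cost_of_event(event, schedule: CostSchedule) -> float:
    """Undiscounted per-tooth cost of one clinical event: the procedure fee,
    with visit-level fees (radiograph pair, AI analysis, assessment/advice)
    divided by the shared-cost divisor."""
    fee = schedule.fee(event.kind)
    if event.kind in SHARED_KINDS:
        fee /= schedule.shared_divisor
    return fee


def price_history(
    history: ToothHistory, schedule: CostSchedule, scenario: ScenarioConfig
) -> ToothHistory:
    """Fill in the discounted and undiscounted cost streams of a history,
    applying the scenario's AI fee, shared divisor and discount rate."""
    sched = schedule.with_overrides(
        ai_fee=scenario.ai_fee, shared_divisor=scenario.shared_divisor
    )
    undisc = 0.0
    disc = 0.0
    rate = scenario.discount_rate
    for ev in history.events:
        c = cost_of_event(ev, sched)
        undisc += c
        disc += c * discount_factor(ev.cycle, rate)
    history.cost_undiscounted = undisc
    history.cost_discounted = disc
    return history


# ---------------------------------------------------------------------------
# Cost-effectiveness statistics
# ---------------------------------------------------------------------------

def icer(test: CohortResult, control: CohortResult) -> float | None:
    """Incremental cost-effectiveness ratio on cohort means (euro per
    retention-year): ``(C_test - C_control) / (E_test - E_control)`` with
    discounted costs and undiscounted effectiveness.  Returns ``None`` when
    the effectiveness difference is exactly zero (dominance is then decided
    by cost alone and a ratio is undefined)."""
    d_cost = float(np.mean(test.cost_discounted) - np.mean(control.cost_discounted))
    d_eff = float(np.mean(test.effectiveness) - np.mean(control.effectiveness))
    if d_eff == 0.0:
        return None
    return d_cost / d_eff


def quadrant_fractions(
    delta_cost: Sequence[float], delta_eff: Sequence[float]
) -> dict:
    """Fractions of paired incremental samples in the four cost-effectiveness
    plane quadrants.  Tie rule: ``delta_cost == 0`` counts as less costly,
    ``delta_eff == 0`` as less effective; the fractions sum to 1 exactly."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_eff, dtype=float)
    if dc.shape != de.shape:
        raise ValueError("delta_cost and delta_eff must have equal length")
    costlier = dc > 0
    more_effective = de > 0
    n = dc.size
    return {
        "more_costly_more_effective": float(np.sum(costlier & more_effective)) / n,
        "more_costly_less_effective": float(np.sum(costlier & ~more_effective)) / n,
        "less_costly_more_effective": float(np.sum(~costlier & more_effective)) / n,
        "less_costly_less_effective": float(np.sum(~costlier & ~more_effective)) / n,
    }


def acceptability_curve(
    test: CohortResult,
    control: CohortResult,
    wtp_grid: Sequence[float],
) -> pd.DataFrame:
    """Cost-effectiveness acceptability: at each willingness-to-pay threshold
    the fraction of paired samples in which a strategy has the strictly
    larger net monetary benefit ``wtp * E - C`` (ties split evenly)."""
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if np.any(wtp < 0):
        raise ValueError("willingness-to-pay thresholds must be >= 0")
    rows = []
    for lam in wtp:
        nmb_t = lam * test.effectiveness - test.cost_discounted
        nmb_c = lam * control.effectiveness - control.cost_discounted
        p_test = float(np.mean((nmb_t > nmb_c) + 0.5 * (nmb_t == nmb_c)))
        rows.append((float(lam), p_test, 1.0 - p_test))
    return pd.DataFrame(rows, columns=["wtp", "p_test", "p_control"])


@dataclass
class CEResult:
    """Full two-strategy comparison: summaries, increments, ICER, quadrant
    fractions and acceptability curves."""

    test: dict
    control: dict
    delta_cost: float
    delta_effectiveness: float
    icer: float | None
    quadrants: dict
    ceac: pd.DataFrame = field(repr=False)
    delta_cost_samples: np.ndarray = field(repr=False)
    delta_eff_samples: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "control": self.control,
            "delta_cost": self.delta_cost,
            "delta_effectiveness": self.delta_effectiveness,
            "icer": self.icer,
            "quadrants": self.quadrants,
            "ceac": self.ceac.to_dict(orient="list"),
        }


def _ceac_from_deltas(
    dc: np.ndarray, de: np.ndarray, wtp_grid: np.ndarray
) -> pd.DataFrame:
    rows = []
    for lam in wtp_grid:
        dnmb = lam * de - dc
        p_test = float(np.mean((dnmb > 0) + 0.5 * (dnmb == 0)))
        rows.append((float(lam), p_test, 1.0 - p_test))
    return pd.DataFrame(rows, columns=["wtp", "p_test", "p_control"])


def compare(
    test: CohortResult,
    control: CohortResult,
    wtp_grid: Sequence[float] | None = None,
    level: str = "bootstrap",
    n_boot: int = 1000,
    boot_seed: int = 0,
) -> CEResult:
    """Compare two cohorts simulated with the same seed (common random
    numbers pair teeth by index).  The willingness-to-pay grid defaults to
    0..100 euro per retention-year in steps of 5.

    ``level`` selects the sampling unit of the incremental cloud behind the
    quadrant fractions and acceptability curves.  The default
    ``"bootstrap"`` draws ``n_boot`` bootstrap replicates of the paired
    cohort means, the natural unit for a decision between strategies
    (per-tooth increments concentrate at exactly zero effectiveness
    difference, since most individual teeth fare identically under both
    strategies).  ``"tooth"`` uses the raw per-tooth paired increments.
    """
    if test.n != control.n:
        raise ValueError("cohorts must have equal size for paired comparison")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 101.0, 5.0)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    dc = test.cost_discounted - control.cost_discounted
    de = test.effectiveness - control.effectiveness
    if level == "bootstrap":
        rng = np.random.default_rng(boot_seed)
        idx = rng.integers(0, test.n, size=(n_boot, test.n))
        dc_s = dc[idx].mean(axis=1)
        de_s = de[idx].mean(axis=1)
    elif level == "tooth":
        dc_s, de_s = dc, de
    else:
        raise ValueError(f"unknown level {level!r} (expected 'bootstrap' or 'tooth')")
    return CEResult(
        test=test.summary(),
        control=control.summary(),
        delta_cost=float(np.mean(dc)),
        delta_effectiveness=float(np.mean(de)),
        icer=icer(test, control),
        quadrants=quadrant_fractions(dc_s, de_s),
        ceac=_ceac_from_deltas(dc_s, de_s, wtp_grid),
        delta_cost_samples=dc_s,
        delta_eff_samples=de_s,
    )


# ---------------------------------------------------------------------------
# Univariate sensitivity table
# ---------------------------------------------------------------------------

def sensitivity_table(
    variants: Sequence[str] | None = None,
    n: int = 1000,
    seed: int = 1,
    model=None,
    cost_schedule: CostSchedule | None = None,
) -> pd.DataFrame:
    """One row per scenario variant: cost and effectiveness (mean and
    2.5/97.5 percentiles) of both strategies plus the ICER.

    Variant names are the scenario presets of :mod:`cariesim.fixtures`
    (``base_case``, ``high_risk``, ``restorative_policy``, ...); an empty
    list yields the base row only.  Both strategies of every row share the
    root seed, and identical simulation settings are run once and re-priced.
    """
    from .engine import run_cohort
    from .fixtures import PRESETS, scenario as make_scenario

    if variants is None:
        variants = list(PRESETS)
    unknown = [v for v in variants if v not in PRESETS]
    if unknown:
        raise KeyError(f"unknown variants {unknown}; known: {list(PRESETS)}")
    if "base_case" not in variants:
        variants = ["base_case", *variants]

    # Cache simulations on the settings that actually shape event streams;
    # fee and discount variants only re-price cached histories.
    sim_cache: dict = {}

    def _cohort(sc: ScenarioConfig) -> CohortResult:
        key = (
            sc.risk,
            sc.strategy,
            sc.policy,
            sc.control_profile,
            sc.horizon,
            sc.replacement,
            sc.vt_interval,
            sc.bw_interval,
            sc.psa,
        )
        if key not in sim_cache:
            sim_cache[key] = run_cohort(
                sc, n, seed, model=model, cost_schedule=cost_schedule,
                keep_histories=True,
            )
        cached = sim_cache[key]
        if (
            cached.scenario.ai_fee == sc.ai_fee
            and cached.scenario.discount_rate == sc.discount_rate
            and cached.scenario.shared_divisor == sc.shared_divisor
        ):
            return cached
        return _reprice(cached, sc, cost_schedule)

    rows = []
    for name in variants:
        test = _cohort(make_scenario(name, strategy="ai"))
        control = _cohort(make_scenario(name, strategy="control"))
        s_t, s_c = test.summary(), control.summary()
        rows.append(
            {
                "scenario": name,
                "cost_ai": s_t["cost"]["mean"],
                "cost_ai_p2.5": s_t["cost"]["p2.5"],
                "cost_ai_p97.5": s_t["cost"]["p97.5"],
                "eff_ai": s_t["effectiveness"]["mean"],
                "eff_ai_p2.5": s_t["effectiveness"]["p2.5"],
                "eff_ai_p97.5": s_t["effectiveness"]["p97.5"],
                "cost_control": s_c["cost"]["mean"],
                "cost_control_p2.5": s_c["cost"]["p2.5"],
                "cost_control_p97.5": s_c["cost"]["p97.5"],
                "eff_control": s_c["effectiveness"]["mean"],
                "eff_control_p2.5": s_c["effectiveness"]["p2.5"],
                "eff_control_p97.5": s_c["effectiveness"]["p97.5"],
                "icer": icer(test, control),
            }
        )
    return pd.DataFrame(rows)


def _reprice(
    cohort: CohortResult, scenario: ScenarioConfig, cost_schedule: CostSchedule | None
) -> CohortResult:
    """Re-price a simulated cohort under different fee/discount settings;
    event streams and retention are unchanged by construction."""
    if not cohort.histories:
        raise ValueError("repricing requires histories (keep_histories=True)")
    schedule = cost_schedule if cost_schedule is not None else default_cost_schedule()
    n = cohort.n
    cost_d = np.empty(n)
    cost_u = np.empty(n)
    eff_d = np.empty(n)
    r = scenario.discount_rate
    for i, hist in enumerate(cohort.histories):
        h = ToothHistory(
            hist.events, hist.retention_years, hist.retention_discounted
        )
        price_history(h, schedule, scenario)
        cost_d[i] = h.cost_discounted
        cost_u[i] = h.cost_undiscounted
        T = hist.retention_years
        eff_d[i] = T if r == 0 else (1 - (1 + r) ** (-T)) / (1 - 1 / (1 + r))
    return CohortResult(
        scenario=scenario,
        n=n,
        seed=cohort.seed,
        effectiveness=cohort.effectiveness.copy(),
        effectiveness_discounted=eff_d,
        cost_discounted=cost_d,
        cost_undiscounted=cost_u,
    )
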