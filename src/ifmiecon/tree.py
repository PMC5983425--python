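"""Decision tree for repeat breast-conserving surgeries after positive margins.

Both strategies share one tree: after the first surgery the pathology
report is positive with probability ``p_first`` (0.30 under standard
techniques, ST; 0.10 under intra-operative fluorescence molecular
imaging, IFMI, at the base-case relative risk of 1/3). Positive margins
trigger a re-excision; a second positive report (probability
``p_second`` = 0.10 in both arms) triggers a third and final surgery.
Expected surgeries per patient are therefore ``1 + p_first*(1 + p_second)``
— 1.33 for ST and 1.11 for IFMI at base case.

Costs accrue per surgery as the DRG lump sum plus lost productivity, and
once per IFMI patient as the add-on (agent, camera, draping, additional
staff, and the operating-time delta). The per-minute operating cost ``c``
and the fixed saving ``F`` attached to skipping frozen section analysis
(FSA) are not derivable from printed inputs alone; `calibrate_time_cost`
recovers the unique pair consistent with two published incremental-cost
anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .parameters import (
    CostParameters,
    MarginModel,
    ParameterError,
    device_cost_per_surgery,
)

__all__ = [
    "PathOutcome",
    "StrategyResult",
    "IncrementalResult",
    "path_distribution",
    "expected_surgeries",
    "device_cost_per_surgery",
    "time_delta_cost",
    "ifmi_addon_cost",
    "path_outcomes",
    "expected_cost",
    "incremental",
    "calibrate_time_cost",
    "floor_eur",
]

Strategy = Literal["IFMI", "ST"]


def floor_eur(x: float) -> int:
    """Truncate a euro amount to whole euros (display convention)."""
    return int(math.floor(x))


@dataclass(frozen=True)
class PathOutcome:
    """One terminal path of the tree: surgery count, probability, total cost."""

    n_surgeries: int
    probability: float
    cost: float


@dataclass(frozen=True)
class StrategyResult:
    """Expected surgeries and expected cost per patient for one strategy."""

    strategy: Strategy
    expected_surgeries: float
    expected_cost: float

    @property
    def expected_cost_eur(self) -> int:
        return floor_eur(self.expected_cost)


@dataclass(frozen=True)
class IncrementalResult:
    """IFMI-minus-ST differences in expected surgeries and expected cost."""

    delta_surgeries: float
    delta_cost: float
    ci_surgeries: tuple[float, float] | None = None
    ci_cost: tuple[float, float] | None = None
    n_draws: int | None = None
    seed: int | None = None


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {p}")


def path_distribution(p_first: float, p_second: float) -> tuple[float, float, float]:
    """Probabilities of stopping after 1, 2 or 3 surgeries.

    ``P(1) = 1 - p_first``, ``P(2) = p_first*(1 - p_second)``,
    ``P(3) = p_first*p_second`` (the third surgery is final regardless of
    margins). The three always sum to 1.
    """
    _check_prob("p_first", p_first)
    _check_prob("p_second", p_second)
    return (1.0 - p_first, p_first * (1.0 - p_second), p_first * p_second)


def expected_surgeries(p_first: float, p_second: float) -> float:
    """Expected surgery count per patient: ``1 + p_first*(1 + p_second)``."""
    _check_prob("p_first", p_first)
    _check_prob("p_second", p_second)
    return 1.0 + p_first * (1.0 + p_second)


def time_delta_cost(
    prolongation: float, fsa_duration: float, s: float, c: float, F: float
):
    """Net cost of the operating-time change under IFMI.

    Fluorescence inspection prolongs surgery by ``prolongation`` minutes;
    skipping FSA saves ``s * fsa_duration`` minutes of staff waiting time
    (``s`` is the staff time saving factor in [0, 1]). The net minutes are
    priced at ``c`` EUR/minute and a fixed FSA saving ``F`` is subtracted:
    ``(prolongation - s*fsa_duration)*c - F``. Negative values are savings.

    Accepts scalars or numpy arrays (used draw-wise by the PSA).
    """
    import numpy as np

    if np.any(np.asarray(s) < 0) or np.any(np.asarray(s) > 1):
        raise ParameterError(f"staff time saving factor must lie in [0, 1], got {s}")
    return (prolongation - s * fsa_duration) * c - F


def ifmi_addon_cost(costs: CostParameters, *, cost_per_minute: float | None = None) -> float:
    """One-time add-on charged to each IFMI patient (first surgery only).

    Agent + camera system + sterile draping + additional staff + the
    operating-time delta. At base case with the calibrated time-cost
    defaults: 500 + 182 + 23 + 107 - 588.62 = 223.38 EUR.
    """
    c = costs.cost_per_minute if cost_per_minute is None else cost_per_minute
    return (
        costs.agent_cost
        + costs.camera_cost
        + costs.draping_cost
        + costs.staff_addon_cost
        + time_delta_cost(
            costs.prolongation,
            costs.fsa_duration,
            costs.staff_time_saving_factor,
            c,
            costs.fsa_fixed_saving,
        )
    )


def derived_cost_per_minute(costs: CostParameters) -> float:
    """Non-calibrated fallback for c: per-surgery lump sum over ST duration.

    ``(drg_cost + lost_productivity)/st_duration`` = 68.29 EUR/min at base
    case, numerically close to the calibrated 68.23.
    """
    return costs.lump_sum_per_surgery / costs.st_duration


def path_outcomes(
    strategy: Strategy, margins: MarginModel, costs: CostParameters
) -> list[PathOutcome]:
    """The three terminal paths with their probabilities and total costs."""
    p_first = margins.p_pos_ifmi if strategy == "IFMI" else margins.p_pos_st
    probs = path_distribution(p_first, margins.p_pos_second)
    addon = ifmi_addon_cost(costs) if strategy == "IFMI" else 0.0
    return [
        PathOutcome(n, p, n * costs.lump_sum_per_surgery + addon)
        for n, p in zip((1, 2, 3), probs)
    ]


def expected_cost(
    strategy: Strategy, margins: MarginModel, costs: CostParameters
) -> StrategyResult:
    """Expected cost per patient: lump sum times expected surgeries, plus
    the add-on once for IFMI. Base case: 5,358.57 EUR (ST), 4,695.57 (IFMI)."""
    if strategy not in ("IFMI", "ST"):
        raise ParameterError(f"strategy must be 'IFMI' or 'ST', got {strategy!r}")
    p_first = margins.p_pos_ifmi if strategy == "IFMI" else margins.p_pos_st
    e_n = expected_surgeries(p_first, margins.p_pos_second)
    cost = costs.lump_sum_per_surgery * e_n
    if strategy == "IFMI":
        cost += ifmi_addon_cost(costs)
    return StrategyResult(strategy=strategy, expected_surgeries=e_n, expected_cost=cost)


def incremental(margins: MarginModel, costs: CostParameters) -> IncrementalResult:
    """Deterministic IFMI-minus-ST endpoints.

    ``delta_surgeries = (p_pos_ifmi - p_pos_st)*(1 + p_pos_second)`` (−0.22
    at base case) and ``delta_cost = delta_surgeries*lump_sum + addon``
    (−663 EUR at base case with the calibrated time-cost defaults).
    """
    d_surg = (margins.p_pos_ifmi - margins.p_pos_st) * (1.0 + margins.p_pos_second)
    d_cost = d_surg * costs.lump_sum_per_surgery + ifmi_addon_cost(costs)
    return IncrementalResult(delta_surgeries=d_surg, delta_cost=d_cost)


#: Flat parameter names understood by :func:`incremental_from_values`.
MODEL_PARAMETERS: tuple[str, ...] = (
    "p_pos_st", "p_pos_ifmi", "p_pos_second",
    "drg_cost", "lost_productivity", "agent_cost", "camera_cost",
    "draping_cost", "staff_addon_cost", "st_duration", "prolongation",
    "fsa_duration", "staff_time_saving_factor",
)


def flatten_values(margins: MarginModel, costs: CostParameters) -> dict[str, float]:
    """Flat name -> value map of every model parameter (margins + costs)."""
    out: dict[str, float] = {}
    for name in MODEL_PARAMETERS:
        out[name] = getattr(margins, name) if hasattr(margins, name) else getattr(costs, name)
    return out


def incremental_from_values(
    v,
    *,
    fsa_fixed_saving: float,
    cost_per_minute: float | None = None,
):
    """Incremental endpoints from a flat value map (scalars or numpy arrays).

    When ``cost_per_minute`` is None, c is derived per evaluation as
    ``(drg_cost + lost_productivity)/st_duration`` — the mode used
    draw-wise by the PSA and variation-wise by the tornado analysis.
    Returns ``(delta_surgeries, delta_cost)``.
    """
    lump = v["drg_cost"] + v["lost_productivity"]
    c = lump / v["st_duration"] if cost_per_minute is None else cost_per_minute
    addon = (
        v["agent_cost"]
        + v["camera_cost"]
        + v["draping_cost"]
        + v["staff_addon_cost"]
        + time_delta_cost(
            v["prolongation"], v["fsa_duration"],
            v["staff_time_saving_factor"], c, fsa_fixed_saving,
        )
    )
    d_surg = (v["p_pos_ifmi"] - v["p_pos_st"]) * (1.0 + v["p_pos_second"])
    d_cost = d_surg * lump + addon
    return d_surg, d_cost


def calibrate_time_cost(
    anchor_a: tuple[float, float],
    anchor_b: tuple[float, float],
    margins: MarginModel | None = None,
    costs: CostParameters | None = None,
) -> tuple[float, float]:
    """Recover (c, F) from two incremental-cost anchors at different staff factors.

    Each anchor is ``(s, delta_cost)``. With everything else at the given
    (default: base-case) parameter values, the incremental cost is affine
    in s: ``delta_cost(s) = K + (prolongation - s*fsa_duration)*c - F``
    with ``K = delta_surgeries*lump_sum + agent + camera + draping + staff``.
    Two anchors with distinct s give a 2x2 linear system with the unique
    solution returned here; the published anchors (0.64, −663) and (0, 516)
    yield c ≈ 68.23 EUR/min and F ≈ 91.91 EUR.
    """
    margins = margins if margins is not None else MarginModel()
    costs = costs if costs is not None else CostParameters()
    (s_a, d_a), (s_b, d_b) = anchor_a, anchor_b
    if s_a == s_b:
        raise ParameterError("calibration anchors must have distinct staff factors")
    d_surg = (margins.p_pos_ifmi - margins.p_pos_st) * (1.0 + margins.p_pos_second)
    K = (
        d_surg * costs.lump_sum_per_surgery
        + costs.agent_cost
        + costs.camera_cost
        + costs.draping_cost
        + costs.staff_addon_cost
    )
    # (d_a - d_b) = (s_b - s_a) * fsa * c
    c = (d_a - d_b) / ((s_b - s_a) * costs.fsa_duration)
    F = (costs.prolongation - s_a * costs.fsa_duration) * c - (d_a - K)
    return c, F
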