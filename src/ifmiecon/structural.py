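"""Structural sensitivity analyses: two alternative tree structures.

Variant A relaxes the deterministic re-excision rule after the first
surgery: patients with positive margins are re-excised only with
probability ``p_reexcise_given_pos`` and patients with negative margins
may nevertheless be re-operated with probability ``p_reexcise_given_neg``
(as observed in practice registries). From the second surgery on, the
base rule applies again. Setting (1, 0) recovers the base tree exactly.

Variant B drops margin dependence altogether: each strategy carries a
probability vector over total surgery counts {1, 2, 3, 4}, allowing a
fourth surgery. The probabilities observed in practice are not part of
the published inputs; the defaults here are illustrative placeholders
(the base tree's own path distribution) and should be overridden with
registry data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import CostParameters, MarginModel, ParameterError
from .tree import IncrementalResult, StrategyResult, Strategy, ifmi_addon_cost

__all__ = [
    "VariantAParams",
    "VariantBParams",
    "variant_a_expected_surgeries",
    "variant_a_expected_cost",
    "variant_a_incremental",
    "variant_b_expected",
    "variant_b_incremental",
]


@dataclass(frozen=True)
class VariantAParams:
    """Re-excision probabilities after the first surgery, by margin status.

    Defaults are illustrative (not published inputs): most positive
    margins re-excised, a small fraction of negative margins re-operated.
    """

    p_reexcise_given_pos: float = 0.9
    p_reexcise_given_neg: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_reexcise_given_pos", "p_reexcise_given_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


def _base_path_vector() -> dict[int, float]:
    # base tree's ST path distribution; illustrative placeholder only
    return {1: 0.70, 2: 0.27, 3: 0.03, 4: 0.0}


@dataclass(frozen=True)
class VariantBParams:
    """Per-strategy probability vectors over total surgery counts {1,2,3,4}.

    Defaults are illustrative placeholders (the base tree's own path
    distribution for both arms), not published inputs.
    """

    ifmi: dict[int, float] = field(default_factory=_base_path_vector)
    st: dict[int, float] = field(default_factory=_base_path_vector)

    def __post_init__(self) -> None:
        for arm, vec in (("ifmi", self.ifmi), ("st", self.st)):
            _validate_vector(arm, vec)


def _validate_vector(arm: str, vec: dict[int, float]) -> None:
    bad_keys = set(vec) - {1, 2, 3, 4}
    if bad_keys:
        raise ParameterError(f"{arm} surgery counts must be in {{1,2,3,4}}, got {sorted(bad_keys)}")
    if any(p < 0 for p in vec.values()):
        raise ParameterError(f"{arm} probabilities must be >= 0")
    total = sum(vec.values())
    if abs(total - 1.0) > 1e-12:
        raise ParameterError(f"{arm} probabilities sum to {total}, expected 1")


def variant_a_second_surgery_probability(p_first: float, va: VariantAParams) -> float:
    """Probability of undergoing a second surgery under variant A."""
    if not 0.0 <= p_first <= 1.0:
        raise ParameterError(f"p_first must lie in [0, 1], got {p_first}")
    return p_first * va.p_reexcise_given_pos + (1.0 - p_first) * va.p_reexcise_given_neg


def variant_a_expected_surgeries(
    p_first: float, va: VariantAParams, p_second: float
) -> float:
    """Expected surgeries with probabilistic first-surgery re-excision.

    ``q = p_first*p_reexcise_given_pos + (1-p_first)*p_reexcise_given_neg``
    patients get a second surgery; a fraction ``p_second`` of those gets
    the final third one: ``1 + q*(1 + p_second)``.
    """
    if not 0.0 <= p_second <= 1.0:
        raise ParameterError(f"p_second must lie in [0, 1], got {p_second}")
    q = variant_a_second_surgery_probability(p_first, va)
    return 1.0 + q * (1.0 + p_second)


def variant_a_expected_cost(
    strategy: Strategy, margins: MarginModel, costs: CostParameters, va: VariantAParams
) -> StrategyResult:
    """Variant-A expected cost: lump sum per surgery, add-on once for IFMI."""
    p_first = margins.p_pos_ifmi if strategy == "IFMI" else margins.p_pos_st
    e_n = variant_a_expected_surgeries(p_first, va, margins.p_pos_second)
    cost = costs.lump_sum_per_surgery * e_n
    if strategy == "IFMI":
        cost += ifmi_addon_cost(costs)
    return StrategyResult(strategy=strategy, expected_surgeries=e_n, expected_cost=cost)


def variant_a_incremental(
    margins: MarginModel, costs: CostParameters, va: VariantAParams
) -> IncrementalResult:
    r_ifmi = variant_a_expected_cost("IFMI", margins, costs, va)
    r_st = variant_a_expected_cost("ST", margins, costs, va)
    return IncrementalResult(
        delta_surgeries=r_ifmi.expected_surgeries - r_st.expected_surgeries,
        delta_cost=r_ifmi.expected_cost - r_st.expected_cost,
    )


def variant_b_expected(
    vb: VariantBParams, costs: CostParameters, strategy: Strategy
) -> StrategyResult:
    """Margin-independent variant: E[N] = sum k*p_k over counts {1,2,3,4}.

    ``vb`` may also be a single plain probability vector (dict), applied
    to the requested strategy.
    """
    if strategy not in ("IFMI", "ST"):
        raise ParameterError(f"strategy must be 'IFMI' or 'ST', got {strategy!r}")
    if isinstance(vb, dict):
        _validate_vector(strategy.lower(), vb)
        vec = vb
    else:
        vec = vb.ifmi if strategy == "IFMI" else vb.st
    e_n = sum(k * p for k, p in vec.items())
    cost = costs.lump_sum_per_surgery * e_n
    if strategy == "IFMI":
        cost += ifmi_addon_cost(costs)
    return StrategyResult(strategy=strategy, expected_surgeries=e_n, expected_cost=cost)


def variant_b_incremental(vb: VariantBParams, costs: CostParameters) -> IncrementalResult:
    r_ifmi = variant_b_expected(vb, costs, "IFMI")
    r_st = variant_b_expected(vb, costs, "ST")
    return IncrementalResult(
        delta_surgeries=r_ifmi.expected_surgeries - r_st.expected_surgeries,
        delta_cost=r_ifmi.expected_cost - r_st.expected_cost,
    )
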