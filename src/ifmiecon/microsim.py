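"""Patient-level microsimulation: a brute-force oracle for the cohort model.

Each simulated patient walks the decision tree with Bernoulli margin
outcomes — first-surgery positive margins with the strategy's proportion,
second-surgery positive margins with the shared proportion — accumulating
the per-surgery lump sum and, for IFMI, the one-time add-on. Costs are
attached deterministically given the realized path: the cohort model is
an expectation, and the simulator's role is to verify it, not to add
patient-level cost noise. Cohort means must therefore agree with the
closed-form expected surgeries and expected costs to Monte-Carlo error,
which the test suite checks across random parameterizations.

Structural variant A (probabilistic re-excision after the first surgery)
is also simulable for oracle coverage of that tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterError, ParameterSet
from .structural import VariantAParams
from .tree import Strategy, ifmi_addon_cost

__all__ = ["PatientRecord", "CohortSummary", "simulate_cohort", "summarize_cohort",
           "cohort_frame"]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's realized trajectory through the tree."""

    strategy: Strategy
    margins: tuple[str, ...]  # assessed outcomes ("positive"/"negative"), surgeries 1..2
    n_surgeries: int
    total_cost: float


@dataclass(frozen=True)
class CohortSummary:
    """Sample means and standard errors of surgeries and cost per strategy."""

    strategy: Strategy
    n_patients: int
    mean_surgeries: float
    se_surgeries: float
    mean_cost: float
    se_cost: float


def simulate_cohort(
    params: ParameterSet,
    n_patients: int,
    seed: int,
    strategy: Strategy,
    variant_a: VariantAParams | None = None,
) -> list[PatientRecord]:
    """Simulate individual trajectories through the (possibly variant-A) tree.

    Reproducible under ``seed``; margin outcomes are Bernoulli draws with
    the configured proportions, costs accumulate per realized path.
    """
    if n_patients < 1:
        raise ParameterError(f"n_patients must be >= 1, got {n_patients}")
    if strategy not in ("IFMI", "ST"):
        raise ParameterError(f"strategy must be 'IFMI' or 'ST', got {strategy!r}")
    margins, costs = params.margins, params.costs
    p_first = margins.p_pos_ifmi if strategy == "IFMI" else margins.p_pos_st
    p_second = margins.p_pos_second
    addon = ifmi_addon_cost(costs) if strategy == "IFMI" else 0.0
    lump = costs.lump_sum_per_surgery

    rng = np.random.default_rng(seed)
    first_pos = rng.random(n_patients) < p_first
    if variant_a is None:
        goes_second = first_pos
    else:
        u = rng.random(n_patients)
        goes_second = np.where(
            first_pos,
            u < variant_a.p_reexcise_given_pos,
            u < variant_a.p_reexcise_given_neg,
        )
    second_pos = np.logical_and(goes_second, rng.random(n_patients) < p_second)
    n_surg = 1 + goes_second.astype(int) + second_pos.astype(int)
    total = n_surg * lump + addon

    records = []
    for i in range(n_patients):
        outcome = ["positive" if first_pos[i] else "negative"]
        if goes_second[i]:
            outcome.append("positive" if second_pos[i] else "negative")
        records.append(
            PatientRecord(
                strategy=strategy,
                margins=tuple(outcome),
                n_surgeries=int(n_surg[i]),
                total_cost=float(total[i]),
            )
        )
    return records


def summarize_cohort(records: list[PatientRecord]) -> CohortSummary:
    """Sample means and standard errors (sd/sqrt(n); NaN for n = 1)."""
    if not records:
        raise ParameterError("summarize_cohort needs a nonempty cohort")
    n = len(records)
    surg = np.array([r.n_surgeries for r in records], dtype=float)
    cost = np.array([r.total_cost for r in records], dtype=float)

    def _se(x: np.ndarray) -> float:
        if n < 2:
            return math.nan
        return float(x.std(ddof=1) / math.sqrt(n))

    return CohortSummary(
        strategy=records[0].strategy,
        n_patients=n,
        mean_surgeries=float(surg.mean()),
        se_surgeries=_se(surg),
        mean_cost=float(cost.mean()),
        se_cost=_se(cost),
    )


def cohort_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Long patient-level table: one row per performed, margin-assessed surgery."""
    rows = []
    for idx, r in enumerate(records):
        for k, outcome in enumerate(r.margins, start=1):
            rows.append(
                {
                    "patient": idx,
                    "strategy": r.strategy,
                    "surgery_index": k,
                    "margin_outcome": outcome,
                    "n_surgeries": r.n_surgeries,
                    "total_cost_eur": r.total_cost,
                }
            )
    return pd.DataFrame(rows)
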