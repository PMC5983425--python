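"""Model parameterization: margin probabilities, cost inputs, and the
sampling distributions used in probabilistic sensitivity analysis (PSA).

The base-case values reproduce the published early-assessment model of
intra-operative fluorescence molecular imaging (IFMI) versus standard
breast-conserving surgery (ST) in the German setting: first-surgery
positive-margin proportions of 0.10 (IFMI) and 0.30 (ST), a shared
second-surgery positive-margin proportion of 0.10, a DRG lump sum of
EUR 3,508 per surgery, and the itemized IFMI add-on components.

Uncertain parameters carry a :class:`DistributionSpec` fitted by the
method of moments: beta for proportions (from mean and standard error),
gamma for costs (from mean and standard error), triangular for durations
(printed min/max with the base case as the mode). Parameters without a
distribution (the staff time saving factor) are held fixed in the PSA.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping

import numpy as np

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "MarginModel",
    "CostParameters",
    "ParameterSet",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "device_cost_per_surgery",
    "default_psa_specs",
    "load_parameters",
    "load_parameters_from_file",
    "default_config_path",
    "spawn_rng",
]


class ParameterError(ValueError):
    """A configuration value violates a type invariant; names the offending key."""


# ---------------------------------------------------------------------------
# Method-of-moments fits
# ---------------------------------------------------------------------------

def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Fit a beta distribution to a proportion's mean and standard error.

    Returns shape parameters ``(a, b)`` with analytic mean ``a/(a+b) = mean``
    and analytic variance ``se**2``. Feasible only for
    ``0 < mean < 1`` and ``0 < se**2 < mean*(1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must lie in (0, 1), got {mean}")
    if not 0.0 < se * se < mean * (1.0 - mean):
        raise ParameterError(
            f"beta fit infeasible: need 0 < se^2 < mean*(1-mean), "
            f"got mean={mean}, se={se}"
        )
    shape_sum = mean * (1.0 - mean) / (se * se) - 1.0
    a = mean * shape_sum
    return a, shape_sum - a


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Fit a gamma distribution to a positive quantity's mean and standard error.

    Returns ``(shape, scale)`` with ``shape*scale = mean`` and
    ``shape*scale**2 = se**2``.
    """
    if mean <= 0.0 or se <= 0.0:
        raise ParameterError(f"gamma fit needs mean > 0 and se > 0, got ({mean}, {se})")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling law of one uncertain parameter.

    kind
        ``"beta"`` or ``"gamma"`` (moment-matched to ``mean`` and ``se``),
        ``"triangular"`` (support ``[min, max]``, mode at ``mean``), or
        ``"fixed"`` (degenerate at ``mean``).
    mean
        Base-case point estimate, in the parameter's natural units.
    se
        Standard error (beta/gamma only).
    min, max
        Support bounds (triangular only).
    """

    kind: str
    mean: float
    se: float | None = None
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "triangular", "fixed"):
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            beta_from_mean_se(self.mean, self._se())
        elif self.kind == "gamma":
            gamma_from_mean_se(self.mean, self._se())
        elif self.kind == "triangular":
            if self.min is None or self.max is None:
                raise ParameterError("triangular spec requires min and max")
            if not (self.min <= self.mean <= self.max and self.min < self.max):
                raise ParameterError(
                    f"triangular spec needs min <= mode <= max and min < max, "
                    f"got ({self.min}, {self.mean}, {self.max})"
                )

    def _se(self) -> float:
        if self.se is None:
            raise ParameterError(f"{self.kind} spec requires an se")
        return self.se

    # -- analytic moments (closed form; used by the moment-recovery checks) --

    def analytic_mean(self) -> float:
        if self.kind == "triangular":
            return (self.min + self.mean + self.max) / 3.0  # type: ignore[operator]
        return self.mean

    def analytic_sd(self) -> float:
        if self.kind == "fixed":
            return 0.0
        if self.kind == "triangular":
            a, c, b = self.min, self.mean, self.max
            return math.sqrt(
                (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0  # type: ignore[operator]
            )
        return self._se()

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; ``fixed`` returns the mean exactly."""
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "beta":
            a, b = beta_from_mean_se(self.mean, self._se())
            return rng.beta(a, b, size)
        if self.kind == "gamma":
            shape, scale = gamma_from_mean_se(self.mean, self._se())
            return rng.gamma(shape, scale, size)
        return rng.triangular(self.min, self.mean, self.max, size)

    def to_dict(self) -> dict[str, Any]:
        d = {"kind": self.kind, "mean": self.mean}
        if self.se is not None:
            d["se"] = self.se
        if self.min is not None:
            d["min"] = self.min
        if self.max is not None:
            d["max"] = self.max
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistributionSpec":
        allowed = {"kind", "mean", "se", "min", "max"}
        unknown = set(d) - allowed
        if unknown:
            raise ParameterError(f"unknown distribution keys {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # missing kind/mean
            raise ParameterError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Margin model and cost parameters
# ---------------------------------------------------------------------------

def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class MarginModel:
    """Positive-margin proportions driving the re-excision decision tree.

    ``p_pos_second`` (probability of positive margins after the second
    surgery, triggering the final third surgery) applies to both the IFMI
    and the ST arm. ``psa_mode`` selects how the PSA treats the IFMI
    proportion: ``"fixed_rr"`` ties it to the sampled ST proportion through
    the base-case relative risk; ``"independent"`` samples it from its own
    beta distribution.
    """

    p_pos_st: float = 0.3
    p_pos_ifmi: float = 0.1
    p_pos_second: float = 0.1
    psa_mode: str = "fixed_rr"

    def __post_init__(self) -> None:
        for name in ("p_pos_st", "p_pos_ifmi", "p_pos_second"):
            _check_prob(name, getattr(self, name))
        if self.psa_mode not in ("fixed_rr", "independent"):
            raise ParameterError(f"psa_mode must be fixed_rr or independent, got {self.psa_mode!r}")

    @property
    def rr(self) -> float:
        """Relative risk of positive margins, IFMI vs ST (base case 1/3)."""
        if self.p_pos_st == 0.0:
            return float("nan")
        return self.p_pos_ifmi / self.p_pos_st

    def with_rr(self, rr: float) -> "MarginModel":
        """Return a copy with ``p_pos_ifmi = rr * p_pos_st``."""
        if not 0.0 <= rr <= 1.0:
            raise ParameterError(f"relative risk must lie in [0, 1], got {rr}")
        return replace(self, p_pos_ifmi=rr * self.p_pos_st)


def device_cost_per_surgery(
    price: float, maintenance_rate: float, lifespan: float, volume: float
) -> float:
    """Amortized camera-system cost per surgery.

    Straight-line depreciation of the purchase price over its operational
    life span plus annual maintenance (a fraction of the price), spread
    over the annual surgery volume:
    ``price/(lifespan*volume) + maintenance_rate*price/volume``.
    The base case (150,000 EUR, 10% p.a., 7 years, 200 surgeries/year)
    gives 182.14, reported as EUR 182 per surgery.
    """
    if price < 0:
        raise ParameterError(f"device price must be >= 0, got {price}")
    if lifespan <= 0 or volume <= 0:
        raise ParameterError("device lifespan and annual volume must be positive")
    if maintenance_rate < 0:
        raise ParameterError(f"maintenance_rate must be >= 0, got {maintenance_rate}")
    return price / (lifespan * volume) + maintenance_rate * price / volume


# Calibrated time-cost defaults: the unique (c, F) solving the two printed
# incremental-cost anchors delta_cost(s=0.64) = -663 and delta_cost(s=0) = 516
# (see tree.calibrate_time_cost). Stored at full precision.
CALIBRATED_COST_PER_MINUTE = 1179.0 / 17.28  # 68.22916...
CALIBRATED_FSA_FIXED_SAVING = 10.0 * CALIBRATED_COST_PER_MINUTE - 590.38  # 91.9116...


@dataclass(frozen=True)
class CostParameters:
    """Itemized cost inputs, all in EUR (durations in minutes).

    The per-surgery lump sum is ``drg_cost`` (German DRG reimbursement)
    plus ``lost_productivity`` (14 working days lost per surgery episode,
    folded into a per-surgery euro amount). The one-time IFMI add-on
    combines the fluorescent agent, the amortized camera system, sterile
    draping, additional staff, and the operating-time difference: a
    prolongation for fluorescence inspection minus the avoided frozen
    section analysis (FSA) waiting time scaled by the staff time saving
    factor, priced at ``cost_per_minute`` with a fixed FSA saving
    ``fsa_fixed_saving`` subtracted.
    """

    drg_cost: float = 3508.0
    lost_productivity: float = 521.0
    agent_cost: float = 500.0
    device_price: float = 150_000.0
    maintenance_rate: float = 0.10
    device_lifespan: float = 7.0
    surgeries_per_year: float = 200.0
    draping_cost: float = 23.0
    staff_addon_cost: float = 107.0
    st_duration: float = 59.0
    prolongation: float = 10.0
    fsa_duration: float = 27.0
    staff_time_saving_factor: float = 0.64
    cost_per_minute: float = CALIBRATED_COST_PER_MINUTE
    fsa_fixed_saving: float = CALIBRATED_FSA_FIXED_SAVING
    working_days_lost: float = 14.0  # informational; folded into lost_productivity
    camera_cost_override: float | None = None  # direct per-surgery camera cost

    def __post_init__(self) -> None:
        for name in (
            "drg_cost", "lost_productivity", "agent_cost", "device_price",
            "maintenance_rate", "draping_cost", "staff_addon_cost",
            "cost_per_minute", "fsa_fixed_saving",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("st_duration", "prolongation", "fsa_duration",
                     "device_lifespan", "surgeries_per_year"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        _check_prob("staff_time_saving_factor", self.staff_time_saving_factor)
        if self.camera_cost_override is not None and self.camera_cost_override < 0:
            raise ParameterError(
                f"camera_cost must be >= 0, got {self.camera_cost_override}"
            )

    @property
    def camera_cost(self) -> float:
        """Camera-system cost per surgery, rounded to whole euros (base 182).

        The rounded amortization is the per-case materials price the model
        carries (and the PSA gamma is centred on); internal arithmetic for
        the amortization itself is full precision. An explicit
        ``camera_cost_override`` (used e.g. by the tornado analysis)
        bypasses the amortization.
        """
        if self.camera_cost_override is not None:
            return self.camera_cost_override
        return float(round(device_cost_per_surgery(
            self.device_price, self.maintenance_rate,
            self.device_lifespan, self.surgeries_per_year,
        )))

    @property
    def lump_sum_per_surgery(self) -> float:
        """DRG plus lost productivity; accrued once per surgery (base 4,029)."""
        return self.drg_cost + self.lost_productivity


# ---------------------------------------------------------------------------
# PSA specification table
# ---------------------------------------------------------------------------

# (kind, se | (min, max)) for every uncertain parameter; means come from the
# point estimates so the two stay consistent under overrides.
_PSA_TABLE: dict[str, tuple[str, Any]] = {
    "p_pos_ifmi": ("beta", 0.018),
    "p_pos_st": ("beta", 0.051),
    "p_pos_second": ("beta", 0.018),
    "drg_cost": ("gamma", 175.0),
    "st_duration": ("triangular", (35.0, 83.0)),
    "prolongation": ("triangular", (5.0, 15.0)),
    "fsa_duration": ("triangular", (13.0, 53.0)),
    "staff_time_saving_factor": ("fixed", None),
    "staff_addon_cost": ("gamma", 5.0),
    "agent_cost": ("gamma", 25.0),
    "camera_cost": ("gamma", 18.0),
    "draping_cost": ("gamma", 2.0),
    "lost_productivity": ("gamma", 52.0),
}

#: Parameters varied in the tornado analysis (all Table-style rows above).
TORNADO_PARAMETERS: tuple[str, ...] = tuple(_PSA_TABLE)


def point_estimate(name: str, margins: MarginModel, costs: CostParameters) -> float:
    """Base-case value of a named model parameter."""
    if hasattr(margins, name):
        return getattr(margins, name)
    if hasattr(costs, name):
        return getattr(costs, name)
    raise ParameterError(f"unknown parameter {name!r}")


def default_psa_specs(
    margins: MarginModel, costs: CostParameters
) -> dict[str, DistributionSpec]:
    """Distribution specs for every uncertain parameter, means at the point estimates.

    A point estimate at the edge of a family's support (a proportion of
    exactly 0 or 1, a cost of 0, a duration outside the printed triangular
    bounds — reachable through sweeps and scenario overrides) is known
    exactly there, so its spec degrades to ``fixed``.
    """
    specs: dict[str, DistributionSpec] = {}
    for name, (kind, extra) in _PSA_TABLE.items():
        mean = point_estimate(name, margins, costs)
        degenerate = (
            (kind == "beta" and not 0.0 < mean < 1.0)
            or (kind == "gamma" and mean <= 0.0)
            or (kind == "triangular" and not extra[0] <= mean <= extra[1])
        )
        if kind == "fixed" or degenerate:
            specs[name] = DistributionSpec("fixed", mean)
        elif kind == "triangular":
            lo, hi = extra
            specs[name] = DistributionSpec("triangular", mean, min=lo, max=hi)
        else:
            specs[name] = DistributionSpec(kind, mean, se=extra)
    return specs


@dataclass(frozen=True)
class ParameterSet:
    """Complete model configuration: margins, costs, PSA specs, run settings."""

    margins: MarginModel = field(default_factory=MarginModel)
    costs: CostParameters = field(default_factory=CostParameters)
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    tornado_fraction: float = 0.25
    n_draws: int = 10_000
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.psa_specs:
            object.__setattr__(
                self, "psa_specs", default_psa_specs(self.margins, self.costs)
            )
        if self.tornado_fraction < 0:
            raise ParameterError(f"tornado_fraction must be >= 0, got {self.tornado_fraction}")
        if self.n_draws < 1:
            raise ParameterError(f"n_draws must be >= 1, got {self.n_draws}")
        for name, spec in self.psa_specs.items():
            pe = point_estimate(name, self.margins, self.costs)
            if not math.isclose(spec.mean, pe, rel_tol=0, abs_tol=1e-9):
                raise ParameterError(
                    f"psa spec mean for {name!r} ({spec.mean}) does not match "
                    f"the point estimate ({pe})"
                )

    def with_values(
        self,
        psa_overrides: Mapping[str, DistributionSpec] | None = None,
        **overrides: float,
    ) -> "ParameterSet":
        """Copy with named margin/cost fields replaced.

        PSA specs are regenerated so their means track the new point
        estimates; ``psa_overrides`` then replaces whole specs (for
        scenarios that also change an SE or a triangular support).
        """
        if "camera_cost" in overrides:
            overrides = dict(overrides)
            overrides["camera_cost_override"] = overrides.pop("camera_cost")
        margin_fields = {f.name for f in dataclasses.fields(MarginModel)}
        cost_fields = {f.name for f in dataclasses.fields(CostParameters)}
        margin_kw = {k: v for k, v in overrides.items() if k in margin_fields}
        cost_kw = {k: v for k, v in overrides.items() if k in cost_fields}
        unknown = set(overrides) - set(margin_kw) - set(cost_kw)
        if unknown:
            raise ParameterError(f"unknown parameter(s) {sorted(unknown)}")
        margins = replace(self.margins, **margin_kw)
        costs = replace(self.costs, **cost_kw)
        specs = default_psa_specs(margins, costs)
        if psa_overrides:
            for name, spec in psa_overrides.items():
                if name not in specs:
                    raise ParameterError(f"unknown psa parameter {name!r}")
                specs[name] = spec
        return replace(self, margins=margins, costs=costs, psa_specs=specs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "margins": dataclasses.asdict(self.margins),
            "costs": dataclasses.asdict(self.costs),
            "psa": {name: spec.to_dict() for name, spec in self.psa_specs.items()},
            "run": {
                "n_draws": self.n_draws,
                "seed": self.seed,
                "tornado_fraction": self.tornado_fraction,
            },
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def load_parameters(config_text: str | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a JSON configuration.

    The document may carry top-level sections ``margins``, ``costs``,
    ``psa`` and ``run``; any key left out takes its base-case default, so
    ``load_parameters()`` (or an empty document) is the published base case.
    Unknown or invariant-violating keys raise :class:`ParameterError`
    naming the key.
    """
    doc: dict[str, Any] = {}
    if config_text is not None and config_text.strip():
        try:
            doc = json.loads(config_text)
        except json.JSONDecodeError as exc:
            raise ParameterError(f"configuration does not parse as JSON: {exc}") from exc
        if not isinstance(doc, dict):
            raise ParameterError("configuration root must be a JSON object")
    unknown = set(doc) - {"margins", "costs", "psa", "run"}
    if unknown:
        raise ParameterError(f"unknown configuration section(s) {sorted(unknown)}")

    def _build(cls, section: str):
        data = doc.get(section, {})
        if not isinstance(data, Mapping):
            raise ParameterError(f"section {section!r} must be an object")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ParameterError(f"unknown key(s) in {section!r}: {sorted(bad)}")
        return cls(**data)

    margins = _build(MarginModel, "margins")
    costs = _build(CostParameters, "costs")
    specs = default_psa_specs(margins, costs)
    for name, d in doc.get("psa", {}).items():
        if name not in specs:
            raise ParameterError(f"unknown psa parameter {name!r}")
        specs[name] = DistributionSpec.from_dict(d)
    run = doc.get("run", {})
    bad = set(run) - {"n_draws", "seed", "tornado_fraction"}
    if bad:
        raise ParameterError(f"unknown key(s) in 'run': {sorted(bad)}")
    return ParameterSet(
        margins=margins,
        costs=costs,
        psa_specs=specs,
        tornado_fraction=run.get("tornado_fraction", 0.25),
        n_draws=run.get("n_draws", 10_000),
        seed=run.get("seed", 42),
    )


def load_parameters_from_file(path) -> ParameterSet:
    with open(path, "r", encoding="utf-8") as fh:
        return load_parameters(fh.read())


def default_config_path():
    """Path of the packaged base-case configuration file."""
    return resources.files("ifmiecon").joinpath("data/default_config.json")


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def spawn_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible substream for one analysis.

    A master seed plus a stable label (hashed) keys each analysis's stream,
    so e.g. the PSA and the microsimulation never share draws.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
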