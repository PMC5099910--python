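"""Parameter containers for the five-compartment thymocyte model.

The state variables are the four live thymocyte populations — double
negative (DN), double positive (DP), CD4 single positive (SP4), CD8 single
positive (SP8) — plus a bookkeeping compartment D collecting apoptotic
cells.  All population sizes are expressed in units of 10^7 cells, so a
single cell is ``1e-7`` units.  Time is a single absolute clock in days
post-conception (dpc); birth is at 19.5 dpc and postnatal day ``d``
corresponds to ``19.5 + d`` dpc.

Two model classes are supported: M1, with purely time-decreasing
(exponential) proliferation rates, and M2, which additionally applies a
logistic density factor with carrying capacities ``K_N`` (DN compartment)
and ``K`` (aggregate of DP+SP4+SP8).  Each class comes in two variants:
V1 estimates all prenatal and postnatal parameters independently, while V2
derives the three postnatal proliferation amplitudes (c_N, c_P, c_48) from
the prenatal ones through a fixed amplitude constraint, removing three
free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Optional

__all__ = [
    "ONE_CELL",
    "CELLS_PER_UNIT",
    "Population",
    "ModelClass",
    "Variant",
    "InfluxMode",
    "StageParameters",
    "ModelSpec",
    "apply_continuity_constraint",
    "count_free_parameters",
    "free_parameter_names",
]

#: one cell on the 10^7-cell scale
ONE_CELL = 1e-7
#: number of cells in one model unit
CELLS_PER_UNIT = 1e7

#: default gestation length for the modeled strain, days
DEFAULT_BIRTH_TIME = 19.5
#: default lifespan after birth, days (~2 years)
DEFAULT_LIFESPAN = 730.0


class Population(str, Enum):
    DN = "DN"
    DP = "DP"
    SP4 = "SP4"
    SP8 = "SP8"


class ModelClass(str, Enum):
    M1 = "M1"
    M2 = "M2"


class Variant(str, Enum):
    V1 = "V1"
    V2 = "V2"


class InfluxMode(str, Enum):
    """Progenitor-influx regimes: the prenatal logistic, a constant plateau
    at ``b0`` (normal postnatal thymus), or zero (progenitor ablation)."""

    LOGISTIC = "logistic"
    CONSTANT_B0 = "constant_b0"
    ZERO = "zero"


_RATE_FIELDS = (
    "b_N", "b_P", "b_4", "b_8",
    "c_N", "c_P", "c_48",
    "s_N", "s_4", "s_8", "s_04", "s_08",
    "d_N", "d_P", "d_4", "d_8",
    "delta", "tau_N",
)


@dataclass
class StageParameters:
    """Stage-specific (prenatal or postnatal) rate parameters.

    Units: all rates 1/day, ``tau_N`` in days, amplitudes ``c_*``
    dimensionless, carrying capacities in 10^7 cells (M2 only).
    """

    # proliferation: decay rates and amplitudes (c_48 shared by SP4 & SP8)
    b_N: float = 0.0
    b_P: float = 0.0
    b_4: float = 0.0
    b_8: float = 0.0
    c_N: float = 0.0
    c_P: float = 0.0
    c_48: float = 0.0
    # transfer and export
    s_N: float = 0.0   # DN -> DP
    s_4: float = 0.0   # DP -> SP4
    s_8: float = 0.0   # DP -> SP8
    s_04: float = 0.0  # SP4 export to periphery
    s_08: float = 0.0  # SP8 export to periphery
    # death
    d_N: float = 0.0
    d_P: float = 0.0
    d_4: float = 0.0
    d_8: float = 0.0
    # apoptotic-cell degradation
    delta: float = 0.0
    # DN -> DP differentiation delay, days
    tau_N: float = 0.0
    # carrying capacities (M2 only)
    K_N: Optional[float] = None
    K: Optional[float] = None

    def validate(self, model_class: ModelClass = ModelClass.M1) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        if ModelClass(model_class) is ModelClass.M2:
            if self.K_N is None or self.K is None or self.K_N <= 0 or self.K <= 0:
                raise ValueError("M2 requires positive carrying capacities K_N and K")

    def satisfies_dp_constraint(self) -> bool:
        """Postnatal feasibility constraint s_N > d_P + s_4 + s_8.

        Keeps the DP population from dropping below DN in late life;
        enforced on postnatal parameter sets during calibration.
        """
        return self.s_N > self.d_P + self.s_4 + self.s_8


@dataclass
class ModelSpec:
    """Complete specification of one model instance.

    ``beta`` (the logistic steepness of the progenitor influx) is derived,
    never free: it is solved from ``(b0, tau_b, t0)`` so that the influx at
    thymopoiesis onset ``t0`` equals exactly one progenitor cell.
    """

    model_class: ModelClass = ModelClass.M1
    variant: Variant = Variant.V1
    prenatal: StageParameters = field(default_factory=StageParameters)
    postnatal: StageParameters = field(default_factory=StageParameters)
    t0: float = 10.5                # thymopoiesis onset, dpc
    b0: float = 0.01                # influx plateau, 10^7 cells/day
    tau_b: float = 16.0             # logistic midpoint, dpc
    beta: Optional[float] = None    # logistic steepness, 1/day (derived)
    birth_time: float = DEFAULT_BIRTH_TIME
    horizon: float = DEFAULT_BIRTH_TIME + DEFAULT_LIFESPAN
    # postnatal proliferation form: "absolute" uses c*exp(-b*t) on the
    # absolute clock (the form under which the V2 amplitude constraint is
    # exactly a continuity condition when the decay rate is unchanged);
    # "birth" restarts the prenatal form c*b*exp(-b*(t-birth)) at birth
    postnatal_clock: str = "absolute"
    # delayed DN->DP transfer: "conveyor" removes cells from DN instantly and
    # delivers them to DP after tau_N; "both_delayed" delays both terms
    delay_convention: str = "conveyor"

    def __post_init__(self) -> None:
        self.model_class = ModelClass(self.model_class)
        self.variant = Variant(self.variant)

    def validate(self) -> None:
        if not 0 < self.t0 < self.birth_time:
            raise ValueError(f"t0 must lie in (0, birth_time), got {self.t0}")
        if self.horizon <= self.birth_time:
            raise ValueError("horizon must exceed birth_time")
        if self.postnatal_clock not in ("birth", "absolute"):
            raise ValueError(f"unknown postnatal_clock {self.postnatal_clock!r}")
        if self.delay_convention not in ("conveyor", "both_delayed"):
            raise ValueError(f"unknown delay_convention {self.delay_convention!r}")
        self.prenatal.validate(self.model_class)
        self.postnatal.validate(self.model_class)

    def stage_at(self, t: float) -> StageParameters:
        return self.prenatal if t < self.birth_time else self.postnatal

    def with_constraint_applied(self) -> "ModelSpec":
        """Return a copy whose postnatal amplitudes obey the V2 constraint.

        No-op for V1 specs.
        """
        if self.variant is not Variant.V2:
            return self
        c_N, c_P, c_48 = apply_continuity_constraint(self.prenatal, self.t0)
        post = replace(self.postnatal, c_N=c_N, c_P=c_P, c_48=c_48)
        return replace(self, postnatal=post)

    # -- flat serialization ------------------------------------------------

    def to_flat_dict(self) -> dict:
        """Flatten to plain keys: header fields plus ``pre_``/``post_``
        prefixed stage parameters, e.g. ``pre_b_N``, ``post_c_48``."""
        out = {
            "model_class": self.model_class.value,
            "variant": self.variant.value,
            "units": "1e7 cells, days post-conception",
            "t0": self.t0,
            "b0": self.b0,
            "tau_b": self.tau_b,
            "beta": self.beta,
            "birth_time": self.birth_time,
            "horizon": self.horizon,
            "postnatal_clock": self.postnatal_clock,
            "delay_convention": self.delay_convention,
        }
        for prefix, stage in (("pre", self.prenatal), ("post", self.postnatal)):
            for f in fields(stage):
                value = getattr(stage, f.name)
                if value is not None:
                    out[f"{prefix}_{f.name}"] = value
        return out

    @classmethod
    def from_flat_dict(cls, data: dict) -> "ModelSpec":
        stage_names = {f.name for f in fields(StageParameters)}
        stages = {"pre": {}, "post": {}}
        header: dict = {}
        for key, value in data.items():
            if key == "units":
                continue
            for prefix in ("pre", "post"):
                tag = prefix + "_"
                if key.startswith(tag) and key[len(tag):] in stage_names:
                    stages[prefix][key[len(tag):]] = float(value)
                    break
            else:
                header[key] = value
        spec = cls(
            model_class=ModelClass(header.get("model_class", "M1")),
            variant=Variant(header.get("variant", "V1")),
            prenatal=StageParameters(**stages["pre"]),
            postnatal=StageParameters(**stages["post"]),
            t0=float(header.get("t0", 10.5)),
            b0=float(header.get("b0", 0.01)),
            tau_b=float(header.get("tau_b", 16.0)),
            beta=None if header.get("beta") is None else float(header["beta"]),
            birth_time=float(header.get("birth_time", DEFAULT_BIRTH_TIME)),
            horizon=float(header.get("horizon", DEFAULT_BIRTH_TIME + DEFAULT_LIFESPAN)),
            postnatal_clock=header.get("postnatal_clock", "birth"),
            delay_convention=header.get("delay_convention", "conveyor"),
        )
        return spec


def apply_continuity_constraint(prenatal: StageParameters, t0: float):
    """Postnatal proliferation amplitudes under variant V2.

    Each postnatal amplitude is fixed from the prenatal one as
    ``c_post = b_pre * c_pre * exp(b_pre * t0)``.  The shared SP amplitude
    ``c_48`` is paired with the SP4 decay rate ``b_4`` (a single shared
    amplitude cannot satisfy the formula for both SP decay rates at once).

    Returns ``(c_N, c_P, c_48)``.  Idempotent in the sense that the result
    depends only on the prenatal stage, never on previous postnatal values.
    """
    c_N = prenatal.b_N * prenatal.c_N * math.exp(prenatal.b_N * t0)
    c_P = prenatal.b_P * prenatal.c_P * math.exp(prenatal.b_P * t0)
    c_48 = prenatal.b_4 * prenatal.c_48 * math.exp(prenatal.b_4 * t0)
    return c_N, c_P, c_48


# per-stage estimated parameters: 7 proliferation + 5 transfer/export +
# 4 death + 1 degradation + 1 delay (+2 carrying capacities under M2)
_PER_STAGE_M1 = 18
_PER_STAGE_M2 = 20
_GLOBAL = 3  # t0, b0, tau_b (beta is derived)

_STAGE_FREE_M1 = _RATE_FIELDS
_STAGE_FREE_M2 = _RATE_FIELDS + ("K_N", "K")
_V2_DERIVED = ("c_N", "c_P", "c_48")


def count_free_parameters(model_class, variant) -> int:
    """Number of independently estimated parameters for a model variant.

    M1.V1 has 39: 18 per stage (prenatal and postnatal) plus the three
    global influx/onset parameters.  M2 adds two carrying capacities per
    stage (+4); V2 derives the three postnatal amplitudes (-3).
    """
    model_class = ModelClass(model_class)
    variant = Variant(variant)
    per_stage = _PER_STAGE_M2 if model_class is ModelClass.M2 else _PER_STAGE_M1
    n = 2 * per_stage + _GLOBAL
    if variant is Variant.V2:
        n -= len(_V2_DERIVED)
    return n


def free_parameter_names(model_class, variant) -> list[str]:
    """Canonical flat-key names of the free parameters of a variant.

    Order: global (t0, b0, tau_b), then prenatal, then postnatal stage
    parameters; under V2 the postnatal amplitudes are omitted (derived).
    """
    model_class = ModelClass(model_class)
    variant = Variant(variant)
    stage_fields = _STAGE_FREE_M2 if model_class is ModelClass.M2 else _STAGE_FREE_M1
    names = ["t0", "b0", "tau_b"]
    names += [f"pre_{f}" for f in stage_fields]
    for f in stage_fields:
        if variant is Variant.V2 and f in _V2_DERIVED:
            continue
        names.append(f"post_{f}")
    assert len(names) == count_free_parameters(model_class, variant)
    return names
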