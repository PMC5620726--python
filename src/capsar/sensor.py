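"""Interdigitated capacitive biosensor model.

The sensing element is a multi-segment interdigitated-electrode capacitor whose
segments are wired in series to keep the baseline capacitance in the femtofarad
range over a large exposure area.  Surface functionalization proceeds through
fixed stages (bare electrode, glutaraldehyde crosslinker, immobilized antibody,
BSA blocking, bound antigen); each stage adds a configured capacitance shift.
The antigen response is summarized by the *ratio of increase*
``(C_antigen - C_antibody) / C_antibody``, which decreases with analyte
concentration.  Calibration anchors the ratio at two concentrations and
interpolates log-linearly in concentration between them (a saturating
Langmuir-style alternative is available); the interpolant is exactly
invertible, which is what concentration estimation relies on.

Units: capacitances in femtofarads (fF), concentrations in mg/L throughout.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InvalidInputError, StageTransitionError

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "SensorConfig",
    "SensorState",
    "series_capacitance",
    "apply_stage",
    "response_ratio",
    "antigen_capacitance",
    "concentration_from_ratio",
]


class Stage(enum.Enum):
    """Functionalization stages, in the only legal order."""

    BARE = "bare"
    CROSSLINKED = "crosslinked"
    ANTIBODY = "antibody"
    BLOCKED = "blocked"
    ANTIGEN = "antigen"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {
    Stage.BARE: 0,
    Stage.CROSSLINKED: 1,
    Stage.ANTIBODY: 2,
    Stage.BLOCKED: 3,
    Stage.ANTIGEN: 4,
}

#: Stage shifts that are zero by construction, so skipping them is harmless.
_SKIPPABLE = {Stage.CROSSLINKED, Stage.BLOCKED}


class SensorConfig(BaseModel):
    """Calibration of one sensor.

    ``anchors`` are two (concentration mg/L, ratio) calibration points; the
    ratio of increase must decrease with concentration.  The JSON form of this
    model (``model_dump``) is the on-disk config format.
    """

    model_config = ConfigDict(frozen=True)

    baseline_capacitance_fF: float = 26.0
    n_segments: int = 9
    antibody_shift_fF: float = 300.0
    bsa_shift_fF: float = 0.0
    anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (1.25, 35.0),
        (10.0, 6.0),
    )
    response_model: str = "loglinear"  # or "langmuir"
    ratio_floor: float = 0.01

    @model_validator(mode="after")
    def _check(self) -> "SensorConfig":
        if self.baseline_capacitance_fF <= 0:
            raise ValueError("baseline_capacitance_fF must be > 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.antibody_shift_fF <= 0:
            raise ValueError("antibody_shift_fF must be > 0")
        if self.bsa_shift_fF < 0:
            raise ValueError("bsa_shift_fF must be >= 0")
        (c_lo, r_lo), (c_hi, r_hi) = self.anchors
        if not (0 < c_lo < c_hi):
            raise ValueError("anchor concentrations must satisfy 0 < low < high")
        if not (r_lo > r_hi > 0):
            raise ValueError("ratio must decrease with concentration (r_low > r_high > 0)")
        if self.response_model not in ("loglinear", "langmuir"):
            raise ValueError("response_model must be 'loglinear' or 'langmuir'")
        if self.ratio_floor <= 0:
            raise ValueError("ratio_floor must be > 0")
        return self

    @property
    def anchor_low(self) -> tuple[float, float]:
        return self.anchors[0]

    @property
    def anchor_high(self) -> tuple[float, float]:
        return self.anchors[1]


@dataclass(frozen=True)
class SensorState:
    """Sensor at one functionalization stage.

    ``concentration_mgL`` is set only at the antigen stage.
    """

    stage: Stage
    capacitance_fF: float
    concentration_mgL: float | None = None

    def __post_init__(self) -> None:
        if self.capacitance_fF <= 0:
            raise InvalidInputError("sensor capacitance must be > 0")
        if (self.concentration_mgL is not None) != (self.stage is Stage.ANTIGEN):
            raise InvalidInputError(
                "concentration is present exactly when stage is 'antigen'"
            )


def series_capacitance(segments: Sequence[float]) -> float:
    """Equivalent capacitance of capacitors in series: ``1 / sum(1/C_i)``.

    Consistency utility for the segmented electrode: n equal segments of C
    give C/n, which is how a large-area sensor reaches a small baseline.
    """
    if len(segments) == 0:
        raise InvalidInputError("segments must be a non-empty list")
    for c in segments:
        if c <= 0:
            raise InvalidInputError(f"segment capacitance must be > 0, got {c}")
    return 1.0 / math.fsum(1.0 / c for c in segments)


def apply_stage(
    state: SensorState,
    config: SensorConfig,
    stage: Stage,
    concentration_mgL: float | None = None,
) -> SensorState:
    """Advance the sensor to the next functionalization stage.

    Only forward moves are allowed; zero-shift stages (crosslinker, BSA block)
    may be skipped.  Shifts accumulate on the current capacitance:
    crosslinking adds nothing, antibody immobilization adds
    ``antibody_shift_fF``, BSA blocking adds ``bsa_shift_fF`` (0 by default —
    the blocking step leaves capacitance unchanged, which is what makes the
    antibody layer specific), and the antigen stage multiplies via the
    concentration response.
    """
    cur, new = state.stage, stage
    if new.order <= cur.order:
        raise StageTransitionError(f"cannot move from {cur.value!r} to {new.value!r}")
    skipped = [s for s in _STAGE_ORDER if cur.order < s.order < new.order]
    if any(s not in _SKIPPABLE for s in skipped):
        raise StageTransitionError(
            f"transition {cur.value!r} -> {new.value!r} skips stage "
            f"{[s.value for s in skipped if s not in _SKIPPABLE][0]!r}"
        )

    c = state.capacitance_fF
    if Stage.ANTIBODY.order > cur.order and new.order >= Stage.ANTIBODY.order:
        c += config.antibody_shift_fF
    if Stage.BLOCKED.order > cur.order and new.order >= Stage.BLOCKED.order:
        c += config.bsa_shift_fF

    if new is Stage.ANTIGEN:
        if concentration_mgL is None:
            raise InvalidInputError("antigen stage requires a concentration")
        c = antigen_capacitance(c, concentration_mgL, config)
        return SensorState(new, c, concentration_mgL)
    if concentration_mgL is not None:
        raise InvalidInputError("concentration only applies to the antigen stage")
    return SensorState(new, c)


def _langmuir_params(config: SensorConfig) -> tuple[float, float]:
    # r(c) = r_max / (1 + c/K), solved through the two anchors.
    (c_lo, r_lo), (c_hi, r_hi) = config.anchors
    k = (r_hi * c_hi - r_lo * c_lo) / (r_lo - r_hi)
    if k <= 0:
        raise InvalidInputError(
            "anchors are incompatible with a saturating (Langmuir) response"
        )
    r_max = r_lo * (1.0 + c_lo / k)
    return r_max, k


def response_ratio(concentration_mgL: float, config: SensorConfig) -> float:
    """Ratio of capacitance increase at a given antigen concentration.

    Default model: log-linear interpolation through the two anchors,
    ``r(c) = r_low + (r_high - r_low) * ln(c/c_low) / ln(c_high/c_low)``.
    Strictly decreasing in concentration.  Outside the anchor interval the
    interpolant extrapolates (logged) and is clamped at ``ratio_floor`` so the
    implied capacitance stays positive.
    """
    if concentration_mgL <= 0:
        raise InvalidInputError("concentration must be > 0")
    (c_lo, r_lo), (c_hi, r_hi) = config.anchors
    if not (c_lo <= concentration_mgL <= c_hi):
        logger.warning(
            "concentration %.4g mg/L is outside the calibrated range [%g, %g]; "
            "extrapolating",
            concentration_mgL,
            c_lo,
            c_hi,
        )
    if config.response_model == "langmuir":
        r_max, k = _langmuir_params(config)
        r = r_max / (1.0 + concentration_mgL / k)
    else:
        frac = math.log(concentration_mgL / c_lo) / math.log(c_hi / c_lo)
        r = r_lo + (r_hi - r_lo) * frac
    if r < config.ratio_floor:
        logger.warning(
            "response ratio %.4g clamped at floor %g", r, config.ratio_floor
        )
        r = config.ratio_floor
    return r


def antigen_capacitance(
    c_antibody_fF: float, concentration_mgL: float, config: SensorConfig
) -> float:
    """Antigen-stage capacitance implied by the calibrated ratio of increase.

    ``C_antigen = C_antibody * (1 + r(c))``; strictly decreasing in
    concentration over the calibrated range.
    """
    if c_antibody_fF <= 0:
        raise InvalidInputError("antibody-stage capacitance must be > 0")
    return c_antibody_fF * (1.0 + response_ratio(concentration_mgL, config))


def concentration_from_ratio(ratio: float, config: SensorConfig) -> float:
    """Exact analytic inverse of :func:`response_ratio` (un-clamped branch)."""
    if ratio <= 0:
        raise InvalidInputError("ratio must be > 0")
    (c_lo, r_lo), (c_hi, r_hi) = config.anchors
    if config.response_model == "langmuir":
        r_max, k = _langmuir_params(config)
        if ratio >= r_max:
            raise InvalidInputError(f"ratio {ratio} is at or above the saturation value")
        return k * (r_max / ratio - 1.0)
    frac = (ratio - r_lo) / (r_hi - r_lo)
    return c_lo * math.exp(frac * math.log(c_hi / c_lo))
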