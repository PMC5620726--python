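"""Charge-redistribution SAR capacitance-to-digital conversion engine.

Model, in the order the hardware runs it.  During sampling the amplifier is in
unity gain and the whole capacitor network (sensor C_SENS, reference bank
C_REF, parasitic C_P) charges to the amplifier switching threshold.  During
conversion the bank bottom plates switch between V_REF and GND under SAR
control; charge conservation makes the amplifier output move by

    dV_O = (C_SENS - C_REF,ON) * V_REF * A / C_T,    C_T = C_SENS + C_REF + C_P

where A is the open-loop inverter gain.  The comparator sees
``V_IN = dV_O + V_OS`` (V_OS = switching-threshold mismatch between amplifier
and comparator) plus an optional Gaussian noise draw, and emits 1 when the
sensor still exceeds the trial reference.  Because the decision depends only
on the *sign* of (C_SENS - C_REF,ON), the output code is insensitive to V_REF
and C_P; what those do control is the voltage swing per LSB and hence how much
offset and noise the decision can tolerate.  The offset-limited floor on the
resolvable capacitance step is

    C_min = V_OS * C_T / (A * V_REF)

which with the implemented gain (98), offset (3.3 mV) and full-scale loading
sits near 1.2 fF — comfortably under the 4.5 fF design LSB, so the converter
stays quantization-limited.

Search schedule: 4 coarse trials MSB-first with the fine word at 0, then 8
fine trials refining the residual.  The fine full scale exceeds one coarse
unit, so the residual left by the coarse phase is always reachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .dac import DacCode, DacRealization
from .errors import InvalidInputError, InvalidStateError

__all__ = [
    "AnalogParams",
    "BitDecision",
    "ConversionResult",
    "RepeatSummary",
    "delta_vo",
    "comparator_decision",
    "sar_convert",
    "resolution_bound",
    "repeat_convert",
]


class AnalogParams(BaseModel):
    """Amplifier/comparator nonidealities.

    Defaults are the implemented circuit's printed values (gain 98, offset
    3.3 mV, 0.9 V analog supply as the reference).  ``ideal()`` gives the
    zero-offset, zero-noise converter used for quantization-only analysis.
    ``v_m1_V`` (amplifier switching threshold) is informational: every voltage
    here is a deviation from it, and it enters the model only through
    V_OS = V_M1 - V_M2.
    """

    model_config = ConfigDict(frozen=True)

    v_ref_V: float = 0.9
    gain_a: float = 98.0
    v_os_V: float = 3.3e-3
    c_p_fF: float = 500.0
    v_m1_V: float = 0.45
    comparator_noise_sigma_V: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AnalogParams":
        if self.v_ref_V <= 0:
            raise ValueError("v_ref_V must be > 0")
        if self.gain_a <= 0:
            raise ValueError("gain_a must be > 0")
        if self.c_p_fF < 0:
            raise ValueError("c_p_fF must be >= 0")
        if self.comparator_noise_sigma_V < 0:
            raise ValueError("comparator_noise_sigma_V must be >= 0")
        return self

    @classmethod
    def ideal(cls, **overrides) -> "AnalogParams":
        """Offset-free, noise-free parameters (quantization-limited converter)."""
        return cls(**{"v_os_V": 0.0, "comparator_noise_sigma_V": 0.0, **overrides})


@dataclass(frozen=True)
class BitDecision:
    phase: str  # "coarse" | "fine"
    trial_weight: int
    delta_vo_V: float
    bit: int


@dataclass(frozen=True)
class ConversionResult:
    code: DacCode
    c_hat_fF: float  # reconstruction on the nominal grid
    bit_trace: tuple[BitDecision, ...]
    saturated: bool

    @property
    def n_decisions(self) -> int:
        return len(self.bit_trace)


def delta_vo(
    c_sens_fF: float, c_ref_on_fF: float, real: DacRealization, params: AnalogParams
) -> float:
    """Amplifier output excursion during the conversion phase, in volts."""
    if c_sens_fF < 0:
        raise InvalidInputError("c_sens must be >= 0")
    c_t = c_sens_fF + real.total_fF + params.c_p_fF
    if c_t <= 0:
        raise InvalidStateError("total capacitance C_T must be > 0")
    return (c_sens_fF - c_ref_on_fF) * params.v_ref_V * params.gain_a / c_t


def comparator_decision(
    c_sens_fF: float,
    c_ref_on_fF: float,
    real: DacRealization,
    params: AnalogParams,
    rng: np.random.Generator | None = None,
) -> int:
    """One comparator strobe: 1 if the (offset- and noise-shifted) amplifier
    excursion is non-negative, else 0.

    The exact balance point (v_in == 0) resolves to 1: the sensor is then
    exactly representable by the trial code and the bit must be kept for the
    reconstruction to be the largest code not exceeding the input.
    """
    v_in = delta_vo(c_sens_fF, c_ref_on_fF, real, params) + params.v_os_V
    if params.comparator_noise_sigma_V > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        v_in += rng.normal(0.0, params.comparator_noise_sigma_V)
    return 1 if v_in >= 0 else 0


def sar_convert(
    c_sens_fF: float,
    real: DacRealization,
    params: AnalogParams,
    rng: np.random.Generator | None = None,
) -> ConversionResult:
    """Full segmented successive-approximation conversion.

    Coarse bits are resolved MSB-first with fine = 0, then fine bits refine
    the residual.  With ideal parameters the result equals the exhaustive
    search for the largest nominal reconstruction not exceeding the input, so
    the error lies in [0, 1 fine LSB).  Inputs at or above full scale clamp to
    the maximum code and set the saturation flag.
    """
    if c_sens_fF < 0:
        raise InvalidInputError("c_sens must be >= 0")
    cfg = real.config
    if params.comparator_noise_sigma_V > 0 and rng is None:
        rng = np.random.default_rng(params.seed)

    trace: list[BitDecision] = []
    coarse = 0
    for j in reversed(range(cfg.coarse_bits)):
        trial = coarse | (1 << j)
        c_on = real.c_ref_on(DacCode(trial, 0))
        dv = delta_vo(c_sens_fF, c_on, real, params)
        bit = comparator_decision(c_sens_fF, c_on, real, params, rng)
        if bit:
            coarse = trial
        trace.append(BitDecision("coarse", 1 << j, dv, bit))

    fine = 0
    for j in reversed(range(cfg.fine_bits)):
        trial = fine | (1 << j)
        c_on = real.c_ref_on(DacCode(coarse, trial))
        dv = delta_vo(c_sens_fF, c_on, real, params)
        bit = comparator_decision(c_sens_fF, c_on, real, params, rng)
        if bit:
            fine = trial
        trace.append(BitDecision("fine", 1 << j, dv, bit))

    code = DacCode(coarse, fine)
    return ConversionResult(
        code=code,
        c_hat_fF=real.nominal_capacitance(code),
        bit_trace=tuple(trace),
        saturated=c_sens_fF >= cfg.nominal_full_scale_fF,
    )


def resolution_bound(
    c_sens_fF: float, real: DacRealization, params: AnalogParams
) -> float:
    """Offset-limited minimum resolvable capacitance step, in fF.

    ``V_OS * C_T / (A * V_REF)``: the capacitance imbalance whose amplified
    excursion just cancels the comparator offset.  Monotone increasing in
    c_sens through C_T; zero offset means no floor.
    """
    if c_sens_fF < 0:
        raise InvalidInputError("c_sens must be >= 0")
    c_t = c_sens_fF + real.total_fF + params.c_p_fF
    if c_t <= 0:
        raise InvalidStateError("total capacitance C_T must be > 0")
    return params.v_os_V * c_t / (params.gain_a * params.v_ref_V)


@dataclass(frozen=True)
class RepeatSummary:
    results: tuple[ConversionResult, ...]
    mean_c_hat_fF: float
    std_c_hat_fF: float


def repeat_convert(
    c_sens_fF: float,
    real: DacRealization,
    params: AnalogParams,
    n_reps: int,
    seed: int | None = None,
) -> RepeatSummary:
    """Repeated conversions at a fixed input with fresh noise draws per rep.

    With zero comparator noise every rep is identical (std exactly 0).  The
    master ``seed`` (falling back to ``params.seed``) makes the whole rep
    sequence reproducible.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    results = tuple(sar_convert(c_sens_fF, real, params, rng) for _ in range(n_reps))
    c_hats = np.array([r.c_hat_fF for r in results])
    return RepeatSummary(
        results=results,
        mean_c_hat_fF=float(c_hats.mean()),
        std_c_hat_fF=float(c_hats.std()),
    )
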