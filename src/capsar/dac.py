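"""Segmented coarse/fine binary-weighted capacitive DAC.

The reference bank is split into a coarse segment (4 bits of 1 pF MIM unit
capacitors by default) and a fine segment (8 bits of 4.5 fF fringe-capacitor
units).  The segments are deliberately non-radix-2 relative to each other: one
coarse unit (1000 fF) is about 222.2 fine LSBs, and the fine full scale
(255 x 4.5 = 1147.5 fF) must cover one coarse unit so the search never strands
a residual.  A code is therefore always the (coarse, fine) pair with its
reconstructed capacitance ``coarse*1000 + fine*4.5`` fF, never a flat 12-bit
binary number.

Mismatch is modelled per physical unit: each of the 2^b - 1 units in a segment
is drawn as ``nominal * (1 + N(0, sigma_rel))``, and the weight-w bit owns w
specific units (contiguous assignment by index), so a bit contributes the same
realized capacitance in every code that sets it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InvalidInputError, RealizationError

__all__ = [
    "DacConfig",
    "DacCode",
    "DacRealization",
    "realize",
    "code_to_capacitance",
    "dnl_inl",
    "LinearityReport",
]


class DacConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    coarse_bits: int = 4
    fine_bits: int = 8
    coarse_unit_fF: float = 1000.0
    fine_unit_fF: float = 4.5
    mismatch_sigma_rel: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "DacConfig":
        if self.coarse_bits < 1 or self.fine_bits < 1:
            raise ValueError("coarse_bits and fine_bits must be >= 1")
        if self.coarse_unit_fF <= 0 or self.fine_unit_fF <= 0:
            raise ValueError("unit capacitances must be > 0")
        if self.mismatch_sigma_rel < 0:
            raise ValueError("mismatch_sigma_rel must be >= 0")
        # Segmentation coverage: the fine segment must be able to span one
        # coarse unit, otherwise some residuals are unreachable.
        fine_fs = (2**self.fine_bits - 1) * self.fine_unit_fF
        if fine_fs < self.coarse_unit_fF:
            raise ValueError(
                f"fine full scale {fine_fs} fF does not cover the coarse unit "
                f"{self.coarse_unit_fF} fF"
            )
        return self

    @property
    def max_coarse(self) -> int:
        return 2**self.coarse_bits - 1

    @property
    def max_fine(self) -> int:
        return 2**self.fine_bits - 1

    @property
    def nominal_full_scale_fF(self) -> float:
        return self.max_coarse * self.coarse_unit_fF + self.max_fine * self.fine_unit_fF


@dataclass(frozen=True)
class DacCode:
    """SAR output word: (coarse, fine) pair."""

    coarse: int
    fine: int


def _bit_group_sums(units: np.ndarray, bits: int) -> np.ndarray:
    """Realized capacitance owned by each bit: weight-2^j bit owns units
    [2^j - 1, 2^(j+1) - 1)."""
    sums = np.empty(bits)
    for j in range(bits):
        lo = 2**j - 1
        hi = 2 ** (j + 1) - 1
        sums[j] = units[lo:hi].sum()
    return sums


@dataclass(frozen=True)
class DacRealization:
    """One Monte-Carlo draw of the capacitor bank (sigma=0 gives the nominal bank)."""

    config: DacConfig
    coarse_units: np.ndarray  # 2^coarse_bits - 1 values, fF
    fine_units: np.ndarray  # 2^fine_bits - 1 values, fF
    coarse_bit_caps: np.ndarray = field(init=False)
    fine_bit_caps: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        if len(self.coarse_units) != cfg.max_coarse or len(self.fine_units) != cfg.max_fine:
            raise InvalidInputError("unit counts must be exactly 2^bits - 1 per segment")
        if np.any(self.coarse_units <= 0) or np.any(self.fine_units <= 0):
            raise InvalidInputError("all unit capacitances must be > 0")
        object.__setattr__(
            self, "coarse_bit_caps", _bit_group_sums(self.coarse_units, cfg.coarse_bits)
        )
        object.__setattr__(
            self, "fine_bit_caps", _bit_group_sums(self.fine_units, cfg.fine_bits)
        )

    @property
    def total_fF(self) -> float:
        """C_REF: total bank capacitance (all units, on or off)."""
        return float(self.coarse_units.sum() + self.fine_units.sum())

    def c_ref_on(self, code: DacCode) -> float:
        """Realized capacitance switched to V_REF for a code."""
        return code_to_capacitance(code, self)

    def c_ref_off(self, code: DacCode) -> float:
        """Realized capacitance left at GND for a code: total - C_REF,ON."""
        return self.total_fF - self.c_ref_on(code)

    def nominal_capacitance(self, code: DacCode) -> float:
        """Reconstruction on the nominal grid — what the digital code *means*."""
        _check_code(code, self.config)
        return code.coarse * self.config.coarse_unit_fF + code.fine * self.config.fine_unit_fF


def _check_code(code: DacCode, cfg: DacConfig) -> None:
    if not (0 <= code.coarse <= cfg.max_coarse):
        raise InvalidInputError(
            f"coarse value {code.coarse} out of range [0, {cfg.max_coarse}]"
        )
    if not (0 <= code.fine <= cfg.max_fine):
        raise InvalidInputError(f"fine value {code.fine} out of range [0, {cfg.max_fine}]")


def realize(config: DacConfig) -> DacRealization:
    """Draw a capacitor bank; seeded and reproducible, sigma=0 yields nominal."""
    if config.mismatch_sigma_rel == 0:
        coarse = np.full(config.max_coarse, config.coarse_unit_fF)
        fine = np.full(config.max_fine, config.fine_unit_fF)
    else:
        rng = np.random.default_rng(config.seed)
        coarse = config.coarse_unit_fF * (
            1.0 + rng.normal(0.0, config.mismatch_sigma_rel, config.max_coarse)
        )
        fine = config.fine_unit_fF * (
            1.0 + rng.normal(0.0, config.mismatch_sigma_rel, config.max_fine)
        )
        if np.any(coarse <= 0) or np.any(fine <= 0):
            raise RealizationError(
                "a drawn unit capacitance is <= 0; mismatch_sigma_rel is too large"
            )
    return DacRealization(config, coarse, fine)


def code_to_capacitance(code: DacCode, real: DacRealization) -> float:
    """Realized C_REF,ON selected by the binary weights of (coarse, fine)."""
    cfg = real.config
    _check_code(code, cfg)
    total = 0.0
    for j in range(cfg.coarse_bits):
        if code.coarse >> j & 1:
            total += real.coarse_bit_caps[j]
    for j in range(cfg.fine_bits):
        if code.fine >> j & 1:
            total += real.fine_bit_caps[j]
    return float(total)


@dataclass(frozen=True)
class LinearityReport:
    """Per-step DNL and cumulative INL, both in fine-LSB units."""

    table: pd.DataFrame  # columns: step_index, segment, dnl_lsb, inl_lsb
    max_abs_dnl_coarse: float
    max_abs_dnl_fine: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def dnl_inl(real: DacRealization) -> LinearityReport:
    """Linearity of the realized bank against its nominal step sizes.

    The fine segment is stepped 0..2^fb-1 at coarse=0 and the coarse segment
    0..2^cb-1 at fine=0 (the monotone reconstruction grid).  DNL of a step is
    its deviation from the nominal step, in fine-LSB units; the design rule is
    that coarse-segment |DNL| stays below 1/2 fine LSB so coarse and fine
    ranges splice without missing codes.  A nominal bank has DNL = INL = 0.
    """
    cfg = real.config
    lsb = cfg.fine_unit_fF

    rows = []
    for seg, n_codes, nominal_step, make in (
        ("fine", cfg.max_fine + 1, cfg.fine_unit_fF, lambda k: DacCode(0, k)),
        ("coarse", cfg.max_coarse + 1, cfg.coarse_unit_fF, lambda k: DacCode(k, 0)),
    ):
        caps = np.array([code_to_capacitance(make(k), real) for k in range(n_codes)])
        steps = np.diff(caps)
        dnl = (steps - nominal_step) / lsb
        inl = np.cumsum(dnl)
        for i, (d, v) in enumerate(zip(dnl, inl), start=1):
            rows.append({"step_index": i, "segment": seg, "dnl_lsb": d, "inl_lsb": v})

    table = pd.DataFrame(rows, columns=["step_index", "segment", "dnl_lsb", "inl_lsb"])
    by_seg = table.groupby("segment")["dnl_lsb"].apply(lambda s: float(np.abs(s).max()))
    return LinearityReport(
        table=table,
        max_abs_dnl_coarse=by_seg["coarse"],
        max_abs_dnl_fine=by_seg["fine"],
    )
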