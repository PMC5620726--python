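"""Converter characterization: transfer sweeps, quantization statistics,
repeatability noise profiles, and end-to-end linearity.

The simulated equivalents of the bench characterization one would run on the
fabricated readout: sweep a dummy capacitor through the range and record the
code (transfer function), measure the rms conversion error (for an ideal
truncating quantizer swept uniformly this approaches LSB/sqrt(12) about its
mean of -LSB/2), and measure the spread of repeated conversions at fixed
inputs (noise profile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cdc import AnalogParams, repeat_convert, sar_convert
from .dac import DacRealization
from .errors import InvalidInputError

__all__ = [
    "TransferFunction",
    "NoiseProfile",
    "sweep_transfer",
    "quantization_rms",
    "noise_profile",
    "transfer_dnl",
]


@dataclass(frozen=True)
class TransferFunction:
    """Sweep result; ``table`` columns: c_true_fF, c_hat_fF, coarse, fine."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.table["c_true_fF"].to_numpy()
        if len(c) and not np.all(np.diff(c) > 0):
            raise InvalidInputError("c_true must be strictly increasing")

    def errors_fF(self) -> np.ndarray:
        """Signed conversion error c_hat - c_true (truncation makes it <= 0)."""
        return (self.table["c_hat_fF"] - self.table["c_true_fF"]).to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class NoiseProfile:
    """Repeatability result; ``table`` columns: c_true_fF, std_fF, n_reps."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_transfer(
    real: DacRealization,
    params: AnalogParams,
    c_min_fF: float,
    c_max_fF: float,
    step_fF: float,
) -> TransferFunction:
    """One conversion per point on the grid c_min, c_min+step, ..., <= c_max.

    With ideal parameters the reconstruction is non-decreasing and every
    error is below one fine LSB.
    """
    if not c_min_fF < c_max_fF:
        raise InvalidInputError("c_min must be < c_max")
    if step_fF <= 0:
        raise InvalidInputError("step must be > 0")
    n = int(math.floor((c_max_fF - c_min_fF) / step_fF + 1e-9)) + 1
    rows = []
    for k in range(n):
        c_true = c_min_fF + k * step_fF
        res = sar_convert(c_true, real, params)
        rows.append(
            {
                "c_true_fF": c_true,
                "c_hat_fF": res.c_hat_fF,
                "coarse": res.code.coarse,
                "fine": res.code.fine,
            }
        )
    return TransferFunction(pd.DataFrame(rows))


def quantization_rms(tf: TransferFunction, about_mean: bool = True) -> float:
    """Root-mean-square conversion error over a sweep, in fF.

    ``about_mean=True`` (default) removes the systematic -LSB/2 truncation
    bias first — the quantization-noise figure, which for a dense uniform
    sweep approaches LSB/sqrt(12); ``about_mean=False`` is the raw rms
    including the bias.
    """
    e = tf.errors_fF()
    if len(e) == 0:
        raise InvalidInputError("transfer function is empty")
    if about_mean:
        return float(np.std(e))
    return float(np.sqrt(np.mean(e**2)))


def noise_profile(
    real: DacRealization,
    params: AnalogParams,
    points_fF: Sequence[float],
    n_reps: int = 100,
    seed: int | None = None,
) -> NoiseProfile:
    """Std of the reconstructed capacitance across repeated conversions,
    per input point.  Sub-LSB comparator noise keeps every std below one LSB."""
    if n_reps < 2:
        raise InvalidInputError("n_reps must be >= 2")
    if len(points_fF) == 0:
        raise InvalidInputError("points must be non-empty")
    base = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for c in points_fF:
        rep_seed = int(base.integers(0, 2**31))
        summary = repeat_convert(c, real, params, n_reps, seed=rep_seed)
        rows.append({"c_true_fF": c, "std_fF": summary.std_c_hat_fF, "n_reps": n_reps})
    return NoiseProfile(pd.DataFrame(rows))


def transfer_dnl(tf: TransferFunction, lsb_fF: float = 4.5) -> np.ndarray:
    """End-to-end DNL from code-transition positions in a fine sweep.

    Returns (width/LSB - 1) per observed code step; resolution is limited by
    the sweep step, so an ideal converter gives |DNL| < step/LSB.
    """
    c_true = tf.table["c_true_fF"].to_numpy()
    c_hat = tf.table["c_hat_fF"].to_numpy()
    if len(c_true) < 2:
        raise InvalidInputError("sweep too short for DNL extraction")
    trans = np.flatnonzero(np.diff(c_hat) > 0)
    if len(trans) < 2:
        raise InvalidInputError("fewer than two code transitions in the sweep")
    positions = c_true[trans + 1]
    widths = np.diff(positions)
    return widths / lsb_fF - 1.0
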