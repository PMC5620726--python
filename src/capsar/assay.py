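"""End-to-end in silico immunoassay.

Chains the pieces the way the platform runs: a concentration sets the
antigen-stage sensor capacitance through the calibrated response model, the
converter digitizes both the antibody-stage reference and the antigen-stage
capacitance, and the ratio of increase

    r_hat = (C_antigen_hat - C_antibody_hat) / C_antibody_hat

is inverted through the calibration to estimate the concentration.  Both
capacitances in the ratio are *digitized* values — the platform never sees
the true analog capacitance — so quantization error propagates into the
estimate (about 1 LSB on a ~324 fF denominator, i.e. roughly 1.4% on the
ratio, amplified through the log-linear inverse to a few percent on
concentration).  Replicate-to-replicate spread between biological samples is
emulated as Gaussian noise on the true antigen capacitance before
digitization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cdc import AnalogParams, sar_convert
from .dac import DacRealization
from .errors import InvalidInputError
from .sensor import (
    SensorConfig,
    SensorState,
    Stage,
    antigen_capacitance,
    apply_stage,
    concentration_from_ratio,
)

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "AssayResult",
    "ratio_of_increase",
    "estimate_concentration",
    "run_assay",
]


def ratio_of_increase(c_antigen_hat_fF: float, c_antibody_hat_fF: float) -> float:
    """(C_antigen - C_antibody) / C_antibody — the concentration-reporting statistic."""
    if c_antibody_hat_fF <= 0:
        raise InvalidInputError("antibody-stage capacitance must be > 0")
    return (c_antigen_hat_fF - c_antibody_hat_fF) / c_antibody_hat_fF


def estimate_concentration(
    ratio: float, config: SensorConfig, guard_rel: float = 0.5
) -> float:
    """Invert the calibrated response to a concentration in mg/L.

    Exact analytic inverse of the response model.  Ratios outside the anchor
    band widened by ``guard_rel`` (relative) are still inverted but flagged as
    extrapolation in the log.
    """
    if ratio <= 0:
        raise InvalidInputError("ratio must be > 0")
    (_, r_lo), (_, r_hi) = config.anchors
    if not (r_hi * (1 - guard_rel) <= ratio <= r_lo * (1 + guard_rel)):
        logger.warning(
            "ratio %.4g is outside the calibrated band [%g, %g] (guard %g); "
            "extrapolating",
            ratio,
            r_hi,
            r_lo,
            guard_rel,
        )
    return concentration_from_ratio(ratio, config)


@dataclass(frozen=True)
class AssayResult:
    """Per-sample table and per-concentration summary of one assay run.

    ``samples`` columns: concentration_mgL, replicate, c_true_fF, coarse,
    fine, c_hat_fF, ratio, conc_est_mgL.
    ``summary`` columns: concentration_mgL, mean_c_hat_fF, std_c_hat_fF,
    mean_ratio, mean_conc_est_mgL.
    ``c_antibody_hat_fF`` is the digitized antibody-stage reference shared by
    every ratio.
    """

    samples: pd.DataFrame
    summary: pd.DataFrame
    c_antibody_hat_fF: float

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "c_antibody_hat_fF": self.c_antibody_hat_fF,
            "per_concentration": self.summary.to_dict(orient="records"),
        }


def run_assay(
    concentrations_mgL: Sequence[float],
    n_reps: int,
    sensor: SensorConfig,
    real: DacRealization,
    params: AnalogParams,
    replicate_noise_sigma_fF: float = 0.0,
    seed: int | None = None,
) -> AssayResult:
    """Simulate the full assay over a concentration panel.

    For each concentration and replicate: draw the true antigen-stage
    capacitance (response model plus replicate noise), digitize it, form the
    ratio against the digitized antibody-stage reference, and invert to an
    estimated concentration.  Fully reproducible from ``seed``.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    if len(concentrations_mgL) == 0:
        raise InvalidInputError("concentration panel must be non-empty")
    if replicate_noise_sigma_fF < 0:
        raise InvalidInputError("replicate_noise_sigma_fF must be >= 0")

    rng = np.random.default_rng(seed)

    # Antibody-stage reference, digitized by the same converter the antigen
    # measurement uses: the platform compares two codes, not two capacitances.
    antibody_state = apply_stage(
        SensorState(Stage.BARE, sensor.baseline_capacitance_fF), sensor, Stage.ANTIBODY
    )
    antibody_state = apply_stage(antibody_state, sensor, Stage.BLOCKED)
    ab_res = sar_convert(antibody_state.capacitance_fF, real, params, rng)
    c_ab_hat = ab_res.c_hat_fF

    rows = []
    for conc in concentrations_mgL:
        c_antigen_true = antigen_capacitance(antibody_state.capacitance_fF, conc, sensor)
        for rep in range(1, n_reps + 1):
            c_true = c_antigen_true
            if replicate_noise_sigma_fF > 0:
                c_true += rng.normal(0.0, replicate_noise_sigma_fF)
            if c_true <= 0:
                raise InvalidInputError(
                    "replicate noise drove the true capacitance non-positive"
                )
            res = sar_convert(c_true, real, params, rng)
            ratio = ratio_of_increase(res.c_hat_fF, c_ab_hat)
            rows.append(
                {
                    "concentration_mgL": conc,
                    "replicate": rep,
                    "c_true_fF": c_true,
                    "coarse": res.code.coarse,
                    "fine": res.code.fine,
                    "c_hat_fF": res.c_hat_fF,
                    "ratio": ratio,
                    "conc_est_mgL": estimate_concentration(ratio, sensor),
                }
            )

    samples = pd.DataFrame(rows)
    summary = (
        samples.groupby("concentration_mgL", sort=False)
        .agg(
            mean_c_hat_fF=("c_hat_fF", "mean"),
            std_c_hat_fF=("c_hat_fF", lambda s: float(np.std(s))),
            mean_ratio=("ratio", "mean"),
            mean_conc_est_mgL=("conc_est_mgL", "mean"),
        )
        .reset_index()
    )
    return AssayResult(samples=samples, summary=summary, c_antibody_hat_fF=c_ab_hat)
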