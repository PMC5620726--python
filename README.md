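# capsar

Behavioral simulator for a label-free capacitive immunoassay platform: an
interdigitated-electrode biosensor whose capacitance encodes the concentration
of the SSAT enzyme (spermidine/spermine N1-acetyltransferase, elevated in
several cancers), digitized by a 12-bit charge-redistribution
successive-approximation capacitance-to-digital converter (CDC) with a
segmented coarse/fine binary-weighted capacitive DAC.

It is aimed at mixed-signal and biosensor designers who want to reason about
such a platform — quantization vs. offset limits, DAC segmentation and
mismatch, calibration inversion — without silicon: every block is a seeded,
testable model with the implemented circuit's parameters as defaults.

## The model in brief

**Sensor.** A 9-segment series-connected interdigitated capacitor (baseline
26 fF; series combination 1/Σ(1/Cᵢ) keeps a large sensing area at femtofarad
baseline). Functionalization stages add fixed shifts (antibody immobilization
+300 fF, BSA blocking +0). The antigen response is the ratio of increase
r = (C_antigen − C_antibody)/C_antibody, calibrated log-linearly through two
anchors — r(1.25 mg/L) = 35, r(10 mg/L) = 6 — and exactly invertible for
concentration estimation.

**Converter.** Charge redistribution makes the amplifier excursion

    ΔV_O = (C_SENS − C_REF,ON) · V_REF · A / C_T,   C_T = C_SENS + C_REF + C_P

and the comparator sees V_IN = ΔV_O + V_OS (gain A = 98, offset
V_OS = 3.3 mV). The SAR logic runs 4 coarse trials (1 pF units) then 8 fine
trials (4.5 fF units), MSB-first; the fine full scale (1147.5 fF) covers one
coarse unit, so the segmented search loses no residual. The code depends only
on the sign of (C_SENS − C_REF,ON), hence is insensitive to V_REF and C_P; the
offset-limited resolution floor V_OS·C_T/(A·V_REF) ≈ 1.2 fF sits below the
4.5 fF LSB, leaving the converter quantization-limited (rms error
LSB/√12 ≈ 1.3 fF).

## Worked example

```python
from capsar import (AnalogParams, DacConfig, SensorConfig, realize,
                    resolution_bound, run_assay, sar_convert)

real = realize(DacConfig())          # nominal 4+8-bit bank: 15 x 1 pF, 255 x 4.5 fF
params = AnalogParams.ideal()        # zero offset/noise: quantization-limited

res = sar_convert(326.0, real, params)
print(f"antibody stage: code=({res.code.coarse},{res.code.fine}) c_hat={res.c_hat_fF} fF")

assay = run_assay((10.0, 5.0, 2.5, 1.25), 1, SensorConfig(), real, params, seed=0)
print(assay.summary.to_string(index=False))

bound = resolution_bound(16137.0, real, AnalogParams())
print(f"offset-limited floor at full scale: {bound:.3f} fF (design LSB 4.5 fF)")
```

prints

```
antibody stage: code=(0,72) c_hat=324.0 fF
 concentration_mgL  mean_c_hat_fF  std_c_hat_fF  mean_ratio  mean_conc_est_mgL
             10.00         2279.0           0.0    6.033951           9.975685
              5.00         5432.0           0.0   15.765432           4.964715
              2.50         8580.5           0.0   25.483025           2.473309
              1.25        11733.5           0.0   35.214506           1.230921
offset-limited floor at full scale: 1.227 fF (design LSB 4.5 fF)
```

The antibody-stage capacitance (26 + 300 = 326 fF) digitizes to code (0, 72),
i.e. 324 fF — a sub-LSB truncation. Running the four-point concentration panel
through the full sensor→converter→calibration-inverse chain reproduces the
anchor ratios (6.03× at 10 mg/L, 35.2× at 1.25 mg/L, within 0.6% of the
calibration values — pure quantization error on two digitized capacitances)
and recovers every concentration within 1.6%. The offset floor (1.227 fF) is
well under the 4.5 fF LSB, confirming the design is quantization-limited.

## Command line

The same runs are scriptable: `capsar convert|sweep|noise|dnl|assay|bound`,
each taking `--config run.json`, `--seed N`, `--set dotted.key=value`
overrides and `--out file.csv`. Identical config + seed gives byte-identical
outputs. Example: `capsar sweep --set sweep.c_max_fF=100 --out tf.csv`.

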