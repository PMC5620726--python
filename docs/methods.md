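# Methods

`capsar` is a behavioral (not circuit-level) simulator of a label-free
capacitive immunoassay platform: an interdigitated-electrode biosensor whose
capacitance encodes the concentration of the SSAT enzyme (a cancer-associated
analyte), digitized by a 12-bit charge-redistribution successive-approximation
capacitance-to-digital converter (CDC) with a segmented coarse/fine
binary-weighted capacitive DAC. This note records the model, its assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Sensor model

The sensing element is a 9-segment interdigitated capacitor with its segments
wired in series, which keeps the baseline capacitance in the femtofarad range
(measured: 26 fF) over a large droplet-scale exposure area. No electrode-
geometry model is attempted: the baseline is a configured parameter, and
`series_capacitance` (the exact 1/Σ(1/Cᵢ) combination) is provided only as a
consistency utility — e.g. nine equal 234 fF segments reproduce the 26 fF
baseline.

Surface functionalization is a staged state machine
`bare → crosslinked → antibody → blocked → antigen`, each stage adding a
configured capacitance shift:

| stage transition | shift | default |
|---|---|---|
| bare → crosslinked (glutaraldehyde) | 0 | no value is reported for this stage |
| → antibody (immobilization) | `antibody_shift_fF` | 300 fF |
| → blocked (BSA passivation) | `bsa_shift_fF` | 0 fF (specific binding only) |
| → antigen | multiplicative, via the response model | — |

Zero-shift stages may be skipped when advancing; skipping a shifted stage is a
state error.

**Concentration response.** The antigen readout statistic is the *ratio of
increase* r = (C_antigen − C_antibody)/C_antibody, which decreases with
concentration (more analyte saturating a fixed antibody layer produces a
proportionally smaller capacitive swing per unit bound in this regime; the
platform reports the empirical ratio, not a binding theory). The calibration
has exactly two quotable anchors — r(1.25 mg/L) = 35 and r(10 mg/L) = 6 — so
the default model is the minimal monotone, exactly invertible interpolant
through them, log-linear in concentration:

    r(c) = r_lo + (r_hi − r_lo) · ln(c/c_lo) / ln(c_hi/c_lo)

Exact invertibility is what makes concentration estimation an analytic inverse
rather than a fit. A saturating Langmuir-style alternative
r(c) = r_max/(1 + c/K), with (r_max, K) solved analytically from the same two
anchors, is available as `response_model="langmuir"` but is not the default:
with only two anchors there is no basis for preferring the extra curvature.
Outside the calibrated range [1.25, 10] mg/L the interpolant extrapolates
(logged as a warning) and is clamped at a configurable positive floor
(`ratio_floor`, default 0.01) so the implied capacitance stays positive.
Binding kinetics over time are not modelled (no kinetic parameters exist to
calibrate them).

## Segmented capacitive DAC

The reference bank is a 4-bit coarse segment (15 unit capacitors of 1 pF) plus
an 8-bit fine segment (255 units of 4.5 fF, the design LSB). The segments are
deliberately **non-radix-2 relative to each other**: one coarse unit is
1000/4.5 ≈ 222.2 fine LSBs, and the fine full scale (1147.5 fF) must cover one
coarse unit so the coarse/fine splice leaves no unreachable residual (enforced
at config validation). A code is therefore always the (coarse, fine) pair with
its reconstruction `coarse·1000 + fine·4.5` fF, never a flat 12-bit integer,
and the code space is redundant: (0, 255) reconstructs *above* (1, 0). The
nominal totals are 1147.5 fF (fine) and 16 147.5 fF (bank); the fabricated
bank's printed figures (1.147 pF, 16.137 pF) differ from nominal arithmetic by
0.04–0.07%, so the hardware's exact unit values were evidently slightly off
nominal; the simulator uses nominal units and treats the printed values as
≈ 0.1%-level statements.

**Mismatch model.** Each physical unit is drawn independently as
`nominal · (1 + N(0, mismatch_sigma_rel))`, seeded; sigma = 0 (the default —
no matching data is available to calibrate it) yields the exact nominal bank.
The weight-2ʲ bit owns the 2ʲ units at indices [2ʲ−1, 2ʲ⁺¹−1), so a bit
contributes the same realized capacitance in every code that sets it, and
disjoint bit selections are exactly additive. A draw producing a non-positive
unit raises rather than resampling (it signals a non-physical sigma).

**Linearity.** DNL/INL are computed over the monotone reconstruction grid —
fine codes 0…255 at coarse 0, and coarse codes 0…15 at fine 0 — as each step's
deviation from its nominal step size in fine-LSB units, with INL the running
sum. The design rule being checked is that coarse-segment |DNL| stays below
half a fine LSB so the segments splice without missing codes; at a mild
10⁻⁴ relative unit mismatch this holds across all tested seeds.

## Conversion engine

Two-phase charge-redistribution model. Sampling charges the whole network
(sensor C_SENS, bank C_REF, parasitic C_P) to the amplifier switching
threshold; in conversion the bank bottom plates switch under SAR control and
charge conservation gives the amplifier excursion

    ΔV_O = (C_SENS − C_REF,ON) · V_REF · A / C_T,   C_T = C_SENS + C_REF + C_P

with A the open-loop gain (default 98, the implemented circuit's value). The
comparator input is V_IN = ΔV_O + V_OS (offset V_OS = V_M1 − V_M2, default
3.3 mV) plus an optional Gaussian draw (`comparator_noise_sigma_V`, default 0)
folding amplifier and comparator noise into one term per decision — the model
has no basis for a finer decomposition. The bit is 1 when V_IN ≥ 0.

Because only the *sign* of (C_SENS − C_REF,ON) matters, the output code is
provably independent of V_REF and C_P when offset and noise are zero (asserted
by tests across V_REF ∈ {0.5, 0.9, 1.8} V and C_P ∈ {0, 500, 2000} fF). V_REF
(default 0.9 V, the analog supply) and C_P (default 500 fF; not a printed
value, exposed in config) instead set the voltage swing per LSB and hence how
much offset/noise a decision tolerates. The offset-limited resolution floor is
the capacitance imbalance whose amplified excursion just cancels the offset:

    C_min = V_OS · C_T / (A · V_REF)

≈ 1.23 fF at full-scale loading with the default parameters — under the 4.5 fF
design LSB, which is why the converter is quantization-limited rather than
offset-limited. (The equality-at-zero comparator case resolves to bit 1: the
sensor then equals the trial code exactly and keeping the bit makes the
reconstruction the largest code not exceeding the input. The alternative
tie-to-0 convention would quantize grid-aligned inputs one full code low,
producing a 1-LSB error exactly where the error should vanish.)

**Search schedule.** Whether the hardware resolves the 12 bits as one merged
search or two sub-searches is not documented; the simulator uses
coarse-then-fine: 4 coarse trials MSB-first with the fine word at 0, then 8
fine trials refining the residual. This is valid precisely because the fine
full scale exceeds one coarse unit. Inputs at or above full scale clamp to
(15, 255) with a saturation flag rather than an error. The reconstruction
`c_hat` is always on the *nominal* grid — the digital code's meaning — even
when the realized (mismatched) bank did the comparisons.

**Oracle and a redundancy caveat.** The reference implementation used in tests
is an exhaustive search for the largest reconstruction not exceeding the
input. Because the code space is redundant, that search must run over the
non-redundant monotone ladder (fine ≤ 222 except at the top coarse word):
over *all* 4096 codes the optimum sometimes lies in the overlap region (e.g.
(7, 253) = 8138.5 fF beats (8, 30) = 8135 fF for inputs just above 8138.5),
and selecting it would require resolving sub-LSB fractional alignment — an
input partition finer than 4096 cells, which no sequence of 12 binary
comparisons can realize. On the non-redundant ladder the SAR output equals the
oracle for every input, and the signed error c_true − c_hat lies in
[0, 1 LSB); its rms about the mean over a dense uniform sweep approaches
LSB/√12 ≈ 1.299 fF.

## Metrics and assay pipeline

`sweep_transfer` emulates the bench characterization (one conversion per grid
point; the documented full sweep is 0 → 16 137 fF in 4.5 fF steps, 3587
points); `quantization_rms` reports the rms error about its mean (the
quantization-noise figure) and optionally raw (including the −LSB/2 truncation
bias — the two are kept separate and labelled because the truncating
convention follows from the largest-code-not-exceeding-input semantics);
`noise_profile` repeats seeded conversions per point (default 100 reps, a
choice — no rep count is documented for the hardware measurement) and reports
the per-point standard deviation; `transfer_dnl` extracts end-to-end DNL from
code-transition positions, with resolution limited by the sweep step.

`run_assay` chains everything: the antibody-stage capacitance
(26 + 300 = 326 fF) is digitized by the same converter as the antigen stage —
the platform compares two codes, never a known analog value — so the reported
ratio uses two quantized numbers. Replicate-to-replicate biological spread is
modelled as Gaussian noise on the true antigen capacitance before digitization
(source uncharacterized in the data; default sigma 0 so the deterministic
pipeline is exactly reproducible, with 25 fF suggested for error-bar
emulation). Per-sample concentration estimates invert the calibration
analytically; ratios outside the anchor band (widened by a configurable guard,
default ±50%) are flagged as extrapolation in the log.

Error budget of the deterministic pipeline: ≤ 1 LSB of truncation on a 324 fF
digitized denominator is ≈ 1.4% on the ratio, amplified through the
log-linear inverse to ≤ 3% on concentration; the observed recoveries of the
{1.25, 2.5, 5, 10} mg/L panel are 1.231, 2.473, 4.965, 9.976 mg/L (0.2–1.6%
error), and the digitized anchor ratios are 35.215 and 6.034 (0.6% from the
calibration values 35 and 6).

## Problem sizes and reproducibility

All computations are desk-scale: the densest default analysis is the
0 → 45 fF sweep at 0.01 fF (4501 conversions) and the noise characterization
(20 points × 100 reps); the whole test suite and the acceptance script each
run in seconds. Every stochastic path (bank mismatch, comparator noise,
replicate noise) flows from one master seed through named substreams
(`substream_seed`), and identical config + seed reproduces byte-identical CSV
output. The comparator-noise sigma used in noise studies is expressed relative
to the per-LSB voltage swing 4.5 fF · V_REF · A / C_T, evaluated at each
point's own C_T, since the swing shrinks as the input loads the summing node.

## What the simulation does and does not show

The generator emulates study conditions, not new data: the baseline, stage
shifts, DAC sizing, gain and offset are the implemented platform's values, and
the concentration response is pinned to its two printed anchors. Passing tests
therefore demonstrate internal consistency of the published architecture and
numbers — that the segmented search is exact, that 4.5 fF quantization (not
the 1.2 fF offset floor) limits resolution, that the calibrated response is
recoverable through the digitizing chain — and nothing about real assay
variability: replicate spread, cross-reactivity, matrix effects, drift and
binding kinetics are either user-set parameters or out of scope. Hardware
figures (power, 42.5 μs measurement time, the fabricated chip's measured
curves) are likewise not reproducible in a behavioral model and are not
attempted.
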