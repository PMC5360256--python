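# Methods

## Signal model

A force-clamp experiment is modeled as a synchronized set of traces:
cantilever deflection `V_defl` (V), servo height `z` (nm, positive away
from the surface), and a voltage-encoded camera frame counter `fnum`
(frame number = `fnum`·10³). The acquisition protocol is a coarsely
sampled approach (0.14 s per point), a push phase establishing tip
contact, four force-clamp segments of 12.5 s at stepwise increasing pull
force, and a short free tail after release.

Deflection voltage converts to force through the spring constant `k`
(N/m) and deflection sensitivity `D` (nm/V):
`F [pN] = 1000·k·D·(V_setpoint − V_baseline)`, pull positive, push
negative. Two baselines bracket the run — `V_contact` averaged over the
last 0.5 s of the approach and `V_end` over the first 0.5 s of the free
tail — and each segment's force is the mean of the two baseline-referenced
values with uncertainty

σ_F = √( (|F_c − F_e|/2)² + (k·D·σ_noise)² ).

This definition attributes the force error to residual surface contact at
the baseline measurement times, which is where it physically arises; the
quadrature term propagates the deflection noise floor. Deflection drifts
linearly with servo height; the drift (V/µm, estimated per recording from
out-of-contact stretches spanning ≥ 50 nm of height) is subtracted before
any level comparison. Drift correction runs before event detection.

A tether-extension event is a deflection transient — linear rise over a
few ms, single-exponential decay with time constant τ as the servo
restores the setpoint — accompanied by a `z` step of the extension
magnitude Δz filtered through a first-order servo lag. The transient
amplitude is modeled as Δz/D volts (the cantilever relaxation before the
servo catches up), capped at 0.5 V where a real servo saturates on
µm-scale steps.

## Synthetic-data generator

`synthgen.simulate_recording` draws, per clamp segment, short events
(Poisson, default 0.24 s⁻¹) with magnitudes Gaussian(4.5, 3.1) nm
truncated below 0.5 nm (extensions must be positive), and long events
(0.02 s⁻¹) log-uniform on 50–2000 nm. Decay constants are log-uniform on
20–200 ms. A configurable fraction (default 0.2) of events is complex:
2–4 sub-transients at gaps of 0.5–1.5 τ whose magnitudes sum to the
event's total. R events (during the setpoint ramp, default probability
0.1 per ramp) and F events (full tip dissociation, deflection drops to
the free level for the rest of the segment, default probability 0.02 per
segment) complete the phenomenology. Deflection carries white Gaussian
noise (default 5 mV) and the drift·z coupling (default −0.05 V/µm); `z`
is treated as noiseless, reflecting the low noise of a closed-loop
position sensor. Defaults for `k` (0.03 N/m) and `D` (50 nm/V) sit in the
middle of the calibrated instrument ranges (0.008–0.04 N/m, 33–67 nm/V);
values outside those ranges are rejected. The clamp sampling rate
defaults to 1 kHz (rates below 50 Hz, which cannot resolve the 200-ms
step-fit windows, are rejected); the push phase defaults to 5 s and the
inter-segment ramp to 0.5 s. Identical seeds give bit-identical output.

The matching TIRF renderer draws the tip vesicle as a 2-D Gaussian spot
(σ = 1 px, 160 nm pixels) whose 3×3-ROI mean equals `I₀·exp(−z/d_TIRF)`
at the vesicle's current height, over a uniform background plus static
surface vesicles, with optional Poisson shot noise; the frame counter is
encoded into `fnum` exactly as the analysis decodes it.

What the generator does **not** emulate: tether polymer elasticity
(WLC/FJC force-extension), cantilever hydrodynamics, membrane mechanics,
1/f instrument noise, camera read noise and EM gain statistics, or
correlations between event magnitude and force. Recovery tests therefore
validate the analysis chain under its own signal model, not instrument
realism.

## Event detection

Detection runs per segment on the drift-corrected deflection after a 5-ms
moving-average pre-filter (transients of interest are ≥ 20 ms). The local
baseline is a 1-s running median; the residual's robust SD (1.4826·MAD)
sets the detection threshold at 4 SD, with an absolute floor of 2 mV so
that effectively noiseless traces do not detect numerical ripple. Event
regions are contiguous excursions above 1 SD (gaps shorter than 30 ms
closed); a region must contain a sample above threshold and is split
wherever the trace returns below 2 SD of baseline for a sustained
(≥ 30 ms) stretch — overlapping peaks that never return form one complex
event. Within a region, resolved maxima (prominence ≥ max(6 SD, 20 % of
the region maximum)) are counted: ≥ 2 makes the event complex.

Per event: `V_max` and its time; the half-maximum crossing on the rise
(interpolated); a linear fit to the 10–90 % rise whose baseline
intersection defines `t_start`; a bounded exponential fit from the last
peak to the baseline return, giving τ and, by extrapolation to 1 baseline
SD, `t_end`. Δz is the difference of two least-squares lines fitted to
200-ms windows of the `z` trace before `t_start` and after `t_end`,
evaluated at the transient midpoint; windows are truncated (flagged) when
a neighboring transient intrudes and the measurement errors out below 10
samples. On noiseless piecewise-linear-plus-step input this estimator is
exact to machine precision.

Events are typed R (start before the segment's first setpoint
attainment; Δz undefined because the piezo is in motion), F (median
deflection after the transient stays within max(25 % of the clamp level,
3 SD) of the free level to the segment end), else FC. Size classes follow
the 50-nm threshold with ties assigned to the extended class (the short
class is defined strictly below 50 nm). Clamp duration runs from the
first setpoint attainment after the last R event to the segment end or
the first F event.

Known limitation: closely overlapping sub-events at low SNR can be split
into separate detections (or partially merged), so complex-event counts
are approximate near threshold; magnitudes of well-separated events are
unbiased (verified to within 2 SE of zero over ~200 paired events).

## Statistics

- **Binomial intervals.** P_FC per 10-min bin uses the exact central
  Clopper-Pearson construction at 68 % (beta quantiles); coverage is
  verified empirically at n = 5, 10, 50.
- **Trend.** Unweighted OLS of the binned proportions on the bin-mean
  time; ≥ 3 bins required.
- **Poisson rates.** n/T with SE √n/T. The two-sample comparison is the
  exact conditional binomial test; its two-sided convention is *central*
  (twice the smaller conditional tail, capped at 1), which reproduces the
  published rate comparison (p = 0.42) exactly, whereas the
  probability-ordering variant (also available as `method="minlike"`, the
  convention of R's `poisson.test`) gives 0.363. Both variants are tested
  against exhaustive enumeration for all totals ≤ 12.
- **Step histograms.** Fixed grid, 2.5-nm bins centered −8.75…48.75 nm
  (negative bins absorb measurement noise), count errors √n. The Gaussian
  peak fit weights bins by those √n errors with absolute-sigma error
  propagation: the residual-scaled covariance of an unweighted fit
  understates the peak-position uncertainty by an order of magnitude at
  n ≈ 53 events (0.03 nm nominal vs ~0.4 nm true seed-to-seed scatter),
  making any SE-based recovery criterion meaningless. Point estimates are
  essentially unchanged by the weighting.
- **Decay-length calibration.** Per-approach three-parameter exponential
  fits (unweighted least squares, d bounded positive); series whose
  intensity does not rise continuously toward the surface (judged on a
  5-point smoothed trace, 2 % tolerance) are excluded and counted.
  Aggregation is the inverse-variance weighted RMS mean (weights from the
  fit covariance) with a matching weighted spread — the weighting and the
  exclusion tolerance are parameters, since only the aggregation family
  is fixed by the procedure being emulated.
- **Unfolding arithmetic.** 0.365 nm unfolded contour per residue minus
  the 0.15 nm helical rise gives 0.215 nm gained per residue; helices of
  25–40 residues give 5.4–8.6 nm per unfolding, and the 6,216 residues of
  the eight exocyst subunits bound the fully unfolded tether at ~2.3 µm.

## Recovery criteria and problem sizes

The short-event peak recovery runs the full pipeline at the published
scale (6 recordings, ~53 short events) and requires the fitted peak
within 3 SE of the generating 4.5 nm. At much larger n the fitted peak
drifts ~+0.4 nm above 4.5: a plain Gaussian fitted to the histogram of a
positivity-truncated Gaussian is asymptotically biased high (the same fit
applied to the *true* injected magnitudes gives 5.4 at n ≈ 400), so the
published-scale criterion tests the estimator in the regime where it is
used. Decay-length calibration recovery uses 5 approaches at d = 102 nm
(3 % multiplicative noise) within 1 aggregate SD, with 2-SD coverage
checked over 100 seeds. The P_FC trend recovery simulates ~600 segments
with per-segment event probability 0.15 + 0.0077·t over t ∈ [10, 90] min
and requires the OLS slope within 2 SE. Detector performance (recall
≥ 95 % at peak SNR ≥ 5, ≤ 1 false positive per 100 s) is measured on 10
recordings (~500 s of clamp time) in the default suite.

## Degenerate inputs and tie-breaks

Out-of-wave intensities (background-subtracted ≤ 0) yield NaN from the
intensity inversion rather than an exception, so paired servo/TIRF traces
keep reporting the servo channel. Missing force baselines flag the
segment and yield NaN forces. Segments whose setpoint is never attained
get zero clamp duration, flagged. F = 0 pN exactly is retained through
the QC cascade with a warning (the strict `F < 0` rule excludes only true
pushes); each excluded segment is attributed to the first rule it fails.
Pixel coordinates are 0-based; ROI centers name the central pixel of the
3×3 window; time intervals are half-open `[start, end)`.
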