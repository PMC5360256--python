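# tetherforce

Analysis of combined AFM force-clamp / TIRF recordings of secretory-vesicle
plasma-membrane tethers.

Secretory vesicles are held at the plasma membrane before fusion by protein
tethers whose molecular identity and mechanics are poorly characterized.
One way to probe them is to press an AFM cantilever onto a membrane sheet
carrying GFP-labeled vesicles, let the tip bind a vesicle, and then apply a
sequence of constant pull forces (a force clamp) while tracking the vesicle
fluorescence in the evanescent field of a TIRF microscope. Each stepwise
tether extension appears simultaneously as a transient in the cantilever
deflection, a step in the positioning-servo `z` trace, and a drop in
vesicle intensity. The distribution of short extension steps peaks near
4.5 nm, matching the 5.4–8.6 nm (0.215 nm per residue) expected from
unfolding single α-helices of CATCHR-family tethering complexes such as
the exocyst.

`tetherforce` is for biophysicists who want to build, test or reuse this
analysis chain without access to raw instrument data: every stage is
exercised against a seeded synthetic-recording generator with known ground
truth.

## What it computes

- **Force calibration** — deflection volts to force:
  `F [pN] = 1000·k·D·(V_setpoint − V_baseline)` with spring constant `k`
  (N/m), deflection sensitivity `D` (nm/V), two free-cantilever baselines
  (`V_contact`, `V_end`) and a height-coupled drift correction (V/µm).
- **Evanescent optics** — forward model `I(z) = I₀·exp(−z/d_TIRF)`, its
  inversion `Δz_TIRF = −d_TIRF·ln((I_f−I_b)/(I_i−I_b))`, the theoretical
  decay length `d = λ/(4π·√(n₁² sin²θ − n₂²))`, and empirical decay-length
  calibration from intensity-vs-height approach data.
- **Event detection** — force transients against a 1-s running-median
  baseline (threshold 4 SD), linear rise fit / single-exponential decay
  fit giving `t_start`, `t_end`, τ; tether extension `Δz` from 200-ms line
  fits to the `z` trace on both sides of the transient; classification
  into FC / R / F types and S / E / C_S / C_E size classes (50 nm
  threshold, unitary vs complex shape).
- **Segment QC** — the ordered selection cascade (setpoint not reached,
  F > 1000 pN, F < −200 pN, σ_F > 200 pN, F < 0 pN, type-U segments)
  with a per-rule audit trail.
- **Statistics** — P_FC per 10-min time-after-lysis bin with exact
  central Clopper-Pearson 68 % intervals and an unweighted OLS trend;
  Poisson rates `n/T ± √n/T` and the exact conditional two-sample Poisson
  test; 2.5-nm step histograms with Gaussian peak fits; helix-unfolding
  length arithmetic.

## Worked example

```python
import tetherforce as tf
from tetherforce.pipeline import summarize

cfg = tf.SimConfig(seed=7)                      # default study conditions
recording, truth = tf.simulate_recording(cfg)   # 4 × 12.5 s clamp segments
segments, events, _ = tf.analyze_recording(recording)
for seg in segments:
    print(f"segment {seg.index}: F = {seg.F:6.1f} +/- {seg.sigma_F:5.1f} pN, "
          f"clamp duration {seg.clamp_duration:5.2f} s")
for e in events:
    print(f"  {e.event_type:2s} {e.shape:8s} {str(e.size_class):4s} "
          f"dz = {e.dz:6.1f} nm  tau = {e.transient.tau*1e3:5.1f} ms")
```

prints

```
segment 1: F =   93.1 +/-  10.1 pN, clamp duration 12.06 s
segment 2: F =  193.1 +/-  10.1 pN, clamp duration 12.17 s
segment 3: F =  293.1 +/-  10.1 pN, clamp duration 12.20 s
segment 4: F =  393.1 +/-  10.1 pN, clamp duration 12.16 s
  FC unitary  E    dz =  128.0 nm  tau =  55.3 ms
  FC unitary  S    dz =    6.0 nm  tau =  69.3 ms
  FC unitary  S    dz =    2.8 nm  tau =  71.7 ms
  FC unitary  S    dz =    4.8 nm  tau =  84.2 ms
  FC unitary  E    dz = 1138.0 nm  tau =  24.2 ms
```

The four pull forces recovered from the deflection baselines (93–393 pN)
match the configured 100–400 pN setpoints within the baseline uncertainty,
and the five detected events match the generator's ground truth (injected
magnitudes 128.0, 6.0, 2.8, 4.8 and 1138.0 nm) — three short (S) events
under 50 nm and two extended (E) events. `summarize(segments, events)`
turns these into rates and, with enough events, a Gaussian peak fit.

The same pipeline is scriptable from the shell:

```sh
tetherforce simulate --seed 7 --out demo/
tetherforce detect --recording demo/recording.tsv --out demo/events.tsv
tetherforce run --seed 7 --out demo_full/       # all stages + QC + stats
```

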