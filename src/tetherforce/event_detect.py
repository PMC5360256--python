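"""Detection and measurement of tether-extension events.

A tether extension under force clamp appears as a transient spike in the
cantilever deflection trace — fast rise, single-exponential decay as the
servo restores the setpoint — accompanied by a step in the servo z trace
whose height is the tether extension dz. The detector follows the
amperometric-spike analysis tradition: spikes are found against a 1-s
running-median local baseline at a threshold of a few baseline SDs, the
rising flank is fitted with a line (its baseline intersection defines
t_start), and the decay with a single exponential (t_end is where the fit
returns to within one baseline SD).

The extension magnitude is measured from the z trace by fitting lines to
200-ms windows before t_start and after t_end and taking their difference
at the midpoint between t_start and t_end — robust against noise and slow
creep in z.

Events are typed FC (during the clamp, after setpoint attainment), R
(during the setpoint ramp; their dz is not measurable because the piezo is
moving) or F (full tip dissociation: deflection stays at the free level for
the rest of the segment), and sized S / E / C_S / C_E by shape (unitary vs
complex, i.e. multiple overlapping peaks) and a 50 nm magnitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .afm_calibration import ClampSegment, Recording, correct_drift

__all__ = [
    "DetectionParams",
    "ForceTransient",
    "TetherEvent",
    "StepEstimate",
    "detect_transients",
    "measure_step",
    "classify_event_type",
    "classify_shape_and_size",
    "clamp_duration",
    "analyze_segment",
    "events_dataframe",
]

SIZE_THRESHOLD_NM = 50.0


@dataclass
class DetectionParams:
    """Tunables of the spike detector; defaults are the package defaults
    (the detection threshold is a multiple of the SD of the residual about
    a running-median local baseline)."""

    threshold_sd: float = 4.0
    smooth_window: float = 0.005  # s, moving-average pre-filter (0 disables)
    baseline_window: float = 1.0  # s, running-median span
    merge_return_sd: float = 2.0  # complex-event merge: no return within this
    min_amplitude_v: float = 0.002  # V, absolute floor (quantization scale)
    min_gap: float = 0.03  # s, sustained-return stretch that separates events
    min_peak_distance: float = 0.005  # s
    noise_floor_frac: float = 1e-3  # amplitude fraction floor for t_end on
    # effectively noiseless traces
    step_window: float = 0.2  # s, line-fit window for measure_step
    min_step_samples: int = 10


@dataclass
class ForceTransient:
    t_start: float
    t_end: float
    t_vmax: float
    v_max: float  # baseline-subtracted, V
    t_half: float
    rise_slope: float  # V/s
    tau: float  # s
    fit_quality: float = float("nan")  # R^2 of the decay fit
    peak_count: int = 1
    flags: list = dfield(default_factory=list)


@dataclass
class TetherEvent:
    transient: ForceTransient
    dz: float | None  # nm; None when not measurable (R events)
    event_type: str  # FC | R | F
    shape: str  # unitary | complex
    size_class: str | None  # S | E | C_S | C_E; None when dz undefined
    segment_index: int
    flags: list = dfield(default_factory=list)


class StepEstimate(NamedTuple):
    dz: float
    truncated: bool


def _running_median(v: np.ndarray, w: int) -> np.ndarray:
    return pd.Series(v).rolling(max(w, 1), center=True, min_periods=1).median().to_numpy()


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_transients(
    times: np.ndarray,
    v_defl: np.ndarray,
    segment: ClampSegment,
    params: DetectionParams | None = None,
) -> list[ForceTransient]:
    """Find force transients within one clamp segment.

    ``v_defl`` should be drift-corrected. Returns fitted
    :class:`ForceTransient` objects in time order; overlapping peaks that do
    not return to within ``merge_return_sd`` SDs of baseline and lie within
    ``3 * tau_guess`` of each other are merged into one complex transient.
    """
    params = params or DetectionParams()
    t0, t1 = segment.t_span
    if t1 - t0 < 2 * params.baseline_window:
        raise ValueError("segment shorter than twice the baseline window")
    i0 = int(np.searchsorted(times, t0))
    i1 = int(np.searchsorted(times, t1))
    t = times[i0:i1]
    v = np.asarray(v_defl[i0:i1], dtype=float)
    if t.size < 10:
        raise ValueError("segment contains too few samples")
    dt = float(np.median(np.diff(t)))
    fs = 1.0 / dt

    w_smooth = int(round(params.smooth_window * fs))
    if w_smooth > 1:
        kern = np.ones(w_smooth) / w_smooth
        v = np.convolve(v, kern, mode="same")

    base = _running_median(v, int(params.baseline_window * fs))
    resid = v - base
    sd = _robust_sd(resid)
    sd_eff = max(sd, 1e-12)
    high_thr = max(params.threshold_sd * sd_eff, params.min_amplitude_v)
    low_thr = max(sd_eff, params.min_amplitude_v / 4.0)

    # Event regions: contiguous excursions above 1 baseline SD (short noise
    # gaps closed), each required to contain at least one sample above the
    # detection threshold. A region is split where the trace returns below
    # merge_return_sd SDs of baseline for a sustained stretch — overlapping
    # peaks that never return are one complex event.
    gap_n = max(1, int(params.min_gap * fs))
    above = resid > low_thr
    regions = _runs(above)
    regions = _close_gaps(regions, gap_n, resid.size)
    out = []
    for a, b in regions:
        for a2, b2 in _split_region(resid, a, b, params.merge_return_sd * sd_eff, gap_n):
            seg_max = resid[a2:b2].max() if b2 > a2 else 0.0
            if seg_max < high_thr:
                continue
            # sub-peak census for shape classification: resolved maxima must
            # stand out both against noise and against the envelope
            peaks, _ = find_peaks(
                resid[a2:b2],
                height=high_thr,
                prominence=max(6.0 * sd_eff, 0.2 * seg_max),
                distance=max(1, int(params.min_peak_distance * fs)),
            )
            group = [a2 + int(p) for p in peaks]
            if not group:
                group = [a2 + int(np.argmax(resid[a2:b2]))]
            tr = _fit_transient(t, resid, group, sd_eff, params, dt, region=(a2, b2))
            if tr is not None:
                out.append(tr)
    return out


def _runs(mask: np.ndarray):
    """Start/stop index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def _close_gaps(regions, gap_n: int, n: int):
    """Merge runs separated by fewer than gap_n samples."""
    if not regions:
        return regions
    merged = [list(regions[0])]
    for a, b in regions[1:]:
        if a - merged[-1][1] < gap_n:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, min(b, n)) for a, b in merged]


def _split_region(resid, a, b, return_level, gap_n):
    """Split [a, b) at sustained dips below the return level."""
    below = resid[a:b] < return_level
    dips = [(s, e) for s, e in _runs(below) if e - s >= gap_n and s > 0 and e < b - a]
    if not dips:
        return [(a, b)]
    cuts = [a + (s + e) // 2 for s, e in dips]
    bounds = [a] + cuts + [b]
    return list(zip(bounds[:-1], bounds[1:]))


def _fit_transient(t, resid, group, sd_eff, params, dt, region=None):
    p_first, p_last = group[0], group[-1]
    span = slice(p_first, p_last + 1)
    i_vmax = p_first + int(np.argmax(resid[span]))
    v_max = float(resid[i_vmax])

    # rising-flank extent: walk left until the residual rejoins baseline
    floor = max(sd_eff, 0.02 * float(resid[p_first]))
    j = p_first
    lo = region[0] if region is not None else 0
    while j > lo and resid[j - 1] > floor:
        j -= 1
    i_base = j

    # half-maximum crossing on the rise (interpolated)
    t_half = float("nan")
    half = v_max / 2.0
    for m in range(i_base, i_vmax + 1):
        if resid[m] >= half:
            if m == i_base:
                t_half = float(t[m])
            else:
                f = (half - resid[m - 1]) / (resid[m] - resid[m - 1])
                t_half = float(t[m - 1] + f * (t[m] - t[m - 1]))
            break

    # linear rise fit between 10% and 90% of the first-peak amplitude
    amp1 = float(resid[p_first])
    rise_idx = [
        m for m in range(i_base, p_first + 1) if 0.1 * amp1 <= resid[m] <= 0.9 * amp1
    ]
    if len(rise_idx) >= 2:
        a, b = np.polyfit(t[rise_idx], resid[rise_idx], 1)
    else:
        m0 = max(i_base - 1, 0)
        denom = t[p_first] - t[m0]
        a = (resid[p_first] - resid[m0]) / denom if denom > 0 else float("inf")
        b = resid[p_first] - a * t[p_first]
    rise_slope = float(a)
    if np.isfinite(a) and a > 0:
        t_start = float(-b / a)
    else:
        t_start = float(t[max(i_base - 1, 0)])
    if not t_start < t[i_vmax]:
        t_start = float(t[max(i_base - 1, 0)])
    if not t_start < t[i_vmax]:  # degenerate: peak at segment start
        t_start = float(t[i_vmax] - dt)

    # decay: exponential fit from the last peak to baseline return
    ret_floor = max(sd_eff, params.noise_floor_frac * v_max)
    i_ret = p_last
    n = region[1] - 1 if region is not None else resid.size - 1
    n = min(n, resid.size - 1)
    while i_ret < n and resid[i_ret] > ret_floor:
        i_ret += 1
    fall_t = t[p_last : i_ret + 1]
    fall_v = resid[p_last : i_ret + 1]
    amp_fall = float(resid[p_last])
    quality = float("nan")
    if fall_t.size >= 4 and amp_fall > 0:
        tau0 = max((fall_t[-1] - fall_t[0]) / 3.0, dt)

        def _decay(tt, aa, tau):
            return aa * np.exp(-(tt - fall_t[0]) / tau)

        try:
            popt, _ = curve_fit(
                _decay,
                fall_t,
                fall_v,
                p0=(amp_fall, tau0),
                bounds=([0.0, dt / 10.0], [np.inf, 100.0]),
                maxfev=5000,
            )
            amp_fit, tau = float(popt[0]), float(popt[1])
            pred = _decay(fall_t, *popt)
            ss_res = float(np.sum((fall_v - pred) ** 2))
            ss_tot = float(np.sum((fall_v - fall_v.mean()) ** 2))
            quality = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        except RuntimeError:
            amp_fit, tau = amp_fall, tau0
    else:
        amp_fit = amp_fall
        tau = max((fall_t[-1] - fall_t[0]) / 3.0, dt) if fall_t.size > 1 else dt

    end_floor = max(sd_eff, params.noise_floor_frac * max(amp_fit, 1e-12))
    if amp_fit > end_floor:
        t_end = float(fall_t[0] + tau * np.log(amp_fit / end_floor))
    else:
        t_end = float(fall_t[-1])
    t_end = min(t_end, float(t[-1]))
    t_end = max(t_end, float(t[i_vmax]))

    return ForceTransient(
        t_start=t_start,
        t_end=t_end,
        t_vmax=float(t[i_vmax]),
        v_max=v_max,
        t_half=t_half,
        rise_slope=rise_slope,
        tau=float(tau),
        fit_quality=quality,
        peak_count=len(group),
    )


def measure_step(
    times: np.ndarray,
    z_servo: np.ndarray,
    transient: ForceTransient,
    window: float = 0.2,
    neighbors=(),
    min_samples: int = 10,
) -> StepEstimate:
    """Tether extension dz (nm) across one transient from the z trace.

    Least-squares lines are fitted to ``[t_start - window, t_start)`` and
    ``(t_end, t_end + window]`` and evaluated at the midpoint of the
    transient; their difference is dz. Windows are truncated (and the
    result flagged) where a neighboring transient intrudes; fewer than
    ``min_samples`` samples on either side is an error.
    """
    times = np.asarray(times, dtype=float)
    z = np.asarray(z_servo, dtype=float)
    w0, w1 = transient.t_start - window, transient.t_start
    a0, a1 = transient.t_end, transient.t_end + window
    truncated = False
    for nb in neighbors:
        if nb is transient:
            continue
        if nb.t_end <= transient.t_start and nb.t_end > w0:
            w0 = nb.t_end
            truncated = True
        if nb.t_start >= transient.t_end and nb.t_start < a1:
            a1 = nb.t_start
            truncated = True
    mb = (times >= w0) & (times < w1)
    ma = (times > a0) & (times <= a1)
    if mb.sum() < min_samples or ma.sum() < min_samples:
        raise ValueError(
            f"step windows too short: {int(mb.sum())}/{int(ma.sum())} samples "
            f"(need {min_samples})"
        )
    line_b = np.polyfit(times[mb], z[mb], 1)
    line_a = np.polyfit(times[ma], z[ma], 1)
    t_mid = 0.5 * (transient.t_start + transient.t_end)
    dz = float(np.polyval(line_a, t_mid) - np.polyval(line_b, t_mid))
    return StepEstimate(dz=dz, truncated=truncated)


def classify_event_type(
    transient: ForceTransient,
    segment: ClampSegment,
    times: np.ndarray,
    v_defl: np.ndarray,
    free_level: float = 0.0,
    noise_sd: float = 0.0,
    min_tail: float = 0.2,
) -> str:
    """Type a transient as FC, R or F (total classification).

    R: starts before the segment's first setpoint attainment. F: after the
    transient the deflection shows no evidence of a pull force — its median
    stays near the free-cantilever level until the segment end. Otherwise
    FC.
    """
    if not segment.reached_setpoint or (
        np.isfinite(segment.t_attain) and transient.t_start < segment.t_attain
    ):
        return "R"
    t1 = segment.t_span[1]
    m = (times > transient.t_end) & (times < t1)
    if m.sum() > 3 and (t1 - transient.t_end) >= min_tail:
        med = float(np.median(v_defl[m]))
        span = segment.setpoint_v - free_level
        if span > 0 and (med - free_level) < max(0.25 * span, 3.0 * noise_sd):
            return "F"
    return "FC"


def classify_shape_and_size(
    shape: str, dz: float | None, threshold: float = SIZE_THRESHOLD_NM
) -> str | None:
    """Size class from shape and magnitude per the event taxonomy.

    Unitary events with dz below ``threshold`` are S (short), at or above it
    E (extended); complex events analogously C_S / C_E. A missing dz (R
    events, where the piezo was in motion) yields None.
    """
    if dz is None or not np.isfinite(dz):
        return None
    if shape == "complex":
        return "C_S" if dz < threshold else "C_E"
    return "S" if dz < threshold else "E"


def clamp_duration(segment: ClampSegment, events) -> float:
    """Effective force-clamp duration of a segment (s).

    Time from the first setpoint attainment after the last R event to the
    segment end or the first F event, whichever comes first; 0 (flagged)
    when the setpoint was never reached.
    """
    if not segment.reached_setpoint or not np.isfinite(segment.t_attain):
        segment.flags.append("no_clamp_duration")
        return 0.0
    start = segment.t_attain
    r_times = [e.transient.t_end for e in events if e.event_type == "R"]
    if r_times:
        start = max(start, max(r_times))
    end = segment.t_span[1]
    f_times = [e.transient.t_start for e in events if e.event_type == "F"]
    if f_times:
        end = min(end, min(f_times))
    return max(end - start, 0.0)


def analyze_segment(
    recording: Recording,
    segment: ClampSegment,
    params: DetectionParams | None = None,
    drift: float | None = None,
) -> list[TetherEvent]:
    """Detect, measure and classify all events of one clamp segment."""
    params = params or DetectionParams()
    v = recording.v_defl
    if drift is not None:
        v = correct_drift(v, recording.z_servo, drift)
    transients = detect_transients(recording.times, v, segment, params)
    noise = recording.meta.get("deflection_noise_sd", 0.0)
    events = []
    for tr in transients:
        etype = classify_event_type(
            tr, segment, recording.times, v, free_level=0.0, noise_sd=noise
        )
        shape = "complex" if tr.peak_count >= 2 else "unitary"
        dz = None
        flags = list(tr.flags)
        if etype != "R":
            try:
                est = measure_step(
                    recording.times,
                    recording.z_servo,
                    tr,
                    window=params.step_window,
                    neighbors=transients,
                    min_samples=params.min_step_samples,
                )
                dz = est.dz
                if est.truncated:
                    flags.append("window_truncated")
            except ValueError:
                flags.append("step_not_measurable")
        else:
            flags.append("piezo_in_motion")
        size = classify_shape_and_size(shape, dz) if etype == "FC" else None
        events.append(
            TetherEvent(
                transient=tr,
                dz=dz,
                event_type=etype,
                shape=shape,
                size_class=size,
                segment_index=segment.index,
                flags=flags,
            )
        )
    segment.clamp_duration = clamp_duration(segment, events)
    return events


def events_dataframe(events) -> pd.DataFrame:
    """Flatten TetherEvent objects into the events table."""
    rows = []
    for e in events:
        tr = e.transient
        rows.append(
            {
                "segment_index": e.segment_index,
                "t_start_s": tr.t_start,
                "t_end_s": tr.t_end,
                "vmax_V": tr.v_max,
                "tau_s": tr.tau,
                "dz_nm": np.nan if e.dz is None else e.dz,
                "event_type": e.event_type,
                "shape": e.shape,
                "size_class": "" if e.size_class is None else e.size_class,
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_index",
            "t_start_s",
            "t_end_s",
            "vmax_V",
            "tau_s",
            "dz_nm",
            "event_type",
            "shape",
            "size_class",
            "flags",
        ],
    )
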