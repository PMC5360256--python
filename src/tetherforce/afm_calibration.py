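"""Cantilever calibration, force conversion and phase parsing.

Raw AFM recordings carry cantilever deflection in photodiode volts. The
deflection sensitivity ``D`` (nm/V) and spring constant ``k`` (N/m) convert
a voltage offset from the free-cantilever baseline into a force:
``F [pN] = 1000 * k * D * (V_setpoint - V_baseline)`` with pull forces
positive and push forces negative.

Two free-cantilever baselines bracket each experiment — ``V_contact``
measured just before surface contact and ``V_end`` just after final release
— and the pull force of a clamp segment is the mean of the two
baseline-referenced values, with half their spread (plus baseline noise in
quadrature) as its uncertainty sigma_F. Deflection drifts linearly with
servo height; the drift (V/um) is estimated from out-of-contact stretches
and subtracted before any voltage-level comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

__all__ = [
    "Recording",
    "ClampSegment",
    "CantileverCalibration",
    "CalibrationError",
    "deflection_sensitivity",
    "estimate_drift",
    "correct_drift",
    "compute_pull_force",
    "parse_phases",
    "sync_frames",
]


class CalibrationError(ValueError):
    pass


@dataclass
class Recording:
    """Synchronized force-clamp time series.

    ``times`` in s, ``v_defl`` in V, ``z_servo`` in nm (positive away from
    the surface), ``fnum`` the voltage-encoded TIRF frame counter (frame
    number = fnum * 1e3). ``meta`` carries spring constant ``k`` (N/m),
    deflection sensitivity ``D`` (nm/V), ``t_lysis`` (min), condition flags
    (``gtpgs``, ``vesicle_observed``) and, for simulated data, the phase
    schedule.
    """

    times: np.ndarray
    v_defl: np.ndarray
    z_servo: np.ndarray
    fnum: np.ndarray
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v_defl = np.asarray(self.v_defl, dtype=float)
        self.z_servo = np.asarray(self.z_servo, dtype=float)
        self.fnum = np.asarray(self.fnum, dtype=float)
        n = self.times.size
        if not (self.v_defl.size == self.z_servo.size == self.fnum.size == n):
            raise ValueError("all traces must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for key in ("spring_constant", "deflection_sensitivity"):
            if key in self.meta and self.meta[key] <= 0:
                raise ValueError(f"{key} must be positive")

    def slice(self, t0: float, t1: float) -> tuple[np.ndarray, ...]:
        """Return (times, v_defl, z_servo) restricted to [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1)
        return self.times[m], self.v_defl[m], self.z_servo[m]


@dataclass
class ClampSegment:
    """One constant-force episode of the clamp phase."""

    index: int
    setpoint_v: float
    t_span: tuple[float, float]  # half-open [start, end)
    F: float = float("nan")  # pN
    sigma_F: float = float("nan")  # pN
    v_contact: float | None = None
    v_end: float | None = None
    clamp_duration: float = float("nan")
    reached_setpoint: bool = True
    t_attain: float = float("nan")  # first setpoint attainment
    ramp_dz: float = float("nan")  # z rise during the entry ramp (nm)
    is_U: bool = False
    flags: list = dfield(default_factory=list)


@dataclass
class CantileverCalibration:
    k: float  # N/m
    D: float  # nm/V
    drift: float = 0.0  # V/um
    noise_sd: float = 0.0  # V, free-baseline noise

    def __post_init__(self) -> None:
        if not (0 < self.k <= 1):
            raise ValueError("spring constant k must be in (0, 1] N/m")
        if self.D <= 0:
            raise ValueError("deflection sensitivity D must be positive")


def deflection_sensitivity(z: np.ndarray, v_defl: np.ndarray, contact_span=None) -> float:
    """Deflection sensitivity D (nm/V) from a push curve.

    With the tip pressed on a hard surface the servo displacement goes
    entirely into cantilever bending, so V_defl vs z is linear in the
    contact region; D is the inverse of that slope. The contact span is
    auto-detected as the largest contiguous run where the local slope
    magnitude is at least half the maximum (or supplied as an index slice).
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v_defl, dtype=float)
    if z.size < 3:
        raise CalibrationError("push curve too short")
    if contact_span is not None:
        sel = slice(*contact_span)
    else:
        # chunked slope scan: local point-wise gradients are noise-dominated
        n_chunks = max(min(z.size // 10, 10), 2)
        edges = np.linspace(0, z.size, n_chunks + 1).astype(int)
        ch_slopes = np.zeros(n_chunks)
        for i in range(n_chunks):
            zz, vv = z[edges[i] : edges[i + 1]], v[edges[i] : edges[i + 1]]
            if zz.size >= 3 and np.ptp(zz) > 0:
                ch_slopes[i] = abs(np.polyfit(zz, vv, 1)[0])
        smax = ch_slopes.max()
        if smax < 1e-9:
            raise CalibrationError("no contact region with significant slope")
        good = ch_slopes >= 0.5 * smax
        # largest contiguous run of steep chunks
        best, cur_start, best_span = 0, None, 0
        for i, g in enumerate(np.append(good, False)):
            if g and cur_start is None:
                cur_start = i
            elif not g and cur_start is not None:
                if i - cur_start > best_span:
                    best, best_span = cur_start, i - cur_start
                cur_start = None
        sel = slice(edges[best], edges[best + best_span])
    zz, vv = z[sel], v[sel]
    if zz.size < 3:
        raise CalibrationError("contact region too short")
    slope = np.polyfit(zz, vv, 1)[0]
    if abs(slope) < 1e-9:
        raise CalibrationError("no contact region with significant slope")
    return 1.0 / abs(slope)


def estimate_drift(free_segments, min_z_span: float = 50.0) -> tuple[float, float]:
    """Deflection drift with servo height from out-of-contact stretches.

    Each segment is a ``(z_nm, v_defl_V)`` pair; per segment the linear
    slope of v_defl vs z is converted to V/um. Returns (mean, SD) across
    segments (SD = 0 for a single segment). Segments spanning less than
    ``min_z_span`` nm of height carry no slope information against the
    deflection noise and are skipped.
    """
    slopes = []
    for z, v in free_segments:
        z = np.asarray(z, dtype=float)
        v = np.asarray(v, dtype=float)
        if z.size < 2 or np.ptp(z) < min_z_span:
            continue
        slopes.append(np.polyfit(z, v, 1)[0] * 1000.0)  # V/nm -> V/um
    if not slopes:
        raise CalibrationError("no usable out-of-contact segment for drift estimation")
    slopes = np.asarray(slopes)
    sd = float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0
    return float(slopes.mean()), sd


def correct_drift(v_defl: np.ndarray, z_servo: np.ndarray, drift: float) -> np.ndarray:
    """Subtract the height-coupled drift term drift [V/um] * z from v_defl."""
    return np.asarray(v_defl, dtype=float) - drift * np.asarray(z_servo, dtype=float) / 1000.0


def compute_pull_force(segment: ClampSegment, cal: CantileverCalibration):
    """Pull force F (pN) and uncertainty sigma_F for one clamp segment.

    Uses the two drift-corrected free-cantilever baselines:
    ``F_c = 1000 k D (setpoint - v_contact)``, ``F_e`` likewise with
    ``v_end``; ``F`` is their mean and ``sigma_F`` combines half their
    spread with the baseline noise in quadrature. Missing baselines flag
    the segment and yield NaN rather than a silent default.
    """
    if segment.v_contact is None or segment.v_end is None:
        segment.flags.append("missing_baseline")
        segment.F = float("nan")
        segment.sigma_F = float("nan")
        return segment.F, segment.sigma_F
    kd = 1000.0 * cal.k * cal.D  # pN per volt
    f_c = kd * (segment.setpoint_v - segment.v_contact)
    f_e = kd * (segment.setpoint_v - segment.v_end)
    segment.F = 0.5 * (f_c + f_e)
    segment.sigma_F = float(np.hypot(0.5 * abs(f_c - f_e), kd * cal.noise_sd))
    return segment.F, segment.sigma_F


def _attainment_time(times, v, setpoint, tol):
    above = np.nonzero(v >= setpoint - tol)[0]
    if above.size == 0:
        return float("nan"), False
    return float(times[above[0]]), True


def parse_phases(
    recording: Recording,
    drift: float | None = None,
    baseline_window: float = 0.5,
    attain_tol: float | None = None,
):
    """Split a recording into approach, push and clamp segments.

    Uses the acquisition schedule from ``recording.meta["schedule"]`` when
    present (the simulator always writes it); otherwise detects setpoint
    plateaus from the deflection trace. Per segment: determines whether and
    when the setpoint was attained, the z rise during the entry ramp, and
    the two free baselines ``v_contact`` (last ``baseline_window`` s of the
    approach) and ``v_end`` (first ``baseline_window`` s of the tail),
    drift-corrected when ``drift`` is given.

    Returns ``(approach_span, push_span, segments)``; fewer than 4 detected
    segments yields a partial result with a ``"missing_segments"`` flag on
    each returned segment.
    """
    t = recording.times
    v = recording.v_defl if drift is None else correct_drift(
        recording.v_defl, recording.z_servo, drift
    )
    meta = recording.meta
    noise = meta.get("deflection_noise_sd", _robust_sd(v))
    sched = meta.get("schedule")
    if sched is None:
        sched = _detect_schedule(t, v, noise)
    approach = tuple(sched["approach"])
    push = tuple(sched["push"])
    tail = tuple(sched.get("tail", (t[-1], t[-1])))

    # free baselines
    m_c = (t >= approach[1] - baseline_window) & (t < approach[1])
    v_contact = float(np.mean(v[m_c])) if m_c.any() else None
    m_e = (t >= tail[0]) & (t < tail[0] + baseline_window)
    v_end = float(np.mean(v[m_e])) if m_e.any() else None

    segments = []
    clamps = sched["clamps"]
    for entry in clamps:
        t0, t1 = entry["t_start"], entry["t_end"]
        setpoint = entry["setpoint_v"]
        tol = attain_tol if attain_tol is not None else max(3.0 * noise, 0.02 * abs(setpoint))
        ts, vs, zs = recording.slice(t0, t1)
        vs_c = vs if drift is None else correct_drift(vs, zs, drift)
        t_attain, reached = _attainment_time(ts, vs_c, setpoint, tol)
        ramp_dz = float("nan")
        if reached and zs.size:
            z_at_attain = zs[np.searchsorted(ts, t_attain)]
            ramp_dz = float(z_at_attain - zs[0])
        seg = ClampSegment(
            index=entry.get("index", len(segments) + 1),
            setpoint_v=setpoint,
            t_span=(t0, t1),
            v_contact=v_contact,
            v_end=v_end,
            reached_setpoint=reached,
            t_attain=t_attain,
            ramp_dz=ramp_dz,
        )
        if not reached:
            seg.flags.append("setpoint_not_reached")
        segments.append(seg)
    if len(segments) < 4:
        for seg in segments:
            seg.flags.append("missing_segments")
    return approach, push, segments


def _detect_schedule(t: np.ndarray, v: np.ndarray, noise: float) -> dict:
    """Reconstruct the phase schedule from the traces themselves.

    The approach phase is recognized by its coarse sampling interval; within
    the finely sampled remainder, setpoint plateaus are found as contiguous
    stretches where a running median of v_defl stays level, the lowest/first
    plateau being the push and subsequent increasing plateaus the clamps.
    Used only when no acquisition schedule is stored in the metadata.
    """
    dt = np.diff(t)
    fine_dt = np.median(dt)
    coarse = dt > 5.0 * fine_dt
    approach_end_idx = 0
    if coarse.any():
        approach_end_idx = int(np.nonzero(coarse)[0][-1] + 1)
    approach = (float(t[0]), float(t[approach_end_idx]))

    tf = t[approach_end_idx:]
    vf = v[approach_end_idx:]
    fs = 1.0 / fine_dt
    w = max(int(0.25 * fs), 3)
    import pandas as _pd

    smooth = _pd.Series(vf).rolling(w, center=True, min_periods=1).median().to_numpy()
    # level-ness judged over a 0.5 s span: sample-scale gradients are noise
    shift = max(int(0.25 * fs), 1)
    padded = np.pad(smooth, shift, mode="edge")
    slope = np.abs(padded[2 * shift :] - padded[: -2 * shift]) / (2 * shift / fs)
    level_tol = max(4.0 * noise, 1e-4)
    stable = slope < level_tol / 0.25
    # contiguous stable runs of at least 1.5 s
    runs = []
    start = None
    for i, s in enumerate(np.append(stable, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if tf[min(i, tf.size - 1)] - tf[start] >= 1.5:
                runs.append((start, i))
            start = None
    if not runs:
        raise CalibrationError("no setpoint plateaus detected")
    # merge adjacent runs at the same level (events split plateaus)
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        lvl_prev = np.median(smooth[merged[-1][0] : merged[-1][1]])
        lvl = np.median(smooth[a:b])
        if abs(lvl - lvl_prev) < 1.5 * level_tol:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    plateaus = [
        (float(tf[a]), float(tf[min(b, tf.size) - 1]), float(np.median(smooth[a:b])))
        for a, b in merged
    ]
    push = (approach[1], plateaus[0][1])
    clamps = []
    prev_end, prev_lvl = plateaus[0][1], plateaus[0][2]
    tail_start = plateaus[-1][1]
    for p_start, p_end, lvl in plateaus[1:]:
        if lvl < prev_lvl + 0.5 * level_tol:
            # level dropped: free tail after final release, not a clamp
            tail_start = prev_end
            break
        clamps.append(
            {
                "index": len(clamps) + 1,
                "t_start": prev_end,  # ramp begins where previous plateau ends
                "t_end": p_end,
                "setpoint_v": lvl,
            }
        )
        prev_end, prev_lvl = p_end, lvl
    return {
        "approach": approach,
        "push": push,
        "clamps": clamps,
        "tail": (tail_start, float(t[-1])),
    }


def _robust_sd(v: np.ndarray) -> float:
    med = np.median(v)
    return 1.4826 * float(np.median(np.abs(v - med)))


def sync_frames(times: np.ndarray, fnum: np.ndarray) -> dict[int, float]:
    """Map TIRF frame numbers to acquisition times.

    The camera fire signal is encoded so that the frame number equals
    ``fnum * 1e3``; each integer frame maps to the first sample time at
    which it appears. Non-monotone fnum traces are rejected.
    """
    times = np.asarray(times, dtype=float)
    frames = np.rint(np.asarray(fnum, dtype=float) * 1000.0).astype(int)
    if np.any(np.diff(frames) < 0):
        raise ValueError("fnum trace is not monotone non-decreasing")
    uniq, first = np.unique(frames, return_index=True)
    return {int(f): float(times[i]) for f, i in zip(uniq, first)}
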