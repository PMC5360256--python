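"""Seeded generator of synthetic force-clamp recordings and TIRF stacks.

Emulates the acquisition protocol of the tether-pulling experiments: a
coarsely sampled approach, a push phase establishing nonspecific tip
contact, four sequential force-clamp segments of increasing pull force
(12.5 s each), and a short free tail after release. Tether-extension events
are injected as deflection transients (fast rise, single-exponential decay)
with a simultaneous servo z step of the true extension magnitude filtered
through a first-order servo lag. Short-event magnitudes are Gaussian around
4.5 nm (SD 3.1 nm), long events log-uniform up to the micrometer scale.
The deflection trace carries white noise and a height-coupled drift term.

Every injected event is written to a :class:`GroundTruthLog` so that the
detection and statistics stages can be tested by parameter recovery. The
generator is deterministic: identical seeds produce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .afm_calibration import Recording
from .tirf_optics import EvanescentField

__all__ = [
    "SimConfig",
    "GroundTruthEvent",
    "GroundTruthLog",
    "simulate_recording",
    "simulate_tirf_stack",
    "simulate_approach_series",
]


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the experimental conditions.

    Forces in pN, lengths in nm, times in s, rates in events/s. The
    cantilever spring constant (N/m) and deflection sensitivity (nm/V) must
    lie in the calibration ranges of the instrument (0.008-0.04 N/m,
    33-67 nm/V); setpoint forces must be strictly increasing.
    """

    seed: int = 0
    sample_rate_clamp: float = 1000.0  # Hz; must resolve 200 ms windows
    approach_rate: float = 0.14  # s per point (coarse approach sampling)
    approach_points: int = 20
    approach_height: float = 1500.0  # nm
    push_duration: float = 5.0
    push_force: float = 200.0  # pN push magnitude (reported F would be -200)
    clamp_durations: tuple = (12.5, 12.5, 12.5, 12.5)
    setpoint_forces: tuple = (100.0, 200.0, 300.0, 400.0)
    ramp_duration: float = 0.5
    tail_duration: float = 2.0
    spring_constant: float = 0.03  # N/m
    deflection_sensitivity: float = 50.0  # nm/V
    drift_rate: float = -0.05  # V/um
    deflection_noise_sd: float = 0.005  # V
    z_noise_sd: float = 0.0  # nm; closed-loop position sensor noise
    servo_response_time: float = 0.01  # s
    event_rate_short: float = 0.24
    event_rate_long: float = 0.02
    short_event_mean: float = 4.5
    short_event_sd: float = 3.1
    min_event_dz: float = 0.5  # truncation of the short-event Gaussian
    long_event_range: tuple = (50.0, 2000.0)
    transient_tau_range: tuple = (0.02, 0.2)
    transient_rise_time: float = 0.004
    transient_amp_cap: float = 0.5  # V; servo saturation for huge steps
    complex_prob: float = 0.2
    r_event_prob: float = 0.1  # per inter-segment ramp
    f_event_prob: float = 0.02  # per segment
    min_event_separation: float = 0.8
    injected_events: tuple = ()  # (segment_index, offset_from_attain_s, dz_nm, tau_s)
    tirf: EvanescentField = field(default_factory=EvanescentField)
    frame_rate: float = 10.0
    pixel_size_nm: float = 160.0
    frame_shape: tuple = (32, 32)
    tirf_shot_noise: bool = True
    vesicle_attached: bool = True
    gtpgs: bool = True
    t_lysis: float = 30.0  # min

    def validate(self) -> None:
        sp = np.asarray(self.setpoint_forces, dtype=float)
        if sp.size != len(self.clamp_durations):
            raise ValueError("setpoint_forces and clamp_durations must match")
        if np.any(np.diff(sp) <= 0):
            raise ValueError("setpoint forces must be strictly increasing")
        if self.sample_rate_clamp < 50:
            raise ValueError(
                "sample_rate_clamp below 50 Hz cannot resolve the 200 ms "
                "step-fit windows"
            )
        for name in ("approach_rate", "push_duration", "ramp_duration", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(d <= 0 for d in self.clamp_durations):
            raise ValueError("clamp durations must be positive")
        if self.short_event_sd <= 0:
            raise ValueError("short_event_sd must be positive")
        if not (0.008 <= self.spring_constant <= 0.04):
            raise ValueError("spring_constant outside calibrated range [0.008, 0.04] N/m")
        if not (33.0 <= self.deflection_sensitivity <= 67.0):
            raise ValueError(
                "deflection_sensitivity outside calibrated range [33, 67] nm/V"
            )
        if self.event_rate_short < 0 or self.event_rate_long < 0:
            raise ValueError("event rates must be non-negative")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruthEvent:
    segment_index: int
    true_time: float  # s
    true_dz: float  # nm
    true_tau: float  # s
    event_type: str  # FC | R | F
    shape: str  # unitary | complex


@dataclass
class GroundTruthLog:
    events: list
    true_d_tirf: float
    true_drift: float

    def of_type(self, *types: str):
        return [e for e in self.events if e.event_type in types]


def _truncated_gaussian(rng, mean, sd, lo, size):
    out = np.empty(size)
    for i in range(size):
        x = rng.normal(mean, sd)
        while x <= lo:
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def simulate_recording(config: SimConfig):
    """Generate one synthetic recording plus its ground-truth event log.

    Returns ``(Recording, GroundTruthLog)``. See the module docstring for
    the signal model; the acquisition schedule (phase boundaries, setpoint
    voltages) is stored in ``Recording.meta["schedule"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k, D = config.spring_constant, config.deflection_sensitivity
    kd = 1000.0 * k * D  # pN per volt
    dt = 1.0 / config.sample_rate_clamp

    # --- time axes -------------------------------------------------------
    t_app = np.arange(config.approach_points) * config.approach_rate
    t_app_end = t_app[-1] + config.approach_rate
    n_c = len(config.clamp_durations)
    fine_dur = (
        config.push_duration + float(np.sum(config.clamp_durations)) + config.tail_duration
    )
    t_fine = t_app_end + np.arange(int(round(fine_dur / dt))) * dt

    # schedule
    push_span = (t_app_end, t_app_end + config.push_duration)
    clamps = []
    cursor = push_span[1]
    for i in range(n_c):
        t0, t1 = cursor, cursor + config.clamp_durations[i]
        clamps.append(
            {
                "index": i + 1,
                "t_start": t0,
                "t_end": t1,
                "setpoint_v": config.setpoint_forces[i] / kd,
                "t_attain": t0 + config.ramp_duration,
            }
        )
        cursor = t1
    tail_span = (cursor, cursor + config.tail_duration)

    # --- baseline deflection schedule (piecewise linear) -----------------
    push_v = -config.push_force / kd
    nodes_t = [t_fine[0], push_span[1]]
    nodes_v = [push_v, push_v]
    for c in clamps:
        nodes_t += [c["t_start"] + config.ramp_duration, c["t_end"]]
        nodes_v += [c["setpoint_v"], c["setpoint_v"]]
    nodes_t += [tail_span[0] + 0.05, t_fine[-1] + dt]
    nodes_v += [0.0, 0.0]
    v_base = np.interp(t_fine, nodes_t, nodes_v)

    z_fine = np.zeros_like(t_fine)  # contact at z = 0
    z_tail_retract = 1000.0 + 5.0 * config.tirf.d_tirf  # release: far out of the wave
    m_tail = t_fine >= tail_span[0]
    z_fine[m_tail] += z_tail_retract * (
        1.0 - np.exp(-(t_fine[m_tail] - tail_span[0]) / (5 * config.servo_response_time))
    )

    # --- event injection -------------------------------------------------
    gt_events: list[GroundTruthEvent] = []
    min_sep = config.min_event_separation

    def add_transient(t_e, dz, tau):
        """Deflection spike (fast rise, exponential decay) + lagged z step."""
        amp = min(dz / D, config.transient_amp_cap)
        s = t_fine - t_e
        rise = config.transient_rise_time
        decay = np.exp(-np.maximum(s - rise, 0.0) / tau)
        shape = np.where(s < 0, 0.0, np.where(s < rise, s / rise, decay))
        v_base_add = amp * shape
        lag = 1.0 - np.exp(-np.maximum(s, 0.0) / config.servo_response_time)
        z_add = np.where(s <= 0, 0.0, dz * lag)
        return v_base_add, z_add

    v_events = np.zeros_like(t_fine)
    for ci, c in enumerate(clamps):
        # R event during the entry ramp
        if config.r_event_prob > 0 and rng.random() < config.r_event_prob:
            t_r = rng.uniform(c["t_start"] + 0.05, c["t_attain"] - 0.05)
            dz_r = float(_truncated_gaussian(rng, config.short_event_mean,
                                             config.short_event_sd,
                                             config.min_event_dz, 1)[0])
            tau_r = float(_loguniform(rng, *config.transient_tau_range))
            va, za = add_transient(t_r, dz_r, tau_r)
            v_events += va
            z_fine += za
            gt_events.append(
                GroundTruthEvent(c["index"], t_r, dz_r, tau_r, "R", "unitary")
            )

        hold0, hold1 = c["t_attain"], c["t_end"]
        # deterministic injections (recovery tests); no rng involved
        for seg_idx, offset, dz_i, tau_i in config.injected_events:
            if seg_idx != c["index"]:
                continue
            t_i = hold0 + offset
            va, za = add_transient(t_i, dz_i, tau_i)
            v_events += va
            z_fine += za
            gt_events.append(
                GroundTruthEvent(c["index"], t_i, dz_i, tau_i, "FC", "unitary")
            )
        t_f = None
        if config.f_event_prob > 0 and rng.random() < config.f_event_prob:
            if hold1 - hold0 > 2 * min_sep + 1.0:
                t_f = rng.uniform(hold0 + min_sep, hold1 - min_sep)
        eff_end = t_f if t_f is not None else hold1
        hold_dur = max(eff_end - hold0, 0.0)

        n_short = rng.poisson(config.event_rate_short * hold_dur)
        n_long = rng.poisson(config.event_rate_long * hold_dur)
        cand = []
        if n_short:
            ts = rng.uniform(hold0 + min_sep / 2, eff_end - min_sep / 2, n_short)
            dzs = _truncated_gaussian(
                rng, config.short_event_mean, config.short_event_sd,
                config.min_event_dz, n_short,
            )
            cand += [(float(t), float(d)) for t, d in zip(ts, dzs)]
        if n_long:
            ts = rng.uniform(hold0 + min_sep / 2, eff_end - min_sep / 2, n_long)
            dzs = _loguniform(rng, *config.long_event_range, n_long)
            cand += [(float(t), float(d)) for t, d in zip(ts, dzs)]
        cand.sort()
        last_t = hold0 - min_sep
        for t_e, dz in cand:
            if t_e - last_t < min_sep or eff_end - t_e < min_sep / 2:
                continue
            last_t = t_e
            tau = float(_loguniform(rng, *config.transient_tau_range))
            if rng.random() < config.complex_prob:
                n_sub = int(rng.integers(2, 5))
                gaps = rng.uniform(0.5 * tau, 1.5 * tau, n_sub - 1)
                offsets = np.concatenate([[0.0], np.cumsum(gaps)])
                w = rng.uniform(0.5, 1.0, n_sub)
                w /= w.sum()
                for off, frac in zip(offsets, w):
                    va, za = add_transient(t_e + off, dz * frac, tau)
                    v_events += va
                    z_fine += za
                gt_events.append(
                    GroundTruthEvent(c["index"], t_e, dz, tau, "FC", "complex")
                )
            else:
                va, za = add_transient(t_e, dz, tau)
                v_events += va
                z_fine += za
                gt_events.append(
                    GroundTruthEvent(c["index"], t_e, dz, tau, "FC", "unitary")
                )

        if t_f is not None:
            dz_f = float(_loguniform(rng, 500.0, 3000.0))
            tau_f = float(_loguniform(rng, *config.transient_tau_range))
            va, za = add_transient(t_f, dz_f, tau_f)
            v_events += va
            z_fine += za
            # force released: baseline drops to the free level for the rest
            m_rest = (t_fine > t_f + config.transient_rise_time) & (t_fine < c["t_end"])
            v_base[m_rest] = 0.0
            gt_events.append(
                GroundTruthEvent(c["index"], t_f, dz_f, tau_f, "F", "unitary")
            )

    # --- assemble traces -------------------------------------------------
    z_app = np.linspace(config.approach_height, 0.0, config.approach_points)
    v_app = config.drift_rate * z_app / 1000.0
    if config.deflection_noise_sd > 0:
        v_app = v_app + rng.normal(0.0, config.deflection_noise_sd, z_app.size)

    v_fine = v_base + v_events + config.drift_rate * z_fine / 1000.0
    if config.deflection_noise_sd > 0:
        v_fine = v_fine + rng.normal(0.0, config.deflection_noise_sd, t_fine.size)
    if config.z_noise_sd > 0:
        z_fine = z_fine + rng.normal(0.0, config.z_noise_sd, t_fine.size)

    times = np.concatenate([t_app, t_fine])
    v_defl = np.concatenate([v_app, v_fine])
    z_servo = np.concatenate([z_app, z_fine])
    fnum = np.floor(times * config.frame_rate) / 1000.0

    meta = {
        "spring_constant": k,
        "deflection_sensitivity": D,
        "drift_rate": config.drift_rate,
        "deflection_noise_sd": config.deflection_noise_sd,
        "sample_rate_clamp": config.sample_rate_clamp,
        "frame_rate": config.frame_rate,
        "seed": config.seed,
        "t_lysis": config.t_lysis,
        "gtpgs": config.gtpgs,
        "vesicle_observed": config.vesicle_attached,
        "z_contact": 0.0,
        "schedule": {
            "approach": (float(times[0]), float(t_app_end)),
            "push": tuple(map(float, push_span)),
            "clamps": clamps,
            "tail": tuple(map(float, tail_span)),
        },
    }
    rec = Recording(times=times, v_defl=v_defl, z_servo=z_servo, fnum=fnum, meta=meta)
    log = GroundTruthLog(
        events=gt_events,
        true_d_tirf=config.tirf.d_tirf,
        true_drift=config.drift_rate,
    )
    return rec, log


def _gaussian_spot(shape, center, sigma):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)))


def simulate_tirf_stack(
    recording: Recording,
    field: EvanescentField,
    config: SimConfig,
    n_background_vesicles: int = 4,
    spot_sigma: float = 1.0,
):
    """Render the TIRF image stack matching a recording.

    Each frame shows the tip-attached vesicle as a 2-D Gaussian spot whose
    3x3-ROI mean intensity equals ``I0 exp(-z/d_TIRF)`` at the vesicle's
    current height (servo position above the contact level), on top of a
    uniform background level and static surface vesicles, with optional
    Poisson shot noise. Returns ``(stack, frame_times)``; the frame counter
    matches the recording's fnum encoding exactly.
    """
    h, w = config.frame_shape
    if h < 3 or w < 3:
        raise ValueError("frame size must be at least 3x3 pixels")
    frames = np.rint(recording.fnum * 1000.0).astype(int)
    n_frames = int(frames.max()) + 1
    frame_times = np.arange(n_frames) / config.frame_rate

    center = (h // 2, w // 2)
    spot = _gaussian_spot((h, w), center, spot_sigma)
    roi = spot[center[0] - 1 : center[0] + 2, center[1] - 1 : center[1] + 2]
    spot_norm = spot / roi.mean()  # 3x3 ROI mean of spot_norm == 1

    rng = np.random.default_rng(int(recording.meta.get("seed", 0)) + 987654321)
    base = np.full((h, w), float(field.i_background))
    # static background vesicles at the surface, kept clear of the tip ROI
    for _ in range(n_background_vesicles):
        while True:
            r = int(rng.integers(2, h - 2))
            c = int(rng.integers(2, w - 2))
            if abs(r - center[0]) + abs(c - center[1]) >= 8:
                break
        amp = float(rng.uniform(0.3, 1.0) * field.i0)
        g = _gaussian_spot((h, w), (r, c), spot_sigma)
        base = base + amp * g

    z_contact = float(recording.meta.get("z_contact", 0.0))
    z_at = np.interp(frame_times, recording.times, recording.z_servo)
    z_ves = np.clip(z_at - z_contact, 0.0, None)

    stack = np.empty((n_frames, h, w))
    for kf in range(n_frames):
        frame = base.copy()
        if config.vesicle_attached:
            frame = frame + field.i0 * np.exp(-z_ves[kf] / field.d_tirf) * spot_norm
        if config.tirf_shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        stack[kf] = frame
    return stack, frame_times


def simulate_approach_series(
    d_tirf: float = 102.0,
    n_series: int = 5,
    seed: int = 0,
    i0: float = 400.0,
    background: float = 100.0,
    noise_frac: float = 0.03,
    z_max: float = 400.0,
    n_points: int = 60,
):
    """Intensity-vs-height series from vesicle approaches, for decay-length
    calibration. Multiplicative Gaussian noise of fractional SD
    ``noise_frac`` models excitation and detection fluctuations."""
    rng = np.random.default_rng(seed)
    series = []
    for _ in range(n_series):
        z = np.linspace(z_max, 0.0, n_points)
        inten = (i0 * np.exp(-z / d_tirf) + background) * (
            1.0 + noise_frac * rng.standard_normal(n_points)
        )
        series.append((z, np.clip(inten, 0.0, None)))
    return series
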