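"""Evanescent-field optics for TIRF vesicle tracking.

Total internal reflection at the glass/buffer interface produces an
evanescent excitation field whose intensity decays exponentially with height
``z`` above the coverslip::

    I_vesicle(z) = I_vesicle,0 * exp(-z / d_TIRF)

The decay length ``d_TIRF`` converts fluorescence-intensity changes of a
vesicle held at the AFM cantilever tip into height changes::

    dz_TIRF = -d_TIRF * ln((I_f - I_background) / (I_i - I_background))

This module implements the forward model, its inversion, the theoretical
decay length from the illumination geometry, empirical decay-length
calibration from approach data, and fixed-ROI intensity extraction from
image stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EvanescentField",
    "IntensityTrace",
    "OutOfWaveError",
    "intensity_at_height",
    "delta_z_tirf",
    "theoretical_decay_length",
    "calibrate_decay_length",
    "camera_pixel_size",
    "roi_mean_intensity",
    "compare_extension_traces",
]


class OutOfWaveError(ValueError):
    """Background-subtracted intensity is non-positive: the vesicle has been
    pulled out of the evanescent wave and only background remains."""


@dataclass(frozen=True)
class EvanescentField:
    """Parameters of the evanescent excitation field.

    Attributes
    ----------
    i0 : float
        Vesicle intensity at ``z = 0`` (camera counts).
    d_tirf : float
        Evanescent decay length (nm).
    i_background : float
        Background intensity level (counts), from surrounding vesicles and
        ambient light.
    wavelength : float
        Excitation wavelength (nm).
    theta_i : float
        Illumination angle of incidence (degrees), above the critical angle.
    n1, n2 : float
        Refractive indices of glass/immersion oil and aqueous buffer.
    """

    i0: float = 400.0
    d_tirf: float = 102.0
    i_background: float = 100.0
    wavelength: float = 488.0
    theta_i: float = 66.8
    n1: float = 1.515
    n2: float = 1.33

    def __post_init__(self) -> None:
        if self.d_tirf <= 0:
            raise ValueError("d_tirf must be positive")
        if not (self.i0 > self.i_background >= 0):
            raise ValueError("require i0 > i_background >= 0")
        if not self.n1 > self.n2:
            raise ValueError("require n1 > n2 for total internal reflection")
        critical = math.degrees(math.asin(self.n2 / self.n1))
        if self.theta_i <= critical:
            raise ValueError(
                f"theta_i={self.theta_i} deg is not above the critical angle "
                f"({critical:.2f} deg): no evanescent decay"
            )


@dataclass
class IntensityTrace:
    """Per-frame mean intensity of a fixed ROI.

    ``values[k]`` is the arithmetic mean of the ROI pixels in frame ``k``;
    ``times`` carries the frame times from *fnum* synchronization.
    """

    times: np.ndarray
    values: np.ndarray
    roi_center: tuple[int, int] = (0, 0)
    roi_size: int = 3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")


def intensity_at_height(field: EvanescentField, z) -> np.ndarray | float:
    """Vesicle intensity (above background) at height ``z`` nm.

    Evaluates ``I0 * exp(-z / d_TIRF)``; strictly decreasing in ``z``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("height z must be non-negative")
    out = field.i0 * np.exp(-z / field.d_tirf)
    return float(out) if out.ndim == 0 else out


def delta_z_tirf(
    i_i: float, i_f: float, i_background: float, d_tirf: float, strict: bool = False
) -> float:
    """Height change (nm) of a vesicle from its intensity change.

    Positive when the vesicle moves away from the surface (intensity drops).
    When either background-subtracted intensity is non-positive the vesicle
    is out of the evanescent wave and the conversion is undefined: returns
    NaN as the flagged non-finite result (or raises :class:`OutOfWaveError`
    with ``strict=True``).
    """
    num = i_f - i_background
    den = i_i - i_background
    if num <= 0 or den <= 0:
        if strict:
            raise OutOfWaveError(
                "background-subtracted intensity <= 0: vesicle out of evanescent wave"
            )
        return float("nan")
    return -d_tirf * math.log(num / den)


def theoretical_decay_length(
    wavelength: float, theta_i: float, n1: float = 1.515, n2: float = 1.33
) -> float:
    """Theoretical evanescent decay length (nm) from illumination geometry.

    ``d = lambda / (4 pi sqrt(n1^2 sin^2(theta) - n2^2))``. Grows without
    bound as ``theta_i`` approaches the critical angle from above.
    """
    s = n1**2 * math.sin(math.radians(theta_i)) ** 2 - n2**2
    if s <= 0:
        raise ValueError("theta_i at or below the critical angle: no evanescent decay")
    return wavelength / (4.0 * math.pi * math.sqrt(s))


def camera_pixel_size(sensor_pixel_um: float = 16.0, magnification: float = 100.0) -> float:
    """Object-plane pixel size (nm) from sensor pixel pitch and magnification."""
    if sensor_pixel_um <= 0 or magnification <= 0:
        raise ValueError("pixel size and magnification must be positive")
    return sensor_pixel_um * 1000.0 / magnification


def _exp_decay(z, a, d, b):
    return a * np.exp(-z / d) + b


@dataclass
class DecayCalibration:
    d_tirf: float
    sd: float
    n: int
    per_series_d: list = field(default_factory=list)
    per_series_var: list = field(default_factory=list)
    excluded: int = 0


def calibrate_decay_length(
    approaches,
    monotonic_tol: float = 0.02,
    d_bounds: tuple[float, float] = (1.0, 1e4),
) -> DecayCalibration:
    """Empirical decay length from intensity-vs-height approach series.

    Each series is a ``(z, I)`` pair of arrays recorded while a tip-attached
    vesicle approaches the surface. Series whose intensity does not increase
    continuously as ``z`` decreases (beyond ``monotonic_tol`` fractional
    backtracking) are excluded and counted. Each surviving series is fitted
    with ``I(z) = A exp(-z/d) + B`` by unweighted least squares with ``d``
    bounded positive; the per-series decay constants are aggregated by the
    inverse-variance weighted RMS mean (weights from the fit covariance),
    with a matching weighted spread.
    """
    if len(approaches) == 0:
        raise ValueError("no approach series supplied")
    ds, variances = [], []
    excluded = 0
    for z, inten in approaches:
        z = np.asarray(z, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if z.size < 5:
            excluded += 1
            continue
        order = np.argsort(z)
        zs, ys = z[order], inten[order]
        # screen: I must rise continuously as z decreases; judged on a
        # lightly smoothed trace so point noise does not reject good series
        w = min(5, ys.size)
        kern = np.ones(w) / w
        smooth = np.convolve(ys, kern, mode="valid")
        rises = np.diff(smooth)  # along increasing z, should be <= 0
        if np.any(rises > monotonic_tol * max(smooth.max(), 1.0)):
            excluded += 1
            continue
        a0 = max(ys.max() - ys.min(), 1e-6)
        d0 = max((zs.max() - zs.min()) / 3.0, d_bounds[0] * 1.001)
        try:
            popt, pcov = curve_fit(
                _exp_decay,
                zs,
                ys,
                p0=(a0, d0, ys.min()),
                bounds=([0.0, d_bounds[0], -np.inf], [np.inf, d_bounds[1], np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            excluded += 1
            continue
        ds.append(popt[1])
        var = pcov[1, 1]
        if not np.isfinite(var) or var <= 0:
            var = 1e-12  # essentially exact fit
        variances.append(var)
    if not ds:
        raise ValueError("all approach series excluded or failed to fit")
    d_arr = np.asarray(ds)
    w = 1.0 / np.asarray(variances)
    w = w / w.sum()
    rms = float(np.sqrt(np.sum(w * d_arr**2)))
    spread = float(np.sqrt(np.sum(w * (d_arr - rms) ** 2))) * math.sqrt(
        len(ds) / max(len(ds) - 1, 1)
    )
    return DecayCalibration(
        d_tirf=rms,
        sd=spread,
        n=len(ds),
        per_series_d=ds,
        per_series_var=variances,
        excluded=excluded,
    )


def roi_mean_intensity(
    stack: np.ndarray,
    center: tuple[int, int],
    frame_times: np.ndarray | None = None,
    roi_size: int = 3,
) -> IntensityTrace:
    """Mean intensity of a ``roi_size x roi_size`` window across frames.

    ``center`` is the (row, col) of the central pixel, 0-based. The window
    must lie fully inside the frame.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    half = roi_size // 2
    r, c = center
    n, h, w = stack.shape
    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        raise ValueError("ROI window clipped by frame edge")
    vals = stack[:, r - half : r + half + 1, c - half : c + half + 1].mean(axis=(1, 2))
    if frame_times is None:
        frame_times = np.arange(n, dtype=float)
    return IntensityTrace(
        times=np.asarray(frame_times, dtype=float),
        values=vals.astype(float),
        roi_center=(r, c),
        roi_size=roi_size,
    )


def compare_extension_traces(
    times_servo: np.ndarray,
    dz_servo: np.ndarray,
    trace: IntensityTrace,
    field: EvanescentField,
    i_background: float | None = None,
):
    """Pair servo-reported extension with TIRF-converted extension.

    Resamples the servo extension onto the frame times of ``trace`` (linear
    interpolation over the overlapping range) and converts intensity to
    height change relative to the first overlapping frame. Frames where the
    vesicle has left the evanescent wave yield NaN in ``dz_tirf`` while
    ``dz_servo`` is still reported. Returns a pandas DataFrame with columns
    ``time_s``, ``dz_servo_nm``, ``dz_tirf_nm``, ``difference_nm``.
    """
    import pandas as pd

    times_servo = np.asarray(times_servo, dtype=float)
    dz_servo = np.asarray(dz_servo, dtype=float)
    ib = field.i_background if i_background is None else float(i_background)
    t0 = max(times_servo[0], trace.times[0])
    t1 = min(times_servo[-1], trace.times[-1])
    if t0 >= t1:
        raise ValueError("servo and intensity traces do not overlap in time")
    mask = (trace.times >= t0) & (trace.times <= t1)
    t = trace.times[mask]
    inten = trace.values[mask]
    servo = np.interp(t, times_servo, dz_servo)
    servo = servo - servo[0]
    i_i = inten[0]
    dz_t = np.array([delta_z_tirf(i_i, i_f, ib, field.d_tirf) for i_f in inten])
    return pd.DataFrame(
        {
            "time_s": t,
            "dz_servo_nm": servo,
            "dz_tirf_nm": dz_t,
            "difference_nm": servo - dz_t,
        }
    )
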