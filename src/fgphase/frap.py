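"""FRAP post-processing: normalization, exponential recovery fit, diffusion.

Recovery of fluorescence in a bleached spot is fitted to the single-exponential
model C(t) = A (1 - exp(-t/tau)), where A (close to 1) absorbs the immobile
fraction.  The half-time t_1/2 = -ln(0.5) tau and the effective bleach-spot
radius R then give the translational diffusion coefficient

    D = 0.224 R^2 / t_1/2.

R is taken from the first postbleach radial profile as the half-width of the
spot at 86% of the bleach depth (the contour where only 14% of the depth
remains), which corrects for diffusion during bleaching and beam blurring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapSeries",
    "FrapFit",
    "normalize",
    "fit_recovery",
    "half_time",
    "diffusion_coefficient",
    "bleach_radius",
    "analyze",
    "summarize_replicates",
]

LN2 = math.log(2.0)
IMMOBILE_RECOVERY_FRACTION = 0.10  # total recovery below this fraction of depth -> immobile


@dataclass(frozen=True)
class FrapSeries:
    """Postbleach ROI time course with the levels needed for normalization.

    ``reference_signal`` is an unbleached-region trace used to correct for
    photobleaching during acquisition; when absent no correction is applied.
    """

    times: np.ndarray
    roi_signal: np.ndarray
    prebleach_level: float
    reference_signal: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.roi_signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "roi_signal", y)
        if t.size != y.size:
            raise ValueError("times and roi_signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.prebleach_level <= 0:
            raise ValueError("prebleach_level must be positive")
        if y[0] >= self.prebleach_level:
            raise ValueError("first postbleach level must be below the prebleach level")
        if self.reference_signal is not None:
            ref = np.asarray(self.reference_signal, dtype=float)
            object.__setattr__(self, "reference_signal", ref)
            if ref.size != t.size:
                raise ValueError("reference trace length must match times")


@dataclass(frozen=True)
class FrapFit:
    a: float                  # mobile-fraction amplitude (~1 for full recovery)
    tau: float | None         # s; None when immobile
    t_half: float | None      # s
    d: float | None           # um^2/s
    bleach_radius_um: float | None
    immobile: bool = False
    a_sd: float = 0.0
    tau_sd: float = 0.0

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.a


def normalize(series: FrapSeries) -> np.ndarray:
    """Corrected, normalized signal C(t) with prebleach == 1.

    The ROI trace is divided by the reference trace rescaled to its own first
    value (exactly cancelling shared acquisition photobleaching), then by the
    prebleach level.  C(0) therefore reflects the bleach depth.  Idempotent:
    a trace already on this scale maps to itself.
    """
    y = series.roi_signal.astype(float)
    if series.reference_signal is not None:
        ref = series.reference_signal
        if np.any(ref <= 0):
            raise ValueError("reference trace reaches zero; cannot correct")
        y = y / (ref / ref[0])
    else:
        warnings.warn(
            "no reference trace supplied; acquisition-photobleaching correction skipped",
            stacklevel=2,
        )
    return y / series.prebleach_level


def fit_recovery(times: np.ndarray, c: np.ndarray, rebase: bool = True) -> FrapFit:
    """Fit C(t) = A (1 - exp(-t/tau)) to a normalized recovery curve.

    With ``rebase`` the curve is first mapped to recovery fraction
    (C - C0) / (1 - C0) measured from the first postbleach frame, so A is the
    mobile fraction regardless of bleach depth; time zero is the first frame.
    Traces recovering less than 10% of the bleach depth are flagged immobile
    (tau reported missing), mirroring condensates with essentially no recovery.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(c, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    t = t - t[0]
    if rebase:
        c0 = y[0]
        depth = 1.0 - c0
        if depth <= 0:
            raise ValueError("no bleach depth: first point already at prebleach level")
        y = (y - c0) / depth

    recovered = float(np.mean(y[-max(3, y.size // 10):]))
    if recovered < IMMOBILE_RECOVERY_FRACTION:
        return FrapFit(a=recovered, tau=None, t_half=None, d=None,
                       bleach_radius_um=None, immobile=True)

    def model(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    # Crude tau start: time to reach half the plateau.
    plateau = max(y[-1], 1e-3)
    half_idx = int(np.argmax(y >= plateau / 2.0))
    tau0 = max(t[half_idx] / LN2, (t[1] - t[0]))
    popt, pcov = curve_fit(model, t, y, p0=(plateau, tau0),
                           bounds=([0.0, 1e-9], [1.2, np.inf]), maxfev=10000)
    a, tau = popt
    sds = np.sqrt(np.diag(pcov))
    th = half_time(tau)
    return FrapFit(a=float(a), tau=float(tau), t_half=th, d=None,
                   bleach_radius_um=None, a_sd=float(sds[0]), tau_sd=float(sds[1]))


def half_time(tau: float) -> float:
    """t_1/2 = -ln(0.5) tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return LN2 * tau


def diffusion_coefficient(t_half: float, radius_um: float) -> float:
    """D = 0.224 R^2 / t_1/2 in um^2/s."""
    if t_half <= 0 or radius_um <= 0:
        raise ValueError("t_half and radius must be positive")
    return 0.224 * radius_um ** 2 / t_half


def bleach_radius(distance_um: np.ndarray, intensity: np.ndarray) -> float:
    """Effective bleach-spot radius from a radial postbleach profile.

    Baseline is the profile's maximum (far-field level); depth the drop to the
    central minimum.  The radius is the half-width of the region where the
    intensity lies below baseline - 0.14 * depth, i.e. where more than 14% of
    the bleach depth remains; crossings are located by linear interpolation.
    """
    x = np.asarray(distance_um, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profile needs matching arrays of >= 3 points")
    baseline = float(np.max(y))
    depth = baseline - float(np.min(y))
    if depth <= 0:
        raise ValueError("profile has no dip")
    level = baseline - 0.14 * depth
    below = y < level
    if not below.any() or below.all():
        raise ValueError("no threshold crossing found in profile")

    # Width of the contiguous below-threshold region around the minimum.
    i_min = int(np.argmin(y))
    left = i_min
    while left > 0 and below[left - 1]:
        left -= 1
    right = i_min
    while right < y.size - 1 and below[right + 1]:
        right += 1

    def interp_cross(i_in, i_out):
        if i_out < 0 or i_out >= y.size:
            return x[i_in]
        x0, x1 = x[i_out], x[i_in]
        y0, y1 = y[i_out], y[i_in]
        if y1 == y0:
            return x1
        return x0 + (level - y0) * (x1 - x0) / (y1 - y0)

    x_left = interp_cross(left, left - 1)
    x_right = interp_cross(right, right + 1)
    return (x_right - x_left) / 2.0


def analyze(series: FrapSeries, radius_um: float) -> FrapFit:
    """Normalization + recovery fit + diffusion coefficient for one replicate."""
    c = normalize(series) if series.reference_signal is not None else \
        series.roi_signal / series.prebleach_level
    fit = fit_recovery(series.times, c)
    if fit.immobile:
        return fit
    d = diffusion_coefficient(fit.t_half, radius_um)
    return FrapFit(a=fit.a, tau=fit.tau, t_half=fit.t_half, d=d,
                   bleach_radius_um=radius_um, a_sd=fit.a_sd, tau_sd=fit.tau_sd)


def summarize_replicates(fits: list[FrapFit]) -> dict:
    """Mean +/- sample SD of D over mobile replicates (reported as in figures)."""
    ds = [f.d for f in fits if not f.immobile and f.d is not None]
    n_immobile = sum(f.immobile for f in fits)
    if not ds:
        return {"d_mean": None, "d_sd": None, "n": 0, "n_immobile": n_immobile}
    mean = float(np.mean(ds))
    sd = float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0
    return {"d_mean": mean, "d_sd": sd, "n": len(ds), "n_immobile": n_immobile}
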