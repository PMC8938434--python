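"""Synthetic-data generators with known ground truth for every analyzer.

Each generator is the exact inverse image of its analyzer at zero noise, so
analyzer-recovery tests are round trips against programmed truth.  Acquisition
designs follow the study conditions the analyzers were built for: 7 relaxation
delays scaled so the last TROSY-state point retains ~30% of the first, FRAP
frames at 2 s intervals, DLS ramps at 1 degC/min between 2 and 40 degC, and
supernatant concentrations obeying sup = min(total, c_crit).  Noise is
Gaussian throughout (multiplicative on intensities and concentrations,
additive on normalized FRAP signals), and every generator is bit-reproducible
under a fixed seed.

All chemical-shift values in DEFAULT_PROTON_SHIFTS / DEFAULT_AMIDE_SHIFTS are
synthetic stand-ins with realistic random-coil magnitudes; they are not
measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dls import DlsRamp
from .frap import FrapSeries
from .phase_assay import AssayPoint
from .spectra import Peak, ShiftTable
from .tract import RelaxationSeries, SpinParameters, eta_forward

__all__ = [
    "GeneratorConfig",
    "REPEAT_UNIT",
    "FIG_PROFILE_PHASE",
    "DEFAULT_PROTON_SHIFTS",
    "DEFAULT_AMIDE_SHIFTS",
    "gen_tract",
    "gen_frap",
    "gen_bleach_profile",
    "gen_dls_ramp",
    "gen_shift_tables",
    "gen_noesy",
    "gen_assay",
]

REPEAT_UNIT = "GGLFGGNTQPAT"

# An 11-residue tau_c profile (ns) shaped like the condensed-phase measurement:
# maxima around L3/F4 and Q9-A11, values spanning the 2-11 ns range.
FIG_PROFILE_PHASE: dict[str, float] = {
    "G1": 4.0, "G2": 5.0, "L3": 8.0, "F4": 9.0, "G5": 4.5, "G6": 4.0,
    "N7": 5.0, "T8": 6.0, "Q9": 9.0, "A11": 10.0, "T12": 6.0,
}

# Synthetic proton shifts (ppm) for one repeat unit; random-coil-like values.
DEFAULT_PROTON_SHIFTS: dict[tuple[int, str], float] = {
    (1, "H"): 8.42, (1, "HA"): 3.95,
    (2, "H"): 8.31, (2, "HA"): 3.90,
    (3, "H"): 8.10, (3, "HA"): 4.32, (3, "HB"): 1.60, (3, "HD"): 0.88,
    (4, "H"): 8.16, (4, "HA"): 4.60, (4, "HB"): 3.05,
    (4, "HD"): 7.25, (4, "HE"): 7.33, (4, "HZ"): 7.29,
    (5, "H"): 8.36, (5, "HA"): 3.92,
    (6, "H"): 8.24, (6, "HA"): 3.88,
    (7, "H"): 8.46, (7, "HA"): 4.70, (7, "HB"): 2.80,
    (8, "H"): 8.05, (8, "HA"): 4.25, (8, "HB"): 4.15, (8, "HG"): 1.17,
    (9, "H"): 8.40, (9, "HA"): 4.31, (9, "HB"): 2.05, (9, "HG"): 2.35,
    (10, "HA"): 4.40, (10, "HB"): 2.26, (10, "HG"): 1.96, (10, "HD"): 3.65,
    (11, "H"): 8.29, (11, "HA"): 4.30, (11, "HB"): 1.38,
    (12, "H"): 8.11, (12, "HA"): 4.28, (12, "HB"): 4.18, (12, "HG"): 1.21,
}

# Synthetic amide 1H/15N shift pairs for the 11 non-proline positions.
DEFAULT_AMIDE_SHIFTS: dict[tuple[int, str], float] = {
    **{(pos, "H"): DEFAULT_PROTON_SHIFTS[(pos, "H")]
       for pos in range(1, 13) if (pos, "H") in DEFAULT_PROTON_SHIFTS},
    (1, "N"): 109.2, (2, "N"): 108.7, (3, "N"): 121.5, (4, "N"): 119.8,
    (5, "N"): 108.9, (6, "N"): 108.5, (7, "N"): 118.6, (8, "N"): 113.9,
    (9, "N"): 121.9, (11, "N"): 124.5, (12, "N"): 112.8,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings: the seed plus per-data-kind noise levels."""

    seed: int = 0
    tract_noise: float = 0.02
    frap_noise: float = 0.02
    dls_noise: float = 0.05
    assay_noise: float = 0.05


def gen_tract(
    tau_profile_ns: dict[str, float],
    sp: SpinParameters | None = None,
    base_rate: float = 40.0,
    noise: float = 0.0,
    seed: int = 0,
    n_delays: int = 7,
    last_fraction: float = 0.30,
) -> tuple[dict[str, RelaxationSeries], dict[str, RelaxationSeries]]:
    """Per-residue alpha/beta relaxation decays for a programmed tau_c profile.

    R_alpha = base_rate - eta_xy(tau), R_beta = base_rate + eta_xy(tau); each
    residue's delays are ``n_delays`` points spaced so the final alpha-state
    intensity is ``last_fraction`` of the first.  ``noise`` is the relative SD
    of multiplicative Gaussian intensity noise.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    sp = sp or SpinParameters()
    rng = np.random.default_rng(seed)
    alpha: dict[str, RelaxationSeries] = {}
    beta: dict[str, RelaxationSeries] = {}
    for label, tau_ns in tau_profile_ns.items():
        if tau_ns <= 0:
            raise ValueError(f"tau_c for {label} must be positive")
        eta = eta_forward(tau_ns * 1e-9, sp)
        r_a = base_rate - eta
        r_b = base_rate + eta
        if r_a <= 0:
            raise ValueError(
                f"base_rate {base_rate} too small for eta_xy {eta:.2f} at {label}"
            )
        t_max = math.log(1.0 / last_fraction) / r_a
        delays = np.linspace(0.0, t_max, n_delays)
        for state, rate, store in (("alpha", r_a, alpha), ("beta", r_b, beta)):
            ideal = 100.0 * np.exp(-rate * delays)
            noisy = ideal * (1.0 + noise * rng.standard_normal(delays.size)) if noise else ideal
            store[label] = RelaxationSeries(label, state, delays, noisy)
    return alpha, beta


def gen_frap(
    d_um2_s: float = 0.06,
    radius_um: float = 2.5,
    bleach_depth: float = 0.8,
    immobile_frac: float = 0.0,
    acq_bleach_rate: float = 0.0,
    dt: float = 2.0,
    t_end: float = 300.0,
    noise: float = 0.0,
    seed: int = 0,
    prebleach_level: float = 100.0,
) -> FrapSeries:
    """A FRAP time course whose analyzer-recovered D equals ``d_um2_s``.

    tau is obtained by inverting D = 0.224 R^2 / (ln 2 * tau); the recovery
    fraction follows A (1 - exp(-t/tau)) with A = 1 - immobile_frac; the
    reference trace (and the ROI with it) decays at ``acq_bleach_rate`` (s^-1)
    to emulate acquisition photobleaching; ``noise`` is additive Gaussian SD on
    the normalized scale.
    """
    if d_um2_s <= 0 or radius_um <= 0:
        raise ValueError("D and radius must be positive")
    if not (0.0 < bleach_depth <= 1.0) or not (0.0 <= immobile_frac <= 1.0):
        raise ValueError("fractions must lie in (0, 1] / [0, 1]")
    rng = np.random.default_rng(seed)
    tau = 0.224 * radius_um ** 2 / (math.log(2.0) * d_um2_s)
    times = np.arange(0.0, t_end + dt / 2.0, dt)
    amplitude = 1.0 - immobile_frac
    c_true = (1.0 - bleach_depth) + bleach_depth * amplitude * (1.0 - np.exp(-times / tau))
    acq = np.exp(-acq_bleach_rate * times)
    roi = c_true * prebleach_level * acq
    ref = prebleach_level * acq
    if noise:
        roi = roi + noise * prebleach_level * rng.standard_normal(times.size)
    return FrapSeries(times=times, roi_signal=roi, prebleach_level=prebleach_level,
                      reference_signal=ref)


def gen_bleach_profile(
    sigma_um: float = 1.2,
    depth: float = 0.8,
    baseline: float = 1.0,
    extent_um: float = 8.0,
    n_points: int = 161,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-blurred bleach dip I(x) = baseline - depth*exp(-x^2/2 sigma^2).

    The analyzer's effective radius of this profile is sigma*sqrt(2 ln(1/0.14))
    ~ 1.98 sigma, so a nominal ~1.5 um bleach blurred to sigma ~1.2 um presents
    as an effective 2-3 um spot.
    """
    x = np.linspace(-extent_um, extent_um, n_points)
    y = baseline - depth * np.exp(-x ** 2 / (2.0 * sigma_um ** 2))
    return x, y


def gen_dls_ramp(
    t_star: float = 16.0,
    r_low: float = 5.0,
    r_high: float = 1000.0,
    width: float = 0.3,
    rate: float = 1.0,
    t_range: tuple[float, float] = (2.0, 40.0),
    noise: float = 0.0,
    seed: int = 0,
    direction: str = "heating",
    hysteresis: float = 0.0,
) -> DlsRamp:
    """Logistic radius jump centred at ``t_star`` sampled at ``rate`` degC/min.

    Cooling ramps run the temperature axis downward with the transition centre
    displaced by ``hysteresis`` degC below t_star (0 = fully reversible).
    ``noise`` is the relative SD of multiplicative radius noise.
    """
    lo, hi = t_range
    if not (lo < t_star < hi):
        raise ValueError("t_star must lie inside the ramp range")
    rng = np.random.default_rng(seed)
    temps = np.arange(lo, hi + rate / 2.0, rate)
    centre = t_star
    if direction == "cooling":
        temps = temps[::-1]
        centre = t_star - hysteresis
    if width > 0:
        radii = r_low + (r_high - r_low) / (1.0 + np.exp(-(temps - centre) / width))
    else:
        radii = np.where(temps >= centre, r_high, r_low).astype(float)
    if noise:
        radii = radii * (1.0 + noise * rng.standard_normal(radii.size))
        radii = np.clip(radii, 1e-3, None)
    return DlsRamp(temperatures=temps, radii=radii, direction=direction, ramp_rate=rate)


def gen_shift_tables(
    base_shifts: dict[tuple[int, str], float] | None = None,
    perturbations: dict[tuple[int, str], float] | None = None,
    condition_a: str = "aqueous",
    condition_b: str = "phase",
) -> tuple[ShiftTable, ShiftTable]:
    """A pair of shift tables where condition B = A + programmed perturbations."""
    base = dict(base_shifts or DEFAULT_AMIDE_SHIFTS)
    pert = perturbations or {}
    unknown = set(pert) - set(base)
    if unknown:
        raise ValueError(f"perturbations reference unknown atoms: {sorted(unknown)}")
    shifted = {key: value + pert.get(key, 0.0) for key, value in base.items()}
    return (ShiftTable(base, condition=condition_a),
            ShiftTable(shifted, condition=condition_b))


def gen_noesy(
    shifts: ShiftTable,
    contacts: list[tuple[tuple[int, str], tuple[int, str]]],
    include_diagonal: bool = True,
    intensity: float = 1.0,
) -> list[Peak]:
    """NOESY peak list: one cross peak per listed contact plus diagonal peaks."""
    peaks: list[Peak] = []
    for atom_i, atom_j in contacts:
        for atom in (atom_i, atom_j):
            if atom not in shifts.shifts:
                raise ValueError(f"contact references unknown atom {atom}")
        peaks.append(Peak(w1=shifts[atom_i], w2=shifts[atom_j], intensity=intensity,
                          assignment=f"{atom_i}-{atom_j}"))
    if include_diagonal:
        for atom, value in shifts.shifts.items():
            peaks.append(Peak(w1=value, w2=value, intensity=10.0 * intensity,
                              assignment=f"{atom}-diag"))
    return peaks


def gen_assay(
    c_crit_by_condition: dict[tuple[float, float], float],
    totals: list[float],
    noise: float = 0.0,
    seed: int = 0,
) -> list[AssayPoint]:
    """Centrifugation-assay points with sup = min(total, c_crit) per condition.

    ``c_crit_by_condition`` maps (temperature degC, NaCl mM) to the programmed
    critical concentration (uM); ``noise`` is the relative SD of multiplicative
    noise on the supernatant readout.
    """
    rng = np.random.default_rng(seed)
    points: list[AssayPoint] = []
    for (temp, nacl), c_crit in c_crit_by_condition.items():
        if c_crit <= 0:
            raise ValueError("c_crit must be positive everywhere")
        for total in totals:
            sup = min(total, c_crit)
            if noise:
                sup = max(sup * (1.0 + noise * rng.standard_normal()), 0.0)
                sup = min(sup, total * (1.0 + _assay_cap(noise)))
            points.append(AssayPoint(total_conc=total, supernatant_conc=sup,
                                     temperature=temp, nacl=nacl))
    return points


def _assay_cap(noise: float) -> float:
    # Keep noisy non-separated points within AssayPoint's tolerance band.
    return min(0.19, 3.0 * noise)
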