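"""DLS temperature ramps: transition detection, phase diagrams, cumulant radii.

During a 1 degC/min temperature ramp, phase separation of an LCST system shows
up as a sharp jump of the apparent hydrodynamic radius from the monomer value
(~5 nm) to that of micron-scale condensate particles (~1000 nm).  The
transition temperature T_p is the first temperature at which the radius
exceeds a threshold (default 10x the running-baseline median) and stays there,
rounded UP to the nearest 0.1 degC.  T_p values over (protein, salt)
concentration series assemble into an LCST phase diagram.

A first-cumulant correlogram fit (g2 - 1 = beta exp(-2 Gamma tau), D =
Gamma/q^2, R_h = k_B T / (6 pi eta D)) is provided for radius extraction from
raw autocorrelation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann as K_B
from scipy.optimize import curve_fit

__all__ = [
    "DlsRamp",
    "PhaseDiagramPoint",
    "Correlogram",
    "DetectionConfig",
    "scattering_vector",
    "detect_transition",
    "aggregate_replicates",
    "build_phase_diagram",
    "cumulant_radius",
    "reversibility",
]


@dataclass(frozen=True)
class DlsRamp:
    temperatures: np.ndarray  # degC, monotone within the ramp direction
    radii: np.ndarray         # nm
    direction: str = "heating"
    ramp_rate: float = 1.0    # degC/min

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "radii", r)
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")
        if t.size != r.size:
            raise ValueError("temperatures and radii must have equal length")
        if np.any(r <= 0):
            raise ValueError("radii must be positive")
        dt = np.diff(t)
        if self.direction == "heating" and np.any(dt <= 0):
            raise ValueError("heating ramp temperatures must be strictly increasing")
        if self.direction == "cooling" and np.any(dt >= 0):
            raise ValueError("cooling ramp temperatures must be strictly decreasing")


@dataclass(frozen=True)
class PhaseDiagramPoint:
    protein_conc_um: float
    nacl_mm: float
    t_p: float
    t_p_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self):
        if self.t_p_sd < 0:
            raise ValueError("t_p_sd must be >= 0")


@dataclass(frozen=True)
class Correlogram:
    lag_times: np.ndarray        # s
    g2_minus_1: np.ndarray
    q: float                     # m^-1
    temperature: float           # K
    viscosity: float             # Pa*s

    def __post_init__(self):
        tau = np.asarray(self.lag_times, dtype=float)
        g = np.asarray(self.g2_minus_1, dtype=float)
        object.__setattr__(self, "lag_times", tau)
        object.__setattr__(self, "g2_minus_1", g)
        if tau.size != g.size:
            raise ValueError("lag_times and g2_minus_1 must have equal length")
        if self.q <= 0:
            raise ValueError("q must be positive")


@dataclass(frozen=True)
class DetectionConfig:
    """Transition-detection knobs: threshold multiple of baseline, persistence,
    fraction of the ramp used for the baseline, rounding quantum (degC)."""

    threshold_factor: float = 10.0
    persistence: int = 3
    baseline_fraction: float = 0.25
    round_to: float = 0.1


def scattering_vector(wavelength_nm: float = 658.0, angle_deg: float = 90.0,
                      refractive_index: float = 1.33) -> float:
    """q = 4 pi n sin(theta/2) / lambda, in m^-1."""
    return (4.0 * math.pi * refractive_index
            * math.sin(math.radians(angle_deg) / 2.0) / (wavelength_nm * 1e-9))


def _round_up(value: float, quantum: float) -> float:
    n = value / quantum
    up = math.ceil(n - 1e-9)  # tolerate fp representation of exact multiples
    return up * quantum


def detect_transition(ramp: DlsRamp, config: DetectionConfig | None = None) -> float | None:
    """Phase-transition temperature from a radius-vs-temperature ramp.

    Returns the first temperature at which the radius exceeds
    ``threshold_factor`` times the baseline median and remains above it for
    ``persistence`` consecutive samples, rounded up to the nearest
    ``round_to`` degC; None if the threshold is never crossed.
    """
    cfg = config or DetectionConfig()
    if ramp.temperatures.size < 10:
        raise ValueError("need at least 10 ramp points")
    n_base = max(3, int(ramp.radii.size * cfg.baseline_fraction))
    baseline = float(np.median(ramp.radii[:n_base]))
    threshold = cfg.threshold_factor * baseline
    above = ramp.radii > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= cfg.persistence:
            t_cross = float(ramp.temperatures[i - cfg.persistence + 1])
            return _round_up(t_cross, cfg.round_to)
    return None


def aggregate_replicates(t_p_values: list[float]) -> tuple[float, float, bool]:
    """Mean and sample SD of replicate T_p values; flag True when n == 1."""
    if not t_p_values:
        raise ValueError("no T_p values to aggregate")
    vals = np.asarray(t_p_values, dtype=float)
    if vals.size == 1:
        return float(vals[0]), 0.0, True
    return float(vals.mean()), float(vals.std(ddof=1)), False


def build_phase_diagram(points: list[PhaseDiagramPoint]) -> pd.DataFrame:
    """Per-salt boundary series sorted by concentration, with LCST flags.

    ``lcst_consistent`` marks salt series whose T_p decreases monotonically
    with protein concentration; ``salt_enhancement`` (same value on all rows)
    marks diagrams where raising NaCl lowers T_p at every shared concentration.
    """
    if not points:
        return pd.DataFrame(
            columns=["nacl_mm", "protein_conc_um", "t_p", "t_p_sd",
                     "n_replicates", "lcst_consistent", "salt_enhancement"]
        )
    df = pd.DataFrame(
        {
            "nacl_mm": [p.nacl_mm for p in points],
            "protein_conc_um": [p.protein_conc_um for p in points],
            "t_p": [p.t_p for p in points],
            "t_p_sd": [p.t_p_sd for p in points],
            "n_replicates": [p.n_replicates for p in points],
        }
    ).sort_values(["nacl_mm", "protein_conc_um"], kind="stable").reset_index(drop=True)

    lcst_flags = {}
    for salt, grp in df.groupby("nacl_mm"):
        lcst_flags[salt] = bool(np.all(np.diff(grp["t_p"].to_numpy()) < 0)) if len(grp) > 1 else True
    df["lcst_consistent"] = df["nacl_mm"].map(lcst_flags)

    salts = sorted(df["nacl_mm"].unique())
    salt_enh = len(salts) > 1
    for lo, hi in zip(salts, salts[1:]):
        a = df[df["nacl_mm"] == lo].set_index("protein_conc_um")["t_p"]
        b = df[df["nacl_mm"] == hi].set_index("protein_conc_um")["t_p"]
        shared = a.index.intersection(b.index)
        if len(shared) == 0 or not bool((b[shared] < a[shared]).all()):
            salt_enh = False
    df["salt_enhancement"] = salt_enh
    return df


def cumulant_radius(c: Correlogram) -> float:
    """Hydrodynamic radius (nm) from a first-cumulant fit of g2 - 1.

    Fits g2 - 1 = beta exp(-2 Gamma tau); D = Gamma / q^2;
    R_h = k_B T / (6 pi eta D).
    """
    tau = c.lag_times
    g = c.g2_minus_1
    if g[0] <= 0 or g[-1] >= g[0]:
        raise ValueError("correlogram does not decay")
    # Log-linear start values from the early decay.
    pos = g > 0
    slope, intercept = np.polyfit(tau[pos], np.log(g[pos]), 1)
    p0 = (math.exp(intercept), max(-slope / 2.0, 1e-3))

    def model(t, beta, gamma):
        return beta * np.exp(-2.0 * gamma * t)

    popt, _ = curve_fit(model, tau, g, p0=p0, maxfev=10000)
    gamma = popt[1]
    if gamma <= 0:
        raise ValueError("non-decaying fit (Gamma <= 0)")
    d = gamma / c.q ** 2  # m^2/s
    r_m = K_B * c.temperature / (6.0 * math.pi * c.viscosity * d)
    return r_m * 1e9


def reversibility(t_p_heating: float, t_p_cooling: float) -> float:
    """Hysteresis metric |T_p(heat) - T_p(cool)|; 0 for a reversible transition."""
    return abs(t_p_heating - t_p_cooling)
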