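"""Critical concentrations from centrifugation assays and partition analytics.

After phase separation, the dilute (aqueous) phase sits exactly at the critical
(saturation) concentration, so the supernatant concentration of a centrifuged
sample equals min(total, c_crit).  The estimator here averages supernatant
concentrations over the points that actually separated; when none did, the
largest total is only a lower bound on c_crit and is flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AssayPoint",
    "CriticalConcEstimate",
    "estimate_critical_conc",
    "partition_coefficient",
    "enrichment_factor",
]

# Supernatant may exceed total by this relative margin before rejection
# (measurement noise on non-separated points).
_SUP_TOLERANCE = 0.2


@dataclass(frozen=True)
class AssayPoint:
    total_conc: float        # uM
    supernatant_conc: float  # uM
    temperature: float       # degC
    nacl: float = 150.0      # mM

    def __post_init__(self):
        if self.total_conc <= 0 or self.supernatant_conc < 0:
            raise ValueError("concentrations must be positive (total) / non-negative (sup)")
        if self.supernatant_conc > self.total_conc * (1.0 + _SUP_TOLERANCE):
            raise ValueError("supernatant exceeds total beyond measurement tolerance")


@dataclass(frozen=True)
class CriticalConcEstimate:
    c_crit: float
    is_lower_bound_only: bool
    temperature: float
    nacl: float
    n_points: int


def estimate_critical_conc(
    points: list[AssayPoint],
    separation_margin: float = 0.05,
) -> CriticalConcEstimate:
    """Critical concentration at one (temperature, NaCl) condition.

    A point counts as phase-separated when its supernatant fell below
    (1 - separation_margin) of the total.  c_crit is the mean supernatant
    concentration over separated points; with no separated point the largest
    total is returned flagged as a lower bound only.
    """
    if not points:
        raise ValueError("need at least one assay point")
    conditions = {(p.temperature, p.nacl) for p in points}
    if len(conditions) > 1:
        raise ValueError(f"points span multiple conditions: {sorted(conditions)}")
    temp, nacl = conditions.pop()

    separated = [p for p in points if p.supernatant_conc < p.total_conc * (1.0 - separation_margin)]
    if not separated:
        bound = max(p.total_conc for p in points)
        return CriticalConcEstimate(bound, True, temp, nacl, len(points))
    c = float(np.mean([p.supernatant_conc for p in separated]))
    return CriticalConcEstimate(c, False, temp, nacl, len(points))


def partition_coefficient(signal_in: float, signal_out: float,
                          detection_floor: float = 0.001) -> float:
    """Probe partition coefficient = signal inside the condensed phase : outside.

    With no detectable outside signal the ratio is a lower bound computed
    against ``detection_floor`` (a fraction of the inside signal).
    """
    if signal_in < 0 or signal_out < 0:
        raise ValueError("signals must be non-negative")
    if signal_out == 0:
        return signal_in / (detection_floor * signal_in) if signal_in > 0 else 0.0
    return signal_in / signal_out


def enrichment_factor(phase_conc: float, starting_conc: float) -> float:
    """Fold concentration of protein in the condensed phase over the input."""
    if phase_conc <= 0 or starting_conc <= 0:
        raise ValueError("concentrations must be positive")
    return phase_conc / starting_conc
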