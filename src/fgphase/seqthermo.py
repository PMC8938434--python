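"""Sequence construction and closed-form hydrodynamics for repeat proteins.

The engineered FG domain studied here is a perfect concatemer of a 12-residue
unit (GGLFGGNTQPAT).  Everything in this module is desk arithmetic on that
sequence: average molecular mass, molar/mass concentration conversions, FG-motif
molarity, the local concentration of motifs confined to a sphere of the chain's
hydrodynamic radius, and Stokes-law predictions for the rotational correlation
time (Stokes-Einstein-Debye) and translational diffusion coefficient
(Stokes-Einstein) of an equivalent hydrated sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.constants import Avogadro as N_A
from scipy.constants import Boltzmann as K_B

__all__ = [
    "RepeatSequence",
    "MoleculeSpec",
    "SolutionConditions",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "build_repeat_sequence",
    "molecular_weight",
    "molar_to_mass_conc",
    "mass_to_molar_conc",
    "motif_molarity",
    "count_motifs",
    "sphere_local_concentration",
    "water_viscosity",
    "hydrated_radius",
    "bare_radius",
    "sed_tau_c",
    "stokes_einstein_D",
    "celsius_to_kelvin",
]

# Average (isotope-abundance-weighted) residue masses in Da, i.e. the amino acid
# minus one water; a free peptide adds WATER_MASS once.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.02  # Da


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty amino-acid sequence")
    for ch in seq:
        if ch not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"invalid amino-acid code {ch!r} (one-letter codes only)")


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + 273.15


@dataclass(frozen=True)
class RepeatSequence:
    """A perfect tandem repeat: ``full_sequence == unit * n_repeats``."""

    unit: str
    n_repeats: int
    full_sequence: str = field(default="")

    def __post_init__(self):
        _validate_sequence(self.unit)
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.full_sequence:
            object.__setattr__(self, "full_sequence", self.unit * self.n_repeats)
        if self.full_sequence != self.unit * self.n_repeats:
            raise ValueError("full_sequence must be unit repeated n_repeats times")

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class SolutionConditions:
    """Solvent conditions entering Stokes' law: temperature (K), viscosity (Pa*s)."""

    temperature: float
    viscosity: float
    note: str = ""

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive (Pa*s)")

    @classmethod
    def water(cls, temp_c: float, note: str = "") -> "SolutionConditions":
        """Pure water at a given temperature in degC."""
        t_k = celsius_to_kelvin(temp_c)
        return cls(temperature=t_k, viscosity=water_viscosity(t_k), note=note)


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule plus the parameters needed for hydrated-sphere hydrodynamics.

    partial_specific_volume in cm^3/g (0.73 is the standard protein value);
    hydration_layer is the thickness of the bound-water shell in angstrom.
    """

    sequence: RepeatSequence
    mw: float = 0.0
    motif: str = "FG"
    motifs_per_chain: int = -1
    partial_specific_volume: float = 0.73
    hydration_layer: float = 3.2

    def __post_init__(self):
        if self.mw == 0.0:
            object.__setattr__(self, "mw", molecular_weight(self.sequence.full_sequence))
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.motifs_per_chain < 0:
            object.__setattr__(
                self, "motifs_per_chain", count_motifs(self.sequence.full_sequence, self.motif)
            )
        if self.hydration_layer < 0:
            raise ValueError("hydration_layer must be >= 0")
        if self.partial_specific_volume <= 0:
            raise ValueError("partial_specific_volume must be positive")


def build_repeat_sequence(unit: str, n: int) -> RepeatSequence:
    """Concatenate ``unit`` ``n`` times into a validated repeat sequence."""
    return RepeatSequence(unit=unit, n_repeats=n)


def count_motifs(seq: str, motif: str = "FG") -> int:
    """Occurrences of ``motif`` in ``seq`` (non-overlapping; FG cannot overlap)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return seq.count(motif)


def molecular_weight(seq: str) -> float:
    """Average molecular mass of a free peptide in Da (residue masses + one water)."""
    _validate_sequence(seq)
    return sum(AVERAGE_RESIDUE_MASS[ch] for ch in seq) + WATER_MASS


def molar_to_mass_conc(c_molar: float, mw: float) -> float:
    """mol/L -> mg/ml.  c * MW(g/mol) is g/L == mg/ml."""
    if c_molar < 0:
        raise ValueError("concentration must be >= 0")
    if mw <= 0:
        raise ValueError("mw must be positive")
    return c_molar * mw


def mass_to_molar_conc(c_mg_ml: float, mw: float) -> float:
    """mg/ml -> mol/L; inverse of :func:`molar_to_mass_conc`."""
    if c_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    if mw <= 0:
        raise ValueError("mw must be positive")
    return c_mg_ml / mw


def motif_molarity(c_chain_molar: float, motifs_per_chain: int) -> float:
    """Molarity of motifs given chain molarity and motifs per chain."""
    if c_chain_molar < 0 or motifs_per_chain < 0:
        raise ValueError("inputs must be >= 0")
    return c_chain_molar * motifs_per_chain


def sphere_local_concentration(n_copies: int, radius_nm: float) -> float:
    """Concentration (mol/L) of ``n_copies`` entities confined to a sphere.

    Used to estimate the local FG-motif concentration inside a single chain's
    hydrodynamic volume (52 motifs in a ~5 nm sphere -> ~0.17 M).
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    volume_l = (4.0 / 3.0) * math.pi * (radius_nm * 1e-9) ** 3 * 1e3  # m^3 -> L
    return n_copies / (N_A * volume_l)


def water_viscosity(temperature_k: float) -> float:
    """Dynamic viscosity of pure water in Pa*s.

    Empirical Vogel-type correlation eta = 2.414e-5 * 10^(247.8/(T-140)),
    accurate to well under 1% against handbook values between 0 and 40 degC
    (1.002 mPa*s at 20 degC).
    """
    if not (273.0 < temperature_k < 373.0):
        raise ValueError(f"temperature {temperature_k} K outside liquid-water range (273, 373)")
    return 2.414e-5 * 10.0 ** (247.8 / (temperature_k - 140.0))


def bare_radius(mw: float, partial_specific_volume: float = 0.73) -> float:
    """Anhydrous equivalent-sphere radius in angstrom from MW (Da) and vbar (cm^3/g)."""
    if mw <= 0 or partial_specific_volume <= 0:
        raise ValueError("mw and vbar must be positive")
    vol_cm3 = mw * partial_specific_volume / N_A  # per molecule
    r_cm = (3.0 * vol_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_cm * 1e8  # cm -> angstrom


def hydrated_radius(spec: MoleculeSpec) -> float:
    """Hydrated-sphere radius in angstrom: bare radius plus the hydration shell."""
    return bare_radius(spec.mw, spec.partial_specific_volume) + spec.hydration_layer


def sed_tau_c(radius_angstrom: float, cond: SolutionConditions) -> float:
    """Stokes-Einstein-Debye rotational correlation time in ns.

    tau_c = 4 pi eta r^3 / (3 k_B T) for a rigid sphere of the given radius.
    """
    if radius_angstrom <= 0:
        raise ValueError("radius must be positive")
    r_m = radius_angstrom * 1e-10
    tau_s = 4.0 * math.pi * cond.viscosity * r_m ** 3 / (3.0 * K_B * cond.temperature)
    return tau_s * 1e9


def stokes_einstein_D(radius_nm: float, cond: SolutionConditions) -> float:
    """Stokes-Einstein translational diffusion coefficient in um^2/s."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    r_m = radius_nm * 1e-9
    d_m2_s = K_B * cond.temperature / (6.0 * math.pi * cond.viscosity * r_m)
    return d_m2_s * 1e12
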