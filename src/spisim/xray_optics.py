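"""Pulse parameters, tabulated photoabsorption, and water-window contrast.

The soft X-ray "water window" lies between the carbon K edge (~284 eV,
lambda ~ 4.37 nm) and the oxygen K edge (~543 eV).  Inside it carbon-rich
material absorbs strongly while water is comparatively transparent, which
is what gives hydrated biological particles natural absorption contrast.
This module provides the pieces needed to quantify that contrast for a
given material composition: a bundled atomic photoabsorption table with
log-log interpolation, linear attenuation coefficients, absorbed
fractions through a slab, and the sample/background contrast ratio.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from ._elements import ATOMIC_MASS, ATOMIC_NUMBER, HC_EV_NM, SUPPORTED_ELEMENTS

__all__ = [
    "FELPulse",
    "Composition",
    "AtomicDataTable",
    "EnergyRangeError",
    "photon_energy",
    "peak_fluence",
    "attenuation_coefficient",
    "absorbed_fraction",
    "contrast_ratio",
    "gaussian_profile",
    "WATER",
    "VIRUS_LIKE",
    "VIRUS_DENSITY_G_CM3",
]

AVOGADRO = 6.02214076e23

#: Mass density of the virus-like material (g/cm^3).  Calibrated once
#: against the 3.3 / 0.85 water-window absorption contrast pair using the
#: bundled photoabsorption table, then frozen; see docs/methods.md.
VIRUS_DENSITY_G_CM3 = 0.877


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated range."""


@dataclass(frozen=True)
class FELPulse:
    """FEL pulse description.

    Parameters
    ----------
    photons_per_pulse : number of photons in one pulse.
    wavelength_nm : photon wavelength, nm.
    focus_diameter_nm : focal-spot diameter (top-hat focus model), nm.
    fwhm_fs : temporal full width at half maximum of the Gaussian
        envelope, fs.
    """

    photons_per_pulse: float
    wavelength_nm: float
    focus_diameter_nm: float
    fwhm_fs: float

    def __post_init__(self) -> None:
        for name in ("photons_per_pulse", "wavelength_nm", "focus_diameter_nm", "fwhm_fs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"FELPulse.{name} must be > 0")

    @property
    def photon_energy_ev(self) -> float:
        return photon_energy(self.wavelength_nm)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


@dataclass(frozen=True)
class Composition:
    """Material composition: stoichiometric formula unit plus mass density.

    ``stoichiometry`` maps element symbol to its (possibly fractional)
    coefficient in the formula unit; ``mass_density`` is in g/cm^3.
    """

    stoichiometry: Mapping[str, float]
    mass_density: float

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError("mass_density must be > 0")
        stoich = dict(self.stoichiometry)
        if not stoich or not any(v > 0 for v in stoich.values()):
            raise ValueError("composition needs at least one positive coefficient")
        for el, n in stoich.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative coefficient for {el}")
        object.__setattr__(self, "stoichiometry", stoich)

    @classmethod
    def from_formula(cls, formula: str, mass_density: float) -> "Composition":
        """Parse e.g. ``"CH1.5O0.5N0.25P0.025"`` (no coefficient means 1)."""
        pos = 0
        stoich: dict[str, float] = {}
        while pos < len(formula):
            m = _FORMULA_TOKEN.match(formula, pos)
            if m is None or m.group(1) not in SUPPORTED_ELEMENTS:
                raise ValueError(f"cannot parse formula at {formula[pos:]!r}")
            stoich[m.group(1)] = stoich.get(m.group(1), 0.0) + float(m.group(2) or 1.0)
            pos = m.end()
        return cls(stoich, mass_density)

    @property
    def formula_mass(self) -> float:
        """Mass of one formula unit, g/mol."""
        return sum(n * ATOMIC_MASS[el] for el, n in self.stoichiometry.items())

    @property
    def electrons_per_formula(self) -> float:
        return sum(n * ATOMIC_NUMBER[el] for el, n in self.stoichiometry.items())

    def electron_density_nm3(self) -> float:
        """Electrons per nm^3 implied by mass density and stoichiometry."""
        formula_per_cm3 = self.mass_density * AVOGADRO / self.formula_mass
        return formula_per_cm3 * self.electrons_per_formula * 1e-21


@dataclass
class AtomicDataTable:
    """Per-element photoabsorption cross sections with log-log interpolation.

    ``energies[el]`` is a strictly increasing array of photon energies (eV)
    and ``cross_sections[el]`` the matching cross sections (cm^2/atom).
    """

    energies: dict = field(repr=False)
    cross_sections: dict = field(repr=False)

    def __post_init__(self) -> None:
        for el, e in self.energies.items():
            e = np.asarray(e, dtype=float)
            s = np.asarray(self.cross_sections[el], dtype=float)
            if e.ndim != 1 or e.shape != s.shape:
                raise ValueError(f"mismatched table arrays for {el}")
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"energies for {el} must be strictly increasing")
            if not np.all(s > 0):
                raise ValueError(f"cross sections for {el} must be positive")
            self.energies[el] = e
            self.cross_sections[el] = s

    @classmethod
    def bundled(cls) -> "AtomicDataTable":
        """Load the packaged table (H, C, N, O, P, S; 200-700 eV)."""
        text = resources.files("spisim.data").joinpath("photoabsorption.csv").read_text()
        energies: dict[str, list[float]] = {}
        sigmas: dict[str, list[float]] = {}
        for line in text.strip().splitlines()[1:]:
            el, e, s = line.split(",")
            energies.setdefault(el, []).append(float(e))
            sigmas.setdefault(el, []).append(float(s))
        return cls(
            {el: np.array(v) for el, v in energies.items()},
            {el: np.array(v) for el, v in sigmas.items()},
        )

    def energy_range(self, element: str) -> tuple[float, float]:
        e = self.energies[element]
        return float(e[0]), float(e[-1])

    def sigma(self, element: str, energy_ev: float) -> float:
        """Photoabsorption cross section (cm^2) by log-log interpolation."""
        if element not in self.energies:
            raise KeyError(f"element {element!r} not in table")
        e = self.energies[element]
        if not (e[0] <= energy_ev <= e[-1]):
            raise EnergyRangeError(
                f"{energy_ev} eV outside table range [{e[0]}, {e[-1]}] for {element}"
            )
        logs = np.interp(math.log(energy_ev), np.log(e), np.log(self.cross_sections[element]))
        return float(math.exp(logs))


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy in eV for a wavelength in nm (E = hc / lambda)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    return HC_EV_NM / wavelength_nm


def peak_fluence(pulse: FELPulse) -> float:
    """Photons per cm^2 at focus for a top-hat focal spot."""
    radius_cm = pulse.focus_diameter_nm / 2.0 * 1e-7
    return pulse.photons_per_pulse / (math.pi * radius_cm**2)


def attenuation_coefficient(
    composition: Composition, energy_ev: float, table: AtomicDataTable
) -> float:
    """Linear attenuation coefficient mu in 1/nm.

    mu = rho * N_A / M_formula * sum_i n_i sigma_i(E); the density enters
    linearly and the result is invariant under rescaling all stoichiometric
    coefficients together.
    """
    sigma_sum = sum(
        n * table.sigma(el, energy_ev) for el, n in composition.stoichiometry.items() if n > 0
    )
    mu_cm = composition.mass_density * AVOGADRO / composition.formula_mass * sigma_sum
    return mu_cm * 1e-7


def absorbed_fraction(
    composition: Composition, thickness_nm: float, energy_ev: float, table: AtomicDataTable
) -> float:
    """Fraction of photons absorbed by a slab: 1 - exp(-mu t)."""
    if thickness_nm < 0:
        raise ValueError("thickness must be >= 0")
    mu = attenuation_coefficient(composition, energy_ev, table)
    return 1.0 - math.exp(-mu * thickness_nm)


def contrast_ratio(
    sample: Composition,
    background: Composition,
    thickness_nm: float,
    energy_ev: float,
    table: AtomicDataTable,
) -> float:
    """Ratio of absorbed fractions sample / background for equal slabs."""
    bg = absorbed_fraction(background, thickness_nm, energy_ev, table)
    if bg == 0.0:
        raise ZeroDivisionError("background absorbs nothing at this energy/thickness")
    return absorbed_fraction(sample, thickness_nm, energy_ev, table) / bg


def gaussian_profile(t_fs, fwhm_fs: float):
    """Normalized Gaussian temporal intensity profile (1/fs), centered at 0.

    The FWHM is the stated pulse duration; the integral over all time is 1.
    """
    if fwhm_fs <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm_fs / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t = np.asarray(t_fs, dtype=float)
    out = np.exp(-0.5 * (t / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    return float(out) if np.isscalar(t_fs) else out


#: Liquid water at ambient density.
WATER = Composition.from_formula("H2O", 1.0)

#: Empirical virus-like material CH1.5O0.5N0.25P0.025 at the calibrated density.
VIRUS_LIKE = Composition.from_formula("CH1.5O0.5N0.25P0.025", VIRUS_DENSITY_G_CM3)
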