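"""Simulated C1s spectra from composition profiles.

Each carbon environment contributes one spectral component, a unit-area line
centred at its characteristic binding energy and weighted by the
environment's carbon fraction; the sum is max-normalized. Binding energies
come from a user-overridable component table whose defaults are anchored to
standard C1s chemical-shift practice (aliphatic CHx at 285.0 eV, ether/
hydroxyl carbon near 286.5 eV, amide near 288 eV, carboxyl near 289 eV).
The default line shape is a pure Gaussian of 1.1 eV FWHM for every
component; a Gaussian-Lorentzian sum shape is available for users who expect
it from interactive fitting software.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chemistry import ENVIRONMENTS
from .composition import CompositionProfile
from .spectrum import Spectrum, energy_grid

_GAUSS_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma per unit FWHM

#: Default component binding energies (eV), user-overridable.
DEFAULT_BINDING_ENERGIES: dict[str, float] = {
    "C=C": 284.7,
    "CHx": 285.0,
    "C-S": 285.4,
    "C-C(O)O": 285.5,
    "C=C-N": 285.9,
    "C-N": 286.2,
    "C-OH": 286.5,
    "C=N": 286.9,
    "N-C=O": 288.1,
    "COOH": 289.0,
}

DEFAULT_FWHM_EV = 1.1


@dataclass(frozen=True)
class Component:
    binding_energy: float
    fwhm: float = DEFAULT_FWHM_EV
    line_shape: str = "gaussian"      # or "gaussian-lorentzian"
    mix: float = 0.3                  # Lorentzian fraction for GL shape

    def __post_init__(self):
        if not 283.0 <= self.binding_energy <= 292.0:
            raise ValueError(f"binding energy {self.binding_energy} eV "
                             "outside the C1s window [283, 292] eV")
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.line_shape not in ("gaussian", "gaussian-lorentzian"):
            raise ValueError(f"unknown line shape {self.line_shape!r}")

    def evaluate(self, energy: np.ndarray) -> np.ndarray:
        """Unit-area line profile on *energy*."""
        x = energy - self.binding_energy
        sigma = self.fwhm * _GAUSS_SIGMA
        gauss = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        if self.line_shape == "gaussian":
            return gauss
        gamma = self.fwhm / 2.0
        lorentz = gamma / (np.pi * (x ** 2 + gamma ** 2))
        return (1.0 - self.mix) * gauss + self.mix * lorentz


@dataclass(frozen=True)
class ComponentTable:
    """Environment -> spectral component parameters (covers all ten)."""

    components: Mapping[str, Component] = field(
        default_factory=lambda: {e: Component(be) for e, be in
                                 DEFAULT_BINDING_ENERGIES.items()})

    def __post_init__(self):
        missing = set(ENVIRONMENTS) - set(self.components)
        if missing:
            raise ValueError(f"component table missing {sorted(missing)}")

    def component(self, env: str,
                  be_override: float | None = None) -> Component:
        base = self.components[env]
        if be_override is None:
            return base
        return Component(be_override, base.fwhm, base.line_shape, base.mix)

    @classmethod
    def from_json(cls, path) -> "ComponentTable":
        """Load overrides from JSON: {env: {binding_energy, fwhm?, line_shape?,
        mix?}} merged over the defaults."""
        with open(path) as fh:
            raw = json.load(fh)
        comps = {e: Component(be) for e, be in DEFAULT_BINDING_ENERGIES.items()}
        for env, params in raw.items():
            if env not in ENVIRONMENTS:
                raise ValueError(f"unknown environment {env!r} in {path}")
            base = comps[env]
            comps[env] = Component(
                params.get("binding_energy", base.binding_energy),
                params.get("fwhm", base.fwhm),
                params.get("line_shape", base.line_shape),
                params.get("mix", base.mix))
        return cls(comps)


DEFAULT_COMPONENT_TABLE = ComponentTable()


def simulate_protein_spectrum(profile: CompositionProfile,
                              table: ComponentTable = DEFAULT_COMPONENT_TABLE,
                              grid=None) -> Spectrum:
    """Simulated, max-normalized C1s spectrum of a composition profile.

    The grid must span every active component's centre by at least three
    FWHM on each side so no peak is clipped.
    """
    grid = energy_grid() if grid is None else np.asarray(grid, dtype=float)
    comps = {env: table.component(env, profile.be_overrides.get(env))
             for env in profile.env_fractions}
    lo = min(c.binding_energy - 3 * c.fwhm for c in comps.values())
    hi = max(c.binding_energy + 3 * c.fwhm for c in comps.values())
    if grid[0] > lo + 1e-9 or grid[-1] < hi - 1e-9:
        raise ValueError(
            f"energy grid [{grid[0]:g}, {grid[-1]:g}] eV too narrow; the "
            f"active components require at least [{lo:g}, {hi:g}] eV")
    intensity = np.zeros_like(grid)
    for env, fraction in profile.env_fractions.items():
        intensity += fraction * comps[env].evaluate(grid)
    return Spectrum(grid, intensity / intensity.max(),
                    ("simulated", "max-normalized"))


def pcl_theoretical_profile() -> CompositionProfile:
    """Stoichiometric carbon-environment profile of the poly(e-caprolactone)
    repeat unit -(CH2)5-C(O)O-.

    Six carbons per repeat: three plain CH2 (CHx), the CH2 alpha to the
    carbonyl (C-C(O)O), the ester-oxygen-bound CH2 (C-O, carried in the C-OH
    slot at 286.5 eV), and the ester carbon itself (carried in the COOH slot
    at 289.0 eV). Elements per repeat: C6 H10 O2.
    """
    return CompositionProfile(
        env_fractions={"CHx": 3 / 6, "C-C(O)O": 1 / 6,
                       "C-OH": 1 / 6, "COOH": 1 / 6},
        elements={"C": 6.0, "H": 10.0, "N": 0.0, "O": 2.0, "S": 0.0},
        be_overrides={"C-OH": 286.5, "COOH": 289.0},
    )
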