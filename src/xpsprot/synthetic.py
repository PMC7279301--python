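"""Synthetic measurement generator: the whole pipeline's test bench.

A scenario states a substrate (a stoichiometric PCL preset, a plasma-polymer
preset, or any composition profile), a packaged protein fixture, a true
mixing fraction, a peak count level, an additive Shirley-like step
background, an optional binding-energy miscalibration and a noise model.
:func:`generate_measurement` turns it into a raw-looking spectrum plus a
truth sidecar recording every knob, so downstream estimates are always
testable as estimator-versus-truth. Nothing generated here is ever compared
against a published figure.

Counting noise is Poisson by default, the physical model for pulse-counting
detectors; a Gaussian option with the same variance is available.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .composition import CompositionProfile, composition_profile, \
    packaged_sequence
from .mixture import mix_spectra
from .spectrum import Spectrum, energy_grid
from .synthesis import ComponentTable, DEFAULT_COMPONENT_TABLE, \
    pcl_theoretical_profile, simulate_protein_spectrum

SUBSTRATE_PRESETS = ("pcl", "pcl-cooh")


def pcl_cooh_preset_profile() -> CompositionProfile:
    """Plausible composition of the carboxyl-rich plasma-polymer coating.

    Component positions follow the substrate's fitted C1s model (aliphatic
    CHx at 285.0 eV, C-O at 286.5 eV, ketone/acetal C=O at 287.4 eV, acid/
    ester C(O)O at 289.0 eV); the fractional weights are package constants —
    a plasma polymer has no stoichiometry to derive them from. The ketone
    C=O rides in the N-C=O slot with a binding-energy override.
    """
    return CompositionProfile(
        env_fractions={"CHx": 0.55, "C-OH": 0.20, "N-C=O": 0.10,
                       "COOH": 0.15},
        elements={"C": 72.3, "H": 0.0, "N": 0.3, "O": 27.5, "S": 0.0},
        be_overrides={"C-OH": 286.5, "N-C=O": 287.4, "COOH": 289.0},
    )


def substrate_profile(preset: str) -> CompositionProfile:
    if preset == "pcl":
        return pcl_theoretical_profile()
    if preset == "pcl-cooh":
        return pcl_cooh_preset_profile()
    raise KeyError(f"unknown substrate preset {preset!r}; available: "
                   f"{SUBSTRATE_PRESETS}")


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully stated synthetic measurement."""

    substrate: str | CompositionProfile = "pcl-cooh"
    protein_fixture: str = "apoa1"
    x_true: float = 0.13
    peak_counts: float = 1e4
    background_height: float = 0.0      # fraction of the peak count level
    be_offset: float = 0.0              # eV, applied to the final grid
    noise: str | None = "poisson"       # "poisson", "gaussian" or None
    seed: int | None = None
    grid_lo: float = 280.0
    grid_hi: float = 294.0
    grid_step: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.x_true <= 1.0:
            raise ValueError(f"x_true={self.x_true} outside [0, 1]")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        if self.noise not in (None, "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise is not None and self.seed is None:
            raise ValueError("a seed is mandatory whenever noise is active")
        if isinstance(self.substrate, str):
            substrate_profile(self.substrate)   # rejects unknown presets


def generate_measurement(scenario: SyntheticScenario,
                         table: ComponentTable = DEFAULT_COMPONENT_TABLE,
                         ) -> tuple[Spectrum, dict]:
    """Generate a raw-like measured spectrum and its truth sidecar.

    Pipeline: simulate substrate and protein spectra, mix at ``x_true``,
    scale to ``peak_counts``, add a Shirley-like step background (height a
    stated fraction of the peak level, shape the running integral of the
    signal), add counting noise, then rigidly shift the grid by
    ``be_offset``. Deterministic given the seed.
    """
    grid = energy_grid(scenario.grid_lo, scenario.grid_hi, scenario.grid_step)
    sub_profile = (substrate_profile(scenario.substrate)
                   if isinstance(scenario.substrate, str)
                   else scenario.substrate)
    sub = simulate_protein_spectrum(sub_profile, table, grid)
    prot_seq = packaged_sequence(scenario.protein_fixture)
    prot = simulate_protein_spectrum(composition_profile(prot_seq),
                                     table, grid)
    mixed = mix_spectra(sub, prot, scenario.x_true)

    signal = mixed.intensity * scenario.peak_counts
    steps = ["synthetic", f"mixed(x={scenario.x_true:g})",
             f"scaled(peak={scenario.peak_counts:g})"]
    if scenario.background_height > 0:
        cum = cumulative_trapezoid(signal, grid, initial=0.0)
        signal = signal + scenario.background_height * scenario.peak_counts \
            * cum / cum[-1]
        steps.append(f"background(step={scenario.background_height:g})")
    if scenario.noise is not None:
        rng = np.random.default_rng(scenario.seed)
        if scenario.noise == "poisson":
            signal = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
        else:
            signal = signal + rng.normal(0.0, np.sqrt(
                np.clip(signal, 0.0, None)))
        steps.append(f"noise({scenario.noise},seed={scenario.seed})")
    out_grid = grid + scenario.be_offset
    if scenario.be_offset:
        steps.append(f"be-offset({scenario.be_offset:+g} eV)")

    truth = {k: v for k, v in asdict(scenario).items()
             if not isinstance(v, CompositionProfile)}
    if not isinstance(scenario.substrate, str):
        truth["substrate"] = "custom-profile"
    return Spectrum(out_grid, signal, tuple(steps)), truth
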