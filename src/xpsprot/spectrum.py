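"""The Spectrum container and spectrum file I/O.

A spectrum is a strictly increasing binding-energy grid (eV), an intensity
array of equal length, and an ordered provenance tuple recording every
processing step applied. Storage order is ascending binding energy; plotting
in the descending-BE XPS convention is a display concern only.

Canonical on-disk format is two-column CSV (binding energy in eV, intensity)
with optional ``#`` comment lines; a read-only importer for tab-separated
CasaXPS ASCII exports is provided as well.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Spectrum:
    energy: np.ndarray          # binding energy, eV, strictly increasing
    intensity: np.ndarray       # counts or normalized units
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        e = np.asarray(self.energy, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "intensity", i)
        if e.ndim != 1 or e.shape != i.shape:
            raise ValueError("energy and intensity must be equal-length 1-D")
        if e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")

    def with_step(self, step: str, intensity=None, energy=None) -> "Spectrum":
        """Copy with a provenance step appended (and optionally new data)."""
        return Spectrum(
            self.energy if energy is None else energy,
            self.intensity if intensity is None else intensity,
            self.provenance + (step,),
        )

    def __len__(self) -> int:
        return self.energy.size


def energy_grid(lo: float = 280.0, hi: float = 294.0,
                step: float = 0.05) -> np.ndarray:
    """Default ascending binding-energy grid."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def same_grid(a: Spectrum, b: Spectrum, tol: float = 1e-9) -> bool:
    return a.energy.shape == b.energy.shape and np.allclose(
        a.energy, b.energy, atol=tol, rtol=0.0)


def resample(spec: Spectrum, target_grid) -> Spectrum:
    """Linear interpolation onto *target_grid* (no extrapolation)."""
    grid = np.asarray(target_grid, dtype=float)
    if grid.min() < spec.energy[0] - 1e-12 or grid.max() > spec.energy[-1] + 1e-12:
        raise ValueError(
            f"target grid [{grid.min():g}, {grid.max():g}] eV extends outside "
            f"the source span [{spec.energy[0]:g}, {spec.energy[-1]:g}] eV; "
            "extrapolation is not supported")
    out = np.interp(grid, spec.energy, spec.intensity)
    return Spectrum(grid, out, spec.provenance + ("resampled",))


def normalize_max(spec: Spectrum) -> Spectrum:
    """Scale so the maximum intensity is exactly 1."""
    m = spec.intensity.max()
    if m <= 0:
        raise ValueError("cannot max-normalize a spectrum with max <= 0")
    if m == 1.0:
        scaled = spec.intensity
    else:
        scaled = spec.intensity / m
    return spec.with_step("normalized", intensity=scaled)


def read_spectrum_csv(path) -> Spectrum:
    """Read the canonical two-column CSV (BE_eV, intensity)."""
    df = pd.read_csv(path, comment="#", header=None, names=["be", "i"],
                     skip_blank_lines=True)
    df = df.apply(pd.to_numeric, errors="coerce").dropna()
    if df.empty:
        raise ValueError(f"{path}: no numeric two-column data found")
    df = df.sort_values("be")
    return Spectrum(df["be"].to_numpy(), df["i"].to_numpy(),
                    (f"read:{path}",))


def write_spectrum_csv(path, spec: Spectrum, comment: str | None = None):
    with open(path, "w") as fh:
        prov = ";".join(spec.provenance)
        fh.write(f"# xpsprot spectrum; provenance: {prov}\n")
        if comment:
            fh.write(f"# {comment}\n")
        for e, i in zip(spec.energy, spec.intensity):
            fh.write(f"{e:.6g},{i:.10g}\n")


def read_casaxps_ascii(path) -> Spectrum:
    """Read a tab-separated CasaXPS ASCII export (header row, first two
    numeric columns taken as BE and intensity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    num = df.apply(pd.to_numeric, errors="coerce").dropna(axis=1, how="all")
    num = num.dropna()
    if num.shape[1] < 2:
        raise ValueError(f"{path}: fewer than two numeric columns")
    be, inten = num.iloc[:, 0].to_numpy(), num.iloc[:, 1].to_numpy()
    order = np.argsort(be)
    return Spectrum(be[order], inten[order], (f"read-casaxps:{path}",))


__all__ = [
    "Spectrum", "energy_grid", "same_grid", "resample", "normalize_max",
    "read_spectrum_csv", "write_spectrum_csv", "read_casaxps_ascii",
    "replace",
]
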