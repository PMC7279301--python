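"""Preparation of experimental spectra: Shirley background subtraction,
binding-energy calibration, resampling and normalization.

The Shirley background at a given binding energy is proportional to the
integrated peak area on the high-kinetic-energy (low binding-energy) side,
reflecting photoelectrons that lost energy inelastically on the way out; the
background therefore steps up across a peak toward high binding energy. The
standard fixed-point iteration is used: starting from a straight line
between the window endpoints, the background is recomputed from the current
background-subtracted signal until it stops changing.

Calibration follows XPS convention: the dominant (aliphatic CHx) peak apex,
located by parabolic interpolation through the three points around the grid
maximum, is rigidly shifted to a reference binding energy of 285.0 eV.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .spectrum import Spectrum, normalize_max, resample

__all__ = ["ShirleyResult", "shirley_background", "calibrate_energy",
           "resample", "normalize_max"]


@dataclass(frozen=True)
class ShirleyResult:
    background: np.ndarray      # on the corrected spectrum's grid
    corrected: Spectrum
    iterations_used: int
    converged: bool
    negative_fraction: float    # share of corrected points below zero


def shirley_background(spec: Spectrum, window_lo: float, window_hi: float, *,
                       tol: float = 1e-6, max_iter: int = 50,
                       endpoint_halfwidth: float = 0.2,
                       clip_negative: bool = False) -> ShirleyResult:
    """Iterative Shirley background over [window_lo, window_hi].

    Endpoint levels are the mean intensity within ``endpoint_halfwidth`` eV
    of each window edge, which suppresses noise in the anchor points.
    Non-convergence is reported via ``converged=False``, never silently.
    Negative corrected intensities are kept (and counted in
    ``negative_fraction``) unless ``clip_negative`` is set, so later
    max-normalization is not biased.
    """
    e, inten = spec.energy, spec.intensity
    if window_lo < e[0] - 1e-9 or window_hi > e[-1] + 1e-9 or window_lo >= window_hi:
        raise ValueError(f"window [{window_lo}, {window_hi}] eV not inside "
                         f"the grid span [{e[0]:g}, {e[-1]:g}] eV")
    sel = (e >= window_lo - 1e-9) & (e <= window_hi + 1e-9)
    e, inten = e[sel], inten[sel]
    lo_level = inten[np.abs(e - e[0]) <= endpoint_halfwidth].mean()
    hi_level = inten[np.abs(e - e[-1]) <= endpoint_halfwidth].mean()

    background = np.linspace(lo_level, hi_level, e.size)
    converged = False
    iterations = 0
    scale = max(np.abs(inten).max(), 1e-300)
    for iterations in range(1, max_iter + 1):
        area = cumulative_trapezoid(inten - background, e, initial=0.0)
        total = area[-1]
        if abs(total) < 1e-300:
            new = np.full_like(background, lo_level)
        else:
            new = lo_level + (hi_level - lo_level) * area / total
        delta = np.abs(new - background).max() / scale
        background = new
        if delta < tol:
            converged = True
            break

    corrected_i = inten - background
    neg = float(np.mean(corrected_i < 0))
    if clip_negative:
        corrected_i = np.clip(corrected_i, 0.0, None)
    corrected = Spectrum(e, corrected_i, spec.provenance + ("shirley",))
    return ShirleyResult(background, corrected, iterations, converged, neg)


def calibrate_energy(spec: Spectrum,
                     reference_be: float = 285.0) -> Spectrum:
    """Rigidly shift the grid so the main-peak apex sits at *reference_be*.

    The apex is located by fitting a parabola through the grid maximum and
    its two neighbours; a spectrum with no interior maximum (flat, or apex
    on the grid edge) is rejected.
    """
    inten = spec.intensity
    span = inten.max() - inten.min()
    if span <= 1e-12 * max(abs(inten.max()), 1.0):
        raise ValueError("spectrum is flat; no apex to calibrate on")
    idx = int(np.argmax(inten))
    if idx == 0 or idx == inten.size - 1:
        raise ValueError("main peak apex lies on the grid edge; widen the "
                         "acquisition window before calibrating")
    x = spec.energy[idx - 1:idx + 2]
    y = inten[idx - 1:idx + 2]
    a, b, _ = np.polyfit(x, y, 2)
    apex = spec.energy[idx] if a == 0 else -b / (2.0 * a)
    shift = reference_be - apex
    return spec.with_step(f"calibrated(shift={shift:+.4f} eV)",
                          energy=spec.energy + shift)
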