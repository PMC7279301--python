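"""Two-component spectral mixture fit for protein surface coverage.

A protein-bearing surface's C1s spectrum is modelled as a convex combination
of the bare-substrate spectrum and the simulated protein spectrum::

    S_model(E; x) = (1 - x) * S_substrate(E) + x * S_protein(E)

with both inputs max-normalized on a common binding-energy grid. The
coverage x is the mixing fraction that makes the model most similar to the
measured spectrum. Because the objective is one-dimensional and cheap, it is
scanned exhaustively over [0, 1] — the full objective curve doubles as a
diagnostic for weak identifiability — and the minimum is then refined by a
bounded scalar search inside the bracketing interval.

The estimator follows the scikit-learn protocol (``fit`` / fitted
attributes with trailing underscores / ``get_params``), so it composes with
sklearn tooling; :func:`fit_coverage` is the equivalent functional surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .composition import present_percent
from .spectrum import Spectrum, normalize_max, resample, same_grid


def _rmse(model: np.ndarray, measured: np.ndarray) -> float:
    return float(np.sqrt(np.mean((model - measured) ** 2)))


def _sse(model: np.ndarray, measured: np.ndarray) -> float:
    return float(np.sum((model - measured) ** 2))


def _max_abs(model: np.ndarray, measured: np.ndarray) -> float:
    return float(np.abs(model - measured).max())


OBJECTIVES = {"rmse": _rmse, "sse": _sse, "max_abs": _max_abs}


def _check_normalized(spec: Spectrum, name: str):
    if abs(spec.intensity.max() - 1.0) > 1e-6:
        raise ValueError(f"{name} spectrum is not max-normalized "
                         f"(max = {spec.intensity.max():g}); apply "
                         "normalize_max first")


def mix_spectra(substrate: Spectrum, protein: Spectrum,
                x: float) -> Spectrum:
    """Pointwise (1-x)*substrate + x*protein on a common grid."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"mixing fraction x={x} outside [0, 1]")
    if not same_grid(substrate, protein):
        raise ValueError("substrate and protein spectra are on different "
                         "grids; resample onto a common grid first")
    _check_normalized(substrate, "substrate")
    _check_normalized(protein, "protein")
    mixed = (1.0 - x) * substrate.intensity + x * protein.intensity
    return Spectrum(substrate.energy, mixed, (f"mixed(x={x:g})",))


@dataclass(frozen=True)
class MixtureFitResult:
    x_hat: float
    x_percent: str
    objective_name: str
    objective_curve: np.ndarray     # shape (n, 2): columns x, objective
    residual_spectrum: Spectrum
    rmse: float
    r_squared: float
    max_abs_dev: float
    weakly_identified: bool


class CoverageEstimator(BaseEstimator):
    """Estimate the protein mixing fraction x of a measured C1s spectrum.

    Parameters
    ----------
    substrate, protein : Spectrum
        Max-normalized spectra on a common grid (the measured spectrum is
        resampled onto it at fit time).
    step : float, default 0.0025
        Scan step for the exhaustive x grid over [0, 1].
    objective : str, default "rmse"
        One of ``rmse``, ``sse``, ``max_abs``.
    renormalize_model : bool, default True
        Re-max-normalize the mixed model before comparison, mirroring the
        convention that all compared spectra are normalized to their maxima.
    flat_tolerance : float, default 0.01
        Fraction of the objective's dynamic range below which a scan point
        counts as "at the minimum"; if >= 20% of the scan is that flat the
        fit is flagged weakly identified.

    Attributes
    ----------
    x_ : float
        Estimated mixing fraction.
    objective_curve_ : ndarray of shape (n, 2)
        The scanned (x, objective) pairs.
    result_ : MixtureFitResult
        Full diagnostics, including the residual spectrum at ``x_``.
    """

    def __init__(self, substrate: Spectrum = None, protein: Spectrum = None,
                 step: float = 0.0025, objective: str = "rmse",
                 renormalize_model: bool = True,
                 flat_tolerance: float = 0.01):
        self.substrate = substrate
        self.protein = protein
        self.step = step
        self.objective = objective
        self.renormalize_model = renormalize_model
        self.flat_tolerance = flat_tolerance

    # -- internals --------------------------------------------------------

    def _objective_fn(self, measured: np.ndarray):
        sub = self.substrate.intensity
        prot = self.protein.intensity
        obj = OBJECTIVES[self.objective]

        def fn(x: float) -> float:
            model = (1.0 - x) * sub + x * prot
            if self.renormalize_model:
                model = model / model.max()
            return obj(model, measured)

        return fn

    def _validate(self, measured: Spectrum) -> Spectrum:
        if self.substrate is None or self.protein is None:
            raise ValueError("substrate and protein spectra are required")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}; "
                             f"choose from {sorted(OBJECTIVES)}")
        if not same_grid(self.substrate, self.protein):
            raise ValueError("substrate and protein spectra are on "
                             "different grids; resample first")
        grid = self.substrate.energy
        if measured.energy[0] > grid[0] + 1e-9 or \
                measured.energy[-1] < grid[-1] - 1e-9:
            raise ValueError(
                "measured spectrum does not cover the model grid "
                f"[{grid[0]:g}, {grid[-1]:g}] eV; no usable overlap")
        _check_normalized(self.substrate, "substrate")
        _check_normalized(self.protein, "protein")
        if not same_grid(measured, self.substrate):
            measured = resample(measured, grid)
        return normalize_max(measured)

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X: Spectrum, y=None) -> "CoverageEstimator":
        """Fit the mixing fraction to the measured spectrum *X*."""
        measured = self._validate(X)
        fn = self._objective_fn(measured.intensity)

        xs = np.arange(0.0, 1.0 + self.step / 2, self.step)
        xs[-1] = min(xs[-1], 1.0)
        objs = np.array([fn(x) for x in xs])
        i = int(np.argmin(objs))

        lo = max(0.0, xs[i] - 2 * self.step)
        hi = min(1.0, xs[i] + 2 * self.step)
        res = minimize_scalar(fn, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        x_hat = float(res.x) if res.fun <= objs[i] else float(xs[i])

        dyn = objs.max() - objs.min()
        # absolute floor so a numerically-flat curve (identical components)
        # is flagged rather than resolved by float noise
        flat = float(np.mean(objs <= objs.min()
                             + self.flat_tolerance * dyn + 1e-12))
        weak = flat >= 0.20

        model = (1.0 - x_hat) * self.substrate.intensity \
            + x_hat * self.protein.intensity
        if self.renormalize_model:
            model = model / model.max()
        resid = measured.intensity - model
        ss_tot = float(np.sum((measured.intensity
                               - measured.intensity.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan

        self.x_ = x_hat
        self.objective_curve_ = np.column_stack([xs, objs])
        self.measured_ = measured
        self.result_ = MixtureFitResult(
            x_hat=x_hat,
            x_percent=present_percent(100.0 * x_hat),
            objective_name=self.objective,
            objective_curve=self.objective_curve_,
            residual_spectrum=Spectrum(self.substrate.energy, resid,
                                       measured.provenance + ("residual",)),
            rmse=_rmse(model, measured.intensity),
            r_squared=r2,
            max_abs_dev=_max_abs(model, measured.intensity),
            weakly_identified=weak,
        )
        return self

    def predict(self, X: Spectrum | None = None) -> float:
        """Return the fitted mixing fraction (fits *X* first if given)."""
        if X is not None:
            self.fit(X)
        if not hasattr(self, "x_"):
            raise ValueError("estimator is not fitted yet")
        return self.x_


def fit_coverage(substrate: Spectrum, protein: Spectrum, measured: Spectrum,
                 x_grid_step: float = 0.0025, *, objective: str = "rmse",
                 renormalize_model: bool = True) -> MixtureFitResult:
    """Functional wrapper around :class:`CoverageEstimator`."""
    est = CoverageEstimator(substrate=substrate, protein=protein,
                            step=x_grid_step, objective=objective,
                            renormalize_model=renormalize_model)
    return est.fit(measured).result_


def coverage_increase(x_a: float, x_b: float) -> float:
    """Relative increase in coverage, in percent: 100 * (x_b - x_a) / x_a."""
    if x_a <= 0:
        raise ValueError("reference coverage x_a must be positive")
    return 100.0 * (x_b - x_a) / x_a
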