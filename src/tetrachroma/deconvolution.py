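"""Non-negative spectral unmixing of oil-droplet absorbance spectra.

A measured C-type droplet absorbance trace is modelled as an additive
mixture of unit-peak pure carotenoid spectra; absorbances add, so the
component weights are constrained non-negative and solved by NNLS.
Because the library is peak-normalized, the reported proportions are in
spectrum units, not molar concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectral_core import Spectrum, resample
from .synthetic import PureLibrary

__all__ = ["MixtureFit", "fit_mixture", "proportions_summary", "DEFAULT_WINDOW"]

#: Default fitting window (nm); below 350 nm instrument noise dominates.
DEFAULT_WINDOW = (350.0, 700.0)

_CONDITION_WARN = 1.0e6


@dataclass(frozen=True)
class MixtureFit:
    """NNLS solution for one droplet observation."""

    component_names: tuple[str, ...]
    weights: np.ndarray
    fitted: Spectrum
    r_squared: float
    residual_rms: float

    @property
    def proportions(self) -> np.ndarray:
        total = self.weights.sum()
        if total == 0:
            return np.zeros_like(self.weights)
        return self.weights / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.component_names))


def fit_mixture(
    observed: Spectrum,
    library: PureLibrary,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> MixtureFit:
    """Best additive non-negative combination of library spectra.

    Minimizes Σ(observed − Σ wⱼ·pureⱼ)² over the fitting window;
    r² = 1 − SS_res/SS_tot.  Warns if the library is nearly collinear on
    the window.
    """
    if observed.grid != library.grid:
        observed = resample(observed, library.grid)
    if not np.any(observed.values > 0):
        raise ValueError("all-zero observed spectrum cannot be unmixed")
    lam = library.grid.wavelengths
    mask = (lam >= window[0]) & (lam <= window[1])
    if mask.sum() < len(library.names):
        raise ValueError("fitting window contains too few samples")
    A = library.matrix()[mask]
    cond = np.linalg.cond(A)
    if cond > _CONDITION_WARN:
        warnings.warn(
            f"pure-spectrum library nearly collinear on window {window} "
            f"(condition number {cond:.2g}); weights may be unstable",
            stacklevel=2,
        )
    b = observed.values[mask]
    weights, _ = nnls(A, b)
    fitted_full = library.matrix() @ weights
    resid = b - A @ weights
    ss_res = float(resid @ resid)
    ss_tot = float(((b - b.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return MixtureFit(
        component_names=library.names,
        weights=weights,
        fitted=Spectrum(library.grid, fitted_full),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        residual_rms=float(np.sqrt(ss_res / mask.sum())),
    )


def proportions_summary(fits: list[MixtureFit]) -> pd.DataFrame:
    """Mean and SD of component proportions across droplets.

    Mirrors the per-species composition summaries: one row per library
    component with the mean ± SD proportion over all fitted droplets.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    names = fits[0].component_names
    if any(f.component_names != names for f in fits):
        raise ValueError("fits use different component libraries")
    P = np.vstack([f.proportions for f in fits])
    return pd.DataFrame({
        "component": list(names),
        "mean_proportion": P.mean(axis=0),
        "sd_proportion": P.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(len(names)),
        "n_droplets": len(fits),
    })
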