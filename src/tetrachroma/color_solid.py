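"""Object-color solids and discriminable-color counts for tetrachromats.

The object-color solid is the convex body of normalized quantum-catch
vectors x achievable by reflectances bounded in [0, 1].  Its boundary is
generated by *optimal color stimuli*: binary reflectance spectra with at
most n−1 transitions (n = number of receptor classes).  Receptor noise
defines a local confusion volume u = c·∏δQᵢ, and the number of
discriminable colors is N = ∫ u⁻¹ ∏dQᵢ over the solid.

Three illumination regimes select the noise law:

=========  =====================  ===========================================
regime     δQᵢ                    shape-factor integrand (x-coordinates)
=========  =====================  ===========================================
very dim   dᵢ (dark noise)        1
dim        √Qᵢ (shot noise)       ∏ xᵢ^(−1/2)
bright     √(Qᵢ + ωᵢ²Qᵢ²)         ∏ (xᵢ + ωᵢ²·T·kᵢ·xᵢ²)^(−1/2)
=========  =====================  ===========================================

With Qᵢ = T·kᵢ·xᵢ the count reduces to

* very dim: N = Tⁿ·G·∏kᵢ / (c·∏dᵢ)
* dim:      N = (1/c)·T^(n/2)·G·∏√kᵢ
* bright:   N = (1/c)·T^(n/2)·G_bright(T)·∏√kᵢ

where G is the regime's shape-factor integral over the solid.  The shape
factors are estimated by Monte Carlo after the substitution xᵢ = yᵢ²,
which renders every integrand bounded (see docs/methods.md), using
bounding-box rejection against the solid's convex hull in y-space.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .spectral_core import (
    ReceptorSpec,
    Spectrum,
    WavelengthGrid,
    receptor_sensitivity,
)

__all__ = [
    "NoiseRegime",
    "VisualSystem",
    "ColorSolid",
    "SolidResult",
    "DEFAULT_WEBER",
    "DEFAULT_DARK_NOISE",
    "LWS_WHITE_CATCH",
    "quantum_catch",
    "normalize_receptors",
    "optimal_color_stimuli",
    "build_color_solid",
    "receptor_noise",
    "membership_samples",
    "shape_factor",
    "shape_factor_from_samples",
    "discriminable_colors",
    "count_colors_qspace",
]


class NoiseRegime(enum.Enum):
    """Illumination regime selecting the dominant receptor-noise source."""

    BRIGHT = "bright"
    DIM = "dim"
    VERY_DIM = "very_dim"


#: Solid-model Weber fractions for SWS1:SWS2:MWS:LWS in bright light.
DEFAULT_WEBER = (0.2, 0.14, 0.14, 0.1)

#: Dark-noise events per integration time, identical for every cone.
DEFAULT_DARK_NOISE = (50.0, 50.0, 50.0, 50.0)

#: Illumination calibration: quantum catch of the LWS cone for the ideal
#: white surface, per regime (photons per integration time).  With
#: k_LWS normalized to 1 this is exactly the intensity scale T.
LWS_WHITE_CATCH = {
    NoiseRegime.BRIGHT: 1.0e5,
    NoiseRegime.DIM: 100.0,
    NoiseRegime.VERY_DIM: 10.0,
}


@dataclass(frozen=True)
class VisualSystem:
    """A set of receptor sensitivities plus illuminant and noise parameters.

    Receptors are ordered shortest- to longest-wavelength sensitive
    (SWS1, SWS2, MWS, LWS for the avian tetrachromat); quantum
    efficiencies are normalized to the last (LWS) receptor.
    """

    sensitivities: tuple[Spectrum, ...]
    illuminant: Spectrum
    names: tuple[str, ...] = ()
    weber: tuple[float, ...] = DEFAULT_WEBER
    dark_noise: tuple[float, ...] = DEFAULT_DARK_NOISE
    c_const: float = 1.0  # threshold constant; N is defined up to 1/c

    def __post_init__(self) -> None:
        n = len(self.sensitivities)
        if not self.names:
            object.__setattr__(self, "names", tuple(f"R{i}" for i in range(n)))
        if len(self.weber) != n or len(self.dark_noise) != n:
            raise ValueError("weber/dark_noise length must match receptor count")
        if any(w <= 0 for w in self.weber) or any(d <= 0 for d in self.dark_noise):
            raise ValueError("weber fractions and dark noise must be positive")
        grid = self.illuminant.grid
        if any(s.grid != grid for s in self.sensitivities):
            raise ValueError("all sensitivities must share the illuminant grid")
        jmax = self.illuminant.values.max()
        if not math.isclose(jmax, 1.0, rel_tol=1e-6):
            object.__setattr__(
                self, "illuminant", Spectrum(grid, self.illuminant.values / jmax)
            )

    @property
    def n_receptors(self) -> int:
        return len(self.sensitivities)

    @property
    def grid(self) -> WavelengthGrid:
        return self.illuminant.grid

    @classmethod
    def from_receptors(
        cls,
        receptors: Sequence[ReceptorSpec],
        illuminant: Spectrum,
        **kwargs,
    ) -> "VisualSystem":
        sens = tuple(receptor_sensitivity(r, illuminant.grid) for r in receptors)
        names = tuple(r.name for r in receptors)
        return cls(sensitivities=sens, illuminant=illuminant, names=names, **kwargs)


def quantum_catch(R: Spectrum, S: Spectrum, I: Spectrum) -> float:
    """Q = ∫ R(λ)·S(λ)·I(λ) dλ (trapezoid rule; common grid required)."""
    return (R * S * I).integral()


def normalize_receptors(
    sensitivities: Sequence[Spectrum], illuminant: Spectrum
) -> tuple[np.ndarray, list[Spectrum]]:
    """Quantum efficiencies kᵢ = ∫Rᵢ·j dλ and normalized rᵢ = Rᵢ/kᵢ.

    Returns k rescaled so the last (LWS) receptor has k = 1, and the
    r spectra, which satisfy ∫ rᵢ·j dλ = 1 for every receptor.
    """
    k_raw = np.array([(R * illuminant).integral() for R in sensitivities])
    if np.any(k_raw <= 0):
        blind = [i for i, k in enumerate(k_raw) if k <= 0]
        raise ValueError(f"receptor(s) {blind} catch no light from the illuminant")
    r = [Spectrum(R.grid, R.values / k) for R, k in zip(sensitivities, k_raw)]
    return k_raw / k_raw[-1], r


def optimal_color_stimuli(n_bins: int, max_transitions: int) -> np.ndarray:
    """All binary step reflectances with at most ``max_transitions`` steps.

    Returns a boolean array of shape (n_spectra, n_bins) containing every
    0/1 pattern over the bins with ≤ max_transitions value changes, for
    both starting values.  Includes the ideal black (all 0) and ideal
    white (all 1) surfaces.  Count = Σ_{t≤max} 2·C(n_bins−1, t).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if max_transitions < 0:
        raise ValueError("max_transitions must be >= 0")
    patterns = []
    boundaries = range(1, n_bins)  # a transition sits before bin index b
    for t in range(min(max_transitions, n_bins - 1) + 1):
        for cuts in itertools.combinations(boundaries, t):
            flips = np.zeros(n_bins, dtype=int)
            for b in cuts:
                flips[b] = 1
            parity = np.cumsum(flips) % 2
            patterns.append(parity == 0)  # starts at 1
            patterns.append(parity == 1)  # starts at 0
    # each (start value, cut set) pair yields a distinct pattern, so no dedupe
    return np.array(patterns, dtype=bool)


def _zonotope_slabs(B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact half-space (slab) representation of the zonotope Σ_b [0, g_b].

    Every facet of a d-dimensional zonotope has a normal orthogonal to
    d−1 of its generators; for each (d−1)-subset of generator columns of
    B we take the unit normal u of their span and the support offsets
    h⁻(u) = Σ_b min(u·g_b, 0), h⁺(u) = Σ_b max(u·g_b, 0).  x lies in the
    solid iff h⁻ ≤ u·x ≤ h⁺ for all these normals.  Returns (U, lo, hi).
    """
    d, m = B.shape
    subsets = np.array(list(itertools.combinations(range(m), d - 1)))
    G = B[:, subsets].transpose(1, 0, 2)  # (n_sub, d, d-1)
    # generalized cross product: u_i = (−1)^i · det(G with row i removed)
    U = np.empty((len(subsets), d))
    rows = np.arange(d)
    for i in range(d):
        minor = G[:, rows != i, :]  # (n_sub, d-1, d-1)
        U[:, i] = ((-1.0) ** i) * np.linalg.det(minor)
    norms = np.linalg.norm(U, axis=1)
    scale = np.linalg.norm(B, axis=0)[subsets].prod(axis=1)  # size of the subset
    keep = norms > 1e-12 * np.maximum(scale, 1e-300)
    if not np.any(keep):
        raise ValueError("degenerate zonotope: no full-rank generator subsets")
    # rank-deficient subsets are dropped: every facet also has a
    # full-rank parallel subset, so no facet normal is lost
    U = U[keep] / norms[keep, None]
    # canonical sign so duplicates collapse
    first_nz = np.argmax(np.abs(U) > 1e-12, axis=1)
    signs = np.sign(U[np.arange(len(U)), first_nz])
    normals = U * signs[:, None]
    U = np.unique(np.round(np.array(normals), 12), axis=0)
    P = U @ B  # (n_normals, m) projections of every generator
    lo = np.minimum(P, 0.0).sum(axis=1)
    hi = np.maximum(P, 0.0).sum(axis=1)
    return U, lo, hi


@dataclass(frozen=True)
class ColorSolid:
    """The object-color solid: a zonotope in normalized-catch coordinates.

    Held as its generator matrix (per-transition-bin catch increments),
    the exact facet slab representation used for membership tests, and
    the images of the optimal color stimuli (its extreme-point
    candidates).  The scipy convex hull is built lazily when the
    ``hull``/``volume`` properties are first used.
    """

    generators: np.ndarray  # (n, n_bins) per-bin catch contributions
    extreme_points: np.ndarray  # (n_candidates, n) images of optimal stimuli
    k_factors: np.ndarray  # quantum efficiencies, k[-1] == 1
    resolution: float  # transition-grid step (nm)
    slab_normals: np.ndarray  # (n_facets, n)
    slab_lo: np.ndarray
    slab_hi: np.ndarray

    @property
    def n_dim(self) -> int:
        return self.extreme_points.shape[1]

    @property
    def x_max(self) -> np.ndarray:
        return self.generators.sum(axis=1)  # the white point

    @property
    def hull(self) -> ConvexHull:
        cached = self.__dict__.get("_hull")
        if cached is None:
            try:
                cached = ConvexHull(self.extreme_points, qhull_options="QJ")
            except QhullError as exc:
                raise ValueError(f"degenerate color solid: {exc}") from exc
            object.__setattr__(self, "_hull", cached)
        return cached

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Membership test against the exact facet slabs, x of shape (m, n)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        inside = np.ones(x.shape[0], dtype=bool)
        U, lo, hi = self.slab_normals, self.slab_lo, self.slab_hi
        chunk = max(1, int(4e6 / max(1, U.shape[0])))
        for start in range(0, x.shape[0], chunk):
            d = x[start : start + chunk] @ U.T
            inside[start : start + chunk] = (
                (d >= lo - tol) & (d <= hi + tol)
            ).all(axis=1)
        return inside


def _bin_weights(
    r_spectra: Sequence[Spectrum], illuminant: Spectrum, resolution: float
) -> np.ndarray:
    """Per-bin contributions B[i, b] = ∫_bin rᵢ(λ)·j(λ) dλ.

    Bins partition the grid span into contiguous intervals of width
    ``resolution`` (the transition grid); a binary reflectance pattern p
    then maps to x = B @ p.
    """
    grid = illuminant.grid
    w = grid.wavelengths
    edges = np.arange(grid.min_nm, grid.max_nm + resolution / 2, resolution)
    if edges[-1] < grid.max_nm - 1e-9:
        edges = np.append(edges, grid.max_nm)
    n_bins = len(edges) - 1
    B = np.zeros((len(r_spectra), n_bins))
    for i, r in enumerate(r_spectra):
        integrand = r.values * illuminant.values
        for b in range(n_bins):
            mask = (w >= edges[b] - 1e-9) & (w <= edges[b + 1] + 1e-9)
            B[i, b] = np.trapezoid(integrand[mask], w[mask])
    return B


def build_color_solid(
    system: VisualSystem,
    resolution: float = 4.0,
    max_transitions: int | None = None,
) -> ColorSolid:
    """Construct the object-color solid of ``system``.

    ``resolution`` is the transition-grid step in nm (binary reflectance
    transitions are restricted to multiples of it); ``max_transitions``
    defaults to n−1 for an n-receptor system, which suffices to generate
    every extreme point of the solid.
    """
    if resolution < system.grid.step_nm:
        raise ValueError("resolution must be at least the wavelength-grid step")
    n = system.n_receptors
    if max_transitions is None:
        max_transitions = n - 1
    k, r = normalize_receptors(system.sensitivities, system.illuminant)
    B = _bin_weights(r, system.illuminant, resolution)
    if np.linalg.matrix_rank(B) < n:
        raise ValueError(
            "degenerate color solid: receptor sensitivities are linearly "
            "dependent (solid has zero volume)"
        )
    patterns = optimal_color_stimuli(B.shape[1], max_transitions)
    points = patterns.astype(float) @ B.T  # (n_patterns, n)
    U, lo, hi = _zonotope_slabs(B)
    return ColorSolid(
        generators=B,
        extreme_points=points,
        k_factors=k,
        resolution=resolution,
        slab_normals=U,
        slab_lo=lo,
        slab_hi=hi,
    )


def receptor_noise(
    Q: float | np.ndarray,
    regime: NoiseRegime,
    omega: float | np.ndarray = 0.0,
    dark: float | np.ndarray = 50.0,
) -> float | np.ndarray:
    """Receptor noise δQ for quantum catch Q under a given regime."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("quantum catch must be non-negative")
    if regime is NoiseRegime.VERY_DIM:
        out = np.broadcast_to(np.asarray(dark, float), Q.shape).copy()
    elif regime is NoiseRegime.DIM:
        out = np.sqrt(Q)
    else:
        out = np.sqrt(Q + np.asarray(omega, float) ** 2 * Q**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SolidResult:
    """Discriminable-color count for one solid and regime."""

    N: float
    G: float
    mc_error: float  # Monte-Carlo standard error of N
    g_error: float  # Monte-Carlo standard error of G
    n_samples: int
    seed: int
    regime: NoiseRegime
    T: float


def _y_space_integrand(
    y: np.ndarray,
    regime: NoiseRegime,
    omega: np.ndarray,
    T: float,
    k: np.ndarray,
) -> np.ndarray:
    """Shape-factor integrand after the substitution x = y² (Jacobian
    2ⁿ·∏y folded in).  Bounded for every regime."""
    n = y.shape[1]
    if regime is NoiseRegime.VERY_DIM:
        return (2.0**n) * np.prod(y, axis=1)
    if regime is NoiseRegime.DIM:
        return np.full(y.shape[0], 2.0**n)
    scale = omega**2 * T * k  # (n,)
    return np.prod(2.0 / np.sqrt(1.0 + scale[None, :] * y**2), axis=1)


def membership_samples(
    solid: ColorSolid, n_samples: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform samples in the solid's bounding box in y = √x coordinates
    plus their hull-membership flags.  One draw can be shared by the
    shape factors of all three noise regimes (and keeps cross-regime and
    cross-cutoff comparisons paired when the seed is shared)."""
    rng = np.random.default_rng(seed)
    y_max = np.sqrt(solid.x_max)
    y = rng.random((n_samples, solid.n_dim)) * y_max[None, :]
    inside = solid.contains(y**2)
    return y, inside


def shape_factor_from_samples(
    solid: ColorSolid,
    regime: NoiseRegime,
    system: VisualSystem,
    y: np.ndarray,
    inside: np.ndarray,
    T: float | None = None,
) -> tuple[float, float]:
    """Shape factor (G, standard error) from precomputed samples."""
    if T is None:
        T = LWS_WHITE_CATCH[regime]
    n_samples = y.shape[0]
    w = np.zeros(n_samples)
    omega = np.asarray(system.weber, dtype=float)
    w[inside] = _y_space_integrand(y[inside], regime, omega, T, solid.k_factors)
    box = float(np.prod(np.sqrt(solid.x_max)))
    G = box * float(w.mean())
    se = box * float(w.std(ddof=1)) / math.sqrt(n_samples)
    return G, se


def shape_factor(
    solid: ColorSolid,
    regime: NoiseRegime,
    system: VisualSystem,
    n_samples: int = 100_000,
    seed: int = 0,
    T: float | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate (G, standard error) of the shape factor.

    Samples y uniformly in the axis-aligned bounding box of the solid in
    y = √x coordinates and rejects points whose image y² falls outside
    the solid; G = box volume × mean of the transformed integrand.
    """
    y, inside = membership_samples(solid, n_samples, seed)
    return shape_factor_from_samples(solid, regime, system, y, inside, T)


def discriminable_colors(
    system: VisualSystem,
    regime: NoiseRegime,
    solid: ColorSolid | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    T: float | None = None,
    resolution: float = 4.0,
    samples: tuple[np.ndarray, np.ndarray] | None = None,
) -> SolidResult:
    """Number of discriminable colors N for ``system`` under ``regime``.

    The illuminant intensity T defaults to the regime calibration (LWS
    white-surface catch of 1e5 / 100 / 10 photons).  N is defined up to
    the omitted threshold constant c (c = 1 here).  ``samples`` may carry
    a precomputed :func:`membership_samples` draw to share across
    regimes.
    """
    if solid is None:
        solid = build_color_solid(system, resolution=resolution)
    if T is None:
        T = LWS_WHITE_CATCH[regime]
    if samples is None:
        samples = membership_samples(solid, n_samples, seed)
    y, inside = samples
    G, g_se = shape_factor_from_samples(solid, regime, system, y, inside, T=T)
    n = solid.n_dim
    k = solid.k_factors
    c = system.c_const
    if regime is NoiseRegime.VERY_DIM:
        prefactor = T**n * np.prod(k) / (c * np.prod(np.asarray(system.dark_noise)))
    else:  # dim and bright share the T^(n/2)·∏√k prefactor
        prefactor = T ** (n / 2) * np.prod(np.sqrt(k)) / c
    return SolidResult(
        N=float(prefactor * G),
        G=G,
        mc_error=float(prefactor * g_se),
        g_error=g_se,
        n_samples=int(y.shape[0]),
        seed=seed,
        regime=regime,
        T=T,
    )


def count_colors_qspace(
    system: VisualSystem,
    regime: NoiseRegime,
    solid: ColorSolid,
    n_samples: int = 100_000,
    seed: int = 0,
    T: float | None = None,
) -> tuple[float, float]:
    """Independent route: N = ∫ 1/(c·∏δQᵢ) ∏dQᵢ evaluated directly in
    quantum-catch coordinates Q = T·k·x (no shape-factor factorisation).

    Uses the same substitution Qᵢ = zᵢ² with box-rejection sampling; kept
    deliberately separate from :func:`discriminable_colors` so the two
    routes cross-validate the reconstructed radicals.
    """
    if T is None:
        T = LWS_WHITE_CATCH[regime]
    rng = np.random.default_rng(seed)
    k = solid.k_factors
    q_max = T * k * solid.x_max
    z_max = np.sqrt(q_max)
    z = rng.random((n_samples, solid.n_dim)) * z_max[None, :]
    Q = z**2
    inside = solid.contains(Q / (T * k)[None, :])
    omega = np.asarray(system.weber, dtype=float)
    dark = np.asarray(system.dark_noise, dtype=float)
    w = np.zeros(n_samples)
    if np.any(inside):
        Qi = Q[inside]
        zi = z[inside]
        n = solid.n_dim
        if regime is NoiseRegime.VERY_DIM:
            dq_prod = np.prod(dark)
            w[inside] = (2.0**n) * np.prod(zi, axis=1) / dq_prod
        elif regime is NoiseRegime.DIM:
            # δQ = √Q = z, so ∏(2z)/∏δQ = 2^n
            w[inside] = 2.0**n
        else:
            dq = np.sqrt(Qi + omega[None, :] ** 2 * Qi**2)
            w[inside] = np.prod(2.0 * zi, axis=1) / np.prod(dq, axis=1)
    box = float(np.prod(z_max))
    c = system.c_const
    N = box * float(w.mean()) / c
    se = box * float(w.std(ddof=1)) / math.sqrt(n_samples) / c
    return N, se
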