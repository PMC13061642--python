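"""Synthetic confined objects and the scalar forward model.

Objects are modeled as near-field amplitude sources (transmission masks
times illumination) under a scalar-field approximation; oblique TIR
illumination contributes only the in-plane phase ramp ``exp(i k∥·x)``
(thin-object approximation).  Each object spec carries its own
support-aware quadrature so that projections onto the Slepian–Pollak modes
and direct transforms to the band are computed to quadrature accuracy even
for features far smaller than the FOV.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .config import IlluminationConfig, OpticalConfig
from .fields import ComplexField, QuadGrid, RasterGrid, gauss_interval
from .slepian import SlepianBasis, finite_fourier


def _as2d(points: np.ndarray, dim: int) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.ndim == 1:
        p = p[:, None] if dim == 1 else p[None, :]
    return p


class SyntheticObject(ABC):
    """A parametric scattering object with analytic amplitude and quadrature."""

    dim: int = 2
    confined: bool = True
    scale: complex = 1.0 + 0.0j

    @abstractmethod
    def amplitude(self, points: np.ndarray) -> np.ndarray:
        """Complex near-field amplitude at the given points."""

    @abstractmethod
    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """(points, weights) integrating exactly over the object support."""

    @abstractmethod
    def bounding_radius(self) -> float:
        """Radius of a ball (centered at origin) containing the support."""

    def shifted(self, offset) -> "SyntheticObject":
        return _Shifted(self, np.atleast_1d(np.asarray(offset, dtype=float)))

    def energy(self) -> float:
        p, w = self.quadrature()
        return float(np.sum(w * np.abs(self.amplitude(p)) ** 2))

    def energy_inside_fov(self, config: OpticalConfig) -> float:
        p, w = self.quadrature()
        a2 = w * np.abs(self.amplitude(p)) ** 2
        pts = _as2d(p, self.dim)
        if config.dim == 1:
            inside = np.abs(pts[:, 0]) <= config.fov_radius
        elif config.fov_shape == "square":
            inside = np.all(np.abs(pts) <= config.fov_radius, axis=1)
        else:
            inside = np.hypot(pts[:, 0], pts[:, 1]) <= config.fov_radius
        tot = float(np.sum(a2))
        return float(np.sum(a2[inside]) / tot) if tot > 0 else 1.0

    def require_confined(self, config: OpticalConfig, min_fraction: float = 0.999) -> None:
        if not self.confined:
            return
        frac = self.energy_inside_fov(config)
        if frac < min_fraction:
            raise ValueError(
                f"{type(self).__name__} exceeds the FOV: only {frac:.4f} of its "
                f"energy lies inside (bounding radius {self.bounding_radius():.3f}λ "
                f"vs FOV radius {config.fov_radius:.3f}λ)"
            )


@dataclass
class _Shifted(SyntheticObject):
    base: SyntheticObject = None
    offset: np.ndarray = None

    def __post_init__(self):
        self.dim = self.base.dim
        self.confined = self.base.confined
        self.scale = self.base.scale

    def amplitude(self, points):
        p = _as2d(points, self.dim)
        return self.base.amplitude(p - self.offset[None, :])

    def quadrature(self):
        p, w = self.base.quadrature()
        return _as2d(p, self.dim) + self.offset[None, :], w

    def bounding_radius(self):
        return self.base.bounding_radius() + float(np.linalg.norm(self.offset))


@dataclass
class PointSource(SyntheticObject):
    """Unit-weight point scatterer (delta source)."""

    position: Sequence[float] = (0.0, 0.0)
    amplitude_value: complex = 1.0
    dim: int = 2
    confined: bool = True

    def amplitude(self, points):
        raise NotImplementedError("a point source has no pointwise amplitude raster")

    def quadrature(self):
        p = np.atleast_1d(np.asarray(self.position, dtype=float))[: self.dim]
        return p[None, :], np.array([1.0])

    def bounding_radius(self):
        return float(np.linalg.norm(np.asarray(self.position)[: self.dim]))

    def energy(self):
        return abs(self.amplitude_value) ** 2

    def energy_inside_fov(self, config):
        p = np.asarray(self.position, dtype=float)[: config.dim]
        r = float(np.linalg.norm(p)) if config.dim == 2 else abs(float(p[0]))
        return 1.0 if r <= config.fov_radius else 0.0


def _disc_quad(center, radius, nr=24, nt=32):
    tr, wr = np.polynomial.legendre.leggauss(nr)
    r = (tr + 1.0) * 0.5 * radius
    wrad = wr * 0.5 * radius * r
    th = (np.arange(nt) + 0.5) * 2 * np.pi / nt
    R, TH = np.meshgrid(r, th, indexing="ij")
    pts = np.stack([(R * np.cos(TH)).ravel(), (R * np.sin(TH)).ravel()], 1)
    w = np.repeat(wrad * 2 * np.pi / nt, nt)
    return pts + np.asarray(center, dtype=float)[None, :], w


@dataclass
class Dot(SyntheticObject):
    """Uniform-amplitude dot: a disc in 2D, a segment in 1D.

    The demonstration-scale calibration object is an 80 nm dot at λ = 638 nm,
    i.e. diameter ≈ 0.1254λ.
    """

    diameter: float = 80.0 / 638.0
    position: Sequence[float] = (0.0, 0.0)
    dim: int = 2
    scale: complex = 1.0 + 0.0j
    confined: bool = True

    def amplitude(self, points):
        p = _as2d(points, self.dim)
        c = np.asarray(self.position, dtype=float)[: self.dim]
        d = np.linalg.norm(p - c[None, :], axis=1)
        return np.where(d <= self.diameter / 2.0, self.scale, 0.0).astype(complex)

    def quadrature(self):
        c = np.asarray(self.position, dtype=float)[: self.dim]
        if self.dim == 1:
            g = gauss_interval(24, self.diameter / 2.0)
            return g.points[:, None] + c[None, :], g.weights
        return _disc_quad(c, self.diameter / 2.0)

    def bounding_radius(self):
        c = np.asarray(self.position, dtype=float)[: self.dim]
        return float(np.linalg.norm(c)) + self.diameter / 2.0


@dataclass
class Line(SyntheticObject):
    """Uniform stripe of given width (1D: a box; 2D: width × length stripe)."""

    width: float = 80.0 / 638.0
    length: float = 0.5
    orientation_deg: float = 90.0  # long-axis direction
    position: Sequence[float] = (0.0, 0.0)
    dim: int = 2
    scale: complex = 1.0 + 0.0j
    confined: bool = True

    def _axes(self):
        a = math.radians(self.orientation_deg)
        u = np.array([math.cos(a), math.sin(a)])  # long axis
        v = np.array([-math.sin(a), math.cos(a)])  # across
        return u, v

    def amplitude(self, points):
        p = _as2d(points, self.dim)
        c = np.asarray(self.position, dtype=float)[: self.dim]
        q = p - c[None, :]
        if self.dim == 1:
            return np.where(np.abs(q[:, 0]) <= self.width / 2, self.scale, 0).astype(complex)
        u, v = self._axes()
        lu, lv = q @ u, q @ v
        hit = (np.abs(lu) <= self.length / 2) & (np.abs(lv) <= self.width / 2)
        return np.where(hit, self.scale, 0).astype(complex)

    def quadrature(self):
        c = np.asarray(self.position, dtype=float)[: self.dim]
        if self.dim == 1:
            g = gauss_interval(24, self.width / 2.0)
            return g.points[:, None] + c[None, :], g.weights
        gu = gauss_interval(32, self.length / 2.0)
        gv = gauss_interval(12, self.width / 2.0)
        u, v = self._axes()
        P = gu.points[:, None, None] * u[None, None, :] + gv.points[None, :, None] * v[None, None, :]
        W = np.outer(gu.weights, gv.weights)
        return P.reshape(-1, 2) + c[None, :], W.ravel()

    def bounding_radius(self):
        c = np.asarray(self.position, dtype=float)[: self.dim]
        half = self.width / 2.0 if self.dim == 1 else math.hypot(self.length / 2, self.width / 2)
        return float(np.linalg.norm(c)) + half


@dataclass
class DoubleDot(SyntheticObject):
    """Two identical dots at a given center-to-center separation."""

    separation: float = 0.2
    diameter: float = 0.06
    orientation_deg: float = 0.0
    dim: int = 2
    scale: complex = 1.0 + 0.0j
    confined: bool = True

    def _centers(self):
        if self.dim == 1:
            u = np.array([1.0])
        else:
            a = math.radians(self.orientation_deg)
            u = np.array([math.cos(a), math.sin(a)])
        return [u * self.separation / 2, -u * self.separation / 2]

    def _dots(self):
        return [
            Dot(diameter=self.diameter, position=tuple(c), dim=self.dim, scale=self.scale)
            for c in self._centers()
        ]

    def amplitude(self, points):
        return sum(d.amplitude(points) for d in self._dots())

    def quadrature(self):
        ps, ws = zip(*(d.quadrature() for d in self._dots()))
        return np.concatenate(ps), np.concatenate(ws)

    def bounding_radius(self):
        return self.separation / 2 + self.diameter / 2


@dataclass
class GridArray(SyntheticObject):
    """count × count array of dots on a square lattice (2D)."""

    pitch: float = 0.2
    count: int = 3
    dot_diameter: float = 0.06
    dim: int = 2
    scale: complex = 1.0 + 0.0j
    confined: bool = True

    def _dots(self):
        off = (self.count - 1) / 2.0
        dots = []
        for i in range(self.count):
            for j in range(self.count):
                pos = ((i - off) * self.pitch, (j - off) * self.pitch)
                dots.append(Dot(diameter=self.dot_diameter, position=pos, dim=2, scale=self.scale))
        return dots

    def amplitude(self, points):
        return sum(d.amplitude(points) for d in self._dots())

    def quadrature(self):
        ps, ws = zip(*(d.quadrature() for d in self._dots()))
        return np.concatenate(ps), np.concatenate(ws)

    def bounding_radius(self):
        off = (self.count - 1) / 2.0
        return off * self.pitch * math.sqrt(2) + self.dot_diameter / 2


@dataclass
class SiemensStar(SyntheticObject):
    """Binary spoke target: n_spokes bright sectors alternating with dark.

    The intensity along any concentric circle has exactly ``n_spokes``
    periods; the center-to-center spoke spacing on a circle of diameter d
    is π·d/n_spokes.
    """

    n_spokes: int = 6
    outer_diameter: float = 0.6
    inner_diameter: float = 0.08
    dim: int = 2
    scale: complex = 1.0 + 0.0j
    confined: bool = True

    def amplitude(self, points):
        p = _as2d(points, 2)
        r = np.hypot(p[:, 0], p[:, 1])
        th = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2 * np.pi)
        sector = np.mod(th * self.n_spokes, 2 * np.pi) < np.pi
        radial = (r >= self.inner_diameter / 2) & (r <= self.outer_diameter / 2)
        return np.where(sector & radial, self.scale, 0).astype(complex)

    def quadrature(self):
        # per-bright-sector tensor Gauss rule: exact for the binary mask
        m = self.n_spokes
        tr, wr = np.polynomial.legendre.leggauss(24)
        r0, r1 = self.inner_diameter / 2, self.outer_diameter / 2
        r = r0 + (tr + 1) * 0.5 * (r1 - r0)
        wrad = wr * 0.5 * (r1 - r0) * r
        tt, wt = np.polynomial.legendre.leggauss(8)
        pts, ws = [], []
        for s in range(m):
            th0 = s * 2 * np.pi / m
            th = th0 + (tt + 1) * 0.5 * (np.pi / m)
            wth = wt * 0.5 * (np.pi / m)
            R, TH = np.meshgrid(r, th, indexing="ij")
            pts.append(np.stack([(R * np.cos(TH)).ravel(), (R * np.sin(TH)).ravel()], 1))
            ws.append(np.outer(wrad, wth).ravel())
        return np.concatenate(pts), np.concatenate(ws)

    def bounding_radius(self):
        return self.outer_diameter / 2


@dataclass
class RandomScatterers(SyntheticObject):
    """n point-like dots with seeded random positions and complex amplitudes."""

    n: int = 5
    seed: int = 0
    diameter: float = 0.05
    max_radius: float = 0.3
    dim: int = 2
    confined: bool = True

    def _dots(self):
        rng = np.random.default_rng(self.seed)
        dots = []
        for _ in range(self.n):
            if self.dim == 1:
                pos = (rng.uniform(-self.max_radius, self.max_radius),)
            else:
                r = self.max_radius * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                pos = (r * math.cos(th), r * math.sin(th))
            amp = rng.normal() + 1j * rng.normal()
            dots.append(Dot(diameter=self.diameter, position=pos, dim=self.dim, scale=amp))
        return dots

    def amplitude(self, points):
        return sum(d.amplitude(points) for d in self._dots())

    def quadrature(self):
        ps, ws = zip(*(d.quadrature() for d in self._dots()))
        return np.concatenate(ps), np.concatenate(ws)

    def bounding_radius(self):
        return self.max_radius + self.diameter / 2


@dataclass
class SpeckleBackground(SyntheticObject):
    """Out-of-FOV contamination: point scatterers with Gaussian amplitudes.

    Emulates residual scattering from surface roughness outside the FOV; it
    contributes to the measured band field but carries no true
    Slepian–Pollak coefficients (its support lies outside the FOV).
    """

    amplitude_rms: float = 0.05
    inner_radius: float = 0.45
    outer_radius: float = 1.2
    n_scatterers: int = 200
    seed: int = 0
    dim: int = 2
    confined: bool = False

    def _sources(self):
        rng = np.random.default_rng(self.seed)
        if self.dim == 1:
            side = rng.choice([-1, 1], self.n_scatterers)
            r = rng.uniform(self.inner_radius, self.outer_radius, self.n_scatterers)
            pts = (side * r)[:, None]
        else:
            r = np.sqrt(rng.uniform(self.inner_radius**2, self.outer_radius**2, self.n_scatterers))
            th = rng.uniform(0, 2 * np.pi, self.n_scatterers)
            pts = np.stack([r * np.cos(th), r * np.sin(th)], 1)
        amps = (rng.normal(size=self.n_scatterers) + 1j * rng.normal(size=self.n_scatterers))
        amps *= self.amplitude_rms / math.sqrt(2)
        return pts, amps

    def amplitude(self, points):
        raise NotImplementedError("speckle is a point-scatterer model; no raster amplitude")

    def quadrature(self):
        pts, _ = self._sources()
        return pts, np.ones(len(pts))

    def bounding_radius(self):
        return self.outer_radius

    def energy(self):
        _, amps = self._sources()
        return float(np.sum(np.abs(amps) ** 2))

    def energy_inside_fov(self, config):
        return 0.0


@dataclass
class Composite(SyntheticObject):
    """Superposition of several objects (e.g. object + speckle background)."""

    parts: Sequence[SyntheticObject] = ()

    def __post_init__(self):
        self.dim = self.parts[0].dim
        self.confined = all(p.confined for p in self.parts)

    def amplitude(self, points):
        return sum(p.amplitude(points) for p in self.parts)

    def quadrature(self):
        ps, ws = zip(*(p.quadrature() for p in self.parts))
        return np.concatenate([_as2d(p, self.dim) for p in ps]), np.concatenate(ws)

    def bounding_radius(self):
        return max(p.bounding_radius() for p in self.parts)

    def energy_inside_fov(self, config):
        tot = sum(p.energy() for p in self.parts)
        ins = sum(p.energy() * p.energy_inside_fov(config) for p in self.parts)
        return ins / tot if tot > 0 else 1.0


# ---------------------------------------------------------------------------
# forward-model operations


def make_object(
    spec: SyntheticObject,
    grid: RasterGrid,
    config: Optional[OpticalConfig] = None,
) -> ComplexField:
    """Render an object spec to a raster near-field amplitude."""
    if config is not None:
        spec.require_confined(config)
    amp = spec.amplitude(grid.coords()).reshape(grid.shape)
    return ComplexField(samples=amp, grid=grid, plane="object")


def illuminate(obj: ComplexField, ill: IlluminationConfig) -> ComplexField:
    """Apply the oblique-illumination phase ramp exp(i k∥·x)."""
    if obj.plane != "object":
        raise ValueError("illumination applies to object-plane fields")
    grid = obj.grid
    coords = grid.coords()
    dim = coords.shape[1]
    kv = np.asarray(ill.k_vector(dim))
    ramp = np.exp(1j * (coords @ kv)).reshape(obj.samples.shape)
    return obj.copy_with(obj.samples * ramp)


def _illumination_values(points: np.ndarray, ill: Optional[IlluminationConfig], dim: int):
    if ill is None:
        return 1.0
    kv = np.asarray(ill.k_vector(dim))
    return np.exp(1j * (_as2d(points, dim) @ kv))


def true_coefficients(fld: ComplexField, basis: SlepianBasis) -> np.ndarray:
    """Project an object-plane field sampled on the basis grid onto the modes."""
    if fld.plane != "object":
        raise ValueError("true_coefficients expects an object-plane field")
    if not isinstance(fld.grid, QuadGrid) or fld.grid.n_points != basis.grid.n_points or not np.allclose(fld.grid.points, basis.grid.points):
        raise ValueError("field grid does not match the basis grid")
    return (basis.modes.T * basis.grid.weights) @ fld.samples.ravel()


def object_coefficients(
    spec: SyntheticObject,
    basis: SlepianBasis,
    illumination: Optional[IlluminationConfig] = None,
) -> np.ndarray:
    """True Slepian–Pollak coefficients c_o of an (illuminated) object.

    Computed with the object's own support quadrature, so narrow features
    are integrated accurately; support outside the FOV contributes nothing
    (the modes exist only on the FOV).
    """
    if spec.confined:
        spec.require_confined(basis.config)
    pts, w = spec.quadrature()
    pts = _as2d(pts, basis.config.dim)
    inside = basis.fov_mask(pts)
    if not np.any(inside):
        return np.zeros(basis.mode_count, dtype=complex)
    pts, w = pts[inside], w[inside]
    if isinstance(spec, PointSource):
        vals = np.full(len(pts), spec.amplitude_value, dtype=complex)
    else:
        vals = spec.amplitude(pts)
    vals = vals * _illumination_values(pts, illumination, basis.config.dim)
    S = basis.evaluate(pts)
    return S.T @ (w * vals)


def propagate_to_band(
    fld: ComplexField, basis: SlepianBasis, allow_outside_fov: bool = False
) -> ComplexField:
    """Finite Fourier transform of a sampled field onto the band grid."""
    return finite_fourier(fld, basis, allow_outside_fov=allow_outside_fov)


def object_band_field(
    spec: SyntheticObject,
    basis: SlepianBasis,
    illumination: Optional[IlluminationConfig] = None,
) -> ComplexField:
    """Band-plane field of an object, by direct transform of its quadrature.

    Unlike a truncated modal synthesis this includes the full out-of-span
    tail (and any out-of-FOV contamination), which is what a measurement
    actually sees.
    """
    pts, w = spec.quadrature()
    pts = _as2d(pts, basis.config.dim)
    if isinstance(spec, (PointSource, SpeckleBackground)):
        if isinstance(spec, PointSource):
            vals = np.full(len(pts), spec.amplitude_value, dtype=complex)
        else:
            _, vals = spec._sources()
    elif isinstance(spec, Composite):
        vals = []
        for p in spec.parts:
            q, _ = p.quadrature()
            if isinstance(p, PointSource):
                vals.append(np.full(1, p.amplitude_value, dtype=complex))
            elif isinstance(p, SpeckleBackground):
                vals.append(p._sources()[1])
            else:
                vals.append(p.amplitude(_as2d(q, p.dim)))
        vals = np.concatenate(vals)
    else:
        vals = spec.amplitude(pts)
    vals = vals * _illumination_values(pts, illumination, basis.config.dim)
    kx = basis.band_grid.coords()
    pref = (2.0 * np.pi) ** (-basis.config.dim / 2.0)
    band = pref * np.exp(-1j * (kx @ pts.T)) @ (w * vals)
    return ComplexField(samples=band, grid=basis.band_grid, plane="fourier")


def band_to_fov(band: ComplexField, basis: SlepianBasis, points=None) -> np.ndarray:
    """Adjoint propagation: evaluate the FOV field of a band-plane profile.

    ``(F^H g)(x) = (2π)^{-d/2} ∫_band g(k) e^{+i k·x} dk`` — the physical
    propagation from a Fourier-plane source back to the object plane,
    restricted to the FOV.
    """
    if points is None:
        points = basis.grid.coords()
    pts = _as2d(points, basis.config.dim)
    wb = band.grid.weights
    kx = band.grid.coords()
    pref = (2.0 * np.pi) ** (-basis.config.dim / 2.0)
    return pref * np.exp(1j * (pts @ kx.T)) @ (wb * band.samples.ravel())


def synthesize_superoscillation(
    target_coeffs: np.ndarray, basis: SlepianBasis
) -> ComplexField:
    """Fourier-plane mask whose FOV image is Σ c_i S_i (hotspot synthesis).

    The reverse of the imaging process: the mask superposes band modes with
    weights c_i/γ_i* so that propagation to the object plane reproduces the
    target inside the FOV; its energy grows as Σ |c_i/γ_i|².
    """
    c = np.asarray(target_coeffs, dtype=complex)
    if len(c) > basis.mode_count:
        raise ValueError("more target coefficients than basis modes")
    g = basis.gammas[: len(c)]
    used = np.abs(c) > 0
    if np.any(np.abs(g[used]) < 1e-12):
        bad = int(np.argmax(used & (np.abs(g) < 1e-12))) + 1
        raise ValueError(
            f"mode {bad} has |γ| below 1e-12 and cannot be synthesized at "
            "numeric precision"
        )
    mask = basis.band_modes()[:, : len(c)] @ (c / np.conj(g))
    return ComplexField(samples=mask, grid=basis.band_grid, plane="fourier")
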