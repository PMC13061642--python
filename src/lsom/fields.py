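"""Sampled complex fields and the grids they live on.

Two grid families are used:

* :class:`QuadGrid` — scattered quadrature nodes with weights, used for all
  inner products (mode orthonormality, coefficient projections, band
  energies).  Nodes are Gauss–Legendre on the 1D interval and a
  Gauss–Legendre (radius) × midpoint (angle) product rule on the 2D disc,
  so integrals of smooth fields are spectrally accurate.
* :class:`RasterGrid` — uniform pixel grids used for rendered images,
  FFT-based metrics and TIFF export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class QuadGrid:
    """Quadrature nodes and weights covering a region.

    ``points`` has shape (n,) in 1D or (n, 2) in 2D; ``weights`` has shape
    (n,) and integrates functions sampled on the nodes.
    """

    points: np.ndarray
    weights: np.ndarray
    dim: int
    region: str  # "interval" | "disc" | "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) != self.n_points:
            raise ValueError("weights must be 1D and match the number of points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def coords(self) -> np.ndarray:
        """Points as an (n, dim) array regardless of dim."""
        p = self.points
        return p[:, None] if p.ndim == 1 else p

    def integrate(self, samples: np.ndarray) -> complex:
        return complex(np.sum(self.weights * samples))

    def inner(self, a: np.ndarray, b: np.ndarray) -> complex:
        """L2 inner product <a, b> = ∫ conj(a)·b under the quadrature."""
        return complex(np.sum(self.weights * np.conj(a) * b))

    def norm2(self, a: np.ndarray) -> float:
        return float(np.sum(self.weights * np.abs(a) ** 2))

    def scaled(self, factor: float, region: Optional[str] = None) -> "QuadGrid":
        """Affinely scaled copy (used to map the FOV grid onto the band)."""
        return QuadGrid(
            points=self.points * factor,
            weights=self.weights * factor**self.dim,
            dim=self.dim,
            region=region or self.region,
            meta=dict(self.meta),
        )


def gauss_interval(n: int, half_width: float) -> QuadGrid:
    """Gauss–Legendre rule on [-half_width, half_width]."""
    t, w = np.polynomial.legendre.leggauss(n)
    return QuadGrid(
        points=t * half_width,
        weights=w * half_width,
        dim=1,
        region="interval",
        meta={"n": n, "half_width": half_width},
    )


def disc_polar(n_radial: int, n_theta: int, radius: float) -> QuadGrid:
    """Product rule on the disc of given radius.

    Gauss–Legendre in radius (Jacobian r folded into the weights), midpoint
    in angle.  Midpoint-in-θ is spectrally accurate for periodic integrands
    and keeps the node set closed under the reflections θ → -θ used to
    canonicalize degenerate angular mode pairs.
    """
    if n_theta % 2:
        raise ValueError("n_theta must be even for reflection symmetry")
    tr, wr = np.polynomial.legendre.leggauss(n_radial)
    r = (tr + 1.0) * 0.5 * radius
    wrad = wr * 0.5 * radius * r
    theta = (np.arange(n_theta) + 0.5) * 2.0 * np.pi / n_theta
    wth = 2.0 * np.pi / n_theta
    R, TH = np.meshgrid(r, theta, indexing="ij")
    pts = np.stack([(R * np.cos(TH)).ravel(), (R * np.sin(TH)).ravel()], axis=1)
    w = np.repeat(wrad * wth, n_theta)
    return QuadGrid(
        points=pts,
        weights=w,
        dim=2,
        region="disc",
        meta={"n_radial": n_radial, "n_theta": n_theta, "radius": radius},
    )


def disc_reflection_indices(grid: QuadGrid) -> np.ndarray:
    """Index map realizing (r, θ) → (r, -θ) on a disc_polar grid."""
    nr, nt = grid.meta["n_radial"], grid.meta["n_theta"]
    j = np.arange(nt)
    jr = (nt - 1 - j) % nt  # θ_j = (j+0.5)Δ → -θ_j ≡ (nt-1-j)+0.5 Δ (mod 2π)
    base = np.arange(nr)[:, None] * nt
    return (base + jr[None, :]).ravel()


@dataclass(frozen=True)
class RasterGrid:
    """Uniform pixel grid, centered on the origin."""

    axes: tuple  # tuple of 1D coordinate arrays, length == dim

    @classmethod
    def centered(cls, extent: float, n: int, dim: int) -> "RasterGrid":
        ax = np.linspace(-extent / 2.0, extent / 2.0, n)
        return cls(axes=tuple(ax for _ in range(dim)))

    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple:
        return tuple(len(a) for a in self.axes)

    @property
    def spacing(self) -> float:
        a = self.axes[0]
        return float(a[1] - a[0])

    def mesh(self) -> tuple:
        if self.dim == 1:
            return (self.axes[0],)
        return tuple(np.meshgrid(*self.axes, indexing="ij"))

    def coords(self) -> np.ndarray:
        """All pixel centers as an (n_pixels, dim) array (C order)."""
        if self.dim == 1:
            return self.axes[0][:, None]
        gx, gy = self.mesh()
        return np.stack([gx.ravel(), gy.ravel()], axis=1)

    def pixel_weights(self) -> np.ndarray:
        return np.full(int(np.prod(self.shape)), self.spacing**self.dim)


@dataclass
class ComplexField:
    """Complex amplitude samples on a grid, tagged by optical plane."""

    samples: np.ndarray
    grid: object  # QuadGrid or RasterGrid
    plane: str  # "object" | "fourier" | "camera"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.plane not in ("object", "fourier", "camera"):
            raise ValueError(f"unknown plane tag {self.plane!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("field contains non-finite values")

    def energy(self) -> float:
        if isinstance(self.grid, QuadGrid):
            return self.grid.norm2(self.samples.ravel())
        w = self.grid.spacing ** self.grid.dim
        return float(np.sum(np.abs(self.samples) ** 2) * w)

    def copy_with(self, samples: np.ndarray, plane: Optional[str] = None) -> "ComplexField":
        return ComplexField(samples=samples, grid=self.grid, plane=plane or self.plane)
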