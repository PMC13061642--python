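"""Slepian–Pollak (prolate spheroidal) bases for a confined field of view.

The object is known to be confined to a FOV of diameter ``D``; the optics
collect plane-wave components up to ``K = NA·k0``.  Propagation from the
object plane to the band-limited Fourier plane is the *finite Fourier
transform*

.. math::

    (\\mathcal{F}\\psi)(k) = (2\\pi)^{-d/2} \\int_{FOV} \\psi(x)\\,
        e^{-i k\\cdot x}\\, dx, \\qquad |k| \\le K,

whose eigenfunctions are the Slepian–Pollak functions:
``F[S_i] = γ_i·S_i`` with the band coordinate rescaled by ``2K/D``.  The
concentration operator ``F^H F`` is an integral operator on the FOV with
the sinc (1D) or jinc (2D disc) kernel; its eigenvalues are the
concentration ratios ``λ_i = |γ_i|² ∈ (0, 1)``, which decay
super-exponentially beyond roughly ``2c/π`` modes (``c = DK/2``).

Everything here is numerical: the kernel is discretized on spectrally
accurate quadrature nodes and densely diagonalized.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.special import j1

from .config import OpticalConfig
from .fields import (
    ComplexField,
    QuadGrid,
    disc_polar,
    disc_reflection_indices,
    gauss_interval,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID_1D = 128
DEFAULT_GRID_2D = (32, 64)  # (n_radial, n_theta)


# ---------------------------------------------------------------------------
# kernels


def sinc_kernel(K: float, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Band-limiting kernel sin(K(x-y))/(π(x-y)) between two 1D point sets."""
    dx = np.subtract.outer(np.ravel(xa), np.ravel(xb))
    small = np.abs(dx) < 1e-13
    safe = np.where(small, 1.0, dx)
    out = np.sin(K * safe) / (np.pi * safe)
    out[small] = K / np.pi
    return out


def jinc_kernel(K: float, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """2D disc-band kernel K·J₁(K·|Δr|)/(2π·|Δr|) between two point sets."""
    pa = np.atleast_2d(pa)
    pb = np.atleast_2d(pb)
    d = np.hypot(
        np.subtract.outer(pa[:, 0], pb[:, 0]), np.subtract.outer(pa[:, 1], pb[:, 1])
    )
    small = d < 1e-13
    safe = np.where(small, 1.0, d)
    out = K * j1(K * safe) / (2.0 * np.pi * safe)
    out[small] = K**2 / (4.0 * np.pi)
    return out


def _bandlimit_kernel(config: OpticalConfig, pa, pb) -> np.ndarray:
    if config.dim == 1:
        return sinc_kernel(config.band_limit, pa, pb)
    return jinc_kernel(config.band_limit, pa, pb)


# ---------------------------------------------------------------------------
# grids


def default_fov_grid(config: OpticalConfig, oversample: float = 1.0) -> QuadGrid:
    """Quadrature grid covering the FOV at the default resolution."""
    if config.dim == 1:
        return gauss_interval(int(DEFAULT_GRID_1D * oversample), config.fov_radius)
    nr, nt = DEFAULT_GRID_2D
    nt_s = int(nt * oversample)
    return disc_polar(int(nr * oversample), nt_s + nt_s % 2, config.fov_radius)


def _check_grid(config: OpticalConfig, grid: QuadGrid) -> None:
    """Refuse grids too coarse to resolve the band, or off-center grids."""
    period = 2.0 * np.pi / config.band_limit
    pts = grid.coords()
    if grid.dim == 1:
        xs = np.sort(pts[:, 0])
        max_gap = float(np.max(np.diff(xs)))
    else:
        nr = grid.meta.get("n_radial")
        nt = grid.meta.get("n_theta")
        if nr is None:
            max_gap = period  # unknown layout: be strict below
        else:
            radius = grid.meta["radius"]
            tr = np.polynomial.legendre.leggauss(nr)[0]
            r = (tr + 1.0) * 0.5 * radius
            rad_gap = float(np.max(np.diff(np.concatenate([[0.0], r, [radius]]))))
            arc_gap = float(r[-1] * 2.0 * np.pi / nt)
            max_gap = max(rad_gap, arc_gap)
    if max_gap > period / 8.0:
        raise ValueError(
            f"grid too coarse: largest node spacing {max_gap:.4g}λ exceeds one "
            f"eighth of the band period {period:.4g}λ; refine the grid"
        )
    center = np.sum(grid.weights[:, None] * pts, axis=0) / np.sum(grid.weights)
    if np.any(np.abs(center) > 1e-9 * config.fov_size):
        raise ValueError("grid is not centered on the origin")


# ---------------------------------------------------------------------------
# concentration kernel and basis


def build_concentration_kernel(config: OpticalConfig, grid: QuadGrid) -> np.ndarray:
    """Discretized band-limiting kernel restricted to the FOV.

    Quadrature weights are folded in symmetrically
    (``A = √w ⊙ Q ⊙ √w``), so the returned matrix is symmetric positive
    semi-definite and shares its spectrum with the concentration operator.
    """
    _check_grid(config, grid)
    pts = grid.points
    Q = _bandlimit_kernel(config, pts, pts)
    sw = np.sqrt(grid.weights)
    A = sw[:, None] * Q * sw[None, :]
    return 0.5 * (A + A.T)  # exactly symmetric despite float rounding


@dataclass
class SlepianBasis:
    """Leading Slepian–Pollak modes of a confined FOV.

    ``modes[:, i]`` holds mode ``S_i`` sampled on ``grid`` and orthonormal
    under the grid quadrature; ``gammas[i]`` is the finite-Fourier
    eigenvalue with ``|γ_i|² = concentration ratio``, ordered
    non-increasing in magnitude.
    """

    config: OpticalConfig
    grid: QuadGrid
    modes: np.ndarray  # (n_points, n_modes), real
    gammas: np.ndarray  # (n_modes,), complex
    angular_orders: Optional[np.ndarray] = None  # 2D only
    meta: dict = dc_field(default_factory=dict)
    _ff_matrix: Optional[np.ndarray] = None
    _band_modes: Optional[np.ndarray] = None
    _band_grid: Optional[QuadGrid] = None
    _synth_cache: dict = dc_field(default_factory=dict)

    @property
    def mode_count(self) -> int:
        return self.modes.shape[1]

    @property
    def concentration_ratios(self) -> np.ndarray:
        return np.abs(self.gammas) ** 2

    @property
    def band_scale(self) -> float:
        """Affine factor mapping the FOV grid onto the band grid."""
        return self.config.band_limit / self.config.fov_radius

    @property
    def band_grid(self) -> QuadGrid:
        if self._band_grid is None:
            self._band_grid = self.grid.scaled(self.band_scale, region="band")
        return self._band_grid

    def band_modes(self) -> np.ndarray:
        """Unit-norm band images Ŝ_i sampled on the band grid."""
        if self._band_modes is None:
            self._band_modes = self.modes * self.band_scale ** (-self.grid.dim / 2.0)
        return self._band_modes

    def finite_fourier_matrix(self) -> np.ndarray:
        """Dense matrix of the discretized finite Fourier transform."""
        if self._ff_matrix is None:
            self._ff_matrix = finite_fourier_matrix(
                self.config, self.grid, self.band_grid
            )
        return self._ff_matrix

    def evaluate(self, points: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Evaluate all modes at arbitrary FOV points.

        Uses the kernel-interpolation identity
        ``S_i(x) = λ_i⁻¹ ∫ q(x, y) S_i(y) dy``; exact for points inside the
        FOV up to quadrature accuracy.  Outside the FOV this returns the
        band-limited extension, which grows superoscillatorily and should
        be masked by callers rendering rasters.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.grid.dim == 1 and pts.shape[1] != 1:
            pts = pts.reshape(-1, 1)
        lam = self.concentration_ratios
        out = np.empty((pts.shape[0], self.mode_count))
        src = self.grid.coords()
        wsrc = self.grid.weights
        for lo in range(0, pts.shape[0], chunk):
            blk = pts[lo : lo + chunk]
            Q = _bandlimit_kernel(self.config, blk if self.grid.dim == 2 else blk[:, 0], src if self.grid.dim == 2 else src[:, 0])
            out[lo : lo + chunk] = (Q * wsrc[None, :]) @ self.modes / lam[None, :]
        return out

    def evaluate_cached(self, points: np.ndarray) -> np.ndarray:
        """As :meth:`evaluate`, memoized on the point set (render grids)."""
        pts = np.ascontiguousarray(np.atleast_2d(np.asarray(points, dtype=float)))
        key = (pts.shape, hash(pts.tobytes()))
        if key not in self._synth_cache:
            if len(self._synth_cache) > 8:
                self._synth_cache.clear()
            self._synth_cache[key] = self.evaluate(pts)
        return self._synth_cache[key]

    def fov_mask(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.config.dim == 1:
            return np.abs(pts[:, 0]) <= self.config.fov_radius + 1e-12
        if self.config.fov_shape == "square":
            return np.all(np.abs(pts) <= self.config.fov_radius + 1e-12, axis=1)
        return np.hypot(pts[:, 0], pts[:, 1]) <= self.config.fov_radius + 1e-12


def finite_fourier_matrix(
    config: OpticalConfig, obj_grid: QuadGrid, band_grid: QuadGrid
) -> np.ndarray:
    """Dense discretization of the finite Fourier transform.

    Maps samples on the object quadrature grid to band samples:
    ``(2π)^{-d/2} Σ_m w_m ψ(x_m) exp(-i k_j · x_m)``.
    """
    kx = band_grid.coords()
    xs = obj_grid.coords()
    phase = np.exp(-1j * (kx @ xs.T))
    pref = (2.0 * np.pi) ** (-config.dim / 2.0)
    return pref * phase * obj_grid.weights[None, :]


# ---------------------------------------------------------------------------
# canonicalization helpers


def _fix_sign_1d(mode: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Make the mode positive at its first extremum walking out from x=0."""
    order = np.argsort(xs)
    xs_s, m_s = xs[order], mode[order]
    pos = xs_s >= 0
    prof = m_s[pos]
    a = np.abs(prof)
    ext = len(prof) - 1
    for i in range(1, len(prof) - 1):
        if a[i] >= a[i - 1] and a[i] >= a[i + 1]:
            ext = i
            break
    else:
        ext = int(np.argmax(a))
    if a[0] > a[1]:  # extremum straddling the origin (even modes)
        ext = 0
    return mode if prof[ext] > 0 else -mode


def _fix_sign_generic(mode: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(mode)))
    return mode if mode[i] > 0 else -mode


def _angular_order(mode: np.ndarray, grid: QuadGrid) -> int:
    nr, nt = grid.meta["n_radial"], grid.meta["n_theta"]
    rings = mode.reshape(nr, nt)
    ring = rings[int(np.argmax(np.sum(rings**2, axis=1)))]
    spec = np.abs(np.fft.rfft(ring))
    return int(np.argmax(spec))


def _canonicalize_2d(
    vecs: np.ndarray, eigs: np.ndarray, grid: QuadGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate degenerate ± angular pairs onto even/odd reflection partners.

    Within each degenerate eigenvalue group the even (cos mθ-like) partner
    is ordered before the odd (sin mθ-like) one.  Returns the rotated
    eigenvector matrix and the per-mode angular order |m|.
    """
    refl = disc_reflection_indices(grid)
    n = vecs.shape[1]
    out = vecs.copy()
    orders = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        j = i + 1
        while j < n and abs(eigs[j] - eigs[i]) <= 1e-8 * max(eigs[i], 1e-30):
            j += 1
        block = out[:, i:j]
        if j - i > 1:
            M = block.T @ block[refl, :]
            M = 0.5 * (M + M.T)
            pvals, pvecs = np.linalg.eigh(M)
            order = np.argsort(-pvals)  # +1 (even) before -1 (odd)
            block = block @ pvecs[:, order]
        else:
            # singlet: symmetrize numerically (must be reflection-even or odd)
            s = float(block[:, 0] @ block[refl, 0])
            if s < 0:
                block = 0.5 * (block - block[refl, :])
            else:
                block = 0.5 * (block + block[refl, :])
            nrm = np.linalg.norm(block[:, 0])
            if nrm > 0:
                block = block / nrm
        for c in range(block.shape[1]):
            block[:, c] = _fix_sign_generic(block[:, c])
            orders[i + c] = _angular_order(block[:, c], grid)
        out[:, i:j] = block
        i = j
    return out, orders


def _select_modes(
    eigs: np.ndarray, orders: Optional[np.ndarray], n_modes: int, selection: str
) -> np.ndarray:
    """Indices of the retained modes among the leading eigenpairs.

    ``"strict"`` takes the top-n by eigenvalue.  ``"multiplet"`` (2D
    default) never splits a degenerate ± angular pair: multiplets are taken
    in decreasing eigenvalue order and a pair that does not fit the
    remaining slot budget is skipped in favour of the next fitting
    multiplet, keeping the retained set rotationally complete.
    """
    if selection == "strict" or orders is None:
        return np.arange(n_modes)
    groups = []
    i = 0
    while i < len(eigs):
        j = i + 1
        while j < len(eigs) and abs(eigs[j] - eigs[i]) <= 1e-8 * max(eigs[i], 1e-30):
            j += 1
        groups.append(list(range(i, j)))
        i = j
    chosen: list[int] = []
    remaining = n_modes
    for g in groups:
        if remaining == 0:
            break
        if len(g) <= remaining:
            chosen.extend(g)
            remaining -= len(g)
    if remaining:
        raise ValueError(
            f"could not assemble {n_modes} modes from complete multiplets; "
            f"compute more eigenpairs"
        )
    return np.array(chosen)


# ---------------------------------------------------------------------------
# basis construction


def compute_basis(
    config: OpticalConfig,
    n_modes: int,
    grid: Optional[QuadGrid] = None,
    selection: str = "multiplet",
) -> SlepianBasis:
    """Compute the leading Slepian–Pollak modes for the configured FOV.

    Modes are real on the object plane, orthonormal under the grid
    quadrature, ordered by non-increasing ``|γ|``; the finite-Fourier
    eigenvalue phase (the ``iⁿ``-type factor) is folded into ``γ_i``.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if config.dim == 2 and config.fov_shape == "square":
        return _compute_basis_square(config, n_modes, selection)
    if grid is None:
        grid = default_fov_grid(config)
    if n_modes > grid.n_points:
        raise ValueError(
            f"requested {n_modes} modes but the grid supports at most "
            f"{grid.n_points}"
        )
    A = build_concentration_kernel(config, grid)
    eigs, vecs = np.linalg.eigh(A)
    eigs, vecs = eigs[::-1].copy(), vecs[:, ::-1].copy()
    n_keep = min(grid.n_points, n_modes + 12)
    eigs, vecs = eigs[:n_keep], vecs[:, :n_keep]
    eigs = np.clip(eigs, 0.0, None)

    orders = None
    if config.dim == 2:
        vecs, orders = _canonicalize_2d(vecs, eigs, grid)
    sel = _select_modes(eigs, orders, n_modes, selection)
    eigs, vecs = eigs[sel], vecs[:, sel]
    if orders is not None:
        orders = orders[sel]

    sw = np.sqrt(grid.weights)
    modes = vecs / sw[:, None]
    if config.dim == 1:
        xs = grid.points
        for i in range(modes.shape[1]):
            modes[:, i] = _fix_sign_1d(modes[:, i], xs)

    basis = SlepianBasis(
        config=config,
        grid=grid,
        modes=modes,
        gammas=np.ones(len(eigs), dtype=complex),
        angular_orders=orders,
        meta={"selection": selection, "kernel_eigenvalues": eigs},
    )
    # γ_i = <Ŝ_i, F S_i> on the band grid: magnitude √λ_i with the
    # finite-Fourier phase folded in.
    E = basis.finite_fourier_matrix()
    band_imgs = E @ modes
    bm = basis.band_modes()
    wb = basis.band_grid.weights
    gammas = np.einsum("j,ji,ji->i", wb, np.conj(bm), band_imgs)
    basis.gammas = gammas
    return basis


def _compute_basis_square(
    config: OpticalConfig, n_modes: int, selection: str
) -> SlepianBasis:
    """Tensor-product basis for a square FOV (side = fov_size)."""
    cfg1 = OpticalConfig(
        objective_na=config.objective_na,
        fov_size=config.fov_size,
        dim=1,
        wavelength=config.wavelength,
    )
    n1 = max(4, int(math.ceil(math.sqrt(n_modes))) + 4)
    b1 = compute_basis(cfg1, n1)
    lam1 = b1.concentration_ratios
    prod = np.multiply.outer(lam1, lam1)
    flat = np.argsort(-prod.ravel(), kind="stable")[: n_modes]
    ii, jj = np.unravel_index(flat, prod.shape)

    g1 = b1.grid
    nx = g1.n_points
    X, Y = np.meshgrid(g1.points, g1.points, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    w = np.outer(g1.weights, g1.weights).ravel()
    grid = QuadGrid(points=pts, weights=w, dim=2, region="custom", meta={"square_n": nx})
    modes = np.empty((nx * nx, n_modes))
    for m, (i, j) in enumerate(zip(ii, jj)):
        modes[:, m] = np.outer(b1.modes[:, i], b1.modes[:, j]).ravel()
    gammas = b1.gammas[ii] * b1.gammas[jj]
    return SlepianBasis(
        config=config,
        grid=grid,
        modes=modes,
        gammas=gammas,
        meta={"selection": selection, "tensor_indices": np.stack([ii, jj], 1)},
    )


# ---------------------------------------------------------------------------
# operations on bases


def energy_transfer_ratios(basis: SlepianBasis) -> np.ndarray:
    """Normalized energy transfer ratios |γ_i/γ_1|² (first entry 1)."""
    if basis.mode_count < 1:
        raise ValueError("basis has no modes")
    lam = basis.concentration_ratios
    return lam / lam[0]


def finite_fourier(
    field: ComplexField, basis: SlepianBasis, allow_outside_fov: bool = False
) -> ComplexField:
    """Finite Fourier transform of an object-plane field onto the band grid.

    Reports (and by default warns about) energy outside the FOV, which the
    confined-object model does not account for.
    """
    if field.plane != "object":
        raise ValueError("finite_fourier expects an object-plane field")
    grid = field.grid
    if isinstance(grid, QuadGrid):
        pts, w = grid.coords(), grid.weights
        samples = field.samples.ravel()
    else:
        pts, w = grid.coords(), grid.pixel_weights()
        samples = field.samples.ravel()
    inside = basis.fov_mask(pts)
    e_out = float(np.sum(w[~inside] * np.abs(samples[~inside]) ** 2))
    e_tot = float(np.sum(w * np.abs(samples) ** 2))
    if e_tot > 0 and e_out > 1e-9 * e_tot and not allow_outside_fov:
        warnings.warn(
            f"field has {e_out / e_tot:.3e} of its energy outside the FOV; "
            "pass allow_outside_fov=True to silence",
            stacklevel=2,
        )
    kx = basis.band_grid.coords()
    pref = (2.0 * np.pi) ** (-basis.config.dim / 2.0)
    band = pref * (np.exp(-1j * (kx @ pts.T)) * w[None, :]) @ samples
    return ComplexField(samples=band, grid=basis.band_grid, plane="fourier")
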