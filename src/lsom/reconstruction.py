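"""Coefficient estimation and image reconstruction.

An image is the finite Slepian–Pollak series Σ_i c_e,i·S_i(x) rendered on
the FOV; multi-direction reconstructions are merged coherently after
removing each direction's illumination ramp and aligning global phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import IlluminationConfig
from .calibration import FilterMatrix
from .fields import ComplexField, QuadGrid, RasterGrid
from .slepian import SlepianBasis


@dataclass
class ReconstructedImage:
    """Complex LSOM image on a grid, with its provenance."""

    field: ComplexField
    coefficients: Optional[np.ndarray] = None
    directions: list = field(default_factory=list)
    fov_mask: Optional[np.ndarray] = None

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.field.samples) ** 2

    def centroid(self) -> np.ndarray:
        """Energy-weighted centroid over the FOV."""
        grid = self.field.grid
        if isinstance(grid, QuadGrid):
            coords, w = grid.coords(), grid.weights
        else:
            coords, w = grid.coords(), grid.pixel_weights()
        inten = (w * np.abs(self.field.samples.ravel()) ** 2)
        if self.fov_mask is not None:
            inten = inten * self.fov_mask.ravel()
        tot = inten.sum()
        if tot <= 0:
            raise ValueError("empty reconstruction: zero energy in the FOV")
        return (inten @ coords) / tot


def estimate_coefficients(c_m: np.ndarray, W: FilterMatrix) -> np.ndarray:
    """Apply the vector linear filter: c_e = W·c_m."""
    c_m = np.asarray(c_m, dtype=complex)
    if c_m.shape[-1] != W.matrix.shape[1]:
        raise ValueError(
            f"coefficient vector length {c_m.shape[-1]} does not match the "
            f"filter's N' = {W.matrix.shape[1]}"
        )
    return c_m @ W.matrix.T


def render_image(
    c_e: np.ndarray,
    basis: SlepianBasis,
    grid: Optional[object] = None,
) -> ReconstructedImage:
    """Render Σ c_e,i·S_i on the basis quadrature grid or a raster grid.

    On a raster, pixels outside the FOV are masked to zero (the modal
    series is only defined inside the FOV).
    """
    c_e = np.asarray(c_e, dtype=complex)
    if len(c_e) > basis.mode_count:
        raise ValueError("more coefficients than basis modes")
    if grid is None or grid is basis.grid:
        samples = basis.modes[:, : len(c_e)] @ c_e
        fld = ComplexField(samples=samples, grid=basis.grid, plane="object")
        return ReconstructedImage(field=fld, coefficients=c_e)
    coords = grid.coords()
    mask = basis.fov_mask(coords)
    vals = np.zeros(coords.shape[0], dtype=complex)
    if np.any(mask):
        S = basis.evaluate_cached(coords[mask])
        vals[mask] = S[:, : len(c_e)] @ c_e
    fld = ComplexField(samples=vals.reshape(grid.shape), grid=grid, plane="object")
    return ReconstructedImage(field=fld, coefficients=c_e, fov_mask=mask.reshape(grid.shape))


def merge_directions(
    images: Sequence[ReconstructedImage],
    illuminations: Sequence[IlluminationConfig],
    compensate_ramp: bool = True,
) -> ReconstructedImage:
    """Coherent summation of per-direction LSOM images.

    Each image is multiplied by exp(−i·k∥·x) to undo its illumination
    ramp, phase-aligned to the first direction by the unit phasor
    maximizing the real part of the mutual overlap, and averaged with
    equal weights.
    """
    if len(images) == 0:
        raise ValueError("need at least one direction")
    if len(images) != len(illuminations):
        raise ValueError("one illumination config per image required")
    g0 = images[0].field.grid
    comp = []
    for img, ill in zip(images, illuminations):
        grid = img.field.grid
        if grid.coords().shape != g0.coords().shape or not np.allclose(
            grid.coords(), g0.coords()
        ):
            raise ValueError("all directions must share one grid")
        s = img.field.samples.ravel()
        if compensate_ramp:
            kv = np.asarray(ill.k_vector(grid.coords().shape[1]))
            s = s * np.exp(-1j * (grid.coords() @ kv))
        comp.append(s)
    ref = comp[0]
    aligned = [ref]
    for s in comp[1:]:
        ov = np.vdot(s, ref)
        phase = ov / abs(ov) if abs(ov) > 0 else 1.0
        aligned.append(s * phase)
    merged = np.mean(aligned, axis=0).reshape(images[0].field.samples.shape)
    fld = ComplexField(samples=merged, grid=g0, plane="object")
    return ReconstructedImage(
        field=fld,
        coefficients=None,
        directions=list(illuminations),
        fov_mask=images[0].fov_mask,
    )


def refine_centroid_pixel(
    candidate_offsets: Sequence,
    reconstruct: Callable[[object], ReconstructedImage],
) -> tuple:
    """Select the candidate pixel whose reconstruction is best centered.

    Returns the offset minimizing the reconstructed centroid norm; ties
    are broken by smaller offset magnitude, then lexicographically.
    """
    if len(candidate_offsets) == 0:
        raise ValueError("need at least one candidate offset")
    best = None
    n_empty = 0
    for off in candidate_offsets:
        off_arr = np.atleast_1d(np.asarray(off, dtype=float))
        try:
            img = reconstruct(off)
            cnorm = float(np.linalg.norm(img.centroid()))
        except ValueError:
            n_empty += 1
            continue
        key = (round(cnorm, 12), round(float(np.linalg.norm(off_arr)), 12), tuple(off_arr))
        if best is None or key < best[0]:
            best = (key, off)
    if best is None:
        raise ValueError("all candidate reconstructions were empty")
    return best[1]
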