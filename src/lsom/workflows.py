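"""High-level runnable workflows (the scriptable face of the package).

Each workflow takes a preset (or explicit configuration), runs one stage
of the toolchain and writes inspectable artifacts — eigenvalue tables,
transfer/filter matrices, reconstructions, metric reports and bound
curves — plus a machine-readable JSON summary carrying the seed and a
config hash.  The ``examples/`` scripts drive these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .config import OpticalConfig
from .fields import RasterGrid
from .limits import budget_curve
from .metrics import psf_full_chain
from .fields import ComplexField
from .measurement import NoiseModel, measure_vector
from .objects import object_coefficients
from .pipeline import LsomPipeline
from .presets import ExperimentPreset, object_suite
from .reconstruction import render_image
from .slepian import compute_basis, energy_transfer_ratios

logger = logging.getLogger(__name__)


def _ensure_dir(out_dir) -> Path:
    p = Path(out_dir)
    if not p.exists():
        logger.info("creating output directory %s", p)
        p.mkdir(parents=True)
    return p


def run_basis(p: ExperimentPreset, out_dir) -> pd.DataFrame:
    """Compute the preset's basis; write the eigenvalue table and modes."""
    out = _ensure_dir(out_dir)
    basis = compute_basis(p.optical, p.n_modes)
    table = io.eigenvalue_table_frame(basis)
    table.to_csv(out / "eigenvalues.csv", index=False)
    trace = float(np.sum(basis.meta["kernel_eigenvalues"]))
    expected = (
        p.optical.fov_size * p.optical.band_limit / np.pi
        if p.optical.dim == 1
        else np.pi * p.optical.fov_radius**2 * p.optical.band_limit**2 / (4 * np.pi)
    )
    logger.info("kernel trace %.9f (identity value %.9f)", trace, expected)
    io.write_json(
        out / "basis_meta.json",
        {
            "n_modes": p.n_modes,
            "min_energy_transfer_ratio": float(energy_transfer_ratios(basis).min()),
            "kernel_trace_leading": trace,
        },
        seed=p.seed,
        config=p.optical,
    )
    return table


def run_pipeline(
    p: ExperimentPreset,
    out_dir,
    noiseless: bool = False,
    objects=None,
    render_n: int = 121,
) -> dict:
    """Calibrate, image the object suite, and write all artifacts."""
    out = _ensure_dir(out_dir)
    basis = compute_basis(p.optical, p.n_modes)
    noise = p.noise if not noiseless else type(p.noise)(
        photons_per_submeasurement=p.noise.photons_per_submeasurement,
        poisson=False,
        seed=p.seed,
    )
    pipe = LsomPipeline.calibrated(
        basis, illuminations=p.illuminations, noise=noise
    )
    io.write_complex_matrix_csv(out / "transfer_matrix.csv", pipe.transfer.matrix)
    io.write_complex_matrix_csv(out / "filter_matrix.csv", pipe.filter.matrix)
    pd.DataFrame({"mode": np.arange(1, len(pipe.plan.r_kk) + 1), "r_kk": pipe.plan.r_kk}).to_csv(
        out / "repetition_plan.csv", index=False
    )
    if objects is None:
        objects = object_suite(p)
    grid = RasterGrid.centered(p.optical.fov_size, render_n, p.optical.dim)
    rng = noise.rng()
    residuals = []
    for i, obj in enumerate(objects):
        img = pipe.reconstruct(obj, grid, rng=rng)
        io.write_complex_tiff(out / f"reconstruction_{i:02d}.tif", img.field)
        c_o = object_coefficients(obj, basis, p.illuminations[0])
        truth = render_image(c_o, basis, grid)
        num = np.linalg.norm(np.abs(img.field.samples) - np.abs(truth.field.samples))
        den = max(np.linalg.norm(np.abs(truth.field.samples)), 1e-300)
        residuals.append(float(num / den))
    # end-to-end identity diagnostic: an in-span coefficient vector, pushed
    # through a noiseless measurement and the calibrated filter, must return
    c_test = (0.9 ** np.arange(basis.mode_count)) * np.exp(
        1j * 0.3 * np.arange(basis.mode_count)
    )
    band = ComplexField(
        basis.band_modes() @ (basis.gammas * c_test), basis.band_grid, "fourier"
    )
    cm_test, _ = measure_vector(
        band,
        basis,
        basis.mode_count,
        pipe.reference_index,
        pipe.plan,
        NoiseModel(photons_per_submeasurement=noise.photons_per_submeasurement, poisson=False),
        split_azimuth_deg=p.illuminations[0].azimuth_deg,
    )
    in_span_residual = float(
        np.linalg.norm(pipe.filter.matrix @ cm_test - c_test) / np.linalg.norm(c_test)
    )
    summary = {
        "preset": p.name,
        "n_objects": len(objects),
        "in_span_identity_residual": in_span_residual,
        "transfer_residual": pipe.transfer.residual,
        "repetitions": pipe.plan.r_kk.tolist(),
        "reconstruction_magnitude_residuals": residuals,
        "noiseless": noiseless,
    }
    io.write_json(out / "summary.json", summary, seed=p.seed, config=p)
    return summary


def run_bounds(
    out_dir,
    fov_sizes: Optional[Sequence[float]] = None,
    photon_budgets: Sequence[float] = (1e3, 1e6, 1e9, 1e12),
    objective_na: float = 0.9,
    plot: bool = False,
) -> pd.DataFrame:
    """Tabulate the budget–resolution trade-off curves and write them."""
    out = _ensure_dir(out_dir)
    if fov_sizes is None:
        fov_sizes = sorted(set(np.round(np.linspace(0.3, 2.0, 18), 4)) | {0.8})
    table = budget_curve(fov_sizes, photon_budgets, objective_na)
    table.to_csv(out / "budget_curves.csv", index=False)
    if plot:  # pragma: no cover - optional rendering
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        for p_tot, sub in table.groupby("photon_budget"):
            ax.plot(sub["fov_size"], sub["resolution"], label=f"P = {p_tot:.0e}")
        ax.axvline(0.8, ls="--", c="gray")
        ax.set_xlabel("FOV size D (λ)")
        ax.set_ylabel("resolution Δ (λ)")
        ax.legend()
        fig.savefig(Path(out) / "budget_curves.png", dpi=150)
        plt.close(fig)
    return table
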