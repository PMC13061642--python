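"""Readers and writers for pipeline artifacts.

Complex rasters are stored as two-plane float32 TIFFs (real, imaginary);
tables as CSV with complex values split into real/imag columns; run
metadata as JSON sidecars carrying the seed and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .fields import ComplexField, RasterGrid


def config_hash(obj) -> str:
    """Stable short hash of a (nested) dataclass/mapping configuration."""

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: norm(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, dict):
            return {k: norm(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    blob = json.dumps(norm(obj), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(path, payload: dict, seed: Optional[int] = None, config=None) -> None:
    out = dict(payload)
    if seed is not None:
        out["seed"] = seed
    if config is not None:
        out["config_hash"] = config_hash(config)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, complex):
            return {"re": o.real, "im": o.imag}
        return str(o)

    Path(path).write_text(json.dumps(out, indent=2, default=default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# complex rasters


def write_complex_tiff(path, fld: ComplexField) -> None:
    if not isinstance(fld.grid, RasterGrid):
        raise ValueError("TIFF export requires a raster field")
    arr = np.stack([fld.samples.real, fld.samples.imag]).astype(np.float32)
    if fld.grid.dim == 1:
        arr = arr[:, None, :]
    tifffile.imwrite(
        path,
        arr,
        metadata={
            "plane": fld.plane,
            "spacing": fld.grid.spacing,
            "dim": fld.grid.dim,
            "extent": float(fld.grid.axes[0][-1] - fld.grid.axes[0][0]),
        },
    )


def read_complex_tiff(path) -> ComplexField:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    dim = int(meta.get("dim", 2))
    if dim == 1:
        arr = arr[:, 0, :]
    samples = arr[0].astype(float) + 1j * arr[1].astype(float)
    n = samples.shape[0] if dim == 1 else samples.shape[0]
    extent = float(meta.get("extent", 1.0))
    grid = RasterGrid.centered(extent, samples.shape[0], dim)
    return ComplexField(samples=samples, grid=grid, plane=meta.get("plane", "object"))


# ---------------------------------------------------------------------------
# tables


def eigenvalue_table_frame(basis) -> pd.DataFrame:
    lam = basis.concentration_ratios
    return pd.DataFrame(
        {
            "mode": np.arange(1, basis.mode_count + 1),
            "gamma_real": basis.gammas.real,
            "gamma_imag": basis.gammas.imag,
            "concentration": lam,
            "energy_transfer_ratio": lam / lam[0],
        }
    )


def write_complex_matrix_csv(path, M: np.ndarray) -> None:
    M = np.asarray(M)
    rows, cols = M.shape
    recs = []
    for i in range(rows):
        for j in range(cols):
            recs.append({"row": i, "col": j, "re": M[i, j].real, "im": M[i, j].imag})
    pd.DataFrame(recs).to_csv(path, index=False)


def read_complex_matrix_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    rows, cols = df["row"].max() + 1, df["col"].max() + 1
    M = np.zeros((rows, cols), dtype=complex)
    M[df["row"], df["col"]] = df["re"].to_numpy() + 1j * df["im"].to_numpy()
    return M


def write_coefficients_csv(path, c: np.ndarray, kind: str = "c_e") -> None:
    pd.DataFrame(
        {
            "mode": np.arange(1, len(c) + 1),
            "re": np.real(c),
            "im": np.imag(c),
            "kind": kind,
        }
    ).to_csv(path, index=False)


def read_coefficients_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["re"].to_numpy() + 1j * df["im"].to_numpy()


# ---------------------------------------------------------------------------
# basis archives


def write_basis_archive(directory, basis) -> None:
    """Persist a computed basis: eigenvalue table (CSV), mode samples and
    quadrature grid (NPZ), and a JSON description of the configuration."""
    from .config import OpticalConfig

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    eigenvalue_table_frame(basis).to_csv(d / "eigenvalues.csv", index=False)
    np.savez_compressed(
        d / "modes.npz",
        modes=basis.modes,
        points=basis.grid.points,
        weights=basis.grid.weights,
        gammas=basis.gammas,
        angular_orders=(
            basis.angular_orders if basis.angular_orders is not None else np.array([])
        ),
    )
    cfg = basis.config
    write_json(
        d / "basis.json",
        {
            "objective_na": cfg.objective_na,
            "fov_size": cfg.fov_size,
            "dim": cfg.dim,
            "fov_shape": cfg.fov_shape,
            "grid_region": basis.grid.region,
            "grid_meta": basis.grid.meta,
            "selection": basis.meta.get("selection"),
        },
        config=cfg,
    )


def read_basis_archive(directory):
    """Load a basis previously written by :func:`write_basis_archive`."""
    from .config import OpticalConfig
    from .fields import QuadGrid
    from .slepian import SlepianBasis

    d = Path(directory)
    meta = read_json(d / "basis.json")
    arrays = np.load(d / "modes.npz")
    cfg = OpticalConfig(
        objective_na=meta["objective_na"],
        fov_size=meta["fov_size"],
        dim=meta["dim"],
        fov_shape=meta["fov_shape"],
    )
    grid = QuadGrid(
        points=arrays["points"],
        weights=arrays["weights"],
        dim=cfg.dim,
        region=meta.get("grid_region", "custom"),
        meta=meta.get("grid_meta") or {},
    )
    orders = arrays["angular_orders"]
    return SlepianBasis(
        config=cfg,
        grid=grid,
        modes=arrays["modes"],
        gammas=arrays["gammas"],
        angular_orders=orders if orders.size else None,
        meta={"selection": meta.get("selection")},
    )
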