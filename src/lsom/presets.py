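"""Reference experiment presets and the synthetic object suite.

The presets mirror the demonstration conditions: λ = 638 nm, NA = 0.9,
FOV D = 0.8λ; 13 modes under four TIR illumination directions (θ = 66°
through sapphire, n = 1.77) in 2D, six modes under two opposing
directions in 1D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .config import IlluminationConfig, OpticalConfig
from .measurement import NoiseModel
from .objects import (
    Composite,
    Dot,
    DoubleDot,
    GridArray,
    Line,
    RandomScatterers,
    SiemensStar,
    SpeckleBackground,
    SyntheticObject,
)

PRESET_NAMES = ("paper_2d", "paper_1d", "crowded", "speckled", "custom")


@dataclass(frozen=True)
class ExperimentPreset:
    """A fully reproducible experiment configuration."""

    name: str
    optical: OpticalConfig
    n_modes: int
    illuminations: tuple
    noise: NoiseModel
    seed: int = 0
    speckle: Optional[SpeckleBackground] = None

    @property
    def n_prime(self) -> int:
        return self.n_modes


def _tir_set(azimuths: Sequence[float]) -> tuple:
    return tuple(
        IlluminationConfig(internal_angle_deg=66.0, substrate_index=1.77, azimuth_deg=a)
        for a in azimuths
    )


def preset(name: str, seed: int = 0, **overrides) -> ExperimentPreset:
    """Return a registered experiment preset.

    ``custom`` starts from the 2D demonstration conditions and applies
    keyword overrides (any ExperimentPreset field).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    wavelength_nm = 638.0
    if name == "paper_1d":
        p = ExperimentPreset(
            name=name,
            optical=OpticalConfig(objective_na=0.9, fov_size=0.8, dim=1),
            n_modes=6,
            illuminations=_tir_set([0.0, 180.0]),
            noise=NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=seed),
            seed=seed,
        )
    elif name == "crowded":
        p = ExperimentPreset(
            name=name,
            optical=OpticalConfig(objective_na=0.9, fov_size=0.8, dim=2),
            n_modes=13,
            illuminations=_tir_set([0.0, 90.0, 180.0, 270.0]),
            noise=NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=seed),
            seed=seed,
        )
    elif name == "speckled":
        p = ExperimentPreset(
            name=name,
            optical=OpticalConfig(objective_na=0.9, fov_size=0.8, dim=2),
            n_modes=13,
            illuminations=_tir_set([0.0, 90.0, 180.0, 270.0]),
            noise=NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=seed),
            seed=seed,
            speckle=SpeckleBackground(amplitude_rms=0.05, seed=seed + 1),
        )
    else:  # paper_2d, custom
        p = ExperimentPreset(
            name=name,
            optical=OpticalConfig(objective_na=0.9, fov_size=0.8, dim=2),
            n_modes=13,
            illuminations=_tir_set([0.0, 90.0, 180.0, 270.0]),
            noise=NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=seed),
            seed=seed,
        )
    if overrides:
        if name != "custom":
            raise ValueError("only the 'custom' preset accepts overrides")
        p = replace(p, **overrides)
    return p


def object_suite(p: ExperimentPreset) -> list[SyntheticObject]:
    """Synthetic stand-ins for the fabricated nanoparticle suite.

    Eight or more FOV-confined objects spanning symmetric, asymmetric,
    grid-like, curved and star categories, plus a sub-diffraction double
    dot; deterministic given the preset seed.
    """
    if p.optical.dim == 1:
        objs = [
            Dot(diameter=0.1254, position=(0.0,), dim=1),
            Dot(diameter=0.1, position=(0.12,), dim=1),
            DoubleDot(separation=0.15, diameter=0.05, dim=1),
            DoubleDot(separation=0.25, diameter=0.06, dim=1),
            Line(width=0.125, dim=1),
            Composite(parts=[
                Dot(diameter=0.06, position=(-0.2,), dim=1),
                Dot(diameter=0.06, position=(0.05,), dim=1),
                Dot(diameter=0.06, position=(0.22,), dim=1),
            ]),
            RandomScatterers(n=4, seed=p.seed + 7, diameter=0.05, max_radius=0.28, dim=1),
            RandomScatterers(n=6, seed=p.seed + 8, diameter=0.04, max_radius=0.3, dim=1),
        ]
    else:
        objs = [
            # four-fold symmetric grid
            GridArray(pitch=0.22, count=2, dot_diameter=0.08),
            # 3x3 grid
            GridArray(pitch=0.18, count=3, dot_diameter=0.06),
            # mirror-asymmetric cluster
            Composite(parts=[
                Dot(diameter=0.08, position=(-0.15, -0.1)),
                Dot(diameter=0.06, position=(0.12, -0.05)),
                Dot(diameter=0.05, position=(0.0, 0.18)),
            ]),
            # double dot below the diffraction limit
            DoubleDot(separation=0.15, diameter=0.06),
            # line pair (grid-like stripes)
            Composite(parts=[
                Line(width=0.06, length=0.4, position=(-0.1, 0.0)),
                Line(width=0.06, length=0.4, position=(0.1, 0.0)),
            ]),
            # curved feature: arc of dots
            Composite(parts=[
                Dot(diameter=0.06, position=(0.22 * np.cos(a), 0.22 * np.sin(a)))
                for a in np.linspace(0.3, np.pi - 0.3, 5)
            ]),
            # Siemens star
            SiemensStar(n_spokes=6, outer_diameter=0.6, inner_diameter=0.1),
            # random scatterers
            RandomScatterers(n=5, seed=p.seed + 7, diameter=0.05, max_radius=0.28),
        ]
    if p.speckle is not None:
        objs = [Composite(parts=[o, p.speckle]) for o in objs]
    for o in objs:
        if o.confined:
            o.require_confined(p.optical)
    return objs
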