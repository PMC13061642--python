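"""Optical and illumination configuration.

All lengths are expressed in units of the vacuum wavelength λ, so the
wavenumber is ``k0 = 2π`` and the collection band limit is ``K = NA·k0``.
Working in λ units removes unit bookkeeping: the field of view of the
demonstration experiments is simply ``D = 0.8``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the confined imaging problem.

    Parameters
    ----------
    objective_na
        Numerical aperture of the collection objective, 0 < NA <= 1
        (air-side collection).
    fov_size
        Diameter ``D`` of the field of view, in units of λ.
    dim
        Dimensionality of the object plane (1 or 2).
    fov_shape
        ``"interval"`` for 1D; ``"disc"`` (default) or ``"square"`` for 2D.
    wavelength
        Physical wavelength used only for converting user-facing lengths
        (e.g. an 80 nm calibration dot) into λ units; internally always 1.
    """

    objective_na: float = 0.9
    fov_size: float = 0.8
    dim: int = 2
    fov_shape: str = "disc"
    wavelength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.objective_na <= 1.0:
            raise ValueError(
                f"objective NA must lie in (0, 1] for air-side collection, "
                f"got {self.objective_na}"
            )
        if self.fov_size <= 0:
            raise ValueError(f"FOV size must be positive, got {self.fov_size}")
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        if self.dim == 1:
            object.__setattr__(self, "fov_shape", "interval")
        elif self.fov_shape not in ("disc", "square"):
            raise ValueError(f"2D fov_shape must be 'disc' or 'square', got {self.fov_shape!r}")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber in λ units: 2π."""
        return 2.0 * math.pi

    @property
    def band_limit(self) -> float:
        """Maximum collected transverse wavenumber K = NA·k0."""
        return self.objective_na * self.k0

    @property
    def space_bandwidth(self) -> float:
        """Space–bandwidth parameter c = (D/2)·K."""
        return 0.5 * self.fov_size * self.band_limit

    @property
    def fov_radius(self) -> float:
        return 0.5 * self.fov_size


@dataclass(frozen=True)
class IlluminationConfig:
    """Oblique (TIR) plane-wave illumination through a high-index substrate.

    The evanescent illumination contributes an in-plane wavevector
    ``k∥ = n·k0·sin θ`` along the azimuth φ; only this phase ramp is kept
    (thin-object approximation).
    """

    internal_angle_deg: float = 66.0
    substrate_index: float = 1.77
    azimuth_deg: float = 0.0
    tir: bool = True

    def __post_init__(self) -> None:
        if self.substrate_index < 1.0:
            raise ValueError("substrate index must be >= 1")
        if self.tir and self.substrate_index > 1.0:
            critical = math.degrees(math.asin(1.0 / self.substrate_index))
            if self.internal_angle_deg <= critical:
                raise ValueError(
                    f"TIR requested but internal angle {self.internal_angle_deg}° "
                    f"does not exceed the critical angle {critical:.2f}°"
                )

    @property
    def k_parallel(self) -> float:
        """In-plane wavenumber magnitude n·k0·sinθ (λ units)."""
        return self.substrate_index * 2.0 * math.pi * math.sin(
            math.radians(self.internal_angle_deg)
        )

    def k_vector(self, dim: int) -> "tuple[float, ...]":
        """In-plane wavevector as a dim-tuple (1D uses cos φ = ±1 projection)."""
        kp = self.k_parallel
        phi = math.radians(self.azimuth_deg)
        if dim == 1:
            return (kp * math.cos(phi),)
        return (kp * math.cos(phi), kp * math.sin(phi))


def normal_illumination() -> IlluminationConfig:
    """Normal-incidence (no ramp) illumination, for ideal-system tests."""
    return IlluminationConfig(internal_angle_deg=0.0, substrate_index=1.0, tir=False)
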