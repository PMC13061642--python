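"""End-to-end imaging chains: calibrate once, then measure and reconstruct.

A :class:`LsomPipeline` bundles the basis, the per-direction illumination
set, the calibrated transfer matrix and MMSE filter, and the repetition
plan, and exposes the measurement → filtering → rendering → merging chain
as single calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    FilterMatrix,
    RepetitionPlan,
    TransferMatrix,
    allocate_repetitions,
    characterization_plan,
    empirical_prior,
    fit_transfer_matrix,
    mmse_filter,
    noise_covariance,
    noise_covariance_scaled,
    shift_lattice,
    simulate_calibration,
)
from .config import IlluminationConfig, OpticalConfig, normal_illumination
from .fields import RasterGrid
from .measurement import NoiseModel, measure_vector
from .objects import Dot, Line, SyntheticObject, object_band_field
from .reconstruction import ReconstructedImage, merge_directions, render_image
from .slepian import SlepianBasis, compute_basis


def default_calibration_object(config: OpticalConfig) -> SyntheticObject:
    """A 0.125λ dot (2D) or line (1D), mirroring an 80 nm feature at 638 nm."""
    if config.dim == 1:
        return Line(width=0.125, dim=1)
    return Dot(diameter=0.125, dim=2)


def ideal_transfer(basis: SlepianBasis, reference_index: int = 0) -> TransferMatrix:
    """The aberration-free transfer matrix T = diag(γ)."""
    return TransferMatrix(
        matrix=np.diag(basis.gammas),
        reference_index=reference_index,
        calibration_size=0,
        residual=0.0,
    )


@dataclass
class LsomPipeline:
    """A calibrated LSOM imaging chain."""

    basis: SlepianBasis
    illuminations: Sequence[IlluminationConfig]
    noise: NoiseModel
    plan: RepetitionPlan
    transfer: TransferMatrix
    filter: FilterMatrix
    reference_index: int = 0
    s_r: float = 1.0

    @classmethod
    def calibrated(
        cls,
        basis: SlepianBasis,
        illuminations: Optional[Sequence[IlluminationConfig]] = None,
        noise: Optional[NoiseModel] = None,
        cal_object: Optional[SyntheticObject] = None,
        n_shifts_side: int = 10,
        reference_index: int = 0,
        plan: Optional[RepetitionPlan] = None,
        allocate: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> "LsomPipeline":
        """Single-pass calibration against the default calibration object.

        The calibration is run under the first illumination direction
        (the fitted T absorbs the ramp's effect on the coefficients of
        the scanned calibration object); shifts live on a centered
        lattice spanning the central half of the FOV, L ≈ n_shifts_side².
        """
        config = basis.config
        if illuminations is None:
            illuminations = [normal_illumination()]
        if noise is None:
            noise = NoiseModel(poisson=False)
        if cal_object is None:
            cal_object = default_calibration_object(config)
        pitch = 0.5 * config.fov_size / n_shifts_side
        shifts = shift_lattice(n_shifts_side, pitch, config.dim)
        if rng is None:
            rng = noise.rng()
        if plan is not None:
            plan0 = plan
        elif noise.poisson:
            # the fit needs its own (much larger) repetition budget: the
            # weak-mode signals of the small calibration object drown in
            # shot noise at the object-measurement plan
            plan0 = characterization_plan(
                cal_object, shifts, basis, noise,
                r=reference_index, illumination=illuminations[0],
            )
        else:
            plan0 = RepetitionPlan.uniform(basis.mode_count)
        ens = simulate_calibration(
            cal_object,
            shifts,
            basis,
            noise,
            plan=plan0,
            r=reference_index,
            illumination=illuminations[0],
            rng=rng,
        )
        T = fit_transfer_matrix(ens, reference_index=reference_index)
        if allocate:
            final_plan = allocate_repetitions(T, noise.photons_per_submeasurement)
        else:
            final_plan = plan0
        # the filter will be applied to object measurements taken under
        # final_plan, so its noise covariance is rescaled from the
        # calibration plan's shot-noise level (entries ∝ 1/R_kk)
        cn = noise_covariance(ens, noise.poisson)
        cn = noise_covariance_scaled(cn, plan0, final_plan)
        W = mmse_filter(T, cn, empirical_prior(ens))
        return cls(
            basis=basis,
            illuminations=list(illuminations),
            noise=noise,
            plan=final_plan,
            transfer=T,
            filter=W,
            reference_index=reference_index,
        )

    @classmethod
    def ideal(
        cls,
        basis: SlepianBasis,
        illuminations: Optional[Sequence[IlluminationConfig]] = None,
    ) -> "LsomPipeline":
        """Noiseless chain with the exact diagonal transfer matrix."""
        if illuminations is None:
            illuminations = [normal_illumination()]
        T = TransferMatrix(
            matrix=np.diag(basis.gammas),
            reference_index=0,
            calibration_size=0,
            residual=0.0,
        )
        W = FilterMatrix(
            matrix=np.diag(1.0 / basis.gammas),
            prior_cov=np.eye(basis.mode_count),
            noise_cov=np.zeros((basis.mode_count, basis.mode_count)),
        )
        return cls(
            basis=basis,
            illuminations=list(illuminations),
            noise=NoiseModel(poisson=False),
            plan=RepetitionPlan.uniform(basis.mode_count),
            transfer=T,
            filter=W,
        )

    # -- chain steps --------------------------------------------------------

    def measure(
        self,
        spec: SyntheticObject,
        ill: IlluminationConfig,
        rng: Optional[np.random.Generator] = None,
    ):
        band = object_band_field(spec, self.basis, ill)
        return measure_vector(
            band,
            self.basis,
            self.basis.mode_count,
            self.reference_index,
            self.plan,
            self.noise,
            s_r=self.s_r,
            split_azimuth_deg=ill.azimuth_deg,
            rng=rng,
        )

    def reconstruct_direction(
        self,
        spec: SyntheticObject,
        ill: IlluminationConfig,
        grid: Optional[RasterGrid] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> ReconstructedImage:
        c_m, _ = self.measure(spec, ill, rng=rng)
        c_e = self.filter.matrix @ c_m
        return render_image(c_e, self.basis, grid)

    def reconstruct(
        self,
        spec: SyntheticObject,
        grid: Optional[RasterGrid] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> ReconstructedImage:
        """Measure under every direction, reconstruct and merge coherently."""
        if rng is None:
            rng = self.noise.rng()
        imgs = [
            self.reconstruct_direction(spec, ill, grid, rng=rng)
            for ill in self.illuminations
        ]
        return merge_directions(imgs, self.illuminations)

    def default_render_grid(self, n: int = 161) -> RasterGrid:
        return RasterGrid.centered(
            self.basis.config.fov_size, n, self.basis.config.dim
        )
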