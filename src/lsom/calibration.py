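"""Transfer-matrix calibration, MMSE inversion and repetition allocation.

A single known calibration object (a small dot in 2D, a thin line in 1D,
mirroring an 80 nm feature at λ = 638 nm) is scanned over L transverse
shifts — emulating the conjugate object/camera relation in which each
camera pixel reads the coefficients of a distinctly shifted copy.  Each
shift yields a pair (c_o, c_m): c_o from the ideal model, c_m from the
measurement simulator.  The transfer matrix is the least-squares solution
of c_m ≈ T·c_o; the vector linear filter W = (T⁻¹)_mms is the linear MMSE
inverse given a signal prior and the shot-noise covariance of the
repetition plan; and the repetition counts R_kk are the smallest integers
for which the per-coefficient accuracy criterion

    P_sin · [ {Re(TᴴT)}⁻¹ ]_rr / [ {Re(TᴴRT)}⁻¹ ]_ii  ≥  1

holds for every estimated coefficient i.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import IlluminationConfig
from .measurement import MeasurementRecord, NoiseModel, RepetitionPlan, measure_vector
from .objects import SyntheticObject, object_band_field, object_coefficients
from .slepian import SlepianBasis

logger = logging.getLogger(__name__)


@dataclass
class TransferMatrix:
    """N′×N system matrix T with c_m ≈ T·c_o."""

    matrix: np.ndarray
    reference_index: int
    calibration_size: int
    residual: float
    s_r: float = 1.0

    @property
    def n_prime(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FilterMatrix:
    """N×N′ linear MMSE inverse of the transfer matrix."""

    matrix: np.ndarray
    prior_cov: np.ndarray
    noise_cov: np.ndarray


@dataclass
class CalibrationEnsemble:
    """Paired true/measured coefficient realizations over shifts."""

    c_o: np.ndarray  # (L, N)
    c_m: np.ndarray  # (L, N')
    shifts: np.ndarray
    rejected: list = field(default_factory=list)
    records: list = field(default_factory=list)
    s_r: float = 1.0


def shift_lattice(n_side: int, pitch: float, dim: int) -> np.ndarray:
    """Centered n_side^dim offset lattice (the demonstration uses 10×10, L = 100)."""
    ax = (np.arange(n_side) - (n_side - 1) / 2.0) * pitch
    if dim == 1:
        return ax[:, None]
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def simulate_calibration(
    cal_object: SyntheticObject,
    shifts: np.ndarray,
    basis: SlepianBasis,
    noise: NoiseModel,
    plan: Optional[RepetitionPlan] = None,
    r: int = 0,
    illumination: Optional[IlluminationConfig] = None,
    s_r: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> CalibrationEnsemble:
    """Measure the calibration object at each transverse shift.

    True coefficients come from the ideal analytic model of the shifted
    object; measured ones from the full interferometric simulator.  Shifts
    that push the object outside the FOV are rejected and logged.
    """
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    n = basis.mode_count
    if plan is None:
        plan = RepetitionPlan.uniform(n)
    if rng is None:
        rng = noise.rng()
    split = illumination.azimuth_deg if illumination is not None else 0.0
    c_o_list, c_m_list, kept, rejected, records = [], [], [], [], []
    for idx, sh in enumerate(shifts):
        shifted = cal_object.shifted(sh[: basis.config.dim])
        try:
            shifted.require_confined(basis.config)
        except ValueError as err:
            logger.info("calibration shift %s rejected: %s", sh, err)
            rejected.append((idx, tuple(sh)))
            continue
        c_o = object_coefficients(shifted, basis, illumination)
        band = object_band_field(shifted, basis, illumination)
        c_m, rec = measure_vector(
            band, basis, n, r, plan, noise, s_r=s_r,
            split_azimuth_deg=split, rng=rng,
        )
        c_o_list.append(c_o)
        c_m_list.append(c_m)
        kept.append(sh)
        records.append(rec)
    if len(c_o_list) < basis.mode_count:
        raise ValueError(
            f"only {len(c_o_list)} usable calibration shifts for "
            f"{basis.mode_count} modes"
        )
    return CalibrationEnsemble(
        c_o=np.array(c_o_list),
        c_m=np.array(c_m_list),
        shifts=np.array(kept),
        rejected=rejected,
        records=records,
        s_r=s_r,
    )


def fit_transfer_matrix(
    ensemble: CalibrationEnsemble, reference_index: int = 0
) -> TransferMatrix:
    """Least-squares fit of T minimizing Σ_l ‖c_m⁽ˡ⁾ − T·c_o⁽ˡ⁾‖²."""
    Co, Cm = ensemble.c_o, ensemble.c_m
    L, n = Co.shape
    rank = np.linalg.matrix_rank(Co)
    if rank < n:
        raise ValueError(
            f"calibration ensemble is rank-deficient: rank {rank} < {n} modes "
            f"(L = {L} shifts)"
        )
    Tt, *_ = np.linalg.lstsq(Co, Cm, rcond=None)
    T = Tt.T
    resid = float(np.linalg.norm(Cm - Co @ Tt) / max(np.linalg.norm(Cm), 1e-300))
    return TransferMatrix(
        matrix=T,
        reference_index=reference_index,
        calibration_size=L,
        residual=resid,
        s_r=ensemble.s_r,
    )


def _check_psd(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.conj().T, atol=1e-10 * max(1.0, np.abs(M).max())):
        raise ValueError(f"{name} covariance is not Hermitian")
    w = np.linalg.eigvalsh(0.5 * (M + M.conj().T))
    if w.min() < -1e-10 * max(abs(w.max()), 1.0):
        raise ValueError(f"{name} covariance is not positive semi-definite")


def mmse_filter(
    T: TransferMatrix,
    noise_cov: np.ndarray,
    prior_cov: Optional[np.ndarray] = None,
) -> FilterMatrix:
    """Linear MMSE inverse W = C_prior·Tᴴ·(T·C_prior·Tᴴ + C_noise)⁻¹."""
    M = T.matrix
    n = M.shape[1]
    if prior_cov is None:
        prior_cov = np.eye(n)
    prior_cov = np.asarray(prior_cov, dtype=complex)
    noise_cov = np.asarray(noise_cov, dtype=complex)
    _check_psd(prior_cov, "prior")
    _check_psd(noise_cov, "noise")
    G = M @ prior_cov @ M.conj().T + noise_cov
    W = prior_cov @ M.conj().T @ np.linalg.pinv(G)
    return FilterMatrix(matrix=W, prior_cov=prior_cov, noise_cov=noise_cov)


def empirical_prior(ensemble: CalibrationEnsemble, shrinkage: float = 0.5) -> np.ndarray:
    """Signal prior: empirical c_o covariance shrunk toward a scaled identity."""
    Co = ensemble.c_o
    C = (Co.conj().T @ Co) / Co.shape[0]
    C = 0.5 * (C + C.conj().T)
    iso = np.eye(C.shape[0]) * (np.trace(C).real / C.shape[0])
    return (1.0 - shrinkage) * C + shrinkage * iso


def noise_covariance(
    ensemble: CalibrationEnsemble, poisson: bool = True
) -> np.ndarray:
    """Diagonal shot-noise covariance from the propagated per-mode errors.

    With shot noise disabled the measurements are exact and the covariance
    is identically zero (the MMSE filter then reduces to the pseudoinverse).
    """
    eps = np.array([rec.uncertainties for rec in ensemble.records])
    n = eps.shape[1]
    if not poisson:
        return np.zeros((n, n), dtype=complex)
    return np.diag(np.mean(eps**2, axis=0)).astype(complex)


def noise_covariance_scaled(
    base: np.ndarray, old_plan: RepetitionPlan, new_plan: RepetitionPlan
) -> np.ndarray:
    """Rescale a diagonal shot-noise covariance for a new repetition plan
    (entries ∝ 1/(R_kk·P_sin))."""
    ratio = old_plan.r_kk.astype(float) / new_plan.r_kk.astype(float)
    return base * np.diag(ratio)


# ---------------------------------------------------------------------------
# repetition allocation (accuracy criterion)


def accuracy_lhs(
    T: TransferMatrix, plan: RepetitionPlan, p_sin: float
) -> np.ndarray:
    """Left side of the per-coefficient accuracy criterion, one per mode."""
    M = T.matrix
    r = T.reference_index
    ReTT = np.real(M.conj().T @ M)
    R = np.diag(plan.r_kk.astype(float))
    ReTRT = np.real(M.conj().T @ R @ M)
    inv1 = np.linalg.inv(ReTT)
    inv2 = np.linalg.inv(ReTRT)
    return p_sin * inv1[r, r] / np.diag(inv2)


def allocate_repetitions(
    T: TransferMatrix,
    p_sin: float,
    n_target_modes: Optional[int] = None,
    max_reps: int = 2**34,
) -> RepetitionPlan:
    """Smallest integer diagonal R satisfying the accuracy criterion.

    Doubles the repetition count of the currently worst coefficient until
    the criterion holds for all modes, then bisects each count down
    (largest first).  For diagonal T with reference index r this lands
    exactly on R_ii = ceil(|γ_r|²/(P_sin·|γ_i|²)).
    """
    M = T.matrix
    n_p, n = M.shape
    if n_target_modes is None:
        n_target_modes = n
    if np.linalg.matrix_rank(M) < n:
        raise ValueError("transfer matrix is not full column rank")
    plan = RepetitionPlan.uniform(n_p, 1)

    def lhs(p):
        return accuracy_lhs(T, p, p_sin)[:n_target_modes]

    guard = 0
    while True:
        vals = lhs(plan)
        if np.all(vals >= 1.0):
            break
        worst = int(np.argmin(vals))
        k = min(worst, n_p - 1)
        if plan.r_kk[k] >= max_reps:
            raise ValueError(
                f"accuracy criterion unsatisfiable for mode {worst + 1} "
                f"(repetitions exceed {max_reps}); eigenvalue underflow"
            )
        new = plan.r_kk.copy()
        new[k] *= 2
        plan = RepetitionPlan(new)
        guard += 1
        if guard > 10000:
            raise RuntimeError("repetition search failed to terminate")

    # bisect each count down, largest first
    for k in np.argsort(-plan.r_kk):
        lo, hi = 1, int(plan.r_kk[k])
        while lo < hi:
            mid = (lo + hi) // 2
            trial = plan.r_kk.copy()
            trial[k] = mid
            if np.all(accuracy_lhs(T, RepetitionPlan(trial), p_sin)[:n_target_modes] >= 1.0):
                hi = mid
            else:
                lo = mid + 1
        new = plan.r_kk.copy()
        new[k] = lo
        plan = RepetitionPlan(new)
    return plan


def characterization_plan(
    cal_object: SyntheticObject,
    shifts: np.ndarray,
    basis: SlepianBasis,
    noise: NoiseModel,
    r: int = 0,
    illumination: Optional[IlluminationConfig] = None,
    relative_error: float = 0.1,
    max_reps: int = 2**30,
) -> RepetitionPlan:
    """Repetitions needed to *fit* each transfer-matrix row accurately.

    The calibration object is known, so everything needed can be computed
    from the noiseless model: the shot-noise level ε_i of each measured
    coefficient at one repetition, and the smallest singular value
    σ_min of the stacked true-coefficient matrix, which controls how
    strongly measurement noise is amplified into the least-squares fit.
    Fit errors anywhere in a row leak into every column, so the noise
    target for *all* rows is set by the weakest column scale min|γ_j|
    (otherwise strong-row noise fakes sensitivity in the weak columns):

        R_i = ceil( (ε_i / (relative_error·min|γ|·σ_min))² ).

    This is far more demanding than the object-measurement criterion,
    because the small calibration feature excites high-order modes only
    weakly — the photon budgets it implies reach the 10⁹–10¹² scale of
    the deep super-resolution trade-off.  Counts are capped at
    ``max_reps`` with a log entry — beyond that budget the channel is not
    characterizable shot-noise-limited.
    """
    exact = NoiseModel(
        photons_per_submeasurement=noise.photons_per_submeasurement, poisson=False
    )
    ens = simulate_calibration(
        cal_object, shifts, basis, exact, r=r, illumination=illumination
    )
    eps1 = np.mean(np.array([rec.uncertainties for rec in ens.records]), axis=0)
    sigma_min = float(np.linalg.svd(ens.c_o, compute_uv=False)[-1])
    target = relative_error * float(np.min(np.abs(basis.gammas))) * sigma_min
    reps = np.ones(basis.mode_count, dtype=int)
    for i in range(basis.mode_count):
        if target <= 0:
            continue
        need = int(np.ceil((eps1[i] / target) ** 2))
        if need > max_reps:
            logger.warning(
                "mode %d needs %.2g repetitions for filter characterization; "
                "capping at %d", i + 1, need, max_reps,
            )
            need = max_reps
        reps[i] = max(1, need)
    return RepetitionPlan(reps)


@dataclass
class IterationTrace:
    residuals: list
    filter_norms: list
    plans: list
    converged: bool


def iterate_filter(
    cal_object: SyntheticObject,
    shifts: np.ndarray,
    basis: SlepianBasis,
    noise: NoiseModel,
    initial_plan: Optional[RepetitionPlan] = None,
    r: int = 0,
    illumination: Optional[IlluminationConfig] = None,
    s_r: float = 1.0,
    rtol: float = 1e-3,
    max_iter: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TransferMatrix, FilterMatrix, RepetitionPlan, IterationTrace]:
    """Alternate calibration → fit → allocation until W stabilizes.

    Each round quadruples the calibration repetition budget (refinement
    by adding repetitions, halving the fit noise per round), refits T and
    W, and reallocates the object-measurement plan from the refined T.
    Convergence: relative change of ‖W‖_F and absolute change of the
    (already relative) fit residual both below ``rtol``.  Noiseless
    systems converge in one refinement step.
    """
    n = basis.mode_count
    if initial_plan is not None:
        cal_plan = initial_plan
    elif noise.poisson:
        cal_plan = characterization_plan(
            cal_object, shifts, basis, noise, r=r, illumination=illumination
        )
    else:
        cal_plan = RepetitionPlan.uniform(n)
    if rng is None:
        rng = noise.rng()
    trace = IterationTrace([], [], [], converged=False)
    prev_W = None
    prev_res = None
    T = W = plan = None
    for it in range(max_iter):
        ens = simulate_calibration(
            cal_object, shifts, basis, noise, plan=cal_plan, r=r,
            illumination=illumination, s_r=s_r, rng=rng,
        )
        T = fit_transfer_matrix(ens, reference_index=r)
        Cn = noise_covariance(ens, noise.poisson)
        W = mmse_filter(T, Cn, empirical_prior(ens))
        plan = allocate_repetitions(T, noise.photons_per_submeasurement)
        wn = float(np.linalg.norm(W.matrix))
        trace.residuals.append(T.residual)
        trace.filter_norms.append(wn)
        trace.plans.append(plan.r_kk.copy())
        if prev_W is not None:
            dw = abs(wn - prev_W) / max(prev_W, 1e-300)
            dr = abs(T.residual - prev_res)
            if dw < rtol and dr < rtol:
                trace.converged = True
                break
        prev_W, prev_res = wn, T.residual
        if noise.poisson:
            cal_plan = RepetitionPlan(cal_plan.r_kk * 4)
    if not trace.converged:
        logger.warning("filter iteration did not converge in %d rounds", max_iter)
    return T, W, plan, trace
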