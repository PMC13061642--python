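"""Shot-noise-limited interferometric measurement of Slepian–Pollak coefficients.

The instrument model is a common-path, single-pixel interferometer: a
reconfigurable mask in the Fourier plane collimates one *target* mode and
one strong *reference* mode onto the detector pixel conjugate to the
object centroid.  The band is split into two half-fields along the
azimuth perpendicular to the illumination direction; in half-config A the
target mask occupies one half and the phase-stepped reference the other,
and in config B the halves swap.  Four phase steps × two configs give the
eight intensity submeasurements per mode; each is Poisson-distributed
(shot-noise-limited) and repeated R_kk times.

The reference half-amplitudes used to demodulate the cross-terms are taken
from the noiseless forward model — a "locked reference" idealization of
the drift-corrected strong reference channel — so the estimator is exactly
linear in the field and exact in the noiseless limit; Poisson noise enters
only through the eight intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fields import ComplexField, QuadGrid
from .slepian import SlepianBasis

PHASE_STEPS = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)


@dataclass
class NoiseModel:
    """Shot-noise configuration.

    ``photons_per_submeasurement`` (P_sin) scales the brightest expected
    submeasurement of the reference channel; with ``poisson=False`` the
    simulator returns exact expectations.
    """

    photons_per_submeasurement: float = 1e4
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.photons_per_submeasurement <= 0:
            raise ValueError("P_sin must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class RepetitionPlan:
    """Diagonal repetition counts R_kk, one per measured coefficient."""

    r_kk: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r_kk)
        if not np.issubdtype(r.dtype, np.integer):
            if not np.allclose(r, np.round(r)):
                raise ValueError("repetition counts must be integers")
            r = np.round(r).astype(int)
        if np.any(r < 1):
            raise ValueError("all repetition counts must be >= 1")
        self.r_kk = r

    def __len__(self):
        return len(self.r_kk)

    @classmethod
    def uniform(cls, n: int, reps: int = 1) -> "RepetitionPlan":
        return cls(np.full(n, reps, dtype=int))


@dataclass
class MeasurementRecord:
    """Raw counts and derived quantities of one coefficient vector."""

    counts: dict = field(default_factory=dict)  # k -> (R_kk, 8) int array
    keep_counts: bool = True
    photons_per_mode: dict = field(default_factory=dict)  # k -> total counts
    coefficients: Optional[np.ndarray] = None
    uncertainties: Optional[np.ndarray] = None
    repetitions: Optional[np.ndarray] = None
    photon_total: float = 0.0
    seed: Optional[int] = None
    scale: float = 1.0

    def to_table(self):
        import pandas as pd

        rows = []
        for k, cnt in self.counts.items():
            rows.append(
                {
                    "mode": k + 1,
                    "repetitions": cnt.shape[0],
                    "total_counts": int(cnt.sum()),
                    "c_m_real": float(np.real(self.coefficients[k])),
                    "c_m_imag": float(np.imag(self.coefficients[k])),
                    "uncertainty": float(self.uncertainties[k]),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# masks


def _half_masks(basis: SlepianBasis, split_azimuth_deg: float) -> np.ndarray:
    """Boolean membership of band nodes in the positive half-field.

    The band is cut along the azimuth perpendicular to the illumination
    direction; nodes with k·û > 0 (û along the illumination azimuth) form
    the positive half.
    """
    k = basis.band_grid.coords()
    if basis.config.dim == 1:
        u = np.array([math.cos(math.radians(split_azimuth_deg))])
        u[0] = 1.0 if u[0] >= 0 else -1.0
    else:
        a = math.radians(split_azimuth_deg)
        u = np.array([math.cos(a), math.sin(a)])
    return (k @ u) > 0


def mode_mask(
    basis: SlepianBasis,
    k: int,
    r: int,
    half_config: str,
    phase_step: float,
    split_azimuth_deg: float = 0.0,
) -> ComplexField:
    """Fourier-plane mask for one submeasurement.

    The mask equals conj(Ŝ_k) on the target half and e^{iφ}·conj(Ŝ_r) on
    the complementary (reference) half; configs "A" and "B" swap the
    halves.  Indices are 0-based.
    """
    if half_config not in ("A", "B"):
        raise ValueError("half_config must be 'A' or 'B'")
    nm = basis.mode_count
    if not (0 <= k < nm and 0 <= r < nm):
        raise ValueError(f"mode indices must lie in [0, {nm})")
    bm = basis.band_modes()
    pos = _half_masks(basis, split_azimuth_deg)
    target_half = pos if half_config == "A" else ~pos
    mask = np.zeros(basis.band_grid.n_points, dtype=complex)
    mask[target_half] = np.conj(bm[target_half, k])
    mask[~target_half] = np.exp(1j * phase_step) * np.conj(bm[~target_half, r])
    return ComplexField(samples=mask, grid=basis.band_grid, plane="fourier")


# ---------------------------------------------------------------------------
# intensities

def _on_axis_amplitude(fourier_field: ComplexField, mask: ComplexField) -> complex:
    """Amplitude at the selected pixel: band integral of mask × field."""
    wb = mask.grid.weights
    return complex(np.sum(wb * mask.samples.ravel() * fourier_field.samples.ravel()))


def photon_scale(
    fourier_field: ComplexField,
    basis: SlepianBasis,
    r: int,
    noise: NoiseModel,
    split_azimuth_deg: float = 0.0,
) -> float:
    """Counts-per-intensity-unit such that the brightest expected
    submeasurement of the reference self-interference channel is P_sin."""
    peak = 0.0
    for cfgname in ("A", "B"):
        for ph in PHASE_STEPS:
            m = mode_mask(basis, r, r, cfgname, ph, split_azimuth_deg)
            peak = max(peak, abs(_on_axis_amplitude(fourier_field, m)) ** 2)
    if peak <= 0:
        raise ValueError("reference channel has zero energy; cannot set exposure")
    return noise.photons_per_submeasurement / peak


def submeasurement_intensity(
    fourier_field: ComplexField,
    mask: ComplexField,
    noise: NoiseModel,
    scale: float = 1.0,
    repetitions: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Photon counts at the selected pixel for one mask, per repetition."""
    if scale <= 0:
        raise ValueError("photon scale must be positive (zero-energy normalization)")
    mu = scale * abs(_on_axis_amplitude(fourier_field, mask)) ** 2
    if not noise.poisson:
        return np.full(repetitions, mu)
    if rng is None:
        rng = noise.rng()
    return rng.poisson(mu, size=repetitions).astype(float)


# ---------------------------------------------------------------------------
# coefficient estimation


def _reference_half_amplitudes(
    fourier_field: ComplexField, basis: SlepianBasis, r: int, split_azimuth_deg: float
) -> tuple[complex, complex]:
    """Noiseless reference amplitudes (u, v) on the two half-fields."""
    bm = basis.band_modes()
    wb = basis.band_grid.weights
    pos = _half_masks(basis, split_azimuth_deg)
    f = fourier_field.samples.ravel()
    u = complex(np.sum(wb[pos] * np.conj(bm[pos, r]) * f[pos]))
    v = complex(np.sum(wb[~pos] * np.conj(bm[~pos, r]) * f[~pos]))
    return u, v


def _cross_term(int_by_phase: np.ndarray) -> complex:
    """Phase-shifting demodulation: cross = target × conj(reference).

    ``int_by_phase`` holds mean intensities at steps (0, π/2, π, 3π/2)
    applied to the reference half; the four-step combination
    [(I₀ − I_π) − i(I_{3π/2} − I_{π/2})]/4 isolates a·conj(b).
    """
    i0, i90, i180, i270 = int_by_phase
    return complex((i0 - i180) - 1j * (i270 - i90)) / 4.0


def measure_coefficient(
    fourier_field: ComplexField,
    basis: SlepianBasis,
    k: int,
    r: int,
    repetitions: int,
    noise: NoiseModel,
    scale: Optional[float] = None,
    s_r: float = 1.0,
    split_azimuth_deg: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    record: Optional[MeasurementRecord] = None,
) -> tuple[complex, float]:
    """Estimate one complex coefficient from eight submeasurements × R reps.

    Returns ``(c_m_k, ε_k)`` where ε_k is the propagated shot-noise
    standard error.  Noiseless, the estimate equals the exact band inner
    product <Ŝ_k, field>/s_r.
    """
    if repetitions < 1:
        raise ValueError("repetition count must be >= 1")
    if rng is None:
        rng = noise.rng()
    if scale is None:
        scale = photon_scale(fourier_field, basis, r, noise, split_azimuth_deg)
    u, v = _reference_half_amplitudes(fourier_field, basis, r, split_azimuth_deg)
    if abs(u) < 1e-300 or abs(v) < 1e-300:
        raise ValueError("reference mode has zero energy on a half-field")

    bm = basis.band_modes()
    wb = basis.band_grid.weights
    pos = _half_masks(basis, split_azimuth_deg)
    f = fourier_field.samples.ravel()
    # target half-amplitudes; with the reference amplitudes these generate
    # all eight expected intensities without building the masks explicitly
    a_pos = complex(np.sum(wb[pos] * np.conj(bm[pos, k]) * f[pos]))
    a_neg = complex(np.sum(wb[~pos] * np.conj(bm[~pos, k]) * f[~pos]))

    keep = record is not None and record.keep_counts and repetitions <= 4096
    est = 0.0 + 0.0j
    var_sum = 0.0
    count_total = 0.0
    all_counts = np.zeros((repetitions, 8)) if keep else None
    for ci, (a, b) in enumerate(((a_pos, v), (a_neg, u))):  # configs A, B
        means = np.empty(4)
        for pi, ph in enumerate(PHASE_STEPS):
            mu = scale * abs(a + np.exp(1j * ph) * b) ** 2
            if not noise.poisson:
                mean_counts = mu
                if keep:
                    all_counts[:, ci * 4 + pi] = mu
            elif keep:
                counts = rng.poisson(mu, size=repetitions).astype(float)
                all_counts[:, ci * 4 + pi] = counts
                mean_counts = counts.mean()
            else:
                # sum of R Poisson(μ) draws ≡ one Poisson(R·μ) draw
                mean_counts = rng.poisson(mu * repetitions) / repetitions
            count_total += mean_counts * repetitions
            means[pi] = mean_counts / scale
            var_sum += mean_counts / (repetitions * scale**2) / (
                16.0 * abs(b) ** 2
            )
        est += _cross_term(means) / np.conj(b)

    eps = math.sqrt(var_sum) / s_r
    if record is not None:
        record.photon_total += count_total
        record.photons_per_mode[k] = record.photons_per_mode.get(k, 0.0) + count_total
        if keep:
            record.counts[k] = all_counts
    return complex(est / s_r), eps


def measure_vector(
    fourier_field: ComplexField,
    basis: SlepianBasis,
    n_prime: int,
    r: int,
    plan: RepetitionPlan,
    noise: NoiseModel,
    s_r: float = 1.0,
    split_azimuth_deg: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    keep_counts: bool = False,
) -> tuple[np.ndarray, MeasurementRecord]:
    """Sequentially measure the first n′ coefficients of a band field."""
    if n_prime > basis.mode_count:
        raise ValueError(f"n_prime={n_prime} exceeds basis mode count {basis.mode_count}")
    if len(plan) < n_prime:
        raise ValueError("repetition plan shorter than n_prime")
    if rng is None:
        rng = noise.rng()
    scale = photon_scale(fourier_field, basis, r, noise, split_azimuth_deg)
    record = MeasurementRecord(seed=noise.seed, scale=scale, keep_counts=keep_counts)
    c_m = np.empty(n_prime, dtype=complex)
    eps = np.empty(n_prime)
    for k in range(n_prime):
        c_m[k], eps[k] = measure_coefficient(
            fourier_field,
            basis,
            k,
            r,
            int(plan.r_kk[k]),
            noise,
            scale=scale,
            s_r=s_r,
            split_azimuth_deg=split_azimuth_deg,
            rng=rng,
            record=record,
        )
    record.coefficients = c_m
    record.uncertainties = eps
    record.repetitions = plan.r_kk[:n_prime].copy()
    return c_m, record
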