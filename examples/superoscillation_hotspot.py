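"""Synthesize a superoscillatory hotspot — the reverse of the imaging task.

A band-limited Fourier-plane mask Σ c_i·Ŝ_i/γ_i* produces the target
field Σ c_i·S_i inside the FOV.  Weighting the modes of a delta-like
target makes the in-FOV spot narrower than the diffraction-limited sinc,
at the price of mask energy growing as Σ|c_i/γ_i|².
"""

import numpy as np

from lsom import OpticalConfig, band_to_fov, compute_basis, synthesize_superoscillation
from lsom.metrics import fwhm_1d

cfg = OpticalConfig(dim=1)
basis = compute_basis(cfg, 6)

# target: the 6-mode projection of a delta at the origin
c = basis.evaluate(np.array([[0.0]]))[0]
mask = synthesize_superoscillation(c, basis)

xs = np.linspace(-0.4, 0.4, 2001)
spot = band_to_fov(mask, basis, points=xs[:, None])
fw, _ = fwhm_1d(np.abs(spot) ** 2, xs)

K = cfg.band_limit
safe = np.where(xs == 0, 1.0, K * xs)
sinc = np.where(xs == 0, 1.0, np.sin(K * xs) / safe) ** 2
fw_sinc, _ = fwhm_1d(sinc, xs)

print(f"hotspot FWHM      : {fw:.4f} λ  (λ/{1 / fw:.1f})")
print(f"diffraction limit : {fw_sinc:.4f} λ  (λ/{1 / fw_sinc:.1f})")
print(f"mask energy cost  : {mask.energy():.1f}  (= Σ|c_i/γ_i|²; the price of the narrow spot)")
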