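"""Shot-noise-limited 1D measurement with a repetition plan.

Shows the full noisy loop: filter characterization on a scanned 0.125λ
line, allocation of the per-coefficient repetition counts from the
accuracy criterion, and coefficient recovery for a held-out object.
"""

import numpy as np

from lsom import (
    LsomPipeline,
    NoiseModel,
    RandomScatterers,
    accuracy_lhs,
    compute_basis,
    estimate_coefficients,
    object_coefficients,
    preset,
)

p = preset("paper_1d", seed=0)
basis = compute_basis(p.optical, p.n_modes)
noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=0)
pipe = LsomPipeline.calibrated(basis, illuminations=p.illuminations, noise=noise)

print("repetition plan R_kk:", pipe.plan.r_kk)
print("accuracy criterion LHS (must be ≥ 1):",
      np.round(accuracy_lhs(pipe.transfer, pipe.plan, noise.photons_per_submeasurement), 2))

obj = RandomScatterers(n=4, seed=77, diameter=0.06, max_radius=0.25, dim=1)
c_o = object_coefficients(obj, basis, p.illuminations[0])
c_m, record = pipe.measure(obj, p.illuminations[0], rng=np.random.default_rng(1))
c_e = estimate_coefficients(c_m, pipe.filter)

print(f"\nphotons detected in this acquisition: {record.photon_total:.3e}")
print("mode   true c_o                estimated c_e")
for i, (a, b) in enumerate(zip(c_o, c_e), start=1):
    print(f"  {i}   {a.real:+.4f}{a.imag:+.4f}j     {b.real:+.4f}{b.imag:+.4f}j")
err = np.linalg.norm(c_e - c_o) / np.linalg.norm(c_o)
print(f"relative coefficient error: {err:.3f}"
      "  (the weakest channel sits near SNR≈1 at the minimal plan)")
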