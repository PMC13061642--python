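"""Compute the Slepian–Pollak bases of the demonstration geometry.

The FOV is D = 0.8λ and the objective collects up to K = 0.9·k0.  Each
mode's |γ_i|² is the fraction of its energy that survives propagation
through the diffraction-limited band; the super-exponential decay of
these ratios is what makes high-order coefficients expensive to measure
— and what sets the resolution/photon-budget trade-off.
"""

import numpy as np

from lsom import OpticalConfig, compute_basis, energy_transfer_ratios

for dim, n_modes in ((1, 6), (2, 13)):
    cfg = OpticalConfig(dim=dim)
    basis = compute_basis(cfg, n_modes)
    ratios = energy_transfer_ratios(basis)
    print(f"\n{dim}D basis, {n_modes} modes, D = {cfg.fov_size}λ, NA = {cfg.objective_na}")
    print(f"  space-bandwidth parameter c = {cfg.space_bandwidth:.4f}")
    for i, (lam, r) in enumerate(zip(basis.concentration_ratios, ratios), start=1):
        mark = ""
        if dim == 2 and basis.angular_orders is not None:
            mark = f"  (angular order {basis.angular_orders[i - 1]})"
        print(f"  mode {i:2d}: |γ|² = {lam:.3e}   |γ_i/γ_1|² = {r:.3e}{mark}")
    print(f"  weakest channel ratio: {ratios.min():.2e}")
    # the last line is the channel strength the measurement must overcome:
    # 1e-6-scale ratios mean a million-fold weaker signal than mode 1
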