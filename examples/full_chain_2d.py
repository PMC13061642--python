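"""Image a sub-diffraction double dot through the complete 2D chain.

Calibrates the transfer matrix on a scanned 0.125λ dot, measures the 13
Slepian–Pollak coefficients of a 0.15λ-separation dot pair under four
TIR illumination directions, inverts with the MMSE filter, and merges
the reconstructions coherently.  Conventional NA-0.9 coherent imaging
cannot resolve this pair (Abbe limit ≈ 0.56λ for coherent light).
"""

import numpy as np

from lsom import (
    DoubleDot,
    LsomPipeline,
    OpticalConfig,
    RasterGrid,
    compute_basis,
    effective_na,
    ideal_fourier_image,
    make_object,
    preset,
    psf_full_chain,
)

p = preset("paper_2d")
basis = compute_basis(p.optical, p.n_modes)
pipe = LsomPipeline.calibrated(basis, illuminations=p.illuminations)

# full-chain point spread function, averaged over FOV positions
rep = psf_full_chain(
    [(0.0, 0.0), (0.1, 0.0), (0.0, 0.1), (-0.1, 0.1)],
    pipe,
    RasterGrid.centered(0.8, 161, 2),
)
print(f"mean PSF FWHM: {rep.mean_fwhm:.4f} λ  (λ/{1 / rep.mean_fwhm:.1f})")

# sub-diffraction pair: resolved by the chain, not by the objective
obj = DoubleDot(separation=0.15, diameter=0.06)
render = RasterGrid.centered(0.8, 121, 2)
img = pipe.reconstruct(obj, render)
truth = make_object(obj, render)
na_eff, flag = effective_na(img.field, truth, np.arange(0.3, 6.01, 0.1))
print(f"effective NA of the reconstruction: {na_eff:.2f} {('(' + flag + ')') if flag else ''}")

conv = ideal_fourier_image(truth, 0.9)
mid = 60
prof = np.abs(conv.samples[:, mid]) ** 2
dip = prof[mid] / prof.max()
print(f"conventional NA-0.9 image: center-to-peak intensity ratio {dip:.2f}"
      " (≈1 means the two dots blur into one lobe)")
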