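"""Render a synthetic core and separate its stains.

A core image is built through the Beer–Lambert forward model (hematoxylin
nuclei, DAB on positive-cell cytoplasm), then deconvolved: RGB -> optical
density -> per-image stain-matrix estimation -> per-pixel concentrations.
"""

import numpy as np

from tmaquant import (
    CoreImageConfig,
    estimate_stain_matrix,
    generate_core_image,
    rgb_to_od,
    unmix,
)

cfg = CoreImageConfig(n_cells=30, cell_radius_um=6.0, fraction_positive=0.3,
                      n_mucus_blobs=2, mucus_radius_um=6.0, seed=42)
image, truth = generate_core_image(cfg)
print(f"rendered {cfg.image_size_px} core: {cfg.n_cells} cells, "
      f"{int(truth.cell_positivity.sum())} truly positive")

od = rgb_to_od(image)
sm = estimate_stain_matrix(od)
print("estimated hematoxylin absorbance:", np.round(sm.hematoxylin, 3))
print("estimated DAB absorbance:        ", np.round(sm.dab, 3))
print("planted vectors:                 ", np.round(np.asarray(cfg.stain_vectors), 3))

c_h, c_d = unmix(od, sm)
err_h = np.abs(c_h - truth.c_h).mean()
err_d = np.abs(c_d - truth.c_d).mean()
print(f"mean abs concentration error: hematoxylin {err_h:.4f}, DAB {err_d:.4f}")
# The estimated absorbance directions sit within a couple of degrees of the
# planted ones, so the recovered concentration maps track the planted maps
# to a few hundredths of a normalized unit even with sensor noise.
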