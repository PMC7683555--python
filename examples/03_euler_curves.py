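"""Euler characteristic curves of a phantom and their FPCA summary.

Thresholding the standardized volume from high to low grows the excursion
set; its Euler characteristic (components - handles + voids, normalized per
liver voxel) traces a curve whose shape encodes how vessels tunnel through
the parenchyma.  The curves are smoothed by right-to-left integration and
summarized by their first three functional principal component scores.
"""

import numpy as np

from hbpqa import PhantomSpec, generate_phantom, preprocess_pipeline
from hbpqa.ecc import ecc_curve, fit_fpca, fpc_scores, smooth_ecc

curves = []
for label, contrast, seed in [("adequate", 0.8, 1), ("adequate", 0.8, 2),
                              ("suboptimal", 0.02, 3), ("suboptimal", 0.02, 4),
                              ("adequate", 0.7, 5), ("suboptimal", 0.03, 6)]:
    vol = generate_phantom(PhantomSpec(contrast=contrast, label=label,
                                       seed=seed))
    std = preprocess_pipeline(vol)
    c = ecc_curve(std)
    curves.append((label, smooth_ecc(c)))
    u_mid = len(c.thresholds) // 2
    print(f"{label:11s} chi at u=0: {c.chi[u_mid]:4d}  "
          f"min chi: {c.chi.min():4d}  max chi: {c.chi.max():4d}")

model = fit_fpca([c for _, c in curves], K=3)
with np.printoptions(precision=2):
    print(f"\nFPCA eigenvalues: {model.eigenvalues}")
for label, c in curves[:4]:
    scores = fpc_scores(model, c)
    with np.printoptions(precision=3, suppress=True):
        print(f"{label:11s} FPC scores: {scores * 1e3} (x 1e-3)")
print()
print("Negative chi at mid-thresholds reflects vessel handles in adequate "
      "exams; the first FPC score separates the two curve shapes.")
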