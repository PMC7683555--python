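"""Fit the two-component intensity mixture to a preprocessed phantom.

After standardization the in-mask intensities have mean 0 / sd 1, so the
five mixture parameters obey two moment identities and the triple
(mu1, sigma1, pi) determines the whole fit — those three numbers are the
intensity features.
"""

from hbpqa import PhantomSpec, generate_phantom, preprocess_pipeline
from hbpqa.gmm import constraint_residuals, em_fit, gmm_features

vol = generate_phantom(PhantomSpec(seed=7))
std = preprocess_pipeline(vol)
params, trace = em_fit(std.in_mask())
mu1, sigma1, pi = gmm_features(params)
c1, c2 = constraint_residuals(params)

print(f"EM converged in {trace.iterations} iterations "
      f"(converged={trace.converged})")
print(f"dark (vessel) component:   mu1={mu1:.3f}  sigma1={sigma1:.3f}")
print(f"bright (parenchyma) component: mu2={params.mu2:.3f} "
      f"sigma2={params.sigma2:.3f}  weight pi={pi:.3f}")
print(f"standardization identities: first-moment residual {c1:.2e}, "
      f"second-moment residual {c2:.2e}")
print()
print("mu1 well below zero means the fitted vessel class is much darker "
      "than the parenchyma — the signature of an adequate exam; the "
      "near-zero residuals confirm (mu2, sigma2) are redundant given the "
      "feature triple.")
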