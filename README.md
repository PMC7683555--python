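# hbpqa — handcrafted-feature adequacy assessment of hepatobiliary-phase liver MRI

On an adequate hepatobiliary-phase (HBP) liver MR exam the parenchyma
retains intracellular contrast agent and blood vessels appear dark against
a bright background; when uptake is impaired or the acquisition is too
early, vessels become near-isointense and the exam is *suboptimal* for
lesion detection.  `hbpqa` implements an interpretable pipeline that
classifies masked 3D liver volumes as adequate vs. suboptimal from three
small families of handcrafted features:

- **Intensity** — a two-component Gaussian mixture
  `(1 − π)·N(μ1, σ1²) + π·N(μ2, σ2²)` fit by EM to standardized in-mask
  intensities (component 1 = darker vessels).  Standardization imposes
  `(1 − π)μ1 + πμ2 = 0` and `(1 − π)(σ1² + μ1²) + π(σ2² + μ2²) = 1`, so
  the triple (μ1, σ1, π) carries the whole fit.
- **Topology** — Euler characteristic curves u ↦ χ(A_u) of the
  superlevel-set filtration `A_u = {s : I(s) > u}` on the cubical complex
  (χ = V − E + F − C = components − handles + voids), normalized per liver
  voxel, smoothed by right-to-left integration, and reduced to the first
  three functional principal component scores
  `ξ_k = ∫ (X(u) − μ(u)) φ_k(u) du`.
- **Texture** — gray-level co-occurrence at distance 1 over the 13 unique
  3D directions, summarized by the Haralick statistics energy, correlation,
  entropy and inverse difference moment.

The 10 features feed a random forest tuned by stratified 10-fold
cross-validated AUC (split variables × trees); evaluation reports AUC and
**specificity at 95% sensitivity** (suboptimal = positive class, so missed
suboptimal exams are expensive) with 2000-replicate percentile bootstrap
confidence intervals and Mean Decrease Gini importance.  Because clinical
HBP series cannot be redistributed, the package ships a synthetic liver
phantom generator whose single class-separating knob is the
vessel-to-parenchyma contrast; the full pipeline is developed and verified
on those phantoms.  See `docs/methods.md` for the model details and what
phantom results do and do not show.

## Worked example

```bash
python examples/05_classify_cohort.py
```

```
test AUC = 1.000  95% CI [1.000, 1.000]
specificity at 95% sensitivity = 1.000  95% CI [1.000, 1.000]
feature importance ranks (1 = most important):
   1. glcm_correlation   MDG=0.270
   2. ecc_fpc1           MDG=0.235
   3. glcm_idm           MDG=0.166
   ...
```

A 60-phantom cohort with the default clear contrast gap separates
perfectly on the held-out 30%: the texture correlation, the first Euler-
curve component and the mixture features all respond to the presence of
dark vessel tubes.  Shrinking the contrast gap toward zero drives the AUC
toward 0.5.  The other `examples/` scripts walk through each stage
(phantom generation, mixture fitting, Euler curves, texture).

From Python:

```python
from hbpqa import generate_cohort, run_experiment, ExperimentConfig

cohort = generate_cohort(n_adequate=40, n_suboptimal=20, seed=5)
report = run_experiment(cohort, seed=0, cfg=ExperimentConfig())
print(report.auc, report.specificity_at_95sens, report.mdg_ranks)
```

A thin CLI wraps the same functions for batch runs
(`hbpqa phantom | extract | train-eval | learning-curve`, each taking a
YAML config, a seed and an output path; outputs embed the config hash,
seed and package version).

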