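"""Generate one adequate and one suboptimal liver phantom and compare them.

The phantom is an ellipsoidal "liver" (parenchyma intensity 1.0) pierced by
dark random-walk vessel tubes, with multiplicative low-frequency bias and
magnitude-style noise.  The single knob that separates the classes is the
vessel-to-parenchyma contrast.
"""

import numpy as np

from hbpqa import PhantomSpec, generate_phantom

for label, contrast in [("adequate", 0.8), ("suboptimal", 0.02)]:
    spec = PhantomSpec(contrast=contrast, label=label, seed=1)
    vol = generate_phantom(spec)
    vals = vol.in_mask()
    dark_fraction = (vals < 0.6).mean()
    print(f"{label:11s} contrast={contrast:.2f}  "
          f"liver voxels={vol.n_mask_voxels}  "
          f"in-mask mean={vals.mean():.3f} sd={vals.std():.3f}  "
          f"dark-voxel fraction={dark_fraction:.3f}")

print()
print("The adequate phantom has a visible dark-vessel population "
      "(dark fraction ~ vessel volume); in the suboptimal phantom the "
      "vessels are hidden inside the noise.")
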