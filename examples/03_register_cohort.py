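"""Establish dense correspondence on a cohort with shuffled tessellation.

Each specimen is re-tessellated at a random parametric seam, so vertex
indices do not correspond across the cohort; the RBF registration has to
recover correspondence. Prints the per-specimen fitting RMS (distance of
the warped reference to each target surface).
"""

import warnings

import numpy as np

from myoshape import GeneratorConfig, generate_cohort, iterative_refit

cohort = generate_cohort(
    GeneratorConfig(n_subjects=8, resolution=10, seed=3, shuffle_topology=True)
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    vectors, history, stop, rms = iterative_refit(cohort.meshes[0], cohort.meshes)

print(f"refit rounds (mean RMS, mm): {[round(h, 3) for h in history]}  [{stop}]")
print(f"per-specimen fitting RMS (mm): {np.round(rms, 3)}")
print("# sub-voxel RMS (< 1 mm) means every warped reference vertex sits on")
print("# its target surface to well below typical MRI resolution")
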