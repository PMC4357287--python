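"""Morphospace disparity with rarefaction and bootstrap tests.

Computes the sum of variances on retained form-space axes per group,
rarefied to the smallest group, and tests pairwise differences with
two-tailed bootstrap p-values.
"""

import pandas as pd

import plastevol as pe
from plastevol.pipeline import _unit_groups

ds = pe.reference_dataset(seed=1)
units = pe.species_average(ds.landmarks)
shape = pe.gpa(units)
sizes = pd.Series({u.specimen_id: u.centroid_size for u in units})
scores = pe.retain_axes(pe.pca(pe.form_space(shape, sizes)), 0.05)
groups = _unit_groups(list(scores.index), ds.groups3)

ests = pe.rarefied_bootstrap(scores, groups, "sum_of_variances",
                             n_boot=2000, seed=1)
for g, est in sorted(ests.items()):
    print(f"{g:3s} sum-of-variances {est.boot_mean:.4f} "
          f"[{est.ci_low:.4f}, {est.ci_high:.4f}] (n rarefied {est.rarefied_to})")

p = pe.disparity_difference_test(scores, groups, "Mn", "St",
                                 n_boot=10_000, seed=2)
print(f"Mn vs St two-tailed bootstrap p = {p:.4f}")
# Secondarily monomorphic species occupy the widest region of form space
# in this design, so Mn should top the ranking and the test reject.
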