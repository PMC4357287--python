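"""Procrustes form space from landmark configurations.

Specimens are averaged into species/morph units, superimposed by
generalized Procrustes analysis, augmented with log centroid size (form
space), and summarized by ordinary and phylogenetic PCA.
"""

import pandas as pd

import plastevol as pe

ds = pe.reference_dataset(seed=1)

units = pe.species_average(ds.landmarks)
shape = pe.gpa(units)
sizes = pd.Series({u.specimen_id: u.centroid_size for u in units})
form = pe.form_space(shape, sizes)

res = pe.pca(form)
print("form-space PC variance proportions:",
      [round(p, 3) for p in res.proportions[:4]])
print("log-CS loading on PC1: %.2f" % res.loadings.loc["logCS", "PC1"])

# phylogenetic PCA with the St morph representing dimorphic species
keep = {u.species: u.specimen_id for u in units if u.morph != "Eu"}
form_phylo = form.loc[list(keep.values())]
form_phylo.index = list(keep.keys())
ppc = pe.phylo_pca(form_phylo, ds.tree)
print("phylogenetic form-PCA PC1 proportion: %.2f" % ppc.proportions[0])
# A large PC1 share (size + correlated shape change) is what justifies
# carrying only PC1 into the evolutionary-rate analyses.
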