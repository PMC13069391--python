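"""Visual ordination space and permutation tests of group separation.

PCA summarises the corrected characters, DAPC builds discriminant axes on
the retained components, and PERMANOVA asks whether group centroids in
the full Euclidean morphospace differ more than label permutations allow.
The pairwise table mirrors the familiar publication layout: pseudo-F,
R^2 (effect size), permutation p and Bonferroni-adjusted p.
"""

import morphodelim as md

ds = md.desmognathus_mimic(seed=1)
X = md.corrected_dataset(ds, "pooled").matrix()

pc = md.pca(X)
print("PCA: first three components explain "
      + ", ".join(f"{v:.1%}" for v in pc.explained[:3]))

res = md.dapc(X, ds.otu_labels, n_pcs="auto")
print(f"DAPC: {res.n_pcs} PCs retained, {res.n_axes} discriminant axes, "
      f"training assignment accuracy {res.accuracy:.2f}")

table = md.pairwise_permanova(pc.scores, ds.otu_labels, n_perm=9999, seed=1,
                              adjust="bonferroni", ids=ds.specimen_ids)
print("\nPairwise PERMANOVA (9,999 permutations):")
print(table.round(6).to_string(index=False))
print("-> OTU1 separates strongly from both others; OTU2 vs OTU3 (same"
      " generating distribution) shows a small R^2 and a non-significant p.")
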