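"""Allometric size correction and summary statistics.

Builds a small synthetic dataset with known allometric growth (log-linear
scaling of every character with body size), prints the per-OTU summary
table and then removes the size effect with the pooled-slope adjustment.
After correction the pooled within-OTU regression of every character on
log body size is zero: what remains is shape, not growth.
"""

import numpy as np

import morphodelim as md

ds = md.simulate_allometric(
    group_intercepts={"north": np.array([0.55, 0.90, 0.70]),
                      "south": np.array([0.45, 0.95, 0.60])},
    group_sizes={"north": 30, "south": 25},
    slopes=np.array([0.9, 1.0, 0.75]),       # near-isometric growth
    residual_sd=0.03, seed=42,
)

print("Summary (N / mean / SD / min / max per OTU and character):")
print(md.summarize(ds).to_string(index=False))

corr = md.thorpe_correct(ds, mode="pooled")
print("\nEstimated allometric slopes (truth: 0.9, 1.0, 0.75):")
print(np.round(corr.slopes, 3))

# residual size effect after correction: pooled within-group slope ~ 0
labels = ds.otu_labels.astype(str)
ls = np.log10(ds.body_size)
cs = np.concatenate([ls[labels == g] - ls[labels == g].mean() for g in ("north", "south")])
cx = np.concatenate([corr.values[labels == g, 0]
                     - corr.values[labels == g, 0].mean() for g in ("north", "south")])
print(f"\nresidual slope of character 1 on log size: {(cs @ cx) / (cs @ cs):.2e}")
print("-> effectively zero: size-related variation has been removed.")
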