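"""Fit and apply per-residue confidence models on degraded predictions.

A clean surrogate is too easy — the model comes out perfect and there is
nothing for a classifier to learn.  Here 30% of the amino-acid labels are
corrupted and a few false-positive atoms are injected before the grids are
simulated, so the built model contains both placement and type errors.
Labels come from 3-A matching against the ground truth; two logistic
regressions then score every residue.
"""

import numpy as np

import cryotrace as ct
from cryotrace.confidence import AA_FEATURES, CA_FEATURES

protein = ct.generate_protein(2, [20, 30], seed=11)
bundle = ct.rasterize(protein)

# corrupt 30% of labeled amino-acid voxels and inject false positives
rng = np.random.default_rng(0)
mask = (bundle.aa_labels != 20) & (rng.random(bundle.aa_labels.shape) < 0.3)
bundle.aa_labels[mask] = rng.integers(0, 20, size=int(mask.sum()))
predictions = ct.simulate_predictions(bundle, correct_prob=0.6,
                                      noise_seed=11, fp_rate=2e-4)

result = ct.run_pipeline(grid=bundle.grid, chains=protein.to_sequences(),
                         predictions=predictions)
model = result.model
truth = protein.to_structure()

ca_labels, aa_labels = ct.make_labels(model, truth)
print(f"labels: {ca_labels.sum()}/{len(ca_labels)} placements correct, "
      f"{aa_labels.sum()} types correct")

ca_fit = ct.fit_confidence(ct.make_ca_features(model), ca_labels,
                           schema=CA_FEATURES)
aa_fit = ct.fit_confidence(ct.make_aa_features(model), aa_labels,
                           schema=AA_FEATURES)
annotation = ct.apply_confidence(model, ca_fit, aa_fit)
print(f"mean C-alpha confidence:    {annotation.mean_ca_confidence:.3f}")
print(f"mean amino-acid confidence: {annotation.mean_aa_confidence:.3f}")
# structure-level confidence is the plain average of per-residue scores and
# estimates the match scores an evaluation against the truth would give
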