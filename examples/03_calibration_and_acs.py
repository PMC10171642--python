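"""Evaluate a probabilistic stager: ECE, mean confidence and ACS.

Constructs a perfectly calibrated prediction set (ten predictions at
confidence 0.60 of which exactly six are correct -> ECE 0), a miscalibrated
one, and shows ACS against a scorers' soft-consensus.
"""

import numpy as np

import hypnofuse as hf

# perfectly calibrated: every bin's accuracy equals its mean confidence
row = np.array([0.6, 0.1, 0.1, 0.1, 0.1])
pred = hf.PredictionMatrix(np.tile(row, (10, 1)))
truth = np.array([0] * 6 + [1] * 4)
rep = hf.ece(pred, truth, n_bins=10)
print(f"calibrated set:   ECE = {rep.ece:.4f}, "
      f"mean confidence = {rep.mean_confidence:.2f}")

# overconfident: confidence 0.95 but only half correct
row = np.array([0.95, 0.02, 0.01, 0.01, 0.01])
pred = hf.PredictionMatrix(np.tile(row, (10, 1)))
truth = np.array([0] * 5 + [1] * 5)
rep = hf.ece(pred, truth, n_bins=10)
print(f"overconfident set: ECE = {rep.ece:.4f} "
      "(|accuracy 0.50 - confidence 0.95|)")

# ACS: cosine similarity between predicted rows and the scorers' votes
sc = np.array([[0.6, 0.2, 0.2, 0.0, 0.0]])
for p, label in [(sc, "predicts the consensus distribution"),
                 (np.array([[1.0, 0, 0, 0, 0]]), "predicts a hard one-hot"),
                 (np.array([[0.0, 0, 0, 1, 0]]), "predicts an unvoted stage")]:
    print(f"ACS = {hf.acs(sc, p):.4f}  when the model {label}")
# 1.0 means the hypnodensity matches the scorers' exactly; the hard one-hot
# still scores ~0.90 because W dominates; a stage no scorer voted for has
# disjoint support and scores 0.
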