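"""Fuse five physicians' stagings of one epoch into a consensus.

Builds the classic five-vote epoch [W, W, W, N1, N2], prints the
soft-consensus distribution (vote occurrences over observations), the
majority-vote label, and each scorer's Soft-Agreement reliability.
"""

import numpy as np

import hypnofuse as hf

labels = hf.annotations.encode_labels([
    ["W", "W", "W", "N1", "N2"],
    ["N2", "N2", "N2", "N2", "N2"],
    ["W", "W", "N1", "N1", "N2"],
])
rec = hf.MultiScoredRecording("demo", ("S1", "S2", "S3", "S4", "S5"), labels)

sc = hf.soft_consensus(rec)
hyp = hf.majority_vote(rec)
print("soft-consensus rows (pW, pN1, pN2, pN3, pR):")
for t in range(rec.n_epochs):
    tie = "  <- tie, broken by most reliable scorer" if hyp.tie_flags[t] else ""
    print(f"  epoch {t}: {np.round(sc.matrix[t], 3)} -> "
          f"{hf.STAGES[hyp.labels[t]]}{tie}")

print("\nSoft-Agreement per scorer (1 = always in the majority or a tie):")
for sr in hf.rank_scorers(rec):
    print(f"  {sr.scorer_id}: SA = {sr.soft_agreement:.3f} (rank {sr.rank})")

# Row 0 reads [0.6, 0.2, 0.2, 0, 0]: three of five votes went to W, so the
# consensus label is W but 40% of the scorer mass disagrees — exactly the
# information a one-hot label throws away.
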