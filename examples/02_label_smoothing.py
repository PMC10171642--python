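"""Smooth one-hot consensus targets with the scorers' vote distribution.

Shows the uniform (LS_U) and soft-consensus (LS_SC) smoothed targets for
the worked epoch [W, W, W, N1, N2] and the cross-entropy each target
induces against a fixed prediction.
"""

import numpy as np

import hypnofuse as hf

labels = hf.annotations.encode_labels([["W", "W", "W", "N1", "N2"]])
rec = hf.MultiScoredRecording("demo", ("S1", "S2", "S3", "S4", "S5"), labels)
sc = hf.soft_consensus(rec)
one_hot = hf.one_hot_targets(hf.majority_vote(rec).labels)

print("one-hot target:     ", one_hot[0])
print("soft-consensus:     ", sc.matrix[0])
print("LS_U  (alpha=0.5):  ", hf.smooth_uniform(one_hot, 0.5)[0])
print("LS_SC (alpha=0.5):  ", hf.smooth_soft_consensus(one_hot, sc, 0.5)[0])
# LS_SC at alpha=0.5 gives [0.8, 0.1, 0.1, 0, 0]: residual mass goes only
# to the stages the scorers actually voted for (N1, N2), not to all five.

pred = np.array([[0.7, 0.15, 0.1, 0.025, 0.025]])
for name, target in [("one-hot", one_hot),
                     ("LS_SC", hf.smooth_soft_consensus(one_hot, sc, 0.5))]:
    print(f"cross-entropy vs {name:8s} target: "
          f"{hf.cross_entropy(target, pred):.4f} nats")
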