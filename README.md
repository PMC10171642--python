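# hypnofuse

Label fusion and evaluation for **multi-scored sleep staging**.

Polysomnography is scored in 30-s epochs into the five AASM stages (W, N1,
N2, N3, R), and different physicians scoring the same night agree only
70–85 % of the time. When a database carries annotations from J scorers,
training an automatic stager on a single majority-vote label throws away
exactly the information that matters: *where* and *how much* the experts
disagreed. `hypnofuse` is a toolkit for keeping that information:

* **Consensus construction** — majority-vote hypnograms with
  reliability-aware tie-breaking, and the per-scorer **Soft-Agreement**
  score: for scorer j, the leave-one-out consensus
  `z^j_k(t) = count_k(t) / max_k count_k(t)` over the other J−1 scorers
  (1 for the majority stage and any stage tied with it), averaged at j's
  own labels — `SA_j = mean_t z^j[y_j(t)] ∈ [0, 1]`.
* **Soft-consensus** — the per-epoch empirical vote distribution
  `softcons_k(t) = #votes for k / M(t)`, e.g. votes [W, W, W, N1, N2] →
  [0.6, 0.2, 0.2, 0, 0]. NC / missing annotations just reduce M.
* **Label smoothing** — training targets
  `y = (1−α)·onehot + α·q` with q uniform (`LS_U`) or the soft-consensus
  row (`LS_SC`), plus the soft-target cross-entropy loss.
* **Evaluation** — per-subject accuracy / macro & weighted F1 / Cohen's κ,
  expected calibration error `ECE = Σ_m (n_m/n)·|acc(B_m) − conf(B_m)|`
  over M equal confidence bins, and the **averaged cosine similarity**
  `ACS = (1/N) Σ_i cos(softcons_i, p̂_i)` between a model's hypnodensity
  and the scorers'.
* **Hypnodensity graphs** — stacked per-stage probability bands over the
  night, for model output or scorer consensus.
* **A synthetic multi-scored database generator** (Markov-chain truth,
  scorers with controllable reliabilities and confusion structure,
  Gaussian class-conditional features) and a minimal reference classifier
  with the full base / LS_U / LS_SC cross-validated experiment protocol.

It is aimed at researchers working with multi-scored PSG cohorts or any
multi-annotator labelling problem with the same shape.

## Worked example

```python
import numpy as np
import hypnofuse as hf

labels = hf.annotations.encode_labels([["W", "W", "W", "N1", "N2"]])
rec = hf.MultiScoredRecording("demo", ("S1","S2","S3","S4","S5"), labels)

sc = hf.soft_consensus(rec)
print(sc.matrix[0])              # [0.6 0.2 0.2 0.  0. ]

one_hot = hf.one_hot_targets(hf.majority_vote(rec).labels)
print(hf.smooth_soft_consensus(one_hot, sc, alpha=0.5)[0])
                                 # [0.8 0.1 0.1 0.  0. ]
```

Three of the five physicians voted W, so the consensus label is W — but
40 % of the scorer mass sits on N1/N2, and the `LS_SC` target at α = 0.5
keeps that residual mass exactly on the stages that were actually voted
for, unlike uniform smoothing which spreads it over all five.

The `examples/` directory has one short script per capability (consensus
and reliability ranking, smoothing, ECE/ACS, database simulation,
hypnodensity rendering, and the miniature three-arm training experiment),
each printing its numbers with a note on what they mean. A thin CLI mirrors
the library for shell use:

```bash
hypnofuse simulate --out-dir sim --seed 7
hypnofuse consensus --annotations sim/subj001.annotations.csv \
    --out-hypnogram hyp.txt --out-softconsensus sc.csv \
    --report-reliability reliability.csv
hypnofuse hypnodensity --probs sc.csv --annotations \
    sim/subj001.annotations.csv --acs-label --out night.png
```

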