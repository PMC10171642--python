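"""Render a hypnodensity graph from a simulated night's soft-consensus.

Writes hypnodensity.png: hypnogram on top, stacked per-stage probability
bands below; the bands' heights at every time point sum to 1.
"""

import hypnofuse as hf

cfg = hf.SimulationConfig(n_subjects=1, epochs_per_subject=480, seed=11)
ds = hf.simulate_dataset(cfg, seed=11)
rec = ds.subjects[0].recording

sc = hf.soft_consensus(rec)
hyp = hf.majority_vote(rec)
series = hf.build_hypnodensity(sc.matrix, source="soft_consensus")
self_acs = hf.acs(sc, hf.PredictionMatrix(sc.matrix))

out = "hypnodensity.png"
hf.render(series, out, hypnogram=hyp.labels, acs_value=self_acs)
print(f"wrote {out}: {series.n_epochs} epochs "
      f"({series.n_epochs * 30 / 3600:.1f} h), ACS vs itself = {self_acs}")
# Bands that are not a solid colour mark epochs where scorers disagreed —
# mostly stage transitions and N1, as in real inter-rater studies.
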