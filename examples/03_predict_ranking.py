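"""Rank candidate lncRNAs for one disease.

Runs the full pipeline — kernel, integration, similarity-derived seeds,
restart walk — on a planted-block benchmark and prints the top ranked
candidates. Because of the planted structure, candidates from the
disease's own block should dominate the top of the list.
"""

from irwrlda import SynthConfig, build_dataset, predict

cfg = SynthConfig(n_lncrnas=40, n_diseases=12, n_blocks=3, seed=7)
ds = build_dataset(cfg)
disease = "disease00"

candidates, known = predict(disease, ds.assoc_matrix, ds.ss, ds.es)

print(f"disease {disease}: {len(known)} known lncRNAs, {len(candidates)} candidates")
print("\ntop 8 candidates (stationary walk probability and rank):")
print(candidates.head(8).round(4))

block0 = {l for l, b in zip(cfg.lnc_ids, cfg.lnc_blocks()) if b == 0}
top8 = set(candidates.head(8).index)
print(f"\n{len(top8 & block0)}/8 of the top candidates come from the disease's")
print("own planted block — the walk concentrates mass where the similarity")
print("network and the seeds agree.")
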