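"""Leave-one-out cross-validation and the pooled ROC curve.

Every known association is held out in turn (the kernel is refit on the
masked matrix, so the held-out pair never leaks into the network), and
the held-out lncRNA's rank among the candidates drives the ROC. An AUC
of 0.5 is chance; 1.0 is perfect recovery.
"""

from irwrlda import SynthConfig, build_dataset, loocv, loocv_summary

ds = build_dataset(SynthConfig(seed=1))  # 80 lncRNAs x 20 diseases, 4 blocks
records = loocv(ds.assoc_matrix, ds.ss, ds.es)

summary = loocv_summary(records)
print(f"folds:            {summary['n_folds']}")
print(f"fallback folds:   {summary['n_fallback']} (no seed evidence after masking)")
print(f"pooled ROC AUC:   {summary['auc']:.4f}")
print(f"closed-form rank-AUC: {summary['rank_auc']:.4f}")

best = min(records, key=lambda r: r.rank)
print(f"\nbest-recovered association: {best.lncrna_id} / {best.disease_id} "
      f"at rank {best.rank:g} of {best.n_candidates + 1}")
print("\nAUC well above 0.5 means held-out associations are systematically")
print("ranked ahead of the unrelated candidates.")
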