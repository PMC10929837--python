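"""Benchmark the learner roster and select the signature panel by RF-RFE.

Twelve informative genes are planted among ~500 noise genes; eight
classical learners are compared under one shared repeated-CV fold plan, and
recursive feature elimination by random-forest Gini importance picks the
12-gene panel.
"""

import ucquant as uq

spec = uq.SimSpec(n_genes=512, n_up=6, n_down=6, seed=12)
(expr, truth), = uq.simulate_cohorts(spec)
train, test = uq.split_cohort(expr, train_fraction=0.7, seed=12)
print(f"train {train.n_samples} samples / test {test.n_samples} samples (stratified 7:3)")

# benchmark on the planted genes only (the candidate pool); each row is a
# learner's cross-validated mean, all scored on identical folds
pool = train.subset_genes(truth["up_genes"] + truth["down_genes"])
bench = uq.benchmark_learners(pool, folds=5, repeats=2, seed=12)
print(bench.summary[["accuracy_mean", "c_index_mean", "rmsr_mean"]].round(3))

sel = uq.rf_rfe(train, folds=3, repeats=1, n_trees=250,
                candidate_sizes=[4, 8, 12, 24, 48], panel_size=12, seed=12)
print("CV error by panel size:\n", sel.error_curve.round(3))
print("optimal size:", sel.optimal_size)
planted = set(truth["up_genes"]) | set(truth["down_genes"])
print(f"selected panel recovers {len(set(sel.panel.genes) & planted)}/12 planted genes")
print("panel:", sel.panel.entries)
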