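"""Generate cells of a requested type with classifier guidance.

Trains the pipeline plus a cell-type classifier on noisy latent codes,
then steers sampling toward each type (guidance weight gamma = 2, active
below T/2). Purity is the fraction of generated cells an oracle
classifier — trained only on real cells — assigns to the requested type;
the per-type KNN AUC compares generated with real cells of that type
(0.5 = indistinguishable).
"""

from scdiffuse import FixtureSpec, RunConfig, simulate_counts
from scdiffuse.workflows import experiment_conditional

cfg = RunConfig.desk_scale().with_seeds(1)
raw = simulate_counts(FixtureSpec(
    n_cells=1200, n_genes=150,
    cell_types=[("TypeA", 0.5), ("TypeB", 0.45), ("TypeC", 0.05)],
    seed=cfg.seed_data))
res = experiment_conditional(raw, cfg)
print(f"oracle accuracy on real held-out cells: {res['oracle_accuracy']:.3f}")
for name, entry in res["per_class"].items():
    knn = entry.get("knn_auc", float("nan"))
    print(f"  {name:6s} n={entry['n']:4d} purity={entry['purity']:.3f} "
          f"knn_auc={knn:.3f}")
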