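"""Generate an out-of-distribution condition combination.

A 2 x 2 cell-type x organ design is simulated with one combination
(TypeB in Mammary) entirely removed from training. Two classifiers — one
per factor — are trained separately and their gradients summed during
sampling, steering generation toward the never-seen combination. Purity
is judged by an oracle trained on real cells from all four combinations
(including the held-out ground truth, which the generator never saw).
"""

from scdiffuse import FixtureSpec, RunConfig
from scdiffuse.workflows import experiment_multicondition

cfg = RunConfig.desk_scale(ae_hidden=[1024, 512], ae_epochs=150,
                           dn_steps=4000, clf_steps=1500).with_seeds(1)
spec = FixtureSpec(n_cells=1000, n_genes=150,
                   cell_types=[("TypeT", 0.5), ("TypeB", 0.5)],
                   seed=cfg.seed_data)
res = experiment_multicondition(spec, cfg)
held = res["held_out"]
print(f"held-out combination: {held[0]} x {held[1]}")
print(f"oracle accuracy: {res['oracle_accuracy']:.3f}")
print(f"purity of generated held-out cells: {res['purity']:.3f}")
print(f"purity of real held-out cells:      {res['real_purity']:.3f}")
print("purity approaching the real cells' shows the two conditions were "
      "composed without ever being observed together")
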