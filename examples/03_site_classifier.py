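"""Train the functional-site classifier on synthetic data and evaluate.

Uses a reduced problem (80 proteins, 160 sites) so the example finishes
in about a minute on one CPU; the printed numbers are held-out metrics
on a stratified 20% split. With the noiseless planted motif the
classifier should be well above chance (accuracy 0.5) after a short
training run.
"""

from phosfx import MockBackend, SynthConfig, simulate, TrainConfig
from phosfx.pipeline import embed_all, run_site_experiment

cfg = SynthConfig(n_proteins=80, n_sites=160, n_pairs=40, seed=3)
data = simulate(cfg)
backend = MockBackend(dim=32, seed=0)
site_ids = {r.protein_id for r in data.sites}
embeddings = embed_all([p for p in data.proteins if p.id in site_ids], backend)

result = run_site_experiment(
    data.sites,
    embeddings,
    seed=3,
    train_cfg=TrainConfig(epochs=40, seed=3, task="site", batch_size=32),
)

print("held-out metrics (32 test sites):")
for name, value in result.metrics.items():
    print(f"  {name:10s} {value:.3f}")
# accuracy/auroc near 1 would mean the planted motif is fully recovered;
# values around 0.5 would mean no signal was learned at all.
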