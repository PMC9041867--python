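"""Train a Stage-1 promoter model and measure held-out predictive ability.

Mean expression in the synthetic world is driven by planted motif copies
and an annotated enhancer state; a conv/pool network over the annotated
promoter learns the mapping, and held-out genes score the out-of-sample
cv-r2 (1 minus SSE over SST against the test-set mean, negative when the
model has no predictive ability).
"""

import tempfile

import numpy as np

from peabrain import genome_io as gio, normalize as nm, synthetic_data as sd
from peabrain.evaluation import cv_r2
from peabrain.stage1_net import Stage1Config, build_stage1, stack_encodings, \
    train_stage1

world = sd.make_stage1_world(tempfile.mkdtemp(), n_genes=200, halfwidth=1000,
                             sigma=0.1, seed=0)
genome = world.load_genome()
encs = [gio.encode_gene(g, genome, 1000, tracks=world.load_tracks())
        for g in world.load_genes()]
X = stack_encodings(encs)
y = nm.mean_abundance(world.load_means()).values

perm = np.random.default_rng(1).permutation(len(X))
test, train = perm[:40], perm[40:]
cfg = Stage1Config(input_length=2000, n_channels=X.shape[2],
                   min_epochs=150, max_epochs=250, patience=20, seed=2)
model = build_stage1(cfg, channel_names=encs[0].channel_names)
train_stage1(model, X[train], y[train])

r2 = cv_r2(y[test], model.predict(X[test]))
print(f"trained {len(model.training_log)} epochs on {len(train)} genes")
print(f"held-out cv-r2 on {len(test)} genes: {r2:.3f}")
print("a value well above 0 means annotated promoter content explains a "
      "substantial share of between-gene variance; accuracy grows with "
      "gene count (the 500-gene acceptance run exceeds cv-r2 = 0.8)")
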