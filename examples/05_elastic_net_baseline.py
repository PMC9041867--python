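"""The elastic-net dosage-difference baseline on a noise-free cohort.

Expression differences between pairs of training individuals are modelled
as a linear function of their dosage differences (mixing parameter 0.5,
regularization strength 3-fold cross-validated), with cv-r2 measured on
pair differences among held-out individuals — the comparator for the
Stage-2 network under identical splits.
"""

import tempfile

import numpy as np

from peabrain import genome_io as gio, synthetic_data as sd
from peabrain.baseline_linear import fit_elastic_net_diff

world = sd.make_stage2_world(tempfile.mkdtemp(), n_individuals=100,
                             window=3000, m_variants=30, c_causal=5,
                             beta_scale=0.8, sigma=0.0, seed=6)
_, dosages, meta = gio.load_dosage_matrix(world.vcf_path)
y = world.load_expression().values.astype(float)

res = fit_elastic_net_diff(dosages, y, n_repeats=3, seed=1)
print(f"repeated-split cv-r2: {[round(v, 3) for v in res.cv_r2_values]}")
print(f"fitted intercept on difference data: {res.intercept:.2e} "
      "(anti-symmetric targets force it to ~0)")

truth = world.load_truth()
support = np.flatnonzero(np.abs(res.weights.values) > 1e-6)
causal = np.flatnonzero(truth["causal"].values)
print(f"causal variants recovered in the nonzero support: "
      f"{len(set(causal) & set(support))}/{len(causal)}")
print("on noise-free linear data the baseline should be near-perfect; the "
      "Stage-2 network earns its keep on non-additive, position-dependent "
      "signal")
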