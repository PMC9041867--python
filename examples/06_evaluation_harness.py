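"""The statistical comparison harness on data with known coefficients.

Logistic enrichment (score vs binary annotation overlap, with
profile-likelihood confidence intervals) and the locus-score regression
(rank-normalized local SNP-heritability on rank-normalized mean impact per
locus) are exercised on simulated inputs where the right answer is known.
"""

import numpy as np
import pandas as pd

from peabrain.evaluation import locus_tissue_regression, logistic_enrichment

rng = np.random.default_rng(3)
scores = rng.normal(size=2000)
labels = (rng.random(2000) < 1 / (1 + np.exp(-2 * scores))).astype(int)
res = logistic_enrichment(scores, labels, task="planted")
print(f"planted log-odds slope 2.0 -> estimate {res.coefficient:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p = {res.p_value:.2e}")

null = logistic_enrichment(rng.normal(size=2000),
                           (rng.random(2000) < 0.3).astype(int), task="null")
print(f"label-independent score -> estimate {null.coefficient:.2f} "
      f"[{null.ci_low:.2f}, {null.ci_high:.2f}] (CI should cover 0)")

loci = pd.Series(rng.uniform(0, 1, 80), index=[f"L{i}" for i in range(80)])
h2 = pd.Series(np.exp(loci.values) + 0.05 * rng.normal(size=80),
               index=loci.index)
df = locus_tissue_regression({"liver": loci, "shuffled": pd.Series(
    rng.permutation(loci.values), index=loci.index)}, h2)
print("\nlocus-score regression (rank-INT both sides, Bonferroni over "
      "tissues):")
print(df[["slope", "p_value", "adjusted_p"]].round(4).to_string())
print("the planted tissue shows a positive significant slope; the shuffled "
      "control does not")
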