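"""Elastic-net dosage-difference baseline: the regularized linear comparator
for the Stage-2 difference model.

For each gene, expression differences between pairs of training individuals
are modelled as a linear function of their dosage differences (elastic net,
mixing parameter 0.5, regularization strength chosen by 3-fold
cross-validation on the training pairs), and scored by cv-r2 on pair
differences among held-out test individuals — the same repeated 95/5
individual-level splits as the Stage-2 network, so results are directly
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

from .evaluation import cv_r2, summarize_cv_r2, CVR2Result
from .stage2_net import enumerate_pairs

__all__ = ["ElasticNetDiffResult", "fit_elastic_net_diff"]


@dataclass
class ElasticNetDiffResult:
    weights: pd.Series            # variant -> beta (repeat 0 model)
    intercept: float
    repeats: pd.DataFrame         # repeat, seed, cv_r2
    summary: CVR2Result = None
    dropped_variants: tuple = ()

    @property
    def cv_r2_values(self):
        return list(self.repeats["cv_r2"])


def _diff_design(dosages, expression, ids, pairs):
    idx = {s: i for i, s in enumerate(ids)}
    rows = [idx[a] for a, b in pairs]
    cols = [idx[b] for a, b in pairs]
    X = dosages[rows] - dosages[cols]
    y = expression[rows] - expression[cols]
    return X, y


def fit_elastic_net_diff(dosages, expression, individual_ids=None,
                         variant_ids=None, alpha: float = 0.5,
                         lambda_folds: int = 3, n_repeats: int = 5,
                         train_fraction: float = 0.95,
                         seed: int = 0) -> ElasticNetDiffResult:
    """Fit the pairwise dosage-difference elastic net over repeated splits.

    ``dosages`` is individuals x variants with alternate-allele counts;
    ``expression`` the rank-normal residual expression vector.  ``alpha`` is
    the elastic-net mixing parameter (0.5: equal lasso/ridge weight).  On
    difference data the intercept is expected to be ~0 (anti-symmetric
    targets).  Constant dosage columns are dropped with a warning; an
    all-zero-weight model is allowed and reported.
    """
    dosages = np.asarray(dosages, dtype=float)
    expression = np.asarray(expression, dtype=float)
    n, m = dosages.shape
    if n < 20:
        raise ValueError("need at least 20 individuals")
    if m < 1:
        raise ValueError("need at least one variant")
    if individual_ids is None:
        individual_ids = [f"I{i}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    keep = dosages.std(axis=0) > 0
    dropped = tuple(v for v, k in zip(variant_ids, keep) if not k)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant dosage column(s)")
    dosages = dosages[:, keep]
    kept_ids = [v for v, k in zip(variant_ids, keep) if k]

    rows = []
    weights = None
    intercept = 0.0
    for rep in range(n_repeats):
        rep_seed = seed + 10_000 * (rep + 1)
        rng = np.random.default_rng(rep_seed)
        perm = list(np.array(individual_ids)[rng.permutation(n)])
        n_test = max(n - int(np.floor(train_fraction * n)), 2)
        test_ids, train_ids = perm[:n_test], perm[n_test:]
        Xtr, ytr = _diff_design(dosages, expression, individual_ids,
                                enumerate_pairs(train_ids, "both-directions"))
        Xte, yte = _diff_design(dosages, expression, individual_ids,
                                enumerate_pairs(test_ids, "both-directions"))
        model = ElasticNetCV(l1_ratio=alpha, cv=lambda_folds, alphas=50,
                             random_state=rep_seed % (2 ** 31), max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        rows.append((rep, rep_seed, cv_r2(yte, model.predict(Xte))))
        if rep == 0:
            weights = pd.Series(model.coef_, index=kept_ids, name="beta")
            intercept = float(model.intercept_)
    repeats = pd.DataFrame(rows, columns=["repeat", "seed", "cv_r2"])
    summary = summarize_cv_r2(repeats["cv_r2"]) if n_repeats >= 3 else None
    return ElasticNetDiffResult(weights=weights, intercept=intercept,
                                repeats=repeats, summary=summary,
                                dropped_variants=dropped)
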