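"""Gene embeddings: penultimate-layer activations of a trained Stage-1
model, their cosine similarity, and gene-set membership prediction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

__all__ = ["extract_embedding", "extract_embeddings", "cosine_similarity",
           "geneset_membership_cv", "read_gmt"]


def read_gmt(path) -> dict:
    """Read gene sets in GMT format: one set per line,
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def geneset_labels(gene_sets: dict, gene_ids) -> dict:
    """Convert name -> member-set mappings into binary label vectors
    aligned with ``gene_ids``."""
    import numpy as np
    gene_ids = list(gene_ids)
    return {name: np.array([g in members for g in gene_ids], dtype=int)
            for name, members in gene_sets.items()}


def extract_embedding(model, enc) -> np.ndarray:
    """Penultimate dense-layer activations for one encoded promoter
    (inference mode, deterministic).  The model's predicted abundance is the
    output layer's linear combination of this vector."""
    mat = enc.matrix if hasattr(enc, "matrix") else np.asarray(enc)
    return model.embed(mat[None])[0]


def extract_embeddings(model, encodings, gene_ids=None) -> pd.DataFrame:
    """Embeddings for many genes as a gene x unit DataFrame."""
    mats = np.stack([e.matrix if hasattr(e, "matrix") else np.asarray(e)
                     for e in encodings])
    emb = model.embed(mats)
    if gene_ids is None:
        gene_ids = [getattr(e, "gene_id", f"g{i}")
                    for i, e in enumerate(encodings)]
    return pd.DataFrame(emb, index=gene_ids,
                        columns=[f"e{i}" for i in range(emb.shape[1])])


def cosine_similarity(x, y) -> float:
    """x . y / (||x|| ||y||), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("embeddings must be equal-length vectors")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def geneset_membership_cv(embeddings: pd.DataFrame, gene_sets: dict,
                          k: int = 10, seed: int = 0,
                          hidden=(200, 100, 50)) -> pd.DataFrame:
    """k-fold cross-validated gene-set membership prediction from
    embeddings, using a multi-layer perceptron (hidden layers 200/100/50,
    rectified-linear activations, quasi-Newton lbfgs optimization).

    Sets with fewer than ``k`` positive genes are skipped with a warning.
    Returns one row per (set, fold) with accuracy and AUROC.
    """
    X = embeddings.values
    rows = []
    for set_name, labels in gene_sets.items():
        y = np.asarray(labels, dtype=int)
        if y.sum() < k or (1 - y).sum() < k:
            warnings.warn(f"gene set {set_name!r} too small for {k}-fold CV; skipped")
            continue
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            clf = MLPClassifier(hidden_layer_sizes=tuple(hidden),
                                activation="relu", solver="lbfgs",
                                max_iter=500, random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[te])[:, 1]
            rows.append((set_name, fold,
                         float((proba.round() == y[te]).mean()),
                         float(roc_auc_score(y[te], proba))))
    return pd.DataFrame(rows, columns=["gene_set", "fold", "accuracy", "auroc"])
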