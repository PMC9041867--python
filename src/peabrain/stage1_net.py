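"""Stage-1 model: a 1D convolutional network that maps an annotated core
promoter window to the tissue's normalized mean gene abundance.

Architecture: a stack of (valid conv, 11 filters of width 5, leaky-rectify
slope 0.01) -> max-pool blocks, a dropout layer (p = 0.5), a linear dense
embedding layer (1001 units by default) and a single linear output neuron,
so the prediction is a linear combination of the embedding activations.
Weights are optimized against mean squared error with Adam (lr 1e-3,
beta1 0.9, beta2 0.999, eps 1e-8) for at least 100 epochs, exiting early on
a held-out validation split (10% of training examples) and returning the
best-validation checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nnet
from .evaluation import cv_r2

__all__ = ["Stage1Config", "Stage1Model", "FoldResult", "build_stage1",
           "train_stage1", "crossvalidate_stage1", "stack_encodings",
           "leaky_rectify"]

leaky_rectify = nnet.leaky_rectify


@dataclass
class Stage1Config:
    input_length: int = 4000
    n_channels: int = 4
    n_filters: int = 11
    filter_width: int = 5
    leaky_slope: float = 0.01
    pool_sizes: tuple = (10, 10, 5)
    dropout_p: float = 0.5
    embedding_units: int = 1001
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    min_epochs: int = 100
    max_epochs: int = 400
    patience: int = 20
    validation_fraction: float = 0.10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.embedding_units < 1:
            raise ValueError("embedding_units must be >= 1")


def _conv_stack(length, channels, cfg, rng):
    """Build the conv/pool blocks, tracking the running length; raises with
    the offending block named if the input is too short."""
    layers = []
    c = channels
    for i, pool in enumerate(cfg.pool_sizes):
        conv = nnet.Conv1D(c, cfg.n_filters, cfg.filter_width,
                           activation="leaky", slope=cfg.leaky_slope, rng=rng)
        try:
            length = conv.out_length(length)
        except ValueError as exc:
            raise ValueError(f"conv block {i}: {exc}") from exc
        layers.append(conv)
        pool_layer = nnet.MaxPool1D(pool)
        try:
            length = pool_layer.out_length(length)
        except ValueError as exc:
            raise ValueError(f"pool block {i}: {exc}") from exc
        layers.append(pool_layer)
        c = cfg.n_filters
    return layers, length, c


class Stage1Model:
    """A built (possibly trained) Stage-1 network.

    Inference (``predict``/``embed``) runs with dropout disabled and is
    deterministic.
    """

    def __init__(self, config: Stage1Config, channel_names=None):
        self.config = config
        self.channel_names = tuple(channel_names) if channel_names else None
        self.training_log = []
        rng = np.random.default_rng(config.seed)
        blocks, length, c = _conv_stack(config.input_length,
                                        config.n_channels, config, rng)
        flat = length * c
        self._embed_layer_index = len(blocks) + 2  # after flatten+dropout+dense
        self.net = nnet.Sequential(blocks + [
            nnet.Flatten(),
            nnet.Dropout(config.dropout_p),
            nnet.Dense(flat, config.embedding_units, activation="linear", rng=rng),
            nnet.Dense(config.embedding_units, 1, activation="linear", rng=rng),
        ])

    def _as_batch(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.input_length or \
                x.shape[2] != self.config.n_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model contract "
                f"({self.config.input_length}, {self.config.n_channels})")
        return x

    def predict(self, x, batch_size=64) -> np.ndarray:
        """Predicted normalized mean abundance, one scalar per input."""
        x = self._as_batch(x)
        out = [self.net.forward(x[i:i + batch_size], train=False).reshape(-1)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out)

    def embed(self, x, batch_size=64) -> np.ndarray:
        """Penultimate-layer (embedding) activations, inference mode."""
        x = self._as_batch(x)
        chunks = []
        for i in range(0, len(x), batch_size):
            h = x[i:i + batch_size]
            for layer in self.net.layers[:-1]:
                h = layer.forward(h, train=False)
            chunks.append(h)
        return np.concatenate(chunks)

    @property
    def output_layer(self):
        return self.net.layers[-1]

    def save(self, prefix):
        """Checkpoint: <prefix>.npz weights + <prefix>.json manifest."""
        weights = self.net.get_weights()
        np.savez(f"{prefix}.npz", **{f"w{i}": w for i, w in enumerate(weights)})
        manifest = {"config": asdict(self.config),
                    "channel_names": self.channel_names,
                    "training_log": self.training_log,
                    "kind": "stage1"}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=list)

    @classmethod
    def load(cls, prefix):
        with open(f"{prefix}.json") as fh:
            manifest = json.load(fh)
        cfg = Stage1Config(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in manifest["config"].items()})
        model = cls(cfg, channel_names=manifest.get("channel_names"))
        data = np.load(f"{prefix}.npz")
        model.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        model.training_log = [tuple(e) for e in manifest.get("training_log", [])]
        return model


def build_stage1(config: Stage1Config, channel_names=None) -> Stage1Model:
    return Stage1Model(config, channel_names=channel_names)


def stack_encodings(encoded) -> np.ndarray:
    """Stack a list of EncodedSequence (or arrays) into (N, L, C) float32."""
    mats = [e.matrix if hasattr(e, "matrix") else np.asarray(e) for e in encoded]
    return np.stack(mats).astype(np.float32)


def train_stage1(model: Stage1Model, encoded, targets,
                 rng=None) -> Stage1Model:
    """Train in place by Adam/MSE with early exit on a 10% validation split.

    Fully reproducible given the config seed (or a caller-supplied rng).
    """
    cfg = model.config
    X = stack_encodings(encoded)
    y = np.asarray(targets, dtype=np.float32)
    if len(X) != len(y):
        raise ValueError("number of encodings and targets differ")
    if len(X) < 20:
        raise ValueError("need at least 20 training examples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training targets")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_val = max(2, int(round(cfg.validation_fraction * len(X))))
    perm = rng.permutation(len(X))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    def batches(rng):
        order = rng.permutation(len(Xtr))
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            yield Xtr[sel], ytr[sel]

    opt = nnet.Adam(model.net.params(), lr=cfg.learning_rate, beta1=cfg.beta1,
                    beta2=cfg.beta2, eps=cfg.epsilon)
    model.training_log = nnet.train_loop(
        model.net, batches, Xval, yval, optimizer=opt, rng=rng,
        min_epochs=cfg.min_epochs, patience=cfg.patience,
        max_epochs=cfg.max_epochs)
    return model


@dataclass
class FoldResult:
    fold_id: int
    test_indices: list
    cv_r2: float
    gene_ids: list = field(default_factory=list)


def crossvalidate_stage1(encoded, targets, config: Stage1Config, k: int = 10,
                         gene_ids=None, trainer=None):
    """k-fold cross-validation over genes: seeded shuffle partition, train on
    k-1 folds (with internal validation split), score cv-r2 on the withheld
    fold.

    ``trainer(X_train, y_train, fold_seed) -> predict_fn`` may be injected
    for testing; the default builds and trains a Stage-1 model per fold.
    """
    X = stack_encodings(encoded)
    y = np.asarray(targets, dtype=np.float32)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X) < k:
        raise ValueError("dataset smaller than number of folds")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(X))
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 genes")
    results = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        if trainer is not None:
            predict = trainer(X[train_idx], y[train_idx], config.seed + fold_id)
        else:
            from dataclasses import replace
            fold_cfg = replace(config, seed=config.seed + 1000 + fold_id)
            model = build_stage1(fold_cfg)
            train_stage1(model, X[train_idx], y[train_idx])
            predict = model.predict
        r2 = cv_r2(y[test_idx], predict(X[test_idx]))
        results.append(FoldResult(
            fold_id=fold_id, test_indices=list(map(int, test_idx)), cv_r2=r2,
            gene_ids=[gene_ids[i] for i in test_idx] if gene_ids else []))
    return results
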