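"""Stage-2 model: a conjoined three-subnetwork CNN trained on pairwise
sequence differences to predict pairwise expression differences between
individuals.

The input window centred on the TSS is split into an upstream flank, the
core promoter, and a downstream flank.  Each split feeds its own conv/pool
stack (the core stack is identical to Stage 1's); the three dense outputs
are concatenated, pass through one penultimate dense layer and a single
output neuron.  At the reference scale the window is 1 Mb (0.48 Mb flanks,
4 kb core) with flank pool sizes (100, 50, 10); at smaller desk-scale
windows the flank pool sizes are scaled down proportionally (cube-root of
the flank-length ratio, since three pool stages multiply) and the actual
values are recorded in the model manifest.

Training protocol: for each repeat the individuals are
split 95/5 into train/test, the model is fitted on directed pair differences
among training individuals (both (A-B) and (B-A)), with an internal
validation subset for early exit after a minimum number of epochs, and
cv-r2 is computed on all directed pair differences among test individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import nnet
from .evaluation import cv_r2, summarize_cv_r2, CVR2Result

__all__ = ["Stage2Config", "Stage2Model", "Stage2RepeatResult",
           "PairDifferenceExample", "enumerate_pairs", "build_stage2",
           "train_stage2", "captured_gene", "scaled_flank_pools"]

REFERENCE_FLANK = 480_000
REFERENCE_FLANK_POOLS = (100, 50, 10)


@dataclass
class Stage2Config:
    flank_length: int = 3000          # desk-scale default; 480000 at full scale
    core_length: int = 4000
    n_channels: int = 4
    n_filters: int = 11
    filter_width: int = 5
    leaky_slope: float = 0.01
    core_pool_sizes: tuple = (10, 10, 5)
    flank_pool_sizes: tuple = None    # derived from flank_length when None
    subnet_units: int = 1001
    merge_units: int = 1001
    dropout_p: float = 0.5
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    min_epochs: int = 100
    max_epochs: int = 400
    patience: int = 10
    validation_fraction: float = 0.10
    train_fraction: float = 0.95
    n_repeats: int = 5
    batch_size: int = 16
    max_pairs_per_epoch: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.flank_pool_sizes is None:
            self.flank_pool_sizes = scaled_flank_pools(self.flank_length)
        self.flank_pool_sizes = tuple(self.flank_pool_sizes)
        self.core_pool_sizes = tuple(self.core_pool_sizes)
        if any(p < 1 for p in self.flank_pool_sizes + self.core_pool_sizes):
            raise ValueError("pool sizes must be positive")

    @property
    def window_length(self):
        return 2 * self.flank_length + self.core_length


def scaled_flank_pools(flank_length: int,
                       reference=(REFERENCE_FLANK, REFERENCE_FLANK_POOLS)):
    """Scale the reference flank pool sizes (100, 50, 10) at 0.48 Mb down to
    a shorter flank, keeping the three-stage reduction proportionate."""
    ref_len, ref_pools = reference
    factor = (flank_length / ref_len) ** (1.0 / len(ref_pools))
    return tuple(max(1, int(round(p * factor))) for p in ref_pools)


def enumerate_pairs(individuals, mode: str = "train"):
    """All pairs of individuals: ``mode='train'`` (unordered, n(n-1)/2) or
    ``mode='both-directions'`` (directed, n(n-1))."""
    individuals = list(individuals)
    if len(set(individuals)) != len(individuals):
        raise ValueError("duplicate individual ids")
    if len(individuals) < 2:
        raise ValueError("need at least two individuals")
    pairs = [(a, b) for i, a in enumerate(individuals)
             for b in individuals[i + 1:]]
    if mode == "train":
        return pairs
    if mode == "both-directions":
        return pairs + [(b, a) for a, b in pairs]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PairDifferenceExample:
    """One training example: the element-wise difference of two diploid
    encodings and the difference of the two normalized expression values.
    The (b, a) example is the element-wise negation with negated target."""

    pair: tuple
    diff_matrix: np.ndarray
    diff_expression: float

    def reversed(self):
        return PairDifferenceExample(pair=(self.pair[1], self.pair[0]),
                                     diff_matrix=-self.diff_matrix,
                                     diff_expression=-self.diff_expression)


class _Subnet:
    """Conv stack + flatten + dropout + linear dense, one per sequence split."""

    def __init__(self, length, cfg, pools, rng):
        layers = []
        c = cfg.n_channels
        for i, pool in enumerate(pools):
            conv = nnet.Conv1D(c, cfg.n_filters, cfg.filter_width,
                               activation="leaky", slope=cfg.leaky_slope,
                               rng=rng)
            try:
                length = conv.out_length(length)
            except ValueError as exc:
                raise ValueError(f"subnet conv block {i}: {exc}") from exc
            pl = nnet.MaxPool1D(pool)
            try:
                length = pl.out_length(length)
            except ValueError as exc:
                raise ValueError(f"subnet pool block {i}: {exc}") from exc
            layers += [conv, pl]
            c = cfg.n_filters
        layers += [nnet.Flatten(), nnet.Dropout(cfg.dropout_p),
                   nnet.Dense(length * c, cfg.subnet_units,
                              activation="linear", rng=rng)]
        self.seq = nnet.Sequential(layers)

    def forward(self, x, train=False, rng=None):
        return self.seq.forward(x, train=train, rng=rng)

    def backward(self, grad):
        return self.seq.backward(grad)

    def params(self):
        return self.seq.params()


class _Conjoined:
    """The full network; implements the same interface as nnet.Sequential so
    the shared training loop applies."""

    def __init__(self, cfg: Stage2Config, rng):
        self.cfg = cfg
        self.up = _Subnet(cfg.flank_length, cfg, cfg.flank_pool_sizes, rng)
        self.core = _Subnet(cfg.core_length, cfg, cfg.core_pool_sizes, rng)
        self.down = _Subnet(cfg.flank_length, cfg, cfg.flank_pool_sizes, rng)
        self.merge = nnet.Dense(3 * cfg.subnet_units, cfg.merge_units,
                                activation="linear", rng=rng)
        self.out = nnet.Dense(cfg.merge_units, 1, activation="linear", rng=rng)

    def _split(self, x):
        f, c = self.cfg.flank_length, self.cfg.core_length
        if x.shape[1] != 2 * f + c:
            raise ValueError(
                f"input length {x.shape[1]} does not match window "
                f"{2 * f + c} (flank {f}, core {c})")
        return x[:, :f], x[:, f:f + c], x[:, f + c:]

    def forward(self, x, train=False, rng=None):
        xu, xc, xd = self._split(x)
        hu = self.up.forward(xu, train=train, rng=rng)
        hc = self.core.forward(xc, train=train, rng=rng)
        hd = self.down.forward(xd, train=train, rng=rng)
        h = np.concatenate([hu, hc, hd], axis=1)
        return self.out.forward(self.merge.forward(h, train=train, rng=rng),
                                train=train, rng=rng)

    def backward(self, grad):
        grad = self.merge.backward(self.out.backward(grad))
        u = self.cfg.subnet_units
        gu = self.up.backward(grad[:, :u])
        gc = self.core.backward(grad[:, u:2 * u])
        gd = self.down.backward(grad[:, 2 * u:])
        out = np.concatenate([gu, gc, gd], axis=1)
        return out

    def params(self):
        return (self.up.params() + self.core.params() + self.down.params()
                + self.merge.params() + self.out.params())

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            p[...] = w


class Stage2Model:
    def __init__(self, config: Stage2Config, channel_names=None):
        self.config = config
        self.channel_names = tuple(channel_names) if channel_names else None
        self.training_log = []
        rng = np.random.default_rng(config.seed)
        self.net = _Conjoined(config, rng)

    def _as_batch(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        return x

    def predict(self, x, batch_size=32) -> np.ndarray:
        """Predicted expression difference for difference-sequence input."""
        x = self._as_batch(x)
        out = [self.net.forward(x[i:i + batch_size], train=False).reshape(-1)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out)

    def save(self, prefix):
        weights = self.net.get_weights()
        np.savez(f"{prefix}.npz", **{f"w{i}": w for i, w in enumerate(weights)})
        manifest = {"config": asdict(self.config),
                    "channel_names": self.channel_names,
                    "training_log": self.training_log,
                    "kind": "stage2",
                    "flank_pool_sizes_actual": list(self.config.flank_pool_sizes)}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=list)

    @classmethod
    def load(cls, prefix):
        with open(f"{prefix}.json") as fh:
            manifest = json.load(fh)
        cfg = Stage2Config(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in manifest["config"].items()})
        model = cls(cfg, channel_names=manifest.get("channel_names"))
        data = np.load(f"{prefix}.npz")
        model.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        model.training_log = [tuple(e) for e in manifest.get("training_log", [])]
        return model


def build_stage2(config: Stage2Config, channel_names=None) -> Stage2Model:
    return Stage2Model(config, channel_names=channel_names)


@dataclass
class Stage2RepeatResult:
    repeat: int
    seed: int
    cv_r2: float
    train_individuals: list
    test_individuals: list


@dataclass
class Stage2TrainResult:
    repeats: list                      # list of Stage2RepeatResult
    model: Stage2Model                 # best-validation model of repeat 0
    summary: CVR2Result = None

    @property
    def cv_r2_values(self):
        return [r.cv_r2 for r in self.repeats]


def _pair_batch(X, y, pairs):
    xb = np.stack([X[a] - X[b] for a, b in pairs])
    yb = np.array([y[a] - y[b] for a, b in pairs], dtype=np.float32)
    return xb, yb


def train_stage2(encodings: dict, expression: dict,
                 config: Stage2Config) -> Stage2TrainResult:
    """Train the difference model for one gene over repeated 95/5 splits.

    ``encodings`` maps individual id -> diploid encoded matrix (L x C);
    ``expression`` maps individual id -> rank-normal residual expression.
    Per repeat: a seeded individual-level split, training on directed pair
    differences among training individuals (a random subset of directed
    pairs each epoch), early exit on a validation subset of individuals, and
    cv-r2 over all directed pair differences among the held-out test
    individuals.  Fully reproducible given the config seed.
    """
    ids = sorted(encodings)
    if sorted(expression) != ids:
        raise ValueError("encoding and expression individual ids differ")
    if len(ids) < 20:
        raise ValueError("need at least 20 individuals")
    X = {i: np.asarray(encodings[i], dtype=np.float32) for i in ids}
    y = {i: float(expression[i]) for i in ids}
    repeats = []
    kept_model = None
    for rep in range(config.n_repeats):
        rep_seed = config.seed + 10_000 * (rep + 1)
        rng = np.random.default_rng(rep_seed)
        perm = list(np.array(ids)[rng.permutation(len(ids))])
        n_test = len(ids) - int(np.floor(config.train_fraction * len(ids)))
        n_test = max(n_test, 2)
        test_ids, train_ids = perm[:n_test], perm[n_test:]
        if len(test_ids) < 2:
            raise ValueError("test split has fewer than 2 individuals")
        n_val = max(2, int(round(config.validation_fraction * len(train_ids))))
        val_ids, fit_ids = train_ids[:n_val], train_ids[n_val:]
        val_pairs = enumerate_pairs(val_ids, "both-directions")
        Xval, yval = _pair_batch(X, y, val_pairs)

        fit_pairs = enumerate_pairs(fit_ids, "both-directions")
        n_epoch_pairs = min(config.max_pairs_per_epoch, len(fit_pairs))

        def batches(rng, fit_pairs=fit_pairs, n=n_epoch_pairs):
            sel = rng.choice(len(fit_pairs), size=n, replace=False)
            for i in range(0, n, config.batch_size):
                chunk = [fit_pairs[j] for j in sel[i:i + config.batch_size]]
                yield _pair_batch(X, y, chunk)

        model = Stage2Model(replace(config, seed=rep_seed))
        opt = nnet.Adam(model.net.params(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2,
                        eps=config.epsilon)
        model.training_log = nnet.train_loop(
            model.net, batches, Xval, yval, optimizer=opt, rng=rng,
            min_epochs=config.min_epochs, patience=config.patience,
            max_epochs=config.max_epochs)
        test_pairs = enumerate_pairs(test_ids, "both-directions")
        Xte, yte = _pair_batch(X, y, test_pairs)
        r2 = cv_r2(yte, model.predict(Xte))
        repeats.append(Stage2RepeatResult(
            repeat=rep, seed=rep_seed, cv_r2=r2,
            train_individuals=list(train_ids),
            test_individuals=list(test_ids)))
        if rep == 0:
            kept_model = model
    summary = summarize_cv_r2([r.cv_r2 for r in repeats]) \
        if len(repeats) >= 3 else None
    return Stage2TrainResult(repeats=repeats, model=kept_model,
                             summary=summary)


def captured_gene(cvr2_repeats) -> CVR2Result:
    """Decision + CI: a gene is "captured" when the 95% CI (mean +/- 1.96 SE,
    normality assumption) over repeated-split cv-r2 lies entirely above 0."""
    return summarize_cv_r2(cvr2_repeats, min_repeats=3)
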