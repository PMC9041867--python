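"""Stage-1 model architecture and training contracts."""

import numpy as np
import pytest

from peabrain import genome_io as gio, normalize as nm
from peabrain.evaluation import cv_r2
from peabrain.stage1_net import (Stage1Config, build_stage1,
                                 crossvalidate_stage1, train_stage1,
                                 stack_encodings)

TINY = dict(input_length=300, pool_sizes=(4, 4, 2), embedding_units=32,
            min_epochs=5, max_epochs=30, patience=3, batch_size=16)


def tiny_config(**kw):
    return Stage1Config(**{**TINY, **kw})


class TestBuild:
    def test_default_forward_returns_finite_scalar(self):
        model = build_stage1(Stage1Config(seed=1))
        x = np.random.default_rng(0).normal(size=(4000, 4)).astype(np.float32)
        out = model.predict(x)
        assert out.shape == (1,) and np.isfinite(out[0])

    def test_penultimate_embedding_has_1001_units(self):
        model = build_stage1(Stage1Config(seed=1))
        x = np.zeros((4000, 4), dtype=np.float32)
        assert model.embed(x).shape == (1, 1001)

    def test_zero_weights_give_zero_output(self):
        model = build_stage1(Stage1Config(seed=2))
        model.net.set_weights([np.zeros_like(w)
                               for w in model.net.get_weights()])
        x = np.random.default_rng(1).normal(size=(4000, 4)).astype(np.float32)
        assert model.predict(x)[0] == 0.0

    def test_parameter_count_matches_config_arithmetic(self):
        cfg = Stage1Config(seed=0)
        model = build_stage1(cfg)
        # independent shape-accounting oracle
        expected, length, c = 0, cfg.input_length, cfg.n_channels
        for pool in cfg.pool_sizes:
            expected += cfg.filter_width * c * cfg.n_filters + cfg.n_filters
            length = (length - cfg.filter_width + 1) // pool
            c = cfg.n_filters
        expected += length * c * cfg.embedding_units + cfg.embedding_units
        expected += cfg.embedding_units + 1
        actual = sum(p.size for p, _ in model.net.params())
        assert actual == expected

    def test_too_short_input_names_offending_block(self):
        with pytest.raises(ValueError, match="block"):
            build_stage1(Stage1Config(input_length=50, seed=0))

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            Stage1Config(dropout_p=1.0)


class TestTraining:
    def _toy_dataset(self, n=60, seed=0):
        """Targets are a simple function of planted channel content."""
        rng = np.random.default_rng(seed)
        X = np.zeros((n, 300, 5), dtype=np.float32)
        dna = rng.integers(0, 4, size=(n, 300))
        for i in range(n):
            X[i, np.arange(300), dna[i]] = 1
        counts = rng.integers(0, 6, size=n)
        for i, k in enumerate(counts):
            pos = rng.choice(290, size=k, replace=False)
            for p in pos:
                X[i, p:p + 8, 4] = 1
        y = nm.rank_inverse_normal(counts + 0.01 * rng.normal(size=n))
        return X, y.astype(np.float32)

    def test_training_loss_decreases_smoothed(self):
        X, y = self._toy_dataset()
        cfg = tiny_config(n_channels=5, min_epochs=30, max_epochs=60, seed=3)
        model = build_stage1(cfg)
        train_stage1(model, X, y)
        train_losses = np.array([l[1] for l in model.training_log])
        smooth = np.convolve(train_losses, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < 0.6 * smooth[0]

    def test_training_is_deterministic_given_seed(self):
        X, y = self._toy_dataset()
        preds = []
        for _ in range(2):
            cfg = tiny_config(n_channels=5, seed=4)
            model = build_stage1(cfg)
            train_stage1(model, X, y)
            preds.append(model.predict(X[:10]))
        assert np.array_equal(preds[0], preds[1])

    def test_rejects_bad_inputs(self):
        X, y = self._toy_dataset(n=30)
        cfg = tiny_config(n_channels=5, seed=5)
        with pytest.raises(ValueError):
            train_stage1(build_stage1(cfg), X[:10], y[:10])  # too few
        y_bad = y.copy()
        y_bad[0] = np.nan
        with pytest.raises(ValueError):
            train_stage1(build_stage1(cfg), X, y_bad)

    def test_checkpoint_roundtrip(self, tmp_path):
        from peabrain.stage1_net import Stage1Model
        X, y = self._toy_dataset(n=30)
        cfg = tiny_config(n_channels=5, min_epochs=2, max_epochs=4, seed=6)
        model = build_stage1(cfg)
        train_stage1(model, X, y)
        prefix = str(tmp_path / "m")
        model.save(prefix)
        loaded = Stage1Model.load(prefix)
        assert np.array_equal(loaded.predict(X[:5]), model.predict(X[:5]))


class TestCrossValidation:
    def _data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 30, 2)).astype(np.float32)
        y = X[:, :, 0].sum(axis=1)
        return X, y

    def test_perfect_oracle_scores_one_everywhere(self):
        X, y = self._data()
        lookup = {x.tobytes(): t for x, t in zip(X, y)}

        def oracle(Xtr, ytr, seed):
            return lambda Xte: np.array([lookup[x.tobytes()] for x in Xte])

        cfg = Stage1Config(input_length=30, n_channels=2, pool_sizes=(2,),
                           seed=7)
        results = crossvalidate_stage1(X, y, cfg, k=5, trainer=oracle)
        assert all(r.cv_r2 == pytest.approx(1.0) for r in results)

    def test_mean_predictor_scores_at_most_zero(self):
        X, y = self._data()

        def mean_model(Xtr, ytr, seed):
            return lambda Xte: np.full(len(Xte), ytr.mean())

        cfg = Stage1Config(input_length=30, n_channels=2, pool_sizes=(2,),
                           seed=8)
        results = crossvalidate_stage1(X, y, cfg, k=5, trainer=mean_model)
        assert all(r.cv_r2 <= 1e-9 for r in results)

    def test_folds_partition_the_gene_set(self):
        X, y = self._data(n=37)
        cfg = Stage1Config(input_length=30, n_channels=2, pool_sizes=(2,),
                           seed=9)
        results = crossvalidate_stage1(
            X, y, cfg, k=5,
            trainer=lambda *a: lambda Xte: np.zeros(len(Xte)))
        seen = sorted(i for r in results for i in r.test_indices)
        assert seen == list(range(37))

    def test_small_fold_errors(self):
        X, y = self._data(n=8)
        cfg = Stage1Config(input_length=30, n_channels=2, pool_sizes=(2,),
                           seed=10)
        with pytest.raises(ValueError):
            crossvalidate_stage1(X, y, cfg, k=7,
                                 trainer=lambda *a: lambda Xte: np.zeros(len(Xte)))


class TestAnnotationChannelsHelp:
    def test_class_b_outperforms_class_a_on_annotation_driven_world(
            self, tmp_path):
        """With expression partly driven by an annotated enhancer state that
        is invisible in the DNA letters, DNA+annotation (class-B) models
        must beat DNA-only (class-A) models on held-out genes."""
        from peabrain import synthetic_data as sd
        world = sd.make_stage1_world(tmp_path / "w", n_genes=200,
                                     halfwidth=1000, sigma=0.0, seed=4)
        genome = world.load_genome()
        genes = world.load_genes()
        tracks = world.load_tracks()
        y = nm.mean_abundance(world.load_means()).values
        encB = stack_encodings([gio.encode_gene(g, genome, 1000, tracks=tracks)
                                for g in genes])
        encA = encB[:, :, :4]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        test, train = perm[:40], perm[40:]
        scores = {}
        for name, X in (("A", encA), ("B", encB)):
            cfg = Stage1Config(input_length=2000, n_channels=X.shape[2],
                               seed=7)
            model = build_stage1(cfg)
            train_stage1(model, X[train], y[train])
            scores[name] = cv_r2(y[test], model.predict(X[test]))
        assert scores["B"] > scores["A"]
        assert scores["B"] > 0.3
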