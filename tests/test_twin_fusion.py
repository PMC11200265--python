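"""Fusion network: standardization, loss, backward pass, training contract."""

import dataclasses

import numpy as np
import pytest

from assaymatch import (
    BTConfig,
    BTModel,
    bt_loss,
    cross_correlation,
    fuse,
    standardize_batch,
    train_bt,
)
from assaymatch.exceptions import (
    ArchiveError,
    BatchTooSmallError,
    ConfigurationError,
    DimensionError,
    DivergenceError,
)

TINY = BTConfig(
    enc_mol_dims=(16, 8),
    enc_text_dims=(8,),
    proj_dims=(12, 6),
    batch_size=16,
    max_epochs=5,
    learning_rate=1e-3,
    seed=3,
)


def _toy_pairs(n=128, d_mol=24, d_text=6, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, d_text))
    X_mol = np.hstack([z, rng.standard_normal((n, d_mol - d_text))])
    X_text = z + 0.1 * rng.standard_normal((n, d_text))
    y = rng.integers(0, 2, n)
    return X_mol, X_text, y


class TestStandardizeBatch:
    def test_already_standardized(self):
        col = np.array([[1.0], [-1.0]])
        assert np.allclose(standardize_batch(col), col, atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        out = standardize_batch(np.array([[5.0], [5.0], [5.0]]))
        assert np.array_equal(out, np.zeros((3, 1)))

    def test_hand_computed_population_variance(self):
        out = standardize_batch(np.array([[0.0], [1.0], [2.0]]))
        expected = np.array([[-1.2247448], [0.0], [1.2247448]])
        assert np.allclose(out, expected, atol=1e-6)

    def test_batch_too_small(self):
        with pytest.raises(BatchTooSmallError):
            standardize_batch(np.ones((1, 3)))


class TestCrossCorrelation:
    def test_identical_uncorrelated_columns_give_identity(self):
        Z = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(cross_correlation(Z, Z), np.eye(2), atol=1e-6)

    def test_negated_input_gives_negative_diagonal(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((32, 4))
        C = cross_correlation(Z, -Z)
        assert np.allclose(np.diag(C), -1.0, atol=1e-6)

    def test_two_by_two_hand_case(self):
        Z = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(
            cross_correlation(Z, Z), np.array([[1.0, -1.0], [-1.0, 1.0]]), atol=1e-6
        )

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            cross_correlation(np.ones((4, 2)), np.ones((4, 3)))

    def test_entries_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            C = cross_correlation(
                rng.standard_normal((16, 5)), rng.standard_normal((16, 5))
            )
            assert np.all(np.abs(C) <= 1.0 + 1e-6)


class TestBtLoss:
    def test_identity_is_zero(self):
        assert bt_loss(np.eye(2), 0.5) == 0.0

    def test_zero_matrix(self):
        assert bt_loss(np.zeros((2, 2)), 0.005) == pytest.approx(2.0)

    def test_hand_case(self):
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert bt_loss(C, 0.005) == pytest.approx(0.01, abs=1e-12)

    def test_zero_iff_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            C = rng.standard_normal((4, 4))
            loss = bt_loss(C, 0.1)
            assert loss >= 0.0
            assert (loss == 0.0) == np.array_equal(C, np.eye(4))

    def test_non_square(self):
        with pytest.raises(DimensionError):
            bt_loss(np.ones((2, 3)), 0.005)


class TestBackwardPass:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the full loss agree with central differences."""
        X_mol, X_text, _ = _toy_pairs(n=20, d_mol=10, d_text=4, seed=4)
        model = BTModel(
            BTConfig(
                enc_mol_dims=(6, 4), enc_text_dims=(4,), proj_dims=(5,),
                batch_size=8, seed=0,
            ),
            d_mol_in=10, d_text_in=4,
        )
        _, grads = model._batch_loss_and_grads(X_mol, X_text)
        params = model._all_params()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for p, g in zip(params, grads):
            for _ in range(3):  # probe a few coordinates per tensor
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = model._batch_loss_and_grads(X_mol, X_text)
                p[idx] = orig - eps
                lm, _ = model._batch_loss_and_grads(X_mol, X_text)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-7)


class TestTrainBt:
    def test_fixed_seed_reproduces_history(self):
        pairs = _toy_pairs(seed=1)
        h1 = train_bt(pairs, TINY).training_history
        h2 = train_bt(pairs, TINY).training_history
        assert h1 == h2

    def test_training_reduces_loss(self):
        model = train_bt(_toy_pairs(seed=2), dataclasses.replace(TINY, max_epochs=15))
        h = model.training_history
        assert h[-1]["train_loss"] <= h[0]["train_loss"]

    def test_too_few_pairs_is_configuration_error(self):
        X_mol, X_text, y = _toy_pairs(n=20)
        with pytest.raises(ConfigurationError):
            train_bt((X_mol, X_text, y), TINY)  # 20 < 2 * batch_size

    def test_early_stopping_with_validation(self):
        pairs = _toy_pairs(seed=3)
        val = _toy_pairs(n=40, seed=5)
        cfg = dataclasses.replace(TINY, max_epochs=25, patience=2)
        model = train_bt(pairs, cfg, val_pairs=val)
        assert len(model.training_history) <= 25
        assert all("val_loss" in e for e in model.training_history)

    def test_positives_only_uses_active_pairs(self):
        X_mol, X_text, y = _toy_pairs(n=256, seed=6)
        y = np.zeros(256, dtype=int)
        y[:20] = 1  # 20 positives < 2 * batch_size
        cfg = dataclasses.replace(TINY, pairs_used="positives_only")
        with pytest.raises(ConfigurationError):
            train_bt((X_mol, X_text, y), cfg)

    def test_non_finite_input_raises_divergence(self):
        X_mol, X_text, y = _toy_pairs(seed=7)
        X_mol[0, 0] = np.nan
        with pytest.raises(DivergenceError):
            train_bt((X_mol, X_text, y), TINY)

    def test_mismatched_component_lengths(self):
        X_mol, X_text, y = _toy_pairs()
        with pytest.raises(DimensionError):
            train_bt((X_mol, X_text[:-5], y), TINY)


@pytest.fixture(scope="module")
def model():
    return train_bt(_toy_pairs(seed=8), TINY)


class TestFuse:

    def test_output_length_is_sum_of_bottlenecks(self, model):
        X_mol, X_text, _ = _toy_pairs(n=4, seed=9)
        fe = fuse(model, X_mol[0], X_text[0])
        assert fe.vector.shape == (8 + 8,)
        assert fe.source == "encoder_concat"

    def test_deterministic(self, model):
        X_mol, X_text, _ = _toy_pairs(n=2, seed=9)
        v1 = fuse(model, X_mol[0], X_text[0]).vector
        v2 = fuse(model, X_mol[0], X_text[0]).vector
        assert np.array_equal(v1, v2)

    def test_text_change_only_affects_text_half(self, model):
        X_mol, X_text, _ = _toy_pairs(n=2, seed=10)
        a = fuse(model, X_mol[0], X_text[0]).vector
        b = fuse(model, X_mol[0], X_text[1]).vector
        assert np.array_equal(a[:8], b[:8])
        assert not np.array_equal(a[8:], b[8:])

    def test_projector_concat_source(self, model):
        X_mol, X_text, _ = _toy_pairs(n=2, seed=9)
        fe = fuse(model, X_mol[0], X_text[0], source="projector_concat")
        assert fe.vector.shape == (6 + 6,)

    def test_dimension_mismatch(self, model):
        with pytest.raises(DimensionError):
            fuse(model, np.ones(5), np.ones(6))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        model = train_bt(_toy_pairs(seed=11), TINY)
        model.save(tmp_path / "bt")
        back = BTModel.load(tmp_path / "bt")
        X_mol, X_text, _ = _toy_pairs(n=8, seed=12)
        assert np.array_equal(
            model.fuse_batch(X_mol, X_text), back.fuse_batch(X_mol, X_text)
        )
        assert back.training_history == model.training_history

    def test_version_mismatch_refused(self, tmp_path):
        import json

        model = train_bt(_toy_pairs(seed=13), TINY)
        model.save(tmp_path / "bt")
        meta = json.loads((tmp_path / "bt" / "bt_config.json").read_text())
        meta["format_version"] = 999
        (tmp_path / "bt" / "bt_config.json").write_text(json.dumps(meta))
        with pytest.raises(ArchiveError):
            BTModel.load(tmp_path / "bt")


def test_encoder_bottleneck_mismatch_rejected():
    with pytest.raises(ConfigurationError):
        BTConfig(enc_mol_dims=(32, 16), enc_text_dims=(32, 8))
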