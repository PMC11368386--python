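"""Autoencoder contracts: shapes, training, layer-replacement finetuning."""

import numpy as np
import pandas as pd
import pytest

from scdiffuse._nn import Linear
from scdiffuse.autoencoder import (
    build_autoencoder,
    decode,
    encode,
    finetune_autoencoder,
    load_autoencoder,
    save_autoencoder,
    train_autoencoder,
)
from scdiffuse.data_io import LOGNORM, ExpressionMatrix


def _lognorm(values):
    v = np.asarray(values, dtype=float)
    return ExpressionMatrix(v, [f"g{j}" for j in range(v.shape[1])],
                            layer_tag=LOGNORM)


class TestBuild:
    def test_dimensions(self):
        m = build_autoencoder(200, 128)
        z = m.encoder.forward(np.zeros((2, 200)))
        assert z.shape == (2, 128)
        assert m.decoder.forward(z).shape == (2, 200)

    def test_empty_hidden_is_single_linear_layer(self):
        m = build_autoencoder(10, 4, hidden_widths=[])
        assert len([l for l in m.encoder.layers if isinstance(l, Linear)]) == 1
        assert len([l for l in m.decoder.layers if isinstance(l, Linear)]) == 1

    def test_same_seed_identical_parameters(self):
        a = build_autoencoder(20, 8, seed=5)
        b = build_autoencoder(20, 8, seed=5)
        for (pa, _), (pb, _) in zip(a.encoder.params(), b.encoder.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_no_compression_warns(self):
        with pytest.warns(UserWarning, match="no compression"):
            build_autoencoder(10, 10)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_autoencoder(0, 4)


class TestTraining:
    def test_zero_epochs_is_noop(self, rng):
        X = _lognorm(rng.uniform(0, 3, size=(20, 10)))
        m = build_autoencoder(10, 4, seed=0)
        before = [p.copy() for p, _ in m.encoder.params()]
        m, hist = train_autoencoder(m, X, epochs=0)
        assert hist == []
        for (p, _), b in zip(m.encoder.params(), before):
            np.testing.assert_array_equal(p, b)

    def test_linear_subspace_is_recovered(self, rng):
        # data on a 2-D linear subspace must be reconstructable with an
        # 8-D latent to well under 1% of the data variance
        basis = rng.uniform(0, 1, size=(2, 30))
        coefs = rng.uniform(0, 2, size=(400, 2))
        X = _lognorm(coefs @ basis)
        m = build_autoencoder(30, 8, hidden_widths=[64], seed=0)
        m, hist = train_autoencoder(m, X, epochs=300, learning_rate=3e-3, seed=0)
        assert hist[-1] < 0.01 * X.values.var()

    def test_loss_decreases_on_fixture(self, small_lognorm):
        m = build_autoencoder(small_lognorm.n_genes, 16, hidden_widths=[64], seed=0)
        m.gene_names = list(small_lognorm.gene_names)
        m, hist = train_autoencoder(m, small_lognorm, epochs=20, seed=0)
        assert hist[-1] < hist[0]

    def test_wrong_layer_rejected(self, small_raw):
        m = build_autoencoder(small_raw.n_genes, 8)
        with pytest.raises(ValueError, match="log-normalized"):
            train_autoencoder(m, small_raw, epochs=1)


class TestEncodeDecode:
    def test_duplicate_cells_encode_identically(self, rng):
        m = build_autoencoder(10, 4, seed=0)
        X = _lognorm(np.tile(rng.uniform(0, 2, size=(1, 10)), (3, 1)))
        Z = encode(m, X)
        np.testing.assert_array_equal(Z[0], Z[1])
        np.testing.assert_array_equal(Z[0], Z[2])

    def test_decode_is_non_negative(self, rng):
        m = build_autoencoder(10, 4, seed=0)
        out = decode(m, rng.normal(size=(50, 4)) * 10)
        assert out.values.min() >= 0.0
        assert out.layer_tag == LOGNORM

    def test_nan_input_rejected(self):
        m = build_autoencoder(4, 2, seed=0)
        bad = np.full((1, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            decode(m, bad)

    def test_reconstruction_rank_correlation_on_fixture(self, small_lognorm):
        from scipy.stats import spearmanr

        m = build_autoencoder(small_lognorm.n_genes, 32, seed=1)
        m.gene_names = list(small_lognorm.gene_names)
        m, _ = train_autoencoder(m, small_lognorm, epochs=150, seed=1)
        rec = decode(m, encode(m, small_lognorm))
        sccs = [spearmanr(small_lognorm.values[i], rec.values[i]).statistic
                for i in range(0, small_lognorm.n_cells, 25)]
        assert np.mean(sccs) >= 0.9

    def test_latent_marginals_roughly_gaussian(self, small_lognorm):
        from scipy.stats import kurtosis

        m = build_autoencoder(small_lognorm.n_genes, 16, seed=2)
        m.gene_names = list(small_lognorm.gene_names)
        m, _ = train_autoencoder(m, small_lognorm, epochs=60, seed=2)
        k = kurtosis(encode(m, small_lognorm), axis=0)
        assert np.all(k > -1.5) and np.all(k < 3.0)


class TestFinetune:
    def test_layer_replacement_contract(self, rng):
        X_old = _lognorm(rng.uniform(0, 2, size=(30, 20)))
        pre = build_autoencoder(20, 6, hidden_widths=[16, 8], seed=0)
        pre, _ = train_autoencoder(pre, X_old, epochs=5, seed=0)

        X_new = _lognorm(rng.uniform(0, 2, size=(30, 15)))
        fresh = finetune_autoencoder(pre, X_new, epochs=0, seed=1)
        enc_new = [l for l in fresh.encoder.layers if isinstance(l, Linear)]
        enc_old = [l for l in pre.encoder.layers if isinstance(l, Linear)]
        dec_new = [l for l in fresh.decoder.layers if isinstance(l, Linear)]
        dec_old = [l for l in pre.decoder.layers if isinstance(l, Linear)]
        # boundary layers resized to the new gene count
        assert enc_new[0].W.shape == (15, 16)
        assert dec_new[-1].W.shape == (16, 15)
        # all interior layers carried over verbatim
        for a, b in zip(enc_new[1:], enc_old[1:]):
            np.testing.assert_array_equal(a.W, b.W)
        for a, b in zip(dec_new[:-1], dec_old[:-1]):
            np.testing.assert_array_equal(a.W, b.W)

    def test_identical_gene_set_keeps_hidden_layers(self, rng):
        X = _lognorm(rng.uniform(0, 2, size=(30, 12)))
        pre = build_autoencoder(12, 4, hidden_widths=[8], seed=0)
        pre, _ = train_autoencoder(pre, X, epochs=3, seed=0)
        fresh = finetune_autoencoder(pre, X, epochs=0, seed=1)
        enc_new = [l for l in fresh.encoder.layers if isinstance(l, Linear)]
        enc_old = [l for l in pre.encoder.layers if isinstance(l, Linear)]
        np.testing.assert_array_equal(enc_new[1].W, enc_old[1].W)
        assert not np.array_equal(enc_new[0].W, enc_old[0].W)

    def test_finetuning_beats_scratch_under_matched_budget(self, small_lognorm):
        # transfer from a trained model reaches lower loss than a cold start
        # within the same (small) epoch budget, across seeds
        idx = np.arange(small_lognorm.n_genes)
        X_sub = ExpressionMatrix(small_lognorm.values[:, idx[:60]],
                                 [small_lognorm.gene_names[j] for j in idx[:60]],
                                 small_lognorm.cell_labels, LOGNORM)
        pre = build_autoencoder(small_lognorm.n_genes, 16, hidden_widths=[64], seed=0)
        pre.gene_names = list(small_lognorm.gene_names)
        pre, _ = train_autoencoder(pre, small_lognorm, epochs=60, seed=0)
        wins = 0
        for seed in range(3):
            tuned = finetune_autoencoder(pre, X_sub, epochs=8, seed=seed)
            _, tuned_hist = train_autoencoder(tuned, X_sub, epochs=1, seed=seed)
            cold = build_autoencoder(60, 16, hidden_widths=[64], seed=seed)
            cold.gene_names = list(X_sub.gene_names)
            cold, _ = train_autoencoder(cold, X_sub, epochs=8, seed=seed)
            _, cold_hist = train_autoencoder(cold, X_sub, epochs=1, seed=seed)
            wins += tuned_hist[0] < cold_hist[0]
        assert wins >= 2


def test_checkpoint_round_trip(tmp_path, rng):
    m = build_autoencoder(12, 4, hidden_widths=[8], seed=0)
    X = _lognorm(rng.uniform(0, 2, size=(20, 12)))
    m, _ = train_autoencoder(m, X, epochs=2, seed=0)
    save_autoencoder(m, tmp_path / "ae.npz")
    loaded = load_autoencoder(tmp_path / "ae.npz")
    z = rng.normal(size=(3, 4))
    np.testing.assert_array_equal(decode(m, z).values, decode(loaded, z).values)
    assert loaded.gene_names == m.gene_names
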