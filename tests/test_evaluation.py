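"""Metric battery: identities, oracles and null behaviors."""

import numpy as np
import pytest

from scdiffuse.data_io import LOGNORM, ExpressionMatrix
from scdiffuse.evaluation import (
    conditional_purity,
    discriminator_auc,
    lisi,
    mmd,
    qq_points,
    scc,
    train_oracle_classifier,
)


def _em(values):
    v = np.asarray(values, dtype=float)
    return ExpressionMatrix(v, [f"g{j}" for j in range(v.shape[1])],
                            layer_tag=LOGNORM)


@pytest.fixture(scope="module")
def cloud():
    rng = np.random.default_rng(3)
    return rng.gamma(2.0, 1.0, size=(400, 30))


class TestSCC:
    def test_identity_is_one(self, cloud):
        assert scc(_em(cloud), _em(cloud)) == pytest.approx(1.0)

    def test_monotone_transform_of_mean_profile_invariant(self, cloud):
        # rank correlation only sees the per-gene mean profile ranks
        cubed_means = np.tile(cloud.mean(axis=0) ** 3, (40, 1))
        assert scc(_em(cloud), _em(cubed_means)) == pytest.approx(1.0)

    def test_hand_computed_rank_swap(self):
        # per-gene means (1,2,3,4) vs (1,2,4,3): one adjacent rank swap.
        # Spearman rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*2/60 = 0.8
        real = _em(np.array([[1.0, 2.0, 3.0, 4.0]] * 3))
        gen = _em(np.array([[1.0, 2.0, 4.0, 3.0]] * 3))
        assert scc(real, gen) == pytest.approx(0.8)

    def test_symmetric(self, cloud):
        other = cloud[::-1] * 1.3
        assert scc(_em(cloud), _em(other)) == pytest.approx(
            scc(_em(other), _em(cloud)))

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            scc(_em(np.ones((5, 2))), _em(np.ones((5, 2))))


class TestMMD:
    def test_self_comparison_near_zero(self, cloud):
        assert mmd(cloud, cloud.copy()) <= 1e-9

    def test_same_distribution_within_permutation_null(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 10))
        Y = rng.normal(size=(200, 10))
        obs = mmd(X, Y, space="gene")
        pooled = np.concatenate([X, Y])
        null = []
        for k in range(30):
            perm = np.random.default_rng(k).permutation(400)
            null.append(mmd(pooled[perm[:200]], pooled[perm[200:]], space="gene"))
        assert abs(obs - np.mean(null)) < 3 * np.std(null)

    def test_mean_shift_detected_against_null(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 8))
        Y = rng.normal(size=(150, 8)) + 2.0
        obs = mmd(X, Y, space="gene")
        pooled = np.concatenate([X, Y])
        null = []
        for k in range(20):
            perm = np.random.default_rng(k).permutation(300)
            null.append(mmd(pooled[perm[:150]], pooled[perm[150:]], space="gene"))
        assert obs > np.quantile(null, 0.95)

    def test_symmetric(self, cloud):
        other = cloud * 1.5
        assert mmd(cloud, other, seed=0) == pytest.approx(mmd(other, cloud, seed=0))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mmd(np.ones((30, 5)), np.ones((30, 5)))


class TestLISI:
    def test_identical_distributions_mix(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 10))
        Y = rng.normal(size=(300, 10))
        assert lisi(X, Y, k=90) >= 0.9

    def test_complete_separation_scores_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 10))
        Y = rng.normal(size=(200, 10)) + 100.0
        assert lisi(X, Y, k=90) <= 0.05

    def test_k_must_be_below_cell_count(self):
        with pytest.raises(ValueError, match="k"):
            lisi(np.zeros((10, 3)), np.zeros((10, 3)), k=30)


class TestDiscriminator:
    def test_iid_halves_indistinguishable(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(400, 12))
        auc = discriminator_auc(Z[:200], Z[200:], "rf", seed=0)
        assert 0.40 <= auc <= 0.60

    def test_large_shift_trivially_separable(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(300, 6))
        auc = discriminator_auc(Z[:150], Z[150:] + 10.0, "rf", seed=0)
        assert auc >= 0.95

    @pytest.mark.parametrize("model", ["rf", "knn"])
    def test_both_models_run_and_bound(self, model):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(100, 5))
        b = rng.normal(size=(100, 5)) + 1.0
        auc = discriminator_auc(a, b, model, seed=1)
        assert 0.5 < auc <= 1.0

    def test_imbalance_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="imbalance"):
            discriminator_auc(rng.normal(size=(700, 4)),
                              rng.normal(size=(60, 4)), "rf", seed=0)


class TestQQ:
    def test_identical_inputs_on_diagonal(self, rng):
        v = rng.exponential(size=200)
        pts = qq_points(v, v.copy(), 50)
        np.testing.assert_allclose(pts[:, 0], pts[:, 1])

    def test_scale_map_is_line_y_2x(self, rng):
        v = rng.exponential(size=500)
        pts = qq_points(v, 2 * v, 50)
        np.testing.assert_allclose(pts[:, 1], 2 * pts[:, 0], rtol=1e-10)

    def test_matches_direct_order_statistic_computation(self, rng):
        # oracle: sort + linear interpolation at the same probability grid,
        # written out independently of the implementation
        r = rng.exponential(size=1000)
        g = rng.uniform(size=1000)
        n_q = 100
        pts = qq_points(r, g, n_q)
        probs = (np.arange(n_q) + 0.5) / n_q
        for vals, col in ((r, 0), (g, 1)):
            srt = np.sort(vals)
            h = probs * (len(vals) - 1)
            lo = np.floor(h).astype(int)
            hi = np.ceil(h).astype(int)
            expect = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
            np.testing.assert_allclose(pts[:, col], expect, rtol=1e-10)


class TestOraclePurity:
    @pytest.fixture(scope="class")
    def oracle_and_data(self, small_lognorm):
        oracle, acc = train_oracle_classifier(small_lognorm, "cell_type", seed=0)
        return oracle, acc, small_lognorm

    def test_real_cells_score_near_oracle_accuracy(self, oracle_and_data):
        oracle, acc, X = oracle_and_data
        mask = (X.cell_labels["cell_type"] == "TypeA").to_numpy()
        purity = conditional_purity(X.subset_cells(mask), "TypeA", oracle)
        assert purity >= acc - 0.1

    def test_label_free_noise_scores_near_chance(self, oracle_and_data, rng):
        # destroy the class signal but keep per-gene marginals by permuting
        # each gene independently across cells
        oracle, _, X = oracle_and_data
        perm = np.column_stack([rng.permutation(X.values[:, j])
                                for j in range(X.n_genes)])
        purity = conditional_purity(_em(perm), "TypeA", oracle)
        assert abs(purity - 0.5) <= 0.15

    def test_unknown_label_rejected(self, oracle_and_data):
        oracle, _, X = oracle_and_data
        with pytest.raises(KeyError, match="vocabulary"):
            conditional_purity(X, "Nope", oracle)
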