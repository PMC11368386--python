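"""Metrics comparing generated to real expression data.

Battery: Spearman correlation of per-gene mean profiles (SCC), unbiased
RBF-kernel maximum mean discrepancy (MMD), a local inverse Simpson mixing
index (LISI) on a joint-PCA nearest-neighbor graph, real-vs-generated
discriminator AUC (random forest with 1000 trees of depth 5, or KNN), and
per-gene QQ points. Conditional generation quality is scored by an oracle
classifier trained only on real cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix, LOGNORM


def _values(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def _lognorm_values(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix) and x.layer_tag != LOGNORM:
        raise ValueError("metric expects log-normalized expression")
    return _values(x)


@dataclass
class EvaluationReport:
    scc: float
    mmd: float
    lisi: float
    rf_auc: float
    knn_auc: float
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def scc(real, gen) -> float:
    """Spearman correlation between the per-gene mean lognorm profiles."""
    R, G = _lognorm_values(real), _lognorm_values(gen)
    if R.shape[1] != G.shape[1]:
        raise ValueError("gene sets differ in size")
    if R.shape[1] < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    rho, _ = stats.spearmanr(R.mean(axis=0), G.mean(axis=0))
    return float(rho)


def _pca_joint(R: np.ndarray, G: np.ndarray, n_pcs: int, seed: int = 0):
    from sklearn.decomposition import PCA

    X = np.concatenate([R, G], axis=0)
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    P = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    return P[: R.shape[0]], P[R.shape[0]:]


def mmd(real, gen, space: str = "pca", kernel_bandwidth: float | str = "auto",
        n_pcs: int = 50, seed: int = 0) -> float:
    """Unbiased squared-MMD estimate with an RBF kernel.

    ``space``: "pca" (default; top PCs of the pooled data), "gene" or
    "latent" (inputs used as-is). Bandwidth is the median pooled pairwise
    distance when "auto". The unbiased estimator can be slightly negative
    for matched distributions.
    """
    R, G = _values(real), _values(gen)
    if R.shape[0] < 20 or G.shape[0] < 20:
        raise ValueError("need at least 20 cells per side")
    if np.allclose(R.std(axis=0), 0) or np.allclose(G.std(axis=0), 0):
        raise ValueError("degenerate (zero-variance) input")
    if space == "pca":
        R, G = _pca_joint(R, G, n_pcs, seed)
    elif space not in ("gene", "latent"):
        raise ValueError("space must be one of pca, gene, latent")

    from sklearn.metrics import pairwise_distances

    X = np.concatenate([R, G], axis=0)
    D = pairwise_distances(X)
    n = R.shape[0]
    if kernel_bandwidth == "auto":
        tri = D[np.triu_indices_from(D, k=1)]
        sigma = float(np.median(tri))
        if sigma <= 0:
            raise ValueError("degenerate input: zero median pairwise distance")
    else:
        sigma = float(kernel_bandwidth)
    K = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    Kxx, Kyy, Kxy = K[:n, :n], K[n:, n:], K[:n, n:]
    m, l = Kxx.shape[0], Kyy.shape[0]
    term_x = (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
    term_y = (Kyy.sum() - np.trace(Kyy)) / (l * (l - 1))
    return float(term_x + term_y - 2.0 * Kxy.mean())


def lisi(real, gen, k: int = 90, n_pcs: int = 50, seed: int = 0) -> float:
    """Mean local inverse Simpson index of real/generated mixing, in [0, 1].

    Each cell's k nearest neighbors (joint PCA space) give a distribution
    over the two origins; the inverse Simpson index 1/sum(p^2) lies in
    [1, 2] for two groups and is rescaled to [0, 1]. 1 = perfectly mixed.
    """
    from sklearn.neighbors import NearestNeighbors

    R, G = _values(real), _values(gen)
    n_total = R.shape[0] + G.shape[0]
    if k >= n_total:
        raise ValueError(f"k = {k} >= total cells {n_total}")
    Rp, Gp = _pca_joint(R, G, n_pcs, seed)
    X = np.concatenate([Rp, Gp], axis=0)
    labels = np.concatenate([np.zeros(R.shape[0]), np.ones(G.shape[0])])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = labels[idx[:, 1:]]  # drop self
    p1 = neigh.mean(axis=1)
    isi = 1.0 / (p1 ** 2 + (1.0 - p1) ** 2)
    return float(np.clip(np.mean(isi) - 1.0, 0.0, 1.0))


def discriminator_auc(real, gen, model: str = "rf", seed: int = 0) -> float:
    """ROC AUC of a real-vs-generated discriminator on a held-out split.

    ``rf``: random forest, 1000 trees, max depth 5, 0.75/0.25 split.
    ``knn``: k-nearest-neighbors (k = 5), 0.7/0.3 split.
    0.5 means the two sets are indistinguishable.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import KNeighborsClassifier

    R, G = _values(real), _values(gen)
    if R.shape[0] < 50 or G.shape[0] < 50:
        raise ValueError("need at least 50 cells per side")
    ratio = max(R.shape[0], G.shape[0]) / min(R.shape[0], G.shape[0])
    if ratio > 10:
        warnings.warn(f"class imbalance {ratio:.1f}:1 between real and generated")
    X = np.concatenate([R, G], axis=0)
    y = np.concatenate([np.zeros(R.shape[0]), np.ones(G.shape[0])])
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=1000, max_depth=5,
                                     random_state=seed, n_jobs=1)
        test_size = 0.25
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
        test_size = 0.3
    else:
        raise ValueError("model must be 'rf' or 'knn'")
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=test_size,
                                          random_state=seed, stratify=y)
    clf.fit(Xtr, ytr)
    return float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))


def qq_points(real_gene_values, gen_gene_values,
              n_quantiles: int = 100) -> np.ndarray:
    """Paired empirical quantiles at n evenly spaced probabilities.

    Returns an (n_quantiles, 2) array of (real, generated) quantiles for
    one gene within one cell type; identical distributions fall on y = x.
    """
    r = np.asarray(real_gene_values, dtype=float).ravel()
    g = np.asarray(gen_gene_values, dtype=float).ravel()
    if r.size < 10 or g.size < 10:
        raise ValueError("need at least 10 values per side")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return np.column_stack([np.quantile(r, probs), np.quantile(g, probs)])


# ---------------------------------------------------------------------------
# Oracle classifier (stands in for an external cell-type annotator): trained
# only on real cells, never on generated ones.
# ---------------------------------------------------------------------------

def train_oracle_classifier(real: ExpressionMatrix, label_column: str,
                            seed: int = 0, test_fraction: float = 0.2):
    """Fit a multinomial logistic oracle on real lognorm cells.

    Returns ``(oracle, held_out_accuracy)``; the oracle exposes the sklearn
    ``predict`` / ``classes_`` interface over lognorm expression values.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    V = _lognorm_values(real)
    y = real.cell_labels[label_column].to_numpy().astype(str)
    Xtr, Xte, ytr, yte = train_test_split(
        V, y, test_size=test_fraction, random_state=seed, stratify=y)
    oracle = LogisticRegression(max_iter=2000, random_state=seed)
    oracle.fit(Xtr, ytr)
    acc = float(np.mean(oracle.predict(Xte) == yte))
    return oracle, acc


def conditional_purity(gen, target_label: str, oracle) -> float:
    """Fraction of generated cells the real-data oracle assigns to the target."""
    classes = [str(c) for c in getattr(oracle, "classes_", [])]
    if classes and str(target_label) not in classes:
        raise KeyError(f"label {target_label!r} not in oracle vocabulary {classes}")
    pred = oracle.predict(_values(gen))
    return float(np.mean(pred.astype(str) == str(target_label)))


def evaluate_pair(real, gen, seed: int = 0, k_lisi: int = 90,
                  n_pcs: int = 50) -> EvaluationReport:
    """Full metric battery between a real and a generated expression set."""
    cfg = {"mmd_space": "pca", "mmd_bandwidth": "median-heuristic",
           "n_pcs": n_pcs, "lisi_k": k_lisi,
           "rf": {"n_estimators": 1000, "max_depth": 5, "test_size": 0.25},
           "knn": {"k": 5, "test_size": 0.3}, "seed": seed}
    return EvaluationReport(
        scc=scc(real, gen),
        mmd=mmd(real, gen, n_pcs=n_pcs, seed=seed),
        lisi=lisi(real, gen, k=k_lisi, n_pcs=n_pcs, seed=seed),
        rf_auc=discriminator_auc(real, gen, "rf", seed=seed),
        knn_auc=discriminator_auc(real, gen, "knn", seed=seed),
        config=cfg,
    )
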