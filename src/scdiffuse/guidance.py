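"""Classifier guidance and gradient interpolation for the reverse process.

A small MLP classifier is trained on *noisy* latent codes: each training
example is a code corrupted to a random step i drawn from 0..floor(T/2)
(clean codes included), paired with its condition label. Beyond T/2 the
signal is considered too degraded to classify, so at inference the
guidance gradient is exactly zero above that ceiling.

During sampling the gradient of the classifier's log-probability for the
target label, scaled by gamma (and by beta_i inside the reverse step),
steers each transition toward the condition. Several classifiers can be
combined by summing their weighted gradients, which permits condition
combinations absent from the training data. Gradient interpolation blends
two targets of one classifier with weights (gamma1, gamma2) and starts the
chain from partially noised real cells instead of pure noise, preserving
their broad characteristics while moving them between states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import MLP, Adam, sinusoidal_embedding, softmax
from .diffusion import NoiseSchedule


class GuidanceClassifier:
    """Four-layer MLP over (latent code, timestep embedding) -> class probabilities."""

    def __init__(self, latent_dim: int, vocabulary: list[str],
                 hidden_widths: list[int] | None = None, time_dim: int = 32,
                 ceiling: int = 0, seed: int = 0):
        if len(vocabulary) < 2:
            raise ValueError("classifier needs at least two classes")
        self.latent_dim = latent_dim
        self.vocabulary = list(vocabulary)
        self.time_dim = time_dim
        self.ceiling = ceiling  # guidance active only at steps <= ceiling
        self.hidden_widths = list(hidden_widths) if hidden_widths else [256, 128, 64]
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.net = MLP([latent_dim + time_dim, *self.hidden_widths, len(vocabulary)], rng)

    def logits(self, x: np.ndarray, i: int | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        steps = np.broadcast_to(np.asarray(i, dtype=float), (x.shape[0],))
        emb = sinusoidal_embedding(steps, self.time_dim)
        return self.net.forward(np.concatenate([x, emb], axis=1))

    def predict_proba(self, x: np.ndarray, i: int | np.ndarray = 0) -> np.ndarray:
        return softmax(self.logits(x, i))

    def predict(self, x: np.ndarray, i: int | np.ndarray = 0) -> np.ndarray:
        idx = np.argmax(self.logits(x, i), axis=1)
        return np.asarray(self.vocabulary, dtype=object)[idx]

    def _target_index(self, target: str) -> int:
        try:
            return self.vocabulary.index(target)
        except ValueError:
            raise KeyError(
                f"unknown target {target!r}; vocabulary: {self.vocabulary}") from None

    def log_prob_input_grad(self, x: np.ndarray, i: int | np.ndarray,
                            target: str) -> np.ndarray:
        """d log p(target | x, i) / dx by backpropagation (parameters untouched)."""
        c = self._target_index(target)
        self.net.zero_grad()
        probs = softmax(self.logits(x, i))
        seed = -probs
        seed[:, c] += 1.0  # d log softmax_c / d logits = e_c - p
        g_in = self.net.backward(seed)
        self.net.zero_grad()
        return g_in[:, :self.latent_dim]


def train_classifier(Z: np.ndarray, labels, s: NoiseSchedule,
                     ceiling: int | None = None, hidden_widths: list[int] | None = None,
                     n_steps: int = 2000, batch_size: int = 128,
                     learning_rate: float = 1e-3, seed: int = 0,
                     balanced: bool = False) -> GuidanceClassifier:
    """Train a guidance classifier on noisy latent codes.

    ``Z`` are clean latent codes on the *normalized* scale the diffusion
    chain runs on (see ``DenoiserModel.normalize``); ``labels`` the
    per-cell condition. Each minibatch example is corrupted to a step drawn
    uniformly from {0, 1, ..., ceiling} (0 = clean) with
    ceiling = floor(T/2) by default, and the model is fit by cross-entropy.

    By default minibatches are drawn uniformly over cells, so the trained
    network estimates the true conditional p(y | x_i) including the class
    prior -- the quantity the guidance term calls for. ``balanced=True``
    instead equalizes classes per minibatch, which estimates a
    prior-shifted conditional; it can help pure classification of rare
    classes but shifts the decision boundary away from their manifold and
    empirically weakens guidance toward them.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if Z.shape[0] != labels.shape[0]:
        raise ValueError("labels must match rows of Z")
    vocab = sorted(set(str(l) for l in labels))
    if len(vocab) < 2:
        raise ValueError(f"need at least two classes, got {vocab}")
    y = np.array([vocab.index(str(l)) for l in labels])
    ceiling = int(s.T // 2) if ceiling is None else int(ceiling)

    clf = GuidanceClassifier(Z.shape[1], vocab, hidden_widths=hidden_widths,
                             ceiling=ceiling, seed=seed)
    rng = np.random.default_rng(seed)
    opt = Adam(clf.net.params(), lr=learning_rate)
    n = Z.shape[0]
    class_idx = [np.where(y == k)[0] for k in range(len(vocab))]
    for _ in range(n_steps):
        if balanced:
            per = max(batch_size // len(vocab), 1)
            idx = np.concatenate([rng.choice(ci, size=per) for ci in class_idx])
        else:
            idx = rng.integers(0, n, size=min(batch_size, n))
        i = rng.integers(0, ceiling + 1, size=idx.size)
        eps = rng.standard_normal((idx.size, Z.shape[1]))
        noisy = Z[idx].copy()
        pos = i > 0
        if np.any(pos):
            _, _, abar = s.at(i[pos])
            noisy[pos] = (np.sqrt(abar)[:, None] * Z[idx][pos]
                          + np.sqrt(1.0 - abar)[:, None] * eps[pos])
        clf.net.zero_grad()
        probs = softmax(clf.logits(noisy, i))
        seed_grad = probs.copy()
        seed_grad[np.arange(idx.size), y[idx]] -= 1.0
        clf.net.backward(seed_grad / idx.size)
        opt.step()
    return clf


def guidance_gradient(clf: GuidanceClassifier, x_i: np.ndarray, i: int,
                      target: str, gamma: float = 2.0) -> np.ndarray:
    """gamma * grad_x log p(target | x_i, i); zero above the active-step ceiling."""
    x_i = np.asarray(x_i, dtype=float)
    clf._target_index(target)  # validate even when returning zeros
    if gamma == 0.0 or i > clf.ceiling:
        return np.zeros_like(x_i)
    return gamma * clf.log_prob_input_grad(x_i, i, target)


def interpolation_gradient(clf: GuidanceClassifier, x_i: np.ndarray, i: int,
                           y1: str, y2: str, gamma1: float, gamma2: float) -> np.ndarray:
    """Blend of two targets: gamma1 * grad log p(y1) + gamma2 * grad log p(y2)."""
    if y1 == y2:
        raise ValueError("interpolation requires two distinct targets")
    return (guidance_gradient(clf, x_i, i, y1, gamma1)
            + guidance_gradient(clf, x_i, i, y2, gamma2))


@dataclass
class GuidanceTerm:
    """One classifier with either a single target (weight gamma) or a pair
    of targets with weights (gamma1, gamma2) for interpolation."""

    classifier: GuidanceClassifier
    target: str | tuple[str, str]
    gamma: float | tuple[float, float] = 2.0

    @property
    def interpolating(self) -> bool:
        return isinstance(self.target, tuple)


@dataclass
class GuidanceSpec:
    terms: list[GuidanceTerm]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("guidance spec needs at least one term")
        dims = {t.classifier.latent_dim for t in self.terms}
        if len(dims) != 1:
            raise ValueError(f"classifiers disagree on latent_dim: {sorted(dims)}")


def combine_guidances(spec: GuidanceSpec):
    """Callable (x_i, i) -> summed weighted gradient over all terms."""

    def fn(x_i: np.ndarray, i: int) -> np.ndarray:
        total = np.zeros_like(np.asarray(x_i, dtype=float))
        for term in spec.terms:
            if term.interpolating:
                y1, y2 = term.target
                g1, g2 = term.gamma if isinstance(term.gamma, tuple) else (term.gamma,) * 2
                total += interpolation_gradient(term.classifier, x_i, i, y1, y2, g1, g2)
            else:
                total += guidance_gradient(term.classifier, x_i, i, term.target,
                                           float(term.gamma))
        return total

    return fn


def make_noised_init(s: NoiseSchedule, x0_cells: np.ndarray, t: int = 600,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Partially noise real cells to step t: sqrt(abar_t) x0 + sqrt(1-abar_t) eps.

    The sampler must then start its reverse loop at step t (pass
    ``start_step=t`` to ``diffusion.sample``). ``x0_cells`` are latent codes
    on the normalized diffusion scale.
    """
    if not 1 <= t <= s.T:
        raise ValueError(f"t = {t} outside 1..{s.T}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x0 = np.asarray(x0_cells, dtype=float)
    _, _, abar = s.at(t)
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * rng.standard_normal(x0.shape)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_classifier(clf: GuidanceClassifier, path: str | Path) -> Path:
    path = Path(path)
    meta = {"version": 1, "latent_dim": clf.latent_dim, "vocabulary": clf.vocabulary,
            "hidden_widths": clf.hidden_widths, "time_dim": clf.time_dim,
            "ceiling": clf.ceiling, "seed": clf.seed}
    arrays = {f"p_{i}": a for i, a in enumerate(clf.net.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_classifier(path: str | Path) -> GuidanceClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        clf = GuidanceClassifier(meta["latent_dim"], meta["vocabulary"],
                                 meta["hidden_widths"], meta["time_dim"],
                                 meta["ceiling"], meta["seed"])
        n = len(clf.net.state_arrays())
        clf.net.load_state_arrays([data[f"p_{i}"] for i in range(n)])
    return clf
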