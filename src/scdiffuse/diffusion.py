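"""DDPM core: noise schedule, forward corruption, denoiser and reverse sampler.

The forward process corrupts a latent code x0 over T steps,
``q(x_i | x_{i-1}) = N(sqrt(1 - beta_i) x_{i-1}, beta_i I)``, which has the
closed form ``x_i = sqrt(abar_i) x0 + sqrt(1 - abar_i) eps``. The per-step
rate is linear between ``beta_min/T`` and ``beta_max/T``:

    beta_i = beta_min/T + (i - 1)/(T - 1) * (beta_max/T - beta_min/T)

A skip-connected MLP with a sinusoidal timestep embedding predicts the
injected noise; the reverse chain steps from x_T (or a partially noised
start) down to x_0 using the standard posterior mean

    mu = (1/sqrt(alpha_i)) (x_i - beta_i/sqrt(1 - abar_i) eps_hat)

plus Gaussian noise whose variance is controlled by a randomness weight w
(see ``reverse_step``). Steps are one-based at every interface.

Latent codes are standardized per dimension before diffusion so the
terminal distribution is comparable to the standard normal the sampler
starts from; the trained model stores the location/scale and undoes the
transform after sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import MLP, Adam, Linear, SiLU, sinusoidal_embedding

VARIANCE_MODES = ("posterior", "plain", "exp_w_beta", "literal")


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step corruption rates beta_i with derived alpha_i and abar_i (1-based)."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    beta_min: float
    beta_max: float

    def at(self, i: int | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(beta_i, alpha_i, abar_i) for one-based step index/indices."""
        idx = np.asarray(i) - 1
        if np.any(idx < 0) or np.any(idx >= self.T):
            raise ValueError(f"step index out of range 1..{self.T}")
        return self.beta[idx], self.alpha[idx], self.alpha_bar[idx]


def make_schedule(T: int = 1000, beta_min: float = 0.1, beta_max: float = 20.0) -> NoiseSchedule:
    """Linear schedule from beta_min/T to beta_max/T over T steps."""
    if T < 2:
        raise ValueError("T must be at least 2")
    if not (0 < beta_min < beta_max):
        raise ValueError("need 0 < beta_min < beta_max")
    i = np.arange(1, T + 1, dtype=float)
    lo, hi = beta_min / T, beta_max / T
    beta = lo + (i - 1.0) / (T - 1.0) * (hi - lo)
    bad = np.where((beta <= 0) | (beta >= 1))[0]
    if bad.size:
        raise ValueError(f"beta_{bad[0] + 1} = {beta[bad[0]]:.4g} outside (0, 1)")
    alpha = 1.0 - beta
    return NoiseSchedule(T, beta, alpha, np.cumprod(alpha), beta_min, beta_max)


def forward_sample(s: NoiseSchedule, x0: np.ndarray, i: int | np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """Closed-form corruption at step i: sqrt(abar_i) x0 + sqrt(1-abar_i) eps."""
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if eps.shape != x0.shape:
        raise ValueError("eps must match x0 in shape")
    _, _, abar = s.at(i)
    abar = np.asarray(abar).reshape(-1, 1) if x0.ndim == 2 and np.ndim(i) else float(abar)
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


# ---------------------------------------------------------------------------
# Denoiser
# ---------------------------------------------------------------------------

class DenoiserModel:
    """Skip-connected fully-connected noise predictor eps_theta(x_i, i).

    Input projection latent_dim -> W, three hidden blocks of width W where a
    long skip connection concatenates the first block's output into the last
    block's input, and a sinusoidal timestep embedding added after a
    two-layer projection. Also carries the latent standardization (loc,
    scale) fixed at training time.
    """

    def __init__(self, latent_dim: int, width: int = 512, time_dim: int = 128,
                 seed: int = 0):
        self.latent_dim = latent_dim
        self.width = width
        self.time_dim = time_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        W = width
        self.temb1 = Linear(time_dim, W, rng)
        self.temb_act = SiLU()
        self.temb2 = Linear(W, W, rng)
        self.lin_in = Linear(latent_dim, W, rng)
        self.act0 = SiLU()
        self.l1 = Linear(W, W, rng)
        self.act1 = SiLU()
        self.l2 = Linear(W, W, rng)
        self.act2 = SiLU()
        self.l3 = Linear(2 * W, W, rng)
        self.act3 = SiLU()
        self.lin_out = Linear(W, latent_dim, rng)
        self.loc = np.zeros(latent_dim)
        self.scale = np.ones(latent_dim)

    # -- latent standardization ---------------------------------------
    def fit_standardization(self, Z: np.ndarray) -> None:
        self.loc = Z.mean(axis=0)
        sd = Z.std(axis=0)
        self.scale = np.where(sd > 1e-8, sd, 1.0)

    def normalize(self, Z: np.ndarray) -> np.ndarray:
        return (Z - self.loc) / self.scale

    def denormalize(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.loc

    # -- forward / backward --------------------------------------------
    def _layers(self):
        return [self.temb1, self.temb_act, self.temb2, self.lin_in, self.act0,
                self.l1, self.act1, self.l2, self.act2, self.l3, self.act3,
                self.lin_out]

    def forward(self, x: np.ndarray, i: int | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        steps = np.broadcast_to(np.asarray(i, dtype=float), (x.shape[0],))
        e = self.temb2.forward(self.temb_act.forward(
            self.temb1.forward(sinusoidal_embedding(steps, self.time_dim))))
        h0 = self.act0.forward(self.lin_in.forward(x) + e)
        h1 = self.act1.forward(self.l1.forward(h0))
        h2 = self.act2.forward(self.l2.forward(h1))
        h3 = self.act3.forward(self.l3.forward(np.concatenate([h2, h0], axis=1)))
        return self.lin_out.forward(h3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Backprop an upstream gradient on the output; returns grad w.r.t. x."""
        W = self.width
        g3 = self.l3.backward(self.act3.backward(self.lin_out.backward(g)))
        g_h2, g_h0_skip = g3[:, :W], g3[:, W:]
        g_h1 = self.l2.backward(self.act2.backward(g_h2))
        g_h0 = self.l1.backward(self.act1.backward(g_h1)) + g_h0_skip
        g_pre = self.act0.backward(g_h0)
        self.temb1.backward(self.temb_act.backward(self.temb2.backward(g_pre)))
        return self.lin_in.backward(g_pre)

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for layer in self._layers():
            layer.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()] + [self.loc, self.scale]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        for (p, _), a in zip(own, arrays[:-2]):
            p[...] = a
        self.loc = arrays[-2]
        self.scale = arrays[-1]


def training_loss(model: DenoiserModel, s: NoiseSchedule, batch: np.ndarray,
                  rng: np.random.Generator, backprop: bool = False) -> float:
    """Simple eps-prediction objective on one minibatch of (normalized) latents.

    Draws a step i uniform in 1..T and eps ~ N(0, I) per row, corrupts with
    the closed form and scores mean squared error between eps and the
    model's prediction. With ``backprop=True`` parameter gradients are
    accumulated (caller steps the optimizer).
    """
    batch = np.asarray(batch, dtype=float)
    if not np.all(np.isfinite(batch)):
        raise ValueError("non-finite values in training batch")
    i = rng.integers(1, s.T + 1, size=batch.shape[0])
    eps = rng.standard_normal(batch.shape)
    _, _, abar = s.at(i)
    x_i = np.sqrt(abar)[:, None] * batch + np.sqrt(1.0 - abar)[:, None] * eps
    pred = model.forward(x_i, i)
    diff = pred - eps
    loss = float(np.mean(diff * diff))
    if not np.isfinite(loss):
        bad = int(i[np.argmax(~np.isfinite(diff).all(axis=1))]) if diff.size else -1
        raise FloatingPointError(f"non-finite diffusion loss (step index {bad})")
    if backprop:
        model.backward((2.0 / diff.size) * diff)
    return loss


def train_denoiser(model: DenoiserModel, s: NoiseSchedule, Z: np.ndarray,
                   n_steps: int = 3000, batch_size: int = 128,
                   learning_rate: float = 1e-3, seed: int = 0,
                   standardize: bool = True) -> list[float]:
    """Adam training of the noise predictor on latent codes Z (raw scale).

    Standardizes Z per dimension (stored on the model) unless disabled.
    Returns the per-step loss history.
    """
    Z = np.asarray(Z, dtype=float)
    if standardize:
        model.fit_standardization(Z)
    Zn = model.normalize(Z)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=learning_rate)
    history = []
    for step in range(n_steps):
        # step-wise learning-rate decay tightens late convergence
        frac = step / max(n_steps, 1)
        opt.lr = learning_rate * (1.0 if frac < 0.6 else 0.3 if frac < 0.85 else 0.1)
        idx = rng.integers(0, Zn.shape[0], size=min(batch_size, Zn.shape[0]))
        model.zero_grad()
        history.append(training_loss(model, s, Zn[idx], rng, backprop=True))
        opt.step()
    return history


# ---------------------------------------------------------------------------
# Reverse process
# ---------------------------------------------------------------------------

def posterior_mean(s: NoiseSchedule, x_i: np.ndarray, i: int,
                   eps_hat: np.ndarray) -> np.ndarray:
    """mu = (1/sqrt(alpha_i)) * (x_i - beta_i/sqrt(1 - abar_i) * eps_hat)."""
    if i < 1:
        raise ValueError("no reverse step below 1")
    x_i = np.asarray(x_i, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if eps_hat.shape != x_i.shape:
        raise ValueError("eps_hat must match x_i in shape")
    beta, alpha, abar = s.at(i)
    return (x_i - (beta / np.sqrt(1.0 - abar)) * eps_hat) / np.sqrt(alpha)


def reverse_variance(s: NoiseSchedule, i: int, w: float,
                     mode: str = "plain") -> float:
    """sigma_i^2 for one reverse step.

    ``plain`` (default) is beta_i, the simple DDPM choice; ``posterior``
    is the exact forward-posterior variance
    beta_tilde_i = (1 - abar_{i-1}) / (1 - abar_i) * beta_i;
    ``exp_w_beta`` -> exp(w) * beta_i and ``literal`` -> exp(w * beta_i)
    are alternative readings of the randomness weight w (w is ignored by
    the first two modes)."""
    beta, _, abar = s.at(i)
    if mode == "posterior":
        abar_prev = 1.0 if i == 1 else float(s.alpha_bar[i - 2])
        return float((1.0 - abar_prev) / (1.0 - abar) * beta)
    if mode == "exp_w_beta":
        return float(np.exp(w) * beta)
    if mode == "literal":
        return float(np.exp(w * beta))
    if mode == "plain":
        return float(beta)
    raise ValueError(f"variance mode must be one of {VARIANCE_MODES}")


def reverse_step(s: NoiseSchedule, model: DenoiserModel, x_i: np.ndarray, i: int,
                 w: float = 0.5, guidance=None,
                 rng: np.random.Generator | None = None,
                 variance_mode: str = "plain") -> np.ndarray:
    """One reverse transition x_i -> x_{i-1}.

    x_{i-1} = mu_theta(x_i, i) + beta_i * guidance(x_i, i) + sigma_i z with
    z ~ N(0, I) (z = 0 at the final step i = 1). ``guidance`` is an optional
    callable returning the weighted classifier score gradient; it must not
    consume the sampling rng, so a null guidance reproduces the unguided
    chain exactly under a shared stream.
    """
    if not 1 <= i <= s.T:
        raise ValueError(f"step {i} outside 1..{s.T}")
    eps_hat = model.forward(x_i, i)
    mu = posterior_mean(s, x_i, i, eps_hat)
    if guidance is not None:
        g = np.asarray(guidance(x_i, i), dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite guidance gradient at step {i}")
        beta, _, _ = s.at(i)
        mu = mu + beta * g
    if i > 1:
        if rng is None:
            raise ValueError("rng required for steps above 1")
        sigma = np.sqrt(reverse_variance(s, i, w, variance_mode))
        mu = mu + sigma * rng.standard_normal(x_i.shape)
    return mu


def sample(model: DenoiserModel, s: NoiseSchedule, n_cells: int | None = None,
           w: float = 0.5, guidance=None, x_init: np.ndarray | None = None,
           start_step: int | None = None,
           rng: np.random.Generator | int | None = None,
           variance_mode: str = "plain",
           denormalize: bool = True) -> np.ndarray:
    """Run the reverse chain from pure noise (or a partially noised start).

    With ``x_init`` (normalized latent scale, e.g. from
    ``guidance.make_noised_init``) the chain starts at ``start_step``
    instead of T. Returns latents on the raw scale unless
    ``denormalize=False``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if x_init is not None:
        x = np.array(x_init, dtype=float)
        start = s.T if start_step is None else start_step
    else:
        if n_cells is None:
            raise ValueError("n_cells required when x_init is not given")
        x = rng.standard_normal((n_cells, model.latent_dim))
        start = s.T
    if x.shape[1] != model.latent_dim:
        raise ValueError(f"x_init dim {x.shape[1]} != model latent_dim {model.latent_dim}")
    if not 1 <= start <= s.T:
        raise ValueError(f"start step {start} outside 1..{s.T}")
    for i in range(start, 0, -1):
        x = reverse_step(s, model, x, i, w=w, guidance=guidance, rng=rng,
                         variance_mode=variance_mode)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values in sampled latents")
    return model.denormalize(x) if denormalize else x


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_denoiser(model: DenoiserModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {"version": 1, "latent_dim": model.latent_dim, "width": model.width,
            "time_dim": model.time_dim, "seed": model.seed}
    arrays = {f"p_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_denoiser(path: str | Path) -> DenoiserModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = DenoiserModel(meta["latent_dim"], meta["width"], meta["time_dim"],
                              seed=meta["seed"])
        n = len(model.state_arrays())
        model.load_state_arrays([data[f"p_{i}"] for i in range(n)])
    return model
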