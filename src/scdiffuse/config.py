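"""Run configuration with the model's standard hyperparameters.

Defaults: T = 1000 diffusion steps, guidance weight gamma = 2, reverse
randomness w = 0.5, noised-start step t = 600, 128-D latent space, beta
endpoints (0.1, 20) under the beta/T linear schedule, 0.8/0.2 train/test
split. ``desk_scale()`` gives a reduced-cost profile (T = 200, shorter
training) for laptop-sized synthetic experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunConfig:
    # diffusion
    T: int = 1000
    beta_min: float = 0.1
    beta_max: float = 20.0
    w: float = 0.5
    variance_mode: str = "plain"
    # guidance
    gamma: float = 2.0
    t_init: int = 600
    guidance_ceiling: int | None = None  # None -> floor(T/2)
    # autoencoder
    latent_dim: int = 128
    ae_hidden: list[int] = field(default_factory=lambda: [512, 256])
    ae_epochs: int = 200
    ae_batch: int = 128
    ae_lr: float = 1e-3
    ae_latent_noise: float = 0.1
    # denoiser
    dn_width: int = 512
    dn_steps: int = 6000
    dn_batch: int = 128
    dn_lr: float = 1e-3
    # classifier
    clf_steps: int = 3000
    clf_batch: int = 128
    clf_lr: float = 1e-3
    clf_ensemble: int = 5
    # data handling
    train_fraction: float = 0.8
    # seeds
    seed_data: int = 0
    seed_training: int = 1
    seed_sampling: int = 2
    name: str = "run"

    @property
    def ceiling(self) -> int:
        return self.T // 2 if self.guidance_ceiling is None else self.guidance_ceiling

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Reduced-cost profile for synthetic-fixture experiments."""
        base = dict(T=200, t_init=120, ae_epochs=150, dn_steps=4000,
                    clf_steps=2500, name="desk")
        base.update(overrides)
        return cls(**base)

    def with_seeds(self, seed: int) -> "RunConfig":
        """Derive the three named seed streams from one master seed."""
        import dataclasses
        return dataclasses.replace(self, seed_data=seed * 3 + 0,
                                   seed_training=seed * 3 + 1,
                                   seed_sampling=seed * 3 + 2)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
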