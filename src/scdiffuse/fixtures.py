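"""Synthetic scRNA-seq fixtures with known ground truth.

Three generators cover the experimental designs the package is exercised
on: a multi-cell-type mixture (with one rare type), a two-factor
cell-type x organ design with a held-out combination, and a continuous
trajectory between two expression programs.

Counts are negative-binomial via the gamma-Poisson mixture, with a
per-cell lognormal library-size factor and a dispersion shared across
genes. Differentially expressed genes form disjoint blocks per condition
so every downstream check has unambiguous ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, RAW


@dataclass
class FixtureSpec:
    """Parameters of the count simulator.

    Defaults give 2000 cells x 200 genes over three cell types, one of
    which is rare (2.5% prevalence), with 10% of genes differentially
    expressed per type at log-fold-change 2.
    """

    n_cells: int = 2000
    n_genes: int = 200
    cell_types: list[tuple[str, float]] = field(
        default_factory=lambda: [("TypeA", 0.5), ("TypeB", 0.475), ("TypeC", 0.025)])
    nb_mean_range: tuple[float, float] = (0.1, 10.0)
    nb_dispersion: float = 2.0
    de_fraction: float = 0.1
    de_logfc: float = 2.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    seed: int = 0

    def __post_init__(self):
        props = [p for _, p in self.cell_types]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {sum(props)}, not 1")
        if min(props) <= 0:
            raise ValueError("all proportions must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        lo, hi = self.nb_mean_range
        if not (0 < lo < hi):
            raise ValueError("nb_mean_range must satisfy 0 < lo < hi")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_cells * min(props) < 1.0:
            raise ValueError(
                f"smallest proportion {min(props)} yields < 1 cell out of {self.n_cells}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        d = json.loads(Path(path).read_text())
        d["cell_types"] = [tuple(t) for t in d["cell_types"]]
        d["nb_mean_range"] = tuple(d["nb_mean_range"])
        d["library_size_lognormal"] = tuple(d["library_size_lognormal"])
        return cls(**d)


def _type_counts(n_cells: int, proportions: list[float]) -> list[int]:
    """Deterministic largest-remainder apportionment of cells to types."""
    raw = np.asarray(proportions) * n_cells
    base = np.floor(raw).astype(int)
    short = n_cells - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    if base.min() < 1:
        raise ValueError("a cell type received zero cells; increase n_cells")
    return base.tolist()


def _baseline_log_mean(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.nb_mean_range
    return rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes)


def _de_blocks(spec: FixtureSpec, n_conditions: int) -> list[np.ndarray]:
    """Disjoint index blocks of DE genes, one block per condition."""
    per = int(round(spec.de_fraction * spec.n_genes))
    if per * n_conditions > spec.n_genes:
        raise ValueError(
            f"{n_conditions} disjoint DE blocks of {per} genes exceed {spec.n_genes} genes")
    return [np.arange(k * per, (k + 1) * per) for k in range(n_conditions)]


def _signed_effect(block: np.ndarray, logfc: float, n_genes: int) -> np.ndarray:
    """Log-mean offset vector: first half of the block up, second half down."""
    eff = np.zeros(n_genes)
    half = len(block) // 2
    eff[block[:half]] = logfc
    eff[block[half:]] = -logfc
    return eff


def _sample_nb(log_mean_rows: np.ndarray, spec: FixtureSpec,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with per-cell library factors. Rows are per-cell log-means."""
    mu_sig = spec.library_size_lognormal
    lib = rng.lognormal(mu_sig[0], mu_sig[1], size=(log_mean_rows.shape[0], 1))
    mu = lib * np.exp(log_mean_rows)
    theta = spec.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam).astype(float)


def type_effects(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """Ground-truth per-type log-mean offsets (relative to the shared baseline)."""
    blocks = _de_blocks(spec, len(spec.cell_types))
    return {name: _signed_effect(blocks[k], spec.de_logfc, spec.n_genes)
            for k, (name, _) in enumerate(spec.cell_types)}


def simulate_counts(spec: FixtureSpec, label_column: str = "cell_type") -> ExpressionMatrix:
    """Multi-type NB mixture with per-type DE blocks; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    base = _baseline_log_mean(spec, rng)
    effects = type_effects(spec)
    counts = _type_counts(spec.n_cells, [p for _, p in spec.cell_types])

    rows, labels = [], []
    for (name, _), n_k in zip(spec.cell_types, counts):
        log_mu = base[None, :] + effects[name][None, :]
        rows.append(_sample_nb(np.repeat(log_mu, n_k, axis=0), spec, rng))
        labels.extend([name] * n_k)
    X = np.concatenate(rows, axis=0)
    genes = [f"gene{j}" for j in range(spec.n_genes)]
    return ExpressionMatrix(X, genes, pd.DataFrame({label_column: labels}), RAW)


def simulate_multicondition(
    spec: FixtureSpec,
    factor2: list[tuple[str, float]] | None = None,
    held_out: tuple[str, str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two-factor (cell type x organ) design with one combination held out.

    Log-means are additive in the two factors. Returns ``(train, truth)``:
    the training matrix contains every combination except ``held_out``;
    the ground-truth matrix contains only the held-out combination and is
    meant for evaluation, never for training.
    """
    if factor2 is None:
        factor2 = [("Spleen", 0.5), ("Mammary", 0.5)]
    if held_out is None:
        held_out = (spec.cell_types[-1][0], factor2[-1][0])
    type_names = [n for n, _ in spec.cell_types]
    organ_names = [n for n, _ in factor2]
    if held_out[0] not in type_names or held_out[1] not in organ_names:
        raise ValueError(f"held_out {held_out} not present in both factors")
    if len(type_names) < 2 or len(organ_names) < 2:
        raise ValueError("both factors need at least two levels")

    rng = np.random.default_rng(spec.seed)
    base = _baseline_log_mean(spec, rng)
    blocks = _de_blocks(spec, len(type_names) + len(organ_names))
    t_eff = {n: _signed_effect(blocks[k], spec.de_logfc, spec.n_genes)
             for k, n in enumerate(type_names)}
    o_eff = {n: _signed_effect(blocks[len(type_names) + k], spec.de_logfc, spec.n_genes)
             for k, n in enumerate(organ_names)}

    combos = [(t, o, pt * po) for t, pt in spec.cell_types for o, po in factor2]
    counts = _type_counts(spec.n_cells, [p for _, _, p in combos])

    train_rows, train_t, train_o = [], [], []
    truth_rows = []
    for (t, o, _), n_k in zip(combos, counts):
        log_mu = (base + t_eff[t] + o_eff[o])[None, :]
        block = _sample_nb(np.repeat(log_mu, n_k, axis=0), spec, rng)
        if (t, o) == held_out:
            truth_rows.append(block)
        else:
            train_rows.append(block)
            train_t.extend([t] * n_k)
            train_o.extend([o] * n_k)
    if not train_t:
        raise ValueError("held-out removal emptied the training data")
    for name, seen in (("cell_type", set(train_t)), ("organ", set(train_o))):
        expect = set(type_names) if name == "cell_type" else set(organ_names)
        if seen != expect:
            raise ValueError(f"holding out {held_out} emptied a level of {name}")

    genes = [f"gene{j}" for j in range(spec.n_genes)]
    train = ExpressionMatrix(
        np.concatenate(train_rows), genes,
        pd.DataFrame({"cell_type": train_t, "organ": train_o}), RAW)
    n_truth = sum(r.shape[0] for r in truth_rows)
    truth = ExpressionMatrix(
        np.concatenate(truth_rows), genes,
        pd.DataFrame({"cell_type": [held_out[0]] * n_truth,
                      "organ": [held_out[1]] * n_truth}), RAW)
    return train, truth


def simulate_trajectory(spec: FixtureSpec, n_timepoints: int = 5,
                        endpoint_logfc: float = 2.0) -> ExpressionMatrix:
    """Cells along a continuous path between two expression programs.

    Timepoint j has log-mean ``(1 - s) * log A + s * log B`` with
    ``s = j / (n_timepoints - 1)``; program B differs from A on a block of
    genes shifted by +/- ``endpoint_logfc``. Labels: ``timepoint`` ("0" ..)
    and ``s`` (the mixing weight, as a string).
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(spec.seed)
    log_a = _baseline_log_mean(spec, rng)
    block = _de_blocks(spec, 1)[0]
    log_b = log_a + _signed_effect(block, endpoint_logfc, spec.n_genes)

    counts = _type_counts(spec.n_cells, [1.0 / n_timepoints] * n_timepoints)
    rows, tp, ss = [], [], []
    for j, n_j in enumerate(counts):
        s = j / (n_timepoints - 1)
        log_mu = ((1.0 - s) * log_a + s * log_b)[None, :]
        rows.append(_sample_nb(np.repeat(log_mu, n_j, axis=0), spec, rng))
        tp.extend([str(j)] * n_j)
        ss.extend([f"{s:.6f}"] * n_j)
    genes = [f"gene{j}" for j in range(spec.n_genes)]
    return ExpressionMatrix(np.concatenate(rows), genes,
                            pd.DataFrame({"timepoint": tp, "s": ss}), RAW)
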