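"""ctPred: a four-layer MLP mapping epigenomic feature vectors to expression.

Architecture: a linear layer D -> 64 followed by ReLU and dropout, then three
identical 64 -> 64 hidden blocks (ReLU + dropout each), then an unconstrained
linear 64 -> 1 head. At the full feature width (D = 5313) this is ~0.35M
parameters. The target is the cross-gene rank-percentile expression of a cell
type; training minimizes MSE with L2 weight decay (5e-4) and dropout 0.05,
with genes split train/validation/test by chromosome to avoid leakage from
overlapping sequence windows.

The network, backpropagation and the Adam optimizer are implemented directly
on numpy arrays; inference runs with dropout disabled and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation

HIDDEN_DIM = 64
N_HIDDEN_BLOCKS = 4  # the D->64 layer plus three identical 64->64 blocks


@dataclass(frozen=True)
class CtPredConfig:
    input_dim: int
    hidden_dim: int = HIDDEN_DIM
    n_hidden_blocks: int = N_HIDDEN_BLOCKS
    dropout: float = 0.05
    weight_decay: float = 5e-4
    learning_rate: float = 1e-4
    max_epochs: int = 80
    early_stop_patience: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("dimensions must be >= 1")


@dataclass
class GeneSplit:
    """Chromosome-pure train/validation/test gene partitions."""

    train_chroms: list[str]
    val_chroms: list[str]
    test_chroms: list[str]
    train_genes: list[str]
    val_genes: list[str]
    test_genes: list[str]


def split_by_chromosome(annotation: GeneAnnotation, train_chroms, val_chroms,
                        test_chroms) -> GeneSplit:
    """Partition genes by chromosome; lists must be disjoint and cover all."""
    train_chroms = [str(c) for c in train_chroms]
    val_chroms = [str(c) for c in val_chroms]
    test_chroms = [str(c) for c in test_chroms]
    if not test_chroms:
        raise ValueError("test set required")
    sets = [set(train_chroms), set(val_chroms), set(test_chroms)]
    if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
        raise ValueError("chromosome lists overlap")
    covered = sets[0] | sets[1] | sets[2]
    present = set(annotation.table["chrom"].astype(str))
    if present - covered:
        raise ValueError(f"chromosomes not assigned to any split: {sorted(present - covered)}")
    t = annotation.table
    pick = lambda chroms: t.loc[t["chrom"].astype(str).isin(chroms), "gene_id"].tolist()
    return GeneSplit(
        train_chroms=train_chroms,
        val_chroms=val_chroms,
        test_chroms=test_chroms,
        train_genes=pick(train_chroms),
        val_genes=pick(val_chroms),
        test_genes=pick(test_chroms),
    )


def default_split_chroms(annotation: GeneAnnotation) -> tuple[list[str], list[str], list[str]]:
    """A default chromosome assignment with roughly 73/14/12% of genes.

    Chromosomes (by descending gene count) are greedily assigned to the split
    currently farthest below its target share.
    """
    counts = annotation.table.groupby(annotation.table["chrom"].astype(str)).size()
    targets = {"train": 0.735, "val": 0.142, "test": 0.123}
    assigned: dict[str, list[str]] = {k: [] for k in targets}
    filled = {k: 0 for k in targets}
    total = counts.sum()
    for chrom in counts.sort_values(ascending=False).index:
        deficit = {k: targets[k] - filled[k] / total for k in targets}
        best = max(deficit, key=deficit.get)
        assigned[best].append(chrom)
        filled[best] += counts[chrom]
    for k in targets:  # every split must be non-empty
        if not assigned[k]:
            donor = max(assigned, key=lambda q: len(assigned[q]))
            assigned[k].append(assigned[donor].pop())
    return assigned["train"], assigned["val"], assigned["test"]


@dataclass
class CtPredModel:
    """Trained MLP weights plus config and per-epoch loss history."""

    config: CtPredConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} != model input_dim {self.config.input_dim}"
            )
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return out.ravel()


def parameter_count(input_dim: int, hidden_dim: int = HIDDEN_DIM,
                    n_hidden_blocks: int = N_HIDDEN_BLOCKS) -> int:
    """Closed-form parameter count of the architecture."""
    n = input_dim * hidden_dim + hidden_dim
    n += (n_hidden_blocks - 1) * (hidden_dim * hidden_dim + hidden_dim)
    n += hidden_dim + 1
    return n


def _init_model(config: CtPredConfig, rng: np.random.Generator) -> CtPredModel:
    dims = [config.input_dim] + [config.hidden_dim] * config.n_hidden_blocks + [1]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        # He initialization for the ReLU stack
        weights.append(rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in))
        biases.append(np.zeros(d_out))
    return CtPredModel(config=config, weights=weights, biases=biases)


def _forward_train(model: CtPredModel, x: np.ndarray, rng: np.random.Generator):
    """Forward pass with inverted dropout; caches activations for backprop."""
    p = model.config.dropout
    hs, masks = [x], []
    h = x
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
        if p > 0:
            mask = (rng.random(h.shape) >= p) / (1 - p)
            h = h * mask
        else:
            mask = None
        masks.append(mask)
        hs.append(h)
    out = h @ model.weights[-1] + model.biases[-1]
    return out, hs, masks


def _backward(model: CtPredModel, out, y, hs, masks):
    """Gradients of mean squared error w.r.t. all weights and biases."""
    n = len(y)
    grad_ws = [None] * len(model.weights)
    grad_bs = [None] * len(model.biases)
    delta = 2.0 * (out - y.reshape(-1, 1)) / n
    grad_ws[-1] = hs[-1].T @ delta
    grad_bs[-1] = delta.sum(axis=0)
    upstream = delta @ model.weights[-1].T
    for layer in range(len(model.weights) - 2, -1, -1):
        h = hs[layer + 1]
        if masks[layer] is not None:
            upstream = upstream * masks[layer]
        upstream = upstream * (h > 0)
        grad_ws[layer] = hs[layer].T @ upstream
        grad_bs[layer] = upstream.sum(axis=0)
        if layer > 0:
            upstream = upstream @ model.weights[layer].T
    return grad_ws, grad_bs


def train(features: dict[str, np.ndarray], targets: pd.Series, split: GeneSplit,
          config: CtPredConfig) -> CtPredModel:
    """Train the MLP on reference features vs cross-gene percentile targets.

    Returns the checkpoint with the best validation loss; the history frame
    has per-epoch train/val MSE and a running best-validation column.
    """
    for gene in split.train_genes + split.val_genes:
        if gene not in features or gene not in targets.index:
            raise ValueError(f"gene {gene!r} lacks features or target")
    if not split.train_genes or not split.val_genes:
        raise ValueError("empty train or validation split")
    x_train = np.vstack([features[g] for g in split.train_genes])
    y_train = targets.loc[split.train_genes].to_numpy(float)
    x_val = np.vstack([features[g] for g in split.val_genes])
    y_val = targets.loc[split.val_genes].to_numpy(float)

    rng = np.random.default_rng(config.seed)
    model = _init_model(config, rng)
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_state = None
    patience_left = config.early_stop_patience
    records = []
    n = len(y_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out, hs, masks = _forward_train(model, x_train[idx], rng)
            if not np.isfinite(out).all():
                raise FloatingPointError("NaN/Inf in training forward pass")
            grad_ws, grad_bs = _backward(model, out, y_train[idx], hs, masks)
            step += 1
            corr = np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i in range(len(model.weights)):
                g = grad_ws[i] + config.weight_decay * model.weights[i]
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * g
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * g * g
                model.weights[i] -= config.learning_rate * corr * m_w[i] / (np.sqrt(v_w[i]) + eps)
                gb = grad_bs[i]
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb * gb
                model.biases[i] -= config.learning_rate * corr * m_b[i] / (np.sqrt(v_b[i]) + eps)
        train_loss = float(np.mean((model.predict(x_train) - y_train) ** 2))
        val_loss = float(np.mean((model.predict(x_val) - y_val) ** 2))
        if not np.isfinite(train_loss):
            raise FloatingPointError("NaN training loss")
        if val_loss < best_val:
            best_val = val_loss
            best_state = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
        records.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "best_val": best_val}
        )
        if patience_left <= 0:
            break
    model.weights, model.biases = best_state
    model.history = pd.DataFrame(records)
    return model


def predict(model: CtPredModel, features: dict[str, np.ndarray]) -> pd.Series | pd.DataFrame:
    """Predict expression for per-gene vectors (Series) or matrices (DataFrame).

    A 1-D entry yields one prediction per gene; a 2-D entry (individuals x D)
    yields a row of per-individual predictions.
    """
    any_matrix = any(np.asarray(v).ndim == 2 for v in features.values())
    if not any_matrix:
        return pd.Series(
            {g: float(model.predict(v)[0]) for g, v in features.items()}
        )
    rows = {g: model.predict(np.atleast_2d(v)) for g, v in features.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def eval_across_genes(pred: pd.Series, obs: pd.Series) -> float:
    """Pearson correlation between predictions and observations across genes."""
    common = pred.index.intersection(obs.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched genes")
    p, o = pred.loc[common].to_numpy(float), obs.loc[common].to_numpy(float)
    if p.std() == 0 or o.std() == 0:
        raise ValueError("zero variance in predictions or observations")
    return float(stats.pearsonr(p, o).statistic)


def eval_across_individuals(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson r and two-sided p across individuals.

    Genes with zero variance in either vector are flagged (``constant=True``)
    and carry NaN statistics; the p-value column feeds pi1 estimation.
    """
    genes = pred.index.intersection(obs.index)
    inds = pred.columns.intersection(obs.columns)
    if len(inds) < 3:
        raise ValueError("need >= 3 matched individuals")
    records = []
    for g in genes:
        x = pred.loc[g, inds].to_numpy(float)
        y = obs.loc[g, inds].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            records.append({"gene": g, "r": np.nan, "p": np.nan, "constant": True})
            continue
        res = stats.pearsonr(x, y)
        records.append(
            {"gene": g, "r": float(res.statistic), "p": float(res.pvalue), "constant": False}
        )
    return pd.DataFrame(records).set_index("gene")
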