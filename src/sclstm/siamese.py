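"""Twin-LSTM pair scorer: learn cell-cell similarity from kernel rows.

Two weight-sharing LSTM branches each consume one row of the kernel matrix
as a sequence; the head concatenates the two final hidden states and applies
dense -> sigmoid -> dense -> sigmoid, yielding a same-type probability in
[0, 1]. Training minimizes binary cross-entropy on same/different pairs so
that same-category cells score high and different-category cells score low.
Scoring every ordered pair and symmetrizing produces the learned similarity
matrix handed to agglomerative clustering.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .clustering import agglomerative_from_similarity
from .io import ValidationError
from .kernel import KernelMatrix


@dataclass
class SiameseConfig:
    hidden_units: int = 64
    # chunked: a kernel row becomes ceil(n/chunk_width) steps of width
    # chunk_width. row_as_sequence (length-n 1-dim steps) is supported but
    # needs far more optimizer updates to converge.
    embed_mode: str = "chunked"
    chunk_width: int = 16
    dense_units: int = 32
    epochs: int = 100
    batch_size: int = 16  # small batches add the gradient noise needed to escape the class-marginal BCE plateau
    learning_rate: float = 1e-2  # 1e-3 plateaus at the class-marginal BCE on realistic epoch budgets
    pairs_per_cell: int = 20
    positive_fraction: float = 0.5
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        for name in ("hidden_units", "chunk_width", "dense_units", "epochs",
                     "batch_size", "pairs_per_cell", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.embed_mode not in ("row_as_sequence", "chunked"):
            raise ValueError(f"unknown embed_mode {self.embed_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairSet:
    """Sampled (i, j, target) training pairs; target 1 = same pseudo-class."""

    pairs: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], int] = {}
        for i, j, y in self.pairs:
            if i == j:
                raise ValidationError(f"self-pair ({i}, {i})")
            key = (min(i, j), max(i, j))
            if seen.setdefault(key, y) != y:
                raise ValidationError(f"pair {key} has conflicting targets")

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.asarray(self.pairs, dtype=np.int64)
        return arr[:, 0], arr[:, 1], arr[:, 2].astype(float)


@dataclass
class LearnedSimilarity:
    """Symmetric n x n matrix of pair scores in [0, 1] with unit diagonal."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValidationError("similarity matrix must be square")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("learned similarity entries must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def derive_pseudo_labels(S: KernelMatrix, k0: int) -> np.ndarray:
    """Provisional classes from agglomerative clustering of the kernel matrix.

    Used only to construct same/different training pairs when no true labels
    are supplied, keeping the pipeline label-free end to end.
    """
    n = S.n_cells
    if not 2 <= k0 <= n - 1:
        raise ValueError(f"k0={k0} out of range [2, {n - 1}]")
    return agglomerative_from_similarity(S, k0).labels


def generate_pairs(
    labels, cfg: SiameseConfig, rng: np.random.Generator | None = None
) -> PairSet:
    """Sample ~pairs_per_cell * n training pairs from class labels.

    A positive_fraction share of the pairs is same-class; classes of size 1
    cannot supply positives and are skipped for that role. Deterministic
    given the generator state.
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 distinct classes to form negative pairs")
    eligible = classes[counts >= 2]
    if len(eligible) == 0:
        raise ValidationError("all classes are singletons; no positive pair exists")
    members = {c: np.flatnonzero(labels == c) for c in classes}

    total = cfg.pairs_per_cell * n
    n_pos = int(round(total * cfg.positive_fraction))
    n_neg = total - n_pos

    pos_pool = np.concatenate([members[c] for c in eligible])
    pairs: list[tuple[int, int, int]] = []
    for _ in range(n_pos):
        i = int(rng.choice(pos_pool))
        mates = members[labels[i]]
        j = int(rng.choice(mates[mates != i]))
        pairs.append((i, j, 1))
    for _ in range(n_neg):
        i = int(rng.integers(n))
        others = np.flatnonzero(labels != labels[i])
        j = int(rng.choice(others))
        pairs.append((i, j, 0))
    return PairSet(pairs)


def _rows_to_sequences(S_values: np.ndarray, cfg: SiameseConfig) -> np.ndarray:
    """Shape kernel rows into LSTM input sequences (n, T, D)."""
    n = S_values.shape[1]
    if cfg.embed_mode == "row_as_sequence":
        return S_values[:, :, None]
    w = cfg.chunk_width
    T = -(-n // w)
    padded = np.zeros((S_values.shape[0], T * w))
    padded[:, :n] = S_values
    return padded.reshape(S_values.shape[0], T, w)


class TrainedPairScorer:
    """Weight-sharing twin-LSTM plus dense/sigmoid head, after training."""

    def __init__(self, params: dict, cfg: SiameseConfig, n_cells: int,
                 epoch_losses: list[float] | None = None):
        self.params = params
        self.cfg = cfg
        self.n_cells = n_cells
        self.epoch_losses = epoch_losses or []

    # -- forward passes -------------------------------------------------
    def embed_rows(self, S_values: np.ndarray, batch: int = 512) -> np.ndarray:
        """Final LSTM hidden state for each kernel row: (n, hidden_units)."""
        X = _rows_to_sequences(np.asarray(S_values, dtype=float), self.cfg)
        out = []
        for start in range(0, X.shape[0], batch):
            h, _ = nn.lstm_forward(X[start : start + batch], self.params["lstm"])
            out.append(h)
        return np.vstack(out)

    def _head(self, ha: np.ndarray, hb: np.ndarray) -> np.ndarray:
        u = np.hstack([ha, hb])
        d1 = self.params["dense1"]
        d2 = self.params["dense2"]
        a1 = nn.sigmoid(u @ d1["W"] + d1["b"])
        return nn.sigmoid(a1 @ d2["W"] + d2["b"]).ravel()

    def score_pairs(self, H: np.ndarray, i_idx, j_idx) -> np.ndarray:
        """Ordered-pair scores f(i, j) from precomputed embeddings."""
        return self._head(H[np.asarray(i_idx)], H[np.asarray(j_idx)])

    def score(self, i: int, j: int, S: KernelMatrix | np.ndarray) -> float:
        vals = S.values if isinstance(S, KernelMatrix) else np.asarray(S)
        H = self.embed_rows(vals[[i, j]])  # rows embed independently
        return float(self.score_pairs(H, [0], [1])[0])


def _init_params(cfg: SiameseConfig, rng: np.random.Generator) -> dict:
    input_dim = 1 if cfg.embed_mode == "row_as_sequence" else cfg.chunk_width
    return {
        "lstm": nn.init_lstm_params(input_dim, cfg.hidden_units, rng),
        "dense1": nn.init_dense_params(2 * cfg.hidden_units, cfg.dense_units, rng),
        "dense2": nn.init_dense_params(cfg.dense_units, 1, rng),
    }


def train_siamese(
    S: KernelMatrix | np.ndarray, pairs: PairSet, cfg: SiameseConfig
) -> TrainedPairScorer:
    """Fit the pair scorer by mini-batch Adam on binary cross-entropy.

    Both branches share one set of LSTM weights, so each batch embeds only
    the unique cells it touches and gradients from the two branches
    accumulate into the shared parameters.
    """
    if len(pairs) == 0:
        raise ValidationError("empty pair set")
    S_values = S.values if isinstance(S, KernelMatrix) else np.asarray(S, dtype=float)
    n = S_values.shape[0]
    i_all, j_all, y_all = pairs.arrays()
    if i_all.max() >= n or j_all.max() >= n:
        raise ValidationError("pair index out of range for the kernel matrix")

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng)
    X_all = _rows_to_sequences(S_values, cfg)
    opt = nn.Adam(params, lr=cfg.learning_rate)
    Hh = cfg.hidden_units
    n_pairs = len(pairs)
    epoch_losses: list[float] = []

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_pairs)
        batch_losses = []
        for start in range(0, n_pairs, cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            bi, bj, by = i_all[sel], j_all[sel], y_all[sel]
            B = len(sel)
            uniq, inv = np.unique(np.concatenate([bi, bj]), return_inverse=True)
            H, cache = nn.lstm_forward(X_all[uniq], params["lstm"])
            ha, hb = H[inv[:B]], H[inv[B:]]
            u = np.hstack([ha, hb])
            d1, d2 = params["dense1"], params["dense2"]
            a1 = nn.sigmoid(u @ d1["W"] + d1["b"])
            p = nn.sigmoid(a1 @ d2["W"] + d2["b"]).ravel()
            loss = nn.bce_loss(p, by)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} "
                    f"(learning_rate={cfg.learning_rate})"
                )
            batch_losses.append(loss)

            # sigmoid + BCE collapses to (p - y) at the last pre-activation
            ds = ((p - by) / B)[:, None]
            g2 = {"W": a1.T @ ds, "b": ds.sum(axis=0)}
            da1 = ds @ d2["W"].T * a1 * (1.0 - a1)
            g1 = {"W": u.T @ da1, "b": da1.sum(axis=0)}
            du = da1 @ d1["W"].T
            dH = np.zeros_like(H)
            np.add.at(dH, inv[:B], du[:, :Hh])
            np.add.at(dH, inv[B:], du[:, Hh:])
            g_lstm = nn.lstm_backward(dH, cache, params["lstm"])
            opt.step(params, {"lstm": g_lstm, "dense1": g1, "dense2": g2})
        epoch_losses.append(float(np.mean(batch_losses)))

    return TrainedPairScorer(params, cfg, n_cells=n, epoch_losses=epoch_losses)


def score_all_pairs(
    model: TrainedPairScorer, S: KernelMatrix | np.ndarray
) -> LearnedSimilarity:
    """Score every cell pair and symmetrize: M_ij = (f(i,j) + f(j,i)) / 2.

    The diagonal is forced to 1 (a cell is always its own type).
    """
    S_values = S.values if isinstance(S, KernelMatrix) else np.asarray(S, dtype=float)
    cell_ids = list(S.cell_ids) if hasattr(S, "cell_ids") else [
        f"cell{i}" for i in range(S_values.shape[0])
    ]
    n = S_values.shape[0]
    if model.n_cells != n:
        raise ValidationError(
            f"model was trained on n={model.n_cells} cells, got n={n}"
        )
    H = model.embed_rows(S_values)
    M = np.empty((n, n))
    block = max(1, 2_000_000 // max(n, 1))  # bound the pair-batch memory
    for start in range(0, n, block):
        rows = np.arange(start, min(start + block, n))
        ii = np.repeat(rows, n)
        jj = np.tile(np.arange(n), len(rows))
        M[rows[0] : rows[-1] + 1, :] = model.score_pairs(H, ii, jj).reshape(
            len(rows), n
        )
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return LearnedSimilarity(values=np.clip(M, 0.0, 1.0), cell_ids=cell_ids)


def embed_single_branch(
    model: TrainedPairScorer, S: KernelMatrix | np.ndarray
) -> np.ndarray:
    """Per-cell embedding from one LSTM branch (the single-branch ablation)."""
    S_values = S.values if isinstance(S, KernelMatrix) else np.asarray(S, dtype=float)
    return model.embed_rows(S_values)
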