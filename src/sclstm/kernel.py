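"""Cell-cell similarity via the improved sigmoid kernel.

Pipeline: log-transform the expression matrix, take all pairwise row inner
products, min-max normalize the inner-product matrix globally, then apply
tanh element-wise. Entries of the result lie in [0, tanh(1)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ValidationError

TANH1 = float(np.tanh(1.0))


@dataclass
class KernelMatrix:
    """Symmetric n x n similarity matrix with entries in [0, tanh(1)]."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValidationError("kernel matrix must be square")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite kernel entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("kernel matrix not symmetric")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def rescaled(self) -> np.ndarray:
        """Values mapped from [0, tanh(1)] onto [0, 1]."""
        return self.values / TANH1


def log_transform(A: np.ndarray | ExpressionMatrix) -> np.ndarray:
    """Element-wise natural log of (a_ij + 1)."""
    vals = A.values if isinstance(A, ExpressionMatrix) else np.asarray(A, dtype=float)
    if np.any(vals < 0):
        raise ValidationError("log transform requires non-negative entries")
    return np.log1p(vals)


def row_inner_products(L: np.ndarray) -> np.ndarray:
    """Gram matrix of the rows: I = L L^T."""
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValidationError("non-finite entries")
    I = L @ L.T
    return (I + I.T) / 2.0  # exact symmetry despite float round-off


def minmax_update(I: np.ndarray) -> np.ndarray:
    """Global min-max normalization onto [0, 1].

    Degenerate case (constant matrix, I_max == I_min): returns all zeros so
    that no-signal input produces no similarity, keeping downstream total.
    """
    I = np.asarray(I, dtype=float)
    lo, hi = I.min(), I.max()
    if hi == lo:
        return np.zeros_like(I)
    return (I - lo) / (hi - lo)


def sigmoid_kernel(I: np.ndarray) -> np.ndarray:
    """Element-wise (e^x - e^-x)/(e^x + e^-x), i.e. tanh."""
    return np.tanh(np.asarray(I, dtype=float))


def kernel_embedding(A: ExpressionMatrix) -> KernelMatrix:
    """Full deterministic kernel pipeline from an expression matrix."""
    L = log_transform(A)
    I = row_inner_products(L)
    S = sigmoid_kernel(minmax_update(I))
    return KernelMatrix(values=S, cell_ids=list(A.cell_ids))
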