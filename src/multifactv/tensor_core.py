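"""Dense third-order tensor container and the linear-algebra primitives.

Conventions
-----------
A tensor ``A`` has shape ``(n1, n2, n3)`` with axes (entity1, entity2,
time).  The mode-``p`` unfolding ``A^(p)`` keeps mode ``p`` as rows and
flattens the remaining two modes into columns with the *lower-numbered
retained mode varying fastest*:

* mode 1: column ``j`` holds ``(s, t)`` with ``j = s + t * n2`` (0-based),
* mode 2: column ``j`` holds ``(r, t)`` with ``j = r + t * n1``,
* mode 3: column ``j`` holds ``(r, s)`` with ``j = r + s * n1``.

Under this ordering the rank-K identity ``A^(1) = U (W kr V)^T`` holds,
where ``kr`` is the Khatri-Rao (column-wise Kronecker) product, and
likewise ``A^(2) = V (W kr U)^T`` and ``A^(3) = W (V kr U)^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class InteractionTensor:
    """A fully dense, labeled entity1 x entity2 x time tensor.

    Entries may be negative; the factorization never assumes
    nonnegativity of the data.  The third axis must be in chronological
    order — the total-variation penalty is meaningless otherwise.
    """

    values: np.ndarray
    axis_labels: tuple[list[str], list[str], list[str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-way array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite entries; resolve missing values first")
        if self.axis_labels is None:
            self.axis_labels = tuple(  # type: ignore[assignment]
                [str(i + 1) for i in range(n)] for n in self.values.shape
            )
        self.axis_labels = tuple(list(map(str, ax)) for ax in self.axis_labels)  # type: ignore[assignment]
        for i, ax in enumerate(self.axis_labels):
            if len(ax) != self.values.shape[i]:
                raise ValueError(
                    f"axis {i + 1} has {len(ax)} labels but dimension {self.values.shape[i]}"
                )
            if len(set(ax)) != len(ax):
                raise ValueError(f"axis {i + 1} labels are not unique")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def unfold(self, mode: int) -> np.ndarray:
        return unfold(self.values, mode)


def unfold(tensor: InteractionTensor | np.ndarray, mode: int) -> np.ndarray:
    """Mode-``p`` matricization, ``p`` in {1, 2, 3} (1-based).

    Returns an ``n_p x (prod of other dims)`` matrix under the column
    ordering documented in the module docstring.
    """
    a = tensor.values if isinstance(tensor, InteractionTensor) else np.asarray(tensor, float)
    if a.ndim != 3:
        raise ValueError("unfold expects a third-order tensor")
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    # Fortran-order flatten of the non-kept axes keeps the earlier axis fastest.
    return np.reshape(np.moveaxis(a, mode - 1, 0), (a.shape[mode - 1], -1), order="F")


def fold(matrix: np.ndarray, mode: int, dims: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the ``dims`` tensor from ``A^(mode)``."""
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    matrix = np.asarray(matrix, float)
    rest = [dims[i] for i in range(3) if i != mode - 1]
    a = np.reshape(matrix, (dims[mode - 1], *rest), order="F")
    return np.moveaxis(a, 0, mode - 1)


def khatri_rao(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of two matrices with K columns each.

    Column ``k`` of the result is ``kron(x[:, k], y[:, k])``, so the
    ``y`` index varies fastest — consistent with :func:`unfold`.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"column-count mismatch: {x.shape[1]} vs {y.shape[1]}"
        )
    return scipy.linalg.khatri_rao(x, y)


def soft_threshold(m: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise shrinkage operator ``m -> sign(m) * max(|m| - tau, 0)``.

    The proximal map of ``tau * ||.||_1``; applied to ``B W + Q/rho``
    in the ADMM update of the time factor.
    """
    if tau < 0:
        raise ValueError(f"shrinkage threshold must be nonnegative, got {tau}")
    m = np.asarray(m, float)
    return np.sign(m) * np.maximum(np.abs(m) - tau, 0.0)


def difference_matrix(n3: int) -> np.ndarray:
    """First-difference operator B of shape ``(n3 - 1, n3)``.

    Row ``i`` has ``+1`` at column ``i`` and ``-1`` at column ``i + 1``,
    so ``B @ w`` is the vector of adjacent differences ``w_i - w_{i+1}``
    and ``||B w||_1`` is the total variation of the time profile ``w``.
    """
    if n3 < 2:
        raise ValueError(f"total variation needs at least 2 time points, got n3={n3}")
    b = np.zeros((n3 - 1, n3))
    idx = np.arange(n3 - 1)
    b[idx, idx] = 1.0
    b[idx, idx + 1] = -1.0
    return b
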