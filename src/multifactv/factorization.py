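"""Alternating least squares with an ADMM inner solver for the time factor.

The model approximates a tensor ``A`` (n1 x n2 x n3) by a sum of K
rank-1 components ``u_k o v_k o w_k`` and penalizes the total variation
of each time profile:

    min_{U,V,W}  ||A - sum_k u_k o v_k o w_k||_F^2
                 + alpha * sum_k ||B w_k||_1
    s.t.         W >= 0,  1^T w_k = 1  for every k,

where ``B`` is the first-difference operator.  ``U`` and ``V`` are
unconstrained in sign (the data may be negative); all scale and sign
indeterminacy of the CP model is carried by them, while each time
profile lives on the probability simplex.

With the other two factors fixed, ``U`` and ``V`` have closed-form
least-squares updates.  The W subproblem

    min_W ||A^(3) - W F||_F^2 + alpha * sum_k ||B w_k||_1,
    F = (V kr U)^T,

is solved by ADMM with splitting ``P = B W`` and scaled dual ``Q``:

    vec(W) <- (F F^T kron 2 I_n3 + rho I_K kron B^T B)^{-1}
              vec(rho B^T (P - Q/rho) + 2 A^(3) F^T)
    P      <- shrink_{alpha/rho}(B W + Q/rho)
    Q      <- Q + rho (B W - P).

After the inner loop, W is projected onto its constraint set (negative
entries clipped, columns L1-normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .tensor_core import (
    InteractionTensor,
    difference_matrix,
    khatri_rao,
    soft_threshold,
    unfold,
)

_COND_LIMIT = 1e12
_RIDGE = 1e-10


@dataclass
class Hyperparameters:
    """Model and solver settings.

    Parameters
    ----------
    K : number of modules (rank of the decomposition).
    alpha : weight of the total-variation penalty on time profiles.
        Larger values push profiles toward piecewise-constant shapes;
        10 is a robust default for the benchmarks this package targets.
    rho : ADMM penalty parameter (any positive value; default 1).
    tau1, tau2, tau3 : extraction thresholds in [0, 1] for the gene,
        condition and time axes respectively.
    outer_tol : stop the alternating loop when the summed squared
        change of U, V and W falls to this value (default 0.001).
    outer_max_iter : hard cap on alternating iterations.
    inner_tol, inner_max_iter : ADMM stopping rule — iterate until both
        the W change and the primal residual ||BW - P|| fall below
        inner_tol, or inner_max_iter is reached.
    seed : RNG seed controlling every random draw in :func:`fit`.
    """

    K: int
    alpha: float = 10.0
    rho: float = 1.0
    tau1: float = 1.0
    tau2: float = 1.0
    tau3: float = 0.75
    outer_tol: float = 1e-3
    outer_max_iter: int = 100
    inner_tol: float = 1e-6
    inner_max_iter: int = 200
    seed: int | None = None

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        for name in ("tau1", "tau2", "tau3"):
            tau = getattr(self, name)
            if not 0.0 <= tau <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {tau}")
        if self.outer_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.outer_max_iter < 1 or self.inner_max_iter < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class FactorSet:
    """The three factor matrices plus the ADMM state of the W solver.

    U : (n1, K) entity1 (gene) loadings, unconstrained sign.
    V : (n2, K) entity2 (condition) loadings, unconstrained sign.
    W : (n3, K) time profiles; after each completed update every column
        is nonnegative and sums to one.
    P : (n3-1, K) ADMM split variable approximating B W.
    Q : (n3-1, K) scaled dual variable.
    """

    U: np.ndarray
    V: np.ndarray
    W: np.ndarray
    P: np.ndarray | None = None
    Q: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.U.shape[1]

    def copy(self) -> "FactorSet":
        return FactorSet(
            self.U.copy(),
            self.V.copy(),
            self.W.copy(),
            None if self.P is None else self.P.copy(),
            None if self.Q is None else self.Q.copy(),
        )


@dataclass
class FitResult:
    factors: FactorSet
    objective_trace: list[float]
    n_outer_iterations: int
    converged: bool
    # squared Frobenius residual recorded after each U, V and W update
    # (three values per outer iteration) when diagnostics are requested
    residual_trace: list[float] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _gram(x: np.ndarray) -> np.ndarray:
    return x.T @ x


def _solve_ls_factor(a_unf: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Least-squares factor update X = A^(p) F^T (F F^T)^{-1}, F = (left kr right)^T.

    F F^T is the Hadamard product of the two small Grams, so the only
    large operation is the matricized-tensor-times-Khatri-Rao product.
    Near-singular Grams (collinear factor columns) get a tiny ridge.
    """
    if left.shape[1] != right.shape[1]:
        raise ValueError("factor column counts disagree")
    if a_unf.shape[1] != left.shape[0] * right.shape[0]:
        raise ValueError(
            f"unfolding has {a_unf.shape[1]} columns, factors imply "
            f"{left.shape[0] * right.shape[0]}"
        )
    z = a_unf @ khatri_rao(left, right)  # A^(p) F^T, the MTTKRP
    g = _gram(left) * _gram(right)  # F F^T
    if np.linalg.cond(g) > _COND_LIMIT:
        warnings.warn(
            "near-collinear factor columns; regularizing the normal equations",
            RuntimeWarning,
            stacklevel=3,
        )
        g = g + _RIDGE * np.eye(g.shape[0])
    try:
        return scipy.linalg.solve(g, z.T, assume_a="pos").T
    except scipy.linalg.LinAlgError:
        warnings.warn("singular factor Gram; falling back to pseudoinverse", RuntimeWarning)
        return z @ np.linalg.pinv(g)


def solve_gene_factor(a1: np.ndarray, V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Closed-form U update: ``U = A^(1) F^T (F F^T)^{-1}`` with ``F = (W kr V)^T``."""
    return _solve_ls_factor(a1, W, V)


def solve_condition_factor(a2: np.ndarray, U: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Closed-form V update: ``V = A^(2) F^T (F F^T)^{-1}`` with ``F = (W kr U)^T``."""
    return _solve_ls_factor(a2, W, U)


def _project_simplex_columns(W: np.ndarray) -> np.ndarray:
    """Clip negatives and L1-normalize each column; uniform reset for zero columns."""
    W = np.maximum(W, 0.0)
    sums = W.sum(axis=0)
    dead = sums <= 0.0
    if np.any(dead):
        warnings.warn(
            f"time-factor column(s) {np.nonzero(dead)[0].tolist()} collapsed to zero; "
            "reset to the uniform profile",
            RuntimeWarning,
            stacklevel=3,
        )
        W[:, dead] = 1.0 / W.shape[0]
        sums = W.sum(axis=0)
    return W / sums


def solve_time_factor_admm(
    a3: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    alpha: float,
    rho: float,
    P0: np.ndarray | None = None,
    Q0: np.ndarray | None = None,
    inner_tol: float = 1e-6,
    inner_max_iter: int = 200,
    project: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """ADMM solver for the TV-regularized W subproblem.

    Returns ``(W, P, Q, n_inner)``.  With ``project=True`` (the
    default), the returned W is clipped to be nonnegative and each
    column normalized to unit sum; set ``project=False`` to inspect the
    raw ADMM fixed point.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    K = U.shape[1]
    n3 = a3.shape[0]
    B = difference_matrix(n3)
    BtB = B.T @ B
    g = _gram(U) * _gram(V)  # F F^T with F = (V kr U)^T
    system = np.kron(g, 2.0 * np.eye(n3)) + rho * np.kron(np.eye(K), BtB)
    if not np.all(np.isfinite(system)):
        raise FloatingPointError("non-finite values in the W-update system matrix")
    try:
        lu = scipy.linalg.lu_factor(system)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular W-update system: a factor column is degenerate"
        ) from exc
    a3f = a3 @ khatri_rao(V, U)  # A^(3) F^T
    P = np.zeros((n3 - 1, K)) if P0 is None else np.array(P0, float)
    Q = np.zeros((n3 - 1, K)) if Q0 is None else np.array(Q0, float)
    W = np.zeros((n3, K))
    n_inner = 0
    for n_inner in range(1, inner_max_iter + 1):
        rhs = rho * (B.T @ (P - Q / rho)) + 2.0 * a3f
        # vec() stacks columns, so the Kronecker system acts column-block-wise
        W_new = scipy.linalg.lu_solve(lu, rhs.reshape(-1, order="F")).reshape(
            (n3, K), order="F"
        )
        BW = B @ W_new
        P = soft_threshold(BW + Q / rho, alpha / rho)
        Q = Q + rho * (BW - P)
        delta = np.linalg.norm(W_new - W)
        primal = np.linalg.norm(BW - P)
        W = W_new
        if max(delta, primal) <= inner_tol:
            break
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("ADMM produced non-finite time factors")
    if project:
        W = _project_simplex_columns(W)
    return W, P, Q, n_inner


def objective(
    tensor: InteractionTensor | np.ndarray, factors: FactorSet, alpha: float
) -> float:
    """Value of the penalized objective at the given factors."""
    a = tensor.values if isinstance(tensor, InteractionTensor) else np.asarray(tensor, float)
    U, V, W = factors.U, factors.V, factors.W
    if a.shape != (U.shape[0], V.shape[0], W.shape[0]):
        raise ValueError(
            f"tensor dims {a.shape} do not match factor dims "
            f"({U.shape[0]}, {V.shape[0]}, {W.shape[0]})"
        )
    if not (U.shape[1] == V.shape[1] == W.shape[1]):
        raise ValueError("factor matrices have different column counts")
    a1 = unfold(a, 1)
    resid = a1 - U @ khatri_rao(W, V).T
    tv = np.abs(difference_matrix(W.shape[0]) @ W).sum()
    return float(np.sum(resid * resid) + alpha * tv)


def _sq_residual(norm_a_sq: float, z: np.ndarray, x: np.ndarray, g: np.ndarray) -> float:
    """||A - low-rank||_F^2 from cached pieces: z = A^(p) F^T, g = F F^T."""
    return float(norm_a_sq - 2.0 * np.sum(z * x) + np.sum((x.T @ x) * g))


def _init_factors(
    dims: tuple[int, int, int], K: int, norm_a: float, rng: np.random.Generator
) -> FactorSet:
    n1, n2, n3 = dims
    scale = norm_a / (K * np.sqrt(n1 * n2)) if norm_a > 0 else 1.0
    U = rng.standard_normal((n1, K)) * scale
    V = rng.standard_normal((n2, K)) * scale
    W = rng.uniform(size=(n3, K))
    W /= W.sum(axis=0)
    return FactorSet(U, V, W)


def fit(
    tensor: InteractionTensor | np.ndarray,
    hp: Hyperparameters,
    track_residuals: bool = False,
    callback=None,
) -> FitResult:
    """Run the full alternating optimization from a random start.

    One outer iteration updates, in order, U (closed form, using the
    previous V and W), V (closed form, using the *fresh* U and the
    previous W), then W via ADMM restarted from random P, Q.  The loop
    stops when ``||dU||^2 + ||dV||^2 + ||dW||^2 <= outer_tol``.

    Results are bitwise-reproducible for a fixed ``hp.seed``.  An
    optional ``callback(t, factors)`` is invoked after every completed
    outer iteration (diagnostics, snapshotting).
    """
    hp.validate()
    a = tensor.values if isinstance(tensor, InteractionTensor) else np.asarray(tensor, float)
    if a.ndim != 3 or a.shape[2] < 2:
        raise ValueError("fit needs a third-order tensor with at least 2 time points")
    rng = np.random.default_rng(hp.seed)
    n1, n2, n3 = a.shape
    a1, a2, a3 = unfold(a, 1), unfold(a, 2), unfold(a, 3)
    norm_a_sq = float(np.sum(a * a))
    B = difference_matrix(n3)

    factors = _init_factors(a.shape, hp.K, np.sqrt(norm_a_sq), rng)
    trace: list[float] = []
    residuals: list[float] = []
    converged = False
    t = 0
    for t in range(1, hp.outer_max_iter + 1):
        U_prev, V_prev, W_prev = factors.U, factors.V, factors.W
        U = solve_gene_factor(a1, V_prev, W_prev)
        V = solve_condition_factor(a2, U, W_prev)
        P0 = rng.standard_normal((n3 - 1, hp.K))
        Q0 = rng.standard_normal((n3 - 1, hp.K))
        W, P, Q, _ = solve_time_factor_admm(
            a3, U, V, hp.alpha, hp.rho, P0, Q0, hp.inner_tol, hp.inner_max_iter
        )
        factors = FactorSet(U, V, W, P, Q)
        if track_residuals:
            residuals.append(
                _sq_residual(norm_a_sq, a1 @ khatri_rao(W_prev, V_prev), U,
                             _gram(W_prev) * _gram(V_prev))
            )
            residuals.append(
                _sq_residual(norm_a_sq, a2 @ khatri_rao(W_prev, U), V,
                             _gram(W_prev) * _gram(U))
            )
            residuals.append(
                _sq_residual(norm_a_sq, a3 @ khatri_rao(V, U), W, _gram(V) * _gram(U))
            )
        # objective from cached Grams: residual + TV penalty
        sq_resid = _sq_residual(norm_a_sq, a3 @ khatri_rao(V, U), W, _gram(V) * _gram(U))
        trace.append(max(sq_resid, 0.0) + hp.alpha * float(np.abs(B @ W).sum()))
        if callback is not None:
            callback(t, factors)
        delta = (
            float(np.sum((U - U_prev) ** 2))
            + float(np.sum((V - V_prev) ** 2))
            + float(np.sum((W - W_prev) ** 2))
        )
        if delta <= hp.outer_tol:
            converged = True
            break
    return FitResult(factors, trace, t, converged, residuals)


def fit_restarts(
    tensor: InteractionTensor | np.ndarray,
    hp: Hyperparameters,
    n_restarts: int = 5,
) -> FitResult:
    """Run :func:`fit` from ``n_restarts`` random starts; keep the best objective.

    Restart seeds are derived from ``hp.seed`` via a seed sequence, so
    the whole procedure is reproducible from the single seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = np.random.SeedSequence(hp.seed).generate_state(n_restarts) % (2**31)
    best: FitResult | None = None
    for s in seeds:
        hp_s = Hyperparameters(**{**hp.__dict__, "seed": int(s)})
        res = fit(tensor, hp_s)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best
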