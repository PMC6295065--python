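"""Iteratively re-weighted l1-norm graph label propagation.

The score matrix ``Q`` for one space (miRNA or disease) minimises

    sum_{i,j} W_ij ||q^i - q^j||_2  +  Tr (Q - A)^T U (Q - A)

where ``W`` is the space's similarity matrix, ``A`` the known 0/1
associations, ``q^i`` the i-th row of ``Q`` (one entity's score profile) and
``U`` a diagonal anchor matrix pulling scores towards the observations.  The
first term is an l1 norm over edge-wise profile distances, so the objective
is convex but non-smooth; it is solved by iterating

    W~_ij = W_ij / (2 ||q^i - q^j||_2)        (re-weighted graph)
    Q     = (L~ + U)^{-1} U A                 (Laplacian linear solve)

which is a majorise-minimise scheme: each re-weighted quadratic upper-bounds
the l1 objective and touches it at the current iterate, so the objective is
non-increasing and converges to the global optimum.  Predictions fuse the
miRNA-space and disease-space solutions as ``(Q_m + Q_d^T) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist

__all__ = [
    "SolverConfig",
    "SolverState",
    "check_association",
    "reweight",
    "objective",
    "solve_space",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Solver parameters.

    anchor_weight
        Uniform diagonal of the anchor matrix U; larger values tie the
        solution more tightly to the observed associations.  The default of
        2.0 makes the exact majorise-minimise iteration used here coincide
        with the conventional re-weighted update ``(L~ + U)^{-1} U A`` taken
        at a unit anchor (the two operators differ only by a factor of two
        on U).
    epsilon
        Floor on the profile distance in the re-weighting step, guarding the
        division when two score profiles coincide.
    tol
        Relative-objective-change convergence threshold.
    max_iter
        Iteration cap.
    seed
        Only consumed by randomized fixture generation; the solver itself is
        deterministic.
    """

    anchor_weight: float = 2.0
    epsilon: float = 1e-8
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anchor_weight <= 0:
            raise ValueError("anchor_weight must be positive")
        if self.epsilon <= 0 or self.tol <= 0:
            raise ValueError("epsilon and tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SolverState:
    """Snapshot of one solver iteration.

    The dense matrices (re-weighted graph, degree, Laplacian, anchor) are
    retained only when ``solve_space`` is called with ``trace_matrices=True``;
    the scalar fields are always populated.
    """

    iteration: int
    objective: float
    objective_vector_norm: float
    W_tilde: np.ndarray | None = field(default=None, repr=False)
    D_tilde: np.ndarray | None = field(default=None, repr=False)
    L_tilde: np.ndarray | None = field(default=None, repr=False)
    U: np.ndarray | None = field(default=None, repr=False)


def check_association(a: pd.DataFrame) -> None:
    """Validate an association matrix: binary entries, unique labels."""
    v = a.to_numpy()
    bad = ~np.isin(v, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary association value {v[i, j]!r} at "
            f"({a.index[i]!r}, {a.columns[j]!r})"
        )
    if a.index.has_duplicates or a.columns.has_duplicates:
        raise ValueError("association matrix labels must be unique per axis")


def reweight(w: np.ndarray, q: np.ndarray, epsilon: float) -> np.ndarray:
    """Re-weighted graph W~_ij = W_ij / (2 max(||q^i - q^j||_2, epsilon)).

    The diagonal is zeroed: self-edges cancel in the Laplacian, and leaving
    them out keeps the distance floor from inflating node degrees.
    """
    w = np.asarray(w, dtype=float)
    q = np.asarray(q, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"W must be square, got shape {w.shape}")
    if q.shape[0] != w.shape[0]:
        raise ValueError(
            f"Q has {q.shape[0]} rows but W is {w.shape[0]}x{w.shape[1]}"
        )
    dist = cdist(q, q)
    np.maximum(dist, epsilon, out=dist)
    wt = w / (2.0 * dist)
    np.fill_diagonal(wt, 0.0)
    return wt


def objective(
    w: np.ndarray, q: np.ndarray, a: np.ndarray, u: np.ndarray
) -> tuple[float, float]:
    """Evaluate the l1-graph objective at Q.

    Returns ``(total, smoothness)`` where ``smoothness`` is the l1 norm of
    the edge-distance vector (sum_ij W_ij ||q^i - q^j||_2) and ``total`` adds
    the anchored fidelity term sum_i U_ii ||q^i - a^i||_2^2.
    """
    w = np.asarray(w, dtype=float)
    q = np.asarray(q, dtype=float)
    a = np.asarray(a, dtype=float)
    u = np.asarray(u, dtype=float)
    dist = cdist(q, q)
    smooth = float((w * dist).sum())
    fidelity = float((u * ((q - a) ** 2).sum(axis=1)).sum())
    return smooth + fidelity, smooth


def solve_space(
    w: pd.DataFrame,
    a_space: np.ndarray | pd.DataFrame,
    config: SolverConfig | None = None,
    trace_matrices: bool = False,
) -> tuple[pd.DataFrame, list[SolverState]]:
    """Solve one space's objective by iterated re-weighted Laplacian solves.

    Starting from ``Q = A``, each iteration rebuilds the re-weighted graph
    from the current scores and solves the symmetric positive-definite system
    ``(L~ + U) Q = U A``.  Iteration stops when the relative change of the
    objective drops below ``config.tol`` or after ``config.max_iter`` rounds.

    Returns the final scores (labeled like ``w`` rows x ``a_space`` columns)
    and the per-iteration state trace.
    """
    config = config or SolverConfig()
    w_arr = w.to_numpy(dtype=float) if isinstance(w, pd.DataFrame) else np.asarray(w, float)
    if isinstance(a_space, pd.DataFrame):
        a_arr = a_space.to_numpy(dtype=float)
        col_labels = list(a_space.columns)
    else:
        a_arr = np.asarray(a_space, dtype=float)
        col_labels = list(range(a_arr.shape[1]))
    if w_arr.shape[0] != a_arr.shape[0]:
        raise ValueError(
            f"similarity is {w_arr.shape[0]}x{w_arr.shape[1]} but the "
            f"association block has {a_arr.shape[0]} rows"
        )
    k = w_arr.shape[0]
    u_diag = np.full(k, config.anchor_weight)
    ua = u_diag[:, None] * a_arr

    q = a_arr.copy()
    prev_obj, _ = objective(w_arr, q, a_arr, u_diag)
    states: list[SolverState] = []
    for it in range(1, config.max_iter + 1):
        wt = reweight(w_arr, q, config.epsilon)
        d_diag = wt.sum(axis=1)
        lap = np.diag(d_diag) - wt
        # Exact majorise-minimise step: the gradient of the re-weighted
        # quadratic sum_ij W~_ij ||q^i - q^j||^2 is 4 L~ Q and the fidelity
        # gradient is 2 U (Q - A), so stationarity gives (2 L~ + U) Q = U A.
        if not wt.any():
            # zero graph: the system is diagonal and the minimiser is A itself
            q = a_arr.copy()
        else:
            try:
                q = scipy.linalg.solve(
                    2.0 * lap + np.diag(u_diag), ua, assume_a="pos"
                )
            except scipy.linalg.LinAlgError as exc:  # pragma: no cover - U > 0 guards this
                raise RuntimeError(f"singular system at iteration {it}: {exc}") from exc
        obj, smooth = objective(w_arr, q, a_arr, u_diag)
        state = SolverState(iteration=it, objective=obj, objective_vector_norm=smooth)
        if trace_matrices:
            state.W_tilde = wt
            state.D_tilde = np.diag(d_diag)
            state.L_tilde = lap
            state.U = np.diag(u_diag)
        states.append(state)
        rel = abs(prev_obj - obj) / max(abs(prev_obj), np.finfo(float).tiny)
        logger.debug("iteration %d objective %.10g rel-change %.3g", it, obj, rel)
        if rel < config.tol:
            break
        prev_obj = obj
    index = list(w.index) if isinstance(w, pd.DataFrame) else list(range(k))
    return pd.DataFrame(q, index=index, columns=col_labels), states


def _require_labels(have: pd.Index, want: list[str], what: str) -> None:
    missing = [x for x in want if x not in have]
    if missing:
        raise KeyError(f"{what} missing entities: {missing}")


def predict(
    w_m: pd.DataFrame,
    w_d: pd.DataFrame,
    a: pd.DataFrame,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Fused association scores from the miRNA-space and disease-space solves.

    ``Q_m`` propagates labels over the miRNA similarity graph, ``Q_d`` over
    the disease graph (on the transposed associations); the prediction is
    their average ``(Q_m + Q_d^T) / 2``, labeled like ``a``.
    """
    config = config or SolverConfig()
    check_association(a)
    _require_labels(w_m.index, list(a.index), "miRNA similarity matrix")
    _require_labels(w_d.index, list(a.columns), "disease similarity matrix")
    w_m = w_m.loc[a.index, a.index]
    w_d = w_d.loc[a.columns, a.columns]
    q_m, _ = solve_space(w_m, a, config)
    q_d, _ = solve_space(w_d, a.T, config)
    return (q_m + q_d.T) / 2.0
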