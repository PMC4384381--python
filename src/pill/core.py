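"""Missing-label estimation and the graph-regularised quadratic solver.

Given n proteins with a (possibly incomplete) binary label matrix Y, the
method first estimates a likelihood for every unknown entry of each labeled
protein from the known labels and the row-normalised correlation matrix C_m:

    y~_ik = 1                  if y_ik = 1
          = y_i^T C_m(., k)    if y_ik = 0,

then finds the score matrix F minimising

    Psi(F) = tr((F - Y~)^T U (F - Y~)) + lambda tr(F^T (I - W)^T (I - W) F),

where U is the diagonal indicator of labeled proteins and W the
row-normalised protein interaction weights (the smoothness term encodes
guilt by association: interacting proteins should receive similar scores).
Psi is an unconstrained convex quadratic; setting its gradient to zero gives
the normal equations

    (U + lambda (I - W)^T (I - W)) F = U Y~,

which are solved exactly by sparse factorisation (conjugate gradients per
label column for very large n).  No true-path post-processing is applied to
the returned scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse import csgraph

from .ontology import AnnotationMatrix, LabelHierarchy, OntologyError
from .similarity import CorrelationMatrix, correlation_matrix

__all__ = [
    "NetworkWeights",
    "PredictionMatrix",
    "SolverError",
    "build_weights",
    "estimate_missing",
    "solve",
    "objective_value",
    "run_variant",
    "VARIANTS",
]

logger = logging.getLogger(__name__)

VARIANTS = ("pill", "pill_jcd", "pill_hsim", "pill_lin", "pill_fc", "pill_gba", "naive")

#: above this many proteins the solver switches from direct factorisation to
#: per-column conjugate gradients.
DIRECT_SOLVER_MAX_N = 20_000

SOLVER_TOL = 1e-10


class SolverError(RuntimeError):
    """Degenerate linear system (no labeled protein reaches a component)."""


@dataclass
class NetworkWeights:
    """Row-normalised protein interaction weights (rows sum to 1 or 0)."""

    proteins: list[str]
    W: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.proteins)

    def isolated(self) -> np.ndarray:
        """Boolean mask of proteins with no interactions (all-zero rows)."""
        return np.asarray(self.W.sum(axis=1)).ravel() == 0


@dataclass
class PredictionMatrix:
    """Solver output: scores F, the estimated prior Y~, and run metadata."""

    proteins: list[str]
    labels: list[str]
    F: np.ndarray
    tilde_Y: np.ndarray
    lam: float
    labeled: np.ndarray  # boolean mask, U's diagonal
    residual: float = 0.0
    variant: str = "pill"


def build_weights(
    edges: list[tuple[str, str, float]], proteins: list[str]
) -> NetworkWeights:
    """Symmetrise (by max), zero the diagonal and row-normalise edge weights.

    Proteins absent from the edge list keep all-zero rows; their count is
    available via :meth:`NetworkWeights.isolated`.
    """
    index = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for a, b, w in edges:
        if w < 0:
            raise ValueError(f"negative edge weight: ({a}, {b}, {w})")
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"edge endpoint not in protein list: {missing!r}")
        if a == b:
            continue
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [float(w), float(w)]
    # duplicate (a, b) entries collapse to the max weight
    A = _symmetric_max(rows, cols, vals, n)
    row_sums = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    W = sp.diags(inv) @ A
    return NetworkWeights(list(proteins), W.tocsr())


def _symmetric_max(rows, cols, vals, n) -> sp.csr_matrix:
    best: dict[tuple[int, int], float] = {}
    for r, c, v in zip(rows, cols, vals):
        key = (r, c)
        if v > best.get(key, -1.0):
            best[key] = v
    if not best:
        return sp.csr_matrix((n, n))
    r, c = zip(*best.keys())
    return sp.coo_matrix((list(best.values()), (r, c)), shape=(n, n)).tocsr()


def estimate_missing(
    Y: AnnotationMatrix, Cm: CorrelationMatrix, labeled: np.ndarray
) -> np.ndarray:
    """Estimate unknown-entry likelihoods Y~ for the labeled proteins.

    *labeled* is a boolean mask over proteins (the diagonal of U).  For a
    labeled protein, known entries stay 1 and unknown entries get
    y_i^T C_m(., k), clipped to [0, 1].  Unlabeled proteins have nothing to
    propagate from and get all-zero rows (the empirical loss masks them out).
    """
    labeled = np.asarray(labeled, dtype=bool)
    if labeled.shape != (Y.n,):
        raise ValueError(f"labeled mask has shape {labeled.shape}, expected ({Y.n},)")
    if list(Y.labels) != list(Cm.labels):
        raise ValueError("annotation matrix and correlation matrix label order differ")
    Yf = Y.Y.astype(float)
    tilde = Yf @ Cm.Cm
    np.clip(tilde, 0.0, 1.0, out=tilde)
    tilde[Yf == 1.0] = 1.0
    tilde[~labeled, :] = 0.0
    return tilde


def _smoothness_operator(W: sp.csr_matrix) -> sp.csr_matrix:
    n = W.shape[0]
    IW = sp.identity(n, format="csr") - W
    return (IW.T @ IW).tocsr()


def _check_solvable(W: sp.csr_matrix, labeled: np.ndarray) -> None:
    """The system is singular iff some row-stochastic connected component of
    the interaction graph contains no labeled protein (constant vectors on it
    lie in the kernel of both U and I - W)."""
    n = W.shape[0]
    sym = W + W.T
    n_comp, comp = csgraph.connected_components(sym, directed=False)
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if labeled[members].any():
            continue
        if np.allclose(row_sums[members], 1.0):
            raise SolverError(
                f"singular system: network component of size {len(members)} "
                f"(e.g. protein index {members[0]}) contains no labeled protein"
            )


def solve(
    tilde_Y: np.ndarray,
    W: NetworkWeights,
    lam: float,
    labeled: np.ndarray,
    tol: float = SOLVER_TOL,
) -> tuple[np.ndarray, float]:
    """Minimise the combined objective; returns (F, relative residual).

    Solves (U + lambda (I - W)^T (I - W)) F = U Y~ exactly via sparse LU, or
    by conjugate gradients per label column when n exceeds
    ``DIRECT_SOLVER_MAX_N``.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    labeled = np.asarray(labeled, dtype=bool)
    n = W.n
    if tilde_Y.shape[0] != n:
        raise ValueError("tilde_Y row count does not match network size")
    _check_solvable(W.W, labeled)
    M = _smoothness_operator(W.W)
    U = sp.diags(labeled.astype(float))
    A = (U + lam * M).tocsc()
    B = np.asarray(U @ tilde_Y)
    if n <= DIRECT_SOLVER_MAX_N:
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - guarded by _check_solvable
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        F = lu.solve(B)
    else:  # pragma: no cover - large-n path exercised only at scale
        F = np.empty_like(B)
        for k in range(B.shape[1]):
            F[:, k], info = spla.cg(A, B[:, k], rtol=tol, atol=0.0)
            if info != 0:
                raise SolverError(f"conjugate gradients failed on column {k} (info={info})")
    denom = np.linalg.norm(B)
    residual = float(np.linalg.norm(A @ F - B) / denom) if denom > 0 else 0.0
    return F, residual


def objective_value(
    F: np.ndarray,
    tilde_Y: np.ndarray,
    W: NetworkWeights,
    lam: float,
    labeled: np.ndarray,
) -> float:
    """Evaluate Psi(F): empirical trace term plus lambda times smoothness."""
    labeled = np.asarray(labeled, dtype=bool)
    D = F - tilde_Y
    empirical = float(np.sum(D[labeled, :] ** 2))
    IW = sp.identity(W.n, format="csr") - W.W
    R = IW @ F
    smooth = float(np.sum(R**2))
    return empirical + lam * smooth


def run_variant(
    variant: str,
    Y: AnnotationMatrix,
    hierarchy: LabelHierarchy,
    W: NetworkWeights,
    labeled: np.ndarray,
    lam: float = 1.0,
    correlation: CorrelationMatrix | None = None,
) -> PredictionMatrix:
    """Run the full method or one of its ablations.

    ``pill`` / ``pill_jcd`` / ``pill_hsim`` / ``pill_lin`` differ only in the
    correlation kind used for missing-label estimation.  ``pill_fc`` keeps
    the estimated Y~ as the prediction (no network smoothing); ``pill_gba``
    smooths the raw Y without correlation-based estimation; ``naive`` scores
    every protein with the label frequencies among labeled proteins.

    A precomputed *correlation* matrix overrides the variant's default kind
    (useful when the caller caches correlations across variants).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    labeled = np.asarray(labeled, dtype=bool)
    kind_map = {"pill": "comsim", "pill_jcd": "jcd", "pill_hsim": "hsim", "pill_lin": "lin"}

    if variant == "naive":
        n_lab = int(labeled.sum())
        freq = Y.Y[labeled].mean(axis=0) if n_lab else np.zeros(Y.K)
        F = np.tile(freq.astype(float), (Y.n, 1))
        tilde = F.copy()
        return PredictionMatrix(
            list(Y.proteins), list(Y.labels), F, tilde, lam, labeled, 0.0, variant
        )

    if variant == "pill_gba":
        tilde = Y.Y.astype(float)
        tilde[~labeled, :] = 0.0
        F, residual = solve(tilde, W, lam, labeled)
        return PredictionMatrix(
            list(Y.proteins), list(Y.labels), F, tilde, lam, labeled, residual, variant
        )

    kind = kind_map.get(variant, "comsim")
    if correlation is None:
        correlation = correlation_matrix(Y, hierarchy, kind)  # type: ignore[arg-type]
    zero_rows = int((correlation.Cm.sum(axis=1) == 0).sum())
    if zero_rows:
        logger.info("correlation matrix has %d all-zero rows", zero_rows)
    tilde = estimate_missing(Y, correlation, labeled)
    if variant == "pill_fc":
        return PredictionMatrix(
            list(Y.proteins), list(Y.labels), tilde.copy(), tilde, lam, labeled, 0.0, variant
        )
    F, residual = solve(tilde, W, lam, labeled)
    return PredictionMatrix(
        list(Y.proteins), list(Y.labels), F, tilde, lam, labeled, residual, variant
    )
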