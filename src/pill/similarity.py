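"""Label-correlation measures: LinSim, HSim, JcdSim and the combined ComSim.

Lin's information-content similarity scores two labels by the specificity of
their most specific common ancestor: with p(s) the fraction of corpus
proteins annotated with s,

    LinSim(s, t) = 2 log p_ca(s, t) / (log p(s) + log p(t)),
    p_ca(s, t)   = min over common ancestors k of p(k).

HSim replaces the *common* ancestors ca(s, t) with the *shared* ancestors
sa(s, t), which additionally contain s itself when s is an ancestor of t
(and vice versa); since an ancestor is more specific than anything above it,
HSim >= LinSim on ancestor-descendant pairs and equals LinSim on
siblings/cousins.  Both collapse to 0 when the only shared ancestor is a
root annotated to (almost) every protein, or when the pair shares no
ancestor at all — situations where flat co-annotation still carries signal.
ComSim therefore switches to the Jaccard coefficient of the member-protein
sets whenever p_sa(s, t) falls outside (0, 1):

    ComSim(s, t) = HSim(s, t)   if 0 < p_sa(s, t) < 1
                 = JcdSim(s, t) otherwise.

The row-normalised form C_m(s, t) = ComSim(s, t) / sum_t' ComSim(s, t') is
what the missing-label estimator consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ontology import AnnotationMatrix, LabelHierarchy, OntologyError

__all__ = [
    "CorrelationMatrix",
    "label_probability",
    "lin_sim",
    "h_sim",
    "jcd_sim",
    "com_sim",
    "correlation_matrix",
    "normalize_correlation",
]

Kind = Literal["lin", "hsim", "jcd", "comsim"]


def label_probability(Y: AnnotationMatrix, label: str) -> float:
    """Fraction of corpus proteins annotated with *label*: |N(label)| / n."""
    if Y.n == 0:
        raise OntologyError("annotation matrix has no proteins")
    return Y.member_count(label) / Y.n


# ---------------------------------------------------------------------------
# ancestor-set machinery


def _common_ancestors(H: LabelHierarchy, s: str, t: str) -> frozenset[str]:
    """ca(s, t): proper ancestors of both labels."""
    return H.ancestors(s) & H.ancestors(t)


def _shared_ancestors(H: LabelHierarchy, s: str, t: str) -> frozenset[str]:
    """sa(s, t): common ancestors, plus s (or t) if it subsumes the other."""
    sa = set(_common_ancestors(H, s, t))
    if H.is_ancestor(s, t):
        sa.add(s)
    if H.is_ancestor(t, s):
        sa.add(t)
    return frozenset(sa)


def _min_probability(Y: AnnotationMatrix, labels: frozenset[str]) -> float:
    """min_k p(k) over a label set; 0 for the empty set (no subsumer)."""
    known = set(Y.labels)
    vals = [label_probability(Y, k) for k in labels if k in known]
    return min(vals) if vals else 0.0


def _lin_family(Y: AnnotationMatrix, s: str, t: str, p_anc: float) -> float:
    """Eq.-1 style ratio given the subsumer probability; handles edge cases."""
    if s == t:
        # degenerate in the formula; self-similarity is maximal by definition
        return 1.0
    if p_anc <= 0.0 or p_anc >= 1.0:
        return 0.0
    ps = label_probability(Y, s)
    pt = label_probability(Y, t)
    if ps <= 0.0 or pt <= 0.0:
        return 0.0  # no annotation evidence
    denom = math.log(ps) + math.log(pt)
    if denom == 0.0:  # both labels cover the whole corpus
        return 0.0
    return 2.0 * math.log(p_anc) / denom


def lin_sim(Y: AnnotationMatrix, H: LabelHierarchy, s: str, t: str) -> float:
    """Lin similarity over common ancestors; 1 when s == t."""
    _require(Y, s, t)
    if s == t:
        return 1.0
    return _lin_family(Y, s, t, _min_probability(Y, _common_ancestors(H, s, t)))


def h_sim(Y: AnnotationMatrix, H: LabelHierarchy, s: str, t: str) -> float:
    """Lin similarity over shared ancestors (self-inclusive on nested pairs)."""
    _require(Y, s, t)
    if s == t:
        return 1.0
    return _lin_family(Y, s, t, _min_probability(Y, _shared_ancestors(H, s, t)))


def jcd_sim(Y: AnnotationMatrix, s: str, t: str) -> float:
    """Jaccard coefficient of member-protein sets; 0 when both are empty."""
    ns, nt = Y.members(s), Y.members(t)
    union = ns | nt
    if not union:
        return 0.0
    return len(ns & nt) / len(union)


def com_sim(Y: AnnotationMatrix, H: LabelHierarchy, s: str, t: str) -> float:
    """Combined similarity: HSim when 0 < p_sa < 1, else Jaccard.

    The Jaccard branch covers pairs with no shared ancestor (p_sa = 0, e.g.
    FunCat top-level labels) and pairs whose most specific shared ancestor
    annotates every protein (p_sa = 1, e.g. under an ontology root).  When
    s, t and that ancestor all annotate the same protein set the value is 1.
    """
    _require(Y, s, t)
    if s == t:
        return 1.0 if Y.member_count(s) > 0 else 0.0
    p_sa = _min_probability(Y, _shared_ancestors(H, s, t))
    if 0.0 < p_sa < 1.0:
        return _lin_family(Y, s, t, p_sa)
    return jcd_sim(Y, s, t)


def _require(Y: AnnotationMatrix, *labels: str) -> None:
    for l in labels:
        Y.label_index(l)  # raises OntologyError on unknown labels


# ---------------------------------------------------------------------------
# full K x K matrices


@dataclass
class CorrelationMatrix:
    """K x K label-correlation matrix plus its row-normalised form C_m."""

    labels: list[str]
    S: np.ndarray
    kind: Kind
    Cm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        K = len(self.labels)
        if self.S.shape != (K, K):
            raise ValueError(f"S shape {self.S.shape} != ({K}, {K})")
        if self.Cm is None:
            self.Cm = _row_normalize(self.S)


def _row_normalize(S: np.ndarray) -> np.ndarray:
    sums = S.sum(axis=1, keepdims=True)
    out = np.divide(S, sums, out=np.zeros_like(S, dtype=float), where=sums > 0)
    return out


def correlation_matrix(
    Y: AnnotationMatrix, H: LabelHierarchy, kind: Kind = "comsim"
) -> CorrelationMatrix:
    """Compute all K^2 pairwise similarities of the requested kind.

    Similarities are computed from the annotation state as given (for
    incomplete-label experiments: the masked training state — recomputing
    them from ground truth would leak the held-out labels).
    """
    labels = list(Y.labels)
    K = len(labels)
    Yb = Y.Y.astype(bool)
    counts = Yb.sum(axis=0).astype(float)  # |N(k)|
    n = Y.n
    p = counts / n if n else counts
    inter = (Yb.T.astype(np.int64) @ Yb.astype(np.int64)).astype(float)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)

    if kind == "jcd":
        S = jac.copy()
        np.fill_diagonal(S, np.where(counts > 0, 1.0, 0.0))
        return CorrelationMatrix(labels, S, kind)

    # hierarchical kinds need per-pair subsumer probabilities
    anc = [H.ancestors(l) for l in labels]
    lidx = {l: k for k, l in enumerate(labels)}
    logp = np.full(K, np.nan)
    pos = p > 0
    logp[pos] = np.log(p[pos])

    def min_p(ancset: frozenset[str]) -> float:
        vals = [p[lidx[a]] for a in ancset if a in lidx]
        return min(vals) if vals else 0.0

    S = np.zeros((K, K))
    for i in range(K):
        for j in range(i, K):
            if i == j:
                if kind == "comsim":
                    S[i, i] = 1.0 if counts[i] > 0 else 0.0
                else:
                    S[i, i] = 1.0
                continue
            ca = anc[i] & anc[j]
            li, lj = labels[i], labels[j]
            if kind == "lin":
                p_anc = min_p(ca)
            else:  # hsim / comsim use shared ancestors
                sa = set(ca)
                if li in anc[j]:
                    sa.add(li)
                if lj in anc[i]:
                    sa.add(lj)
                p_anc = min_p(frozenset(sa))
            if 0.0 < p_anc < 1.0 and p[i] > 0 and p[j] > 0:
                denom = logp[i] + logp[j]
                val = 2.0 * math.log(p_anc) / denom if denom != 0.0 else 0.0
            elif kind == "comsim":
                val = jac[i, j]
            else:
                val = 0.0
            S[i, j] = S[j, i] = val
    return CorrelationMatrix(labels, S, kind)


def normalize_correlation(S: CorrelationMatrix) -> CorrelationMatrix:
    """Recompute C_m: each row divided by its sum (all-zero rows stay zero)."""
    return CorrelationMatrix(list(S.labels), S.S.copy(), S.kind, _row_normalize(S.S))


# ---------------------------------------------------------------------------
# cache keyed by the annotation state


def correlation_cache_key(Y: AnnotationMatrix, kind: Kind) -> str:
    """Hash of the annotation state and similarity kind.

    Correlations depend only on (labels, Y, kind), so a matrix computed for
    one masking state can be reused for any run that shares it.
    """
    import hashlib

    h = hashlib.sha256()
    h.update(kind.encode())
    h.update("\x00".join(Y.labels).encode())
    h.update("\x00".join(Y.proteins).encode())
    h.update(np.ascontiguousarray(Y.Y).tobytes())
    return h.hexdigest()


def save_correlation(C: CorrelationMatrix, Y: AnnotationMatrix, cache_dir: str) -> str:
    """Store S/Cm under the annotation-state key; returns the file path."""
    import os

    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, correlation_cache_key(Y, C.kind) + ".npz")
    np.savez_compressed(path, S=C.S, Cm=C.Cm, labels=np.array(C.labels), kind=C.kind)
    return path


def load_correlation(
    Y: AnnotationMatrix, kind: Kind, cache_dir: str
) -> CorrelationMatrix | None:
    """Return the cached matrix for this annotation state, or None."""
    import os

    path = os.path.join(cache_dir, correlation_cache_key(Y, kind) + ".npz")
    if not os.path.exists(path):
        return None
    with np.load(path, allow_pickle=False) as data:
        return CorrelationMatrix(
            [str(l) for l in data["labels"]], data["S"], str(data["kind"]), data["Cm"]
        )
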