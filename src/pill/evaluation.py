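"""Multi-label evaluation metrics and the two benchmark experiments.

Five metrics, all oriented so higher is better and bounded in [0, 1]:

* MicroF1 / MacroF1 — F1 on binarised scores, pooled over entries (micro) or
  averaged per label (macro).  Binarisation defaults to an oracle top-r cut
  per protein (r = the protein's in-scope positive count), switchable to a
  fixed threshold.
* AvgROC — mean per-label ROC AUC over labels with both classes in scope.
* 1-RankLoss — one minus the mean, over proteins, of the fraction of
  (positive, negative) label pairs ranked discordantly (ties count half).
* Fmax — max over a 101-point threshold grid of the protein-averaged F1
  (protein-centric, CAFA style).

Evaluation is restricted to an explicit (protein, label) entry mask: for the
replenishment task, the entries unknown at training time on labeled proteins
(the masked labels are the positives); for the unlabeled-protein task, all
entries of the held-out test proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import build_weights, run_variant
from .ontology import AnnotationMatrix
from .simulation import SyntheticDataset, mask_leaf_labels

__all__ = [
    "METRICS",
    "evaluate",
    "run_replenish_experiment",
    "run_unlabeled_experiment",
]

METRICS = ("MicroF1", "MacroF1", "AvgROC", "1-RankLoss", "Fmax")

FMAX_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _binarize(
    scores: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
    mode: str,
    threshold: float,
) -> np.ndarray:
    """Binary predictions on in-scope entries (out-of-scope stays 0)."""
    pred = np.zeros_like(truth, dtype=bool)
    if mode == "threshold":
        pred[mask] = scores[mask] >= threshold
        return pred
    if mode != "oracle":
        raise ValueError(f"unknown binarization mode {mode!r}")
    for i in range(truth.shape[0]):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        r = int(truth[i, cols].sum())
        if r == 0:
            continue
        order = cols[np.argsort(-scores[i, cols], kind="stable")]
        pred[i, order[:r]] = True
    return pred


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _ranking_loss(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    per_protein = []
    for i in range(truth.shape[0]):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        t = truth[i, cols].astype(bool)
        s = scores[i, cols]
        pos, neg = s[t], s[~t]
        if pos.size == 0 or neg.size == 0:
            continue
        diff = pos[:, None] - neg[None, :]
        bad = (diff < 0).sum() + 0.5 * (diff == 0).sum()
        per_protein.append(bad / (pos.size * neg.size))
    if not per_protein:
        raise ValueError("no protein has both classes in scope")
    return float(np.mean(per_protein))


def _fmax(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray,
          thresholds: np.ndarray = FMAX_GRID) -> float:
    rows = []
    for i in range(truth.shape[0]):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0 or truth[i, cols].sum() == 0:
            continue
        rows.append((scores[i, cols], truth[i, cols].astype(bool)))
    if not rows:
        raise ValueError("no protein has a positive entry in scope")
    best = 0.0
    for tau in thresholds:
        f1s = []
        for s, t in rows:
            pred = s >= tau
            tp = int((pred & t).sum())
            f1s.append(_f1(tp, int(pred.sum()) - tp, int(t.sum()) - tp))
        best = max(best, float(np.mean(f1s)))
    return best


def _avg_roc(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    aucs = []
    for k in range(truth.shape[1]):
        rows = np.flatnonzero(mask[:, k])
        if rows.size == 0:
            continue
        t = truth[rows, k]
        if t.min() == t.max():
            continue  # single class in scope for this label
        aucs.append(roc_auc_score(t, scores[rows, k]))
    if not aucs:
        raise ValueError("no label has both classes in scope")
    return float(np.mean(aucs))


def evaluate(
    scores: np.ndarray,
    ground_truth: AnnotationMatrix,
    eval_mask: np.ndarray,
    metrics: tuple[str, ...] = METRICS,
    binarization: str = "oracle",
    threshold: float = 0.5,
) -> dict[str, float]:
    """Score predictions on the in-scope entries with the requested metrics.

    *eval_mask* is a boolean (n, K) array selecting the scored entries.
    Proteins (or labels) with a single class in scope are skipped by the
    protein-centric (label-centric) metrics.
    """
    truth = ground_truth.Y.astype(int)
    mask = np.asarray(eval_mask, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError(f"mask shape {mask.shape} != truth shape {truth.shape}")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    out: dict[str, float] = {}
    needs_binary = {"MicroF1", "MacroF1"} & set(metrics)
    if needs_binary:
        pred = _binarize(scores, truth, mask, binarization, threshold)
    for metric in metrics:
        if metric == "MicroF1":
            t, p = truth[mask].astype(bool), pred[mask]
            tp = int((t & p).sum())
            out[metric] = _f1(tp, int(p.sum()) - tp, int(t.sum()) - tp)
        elif metric == "MacroF1":
            f1s = []
            for k in range(truth.shape[1]):
                rows = np.flatnonzero(mask[:, k])
                if rows.size == 0:
                    continue
                t = truth[rows, k].astype(bool)
                if t.min() == t.max():
                    continue
                p = pred[rows, k]
                tp = int((t & p).sum())
                f1s.append(_f1(tp, int(p.sum()) - tp, int(t.sum()) - tp))
            if not f1s:
                raise ValueError("no label has both classes in scope")
            out[metric] = float(np.mean(f1s))
        elif metric == "AvgROC":
            out[metric] = _avg_roc(scores, truth, mask)
        elif metric == "1-RankLoss":
            out[metric] = 1.0 - _ranking_loss(scores, truth, mask)
        elif metric == "Fmax":
            out[metric] = _fmax(scores, truth, mask)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


# ---------------------------------------------------------------------------
# experiments


def _labeled_mask(Y: AnnotationMatrix) -> np.ndarray:
    return Y.Y.sum(axis=1) > 0


def run_replenish_experiment(
    dataset: SyntheticDataset,
    m_values: tuple[int, ...] = (1, 3, 5),
    repeats: int = 5,
    variants: tuple[str, ...] = ("pill", "naive"),
    base_seed: int = 0,
    lam: float = 1.0,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Replenishment benchmark: mask leaves, replenish, score masked entries.

    All annotated proteins serve as both training and test data.  Each repeat
    re-masks with a fresh seed and recomputes correlations from the masked
    state.  Returns one row per (variant, m, metric) with mean and sample std
    over repeats.
    """
    W = build_weights(dataset.edges, dataset.Y_true.proteins)
    records = []
    for m in m_values:
        for rep in range(repeats):
            seed = int(np.random.SeedSequence([base_seed, m, rep]).generate_state(1)[0] % (2**31))
            masking = mask_leaf_labels(dataset.Y_true, dataset.hierarchy, m, seed)
            Y_train = masking.Y_masked
            labeled = _labeled_mask(Y_train)
            scope = (Y_train.Y == 0) & labeled[:, None]
            for variant in variants:
                result = run_variant(variant, Y_train, dataset.hierarchy, W, labeled, lam)
                vals = evaluate(result.F, dataset.Y_true, scope, metrics)
                for metric, value in vals.items():
                    records.append((variant, m, rep, metric, value, masking.N_m))
    df = pd.DataFrame(records, columns=["variant", "m", "repeat", "metric", "value", "N_m"])
    table = (
        df.groupby(["variant", "m", "metric"])
        .agg(mean=("value", "mean"), std=("value", lambda v: v.std(ddof=1)), N_m=("N_m", "mean"))
        .reset_index()
    )
    return table


def run_unlabeled_experiment(
    dataset: SyntheticDataset,
    train_fraction: float = 0.7,
    m: int = 3,
    repeats: int = 5,
    variants: tuple[str, ...] = ("pill", "naive"),
    base_seed: int = 0,
    lam: float = 1.0,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Unlabeled-protein benchmark: 70/30 split, mask training side at m.

    Test proteins' labels are fully hidden; scores are evaluated on every
    entry of the test proteins.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1) to leave a test set")
    W = build_weights(dataset.edges, dataset.Y_true.proteins)
    n = dataset.Y_true.n
    records = []
    for rep in range(repeats):
        ss = np.random.SeedSequence([base_seed, rep])
        seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        train_idx = np.zeros(n, dtype=bool)
        train_idx[perm[:n_train]] = True
        masking = mask_leaf_labels(dataset.Y_true, dataset.hierarchy, m, seed + 1)
        Y_train = masking.Y_masked.copy()
        Y_train.Y[~train_idx, :] = 0
        labeled = train_idx & _labeled_mask(Y_train)
        scope = np.zeros_like(Y_train.Y, dtype=bool)
        scope[~train_idx, :] = True
        for variant in variants:
            result = run_variant(variant, Y_train, dataset.hierarchy, W, labeled, lam)
            vals = evaluate(result.F, dataset.Y_true, scope, metrics)
            for metric, value in vals.items():
                records.append((variant, rep, metric, value))
    df = pd.DataFrame(records, columns=["variant", "repeat", "metric", "value"])
    return (
        df.groupby(["variant", "metric"])
        .agg(mean=("value", "mean"), std=("value", lambda v: v.std(ddof=1)))
        .reset_index()
    )
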