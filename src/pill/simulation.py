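"""Synthetic hierarchies, annotations, homophilous networks, and leaf masking.

Real benchmark corpora pair a curated PPI network with FunCat or GO
annotations; no public corpus records which labels are *missing*, so
incomplete annotation is simulated by masking.  This module generates the
three inputs with the structure the method assumes —

* a rooted label tree (optionally a DAG) of configurable depth/branching,
* true-path-closed annotations produced by root-to-node random walks, so a
  protein's labels form downward-closed paths and sibling labels co-occur,
* a weighted interaction network whose edges preferentially join proteins
  with overlapping label sets (guilt by association, tunable homophily) —

and implements the leaf-masking protocol: per protein, m rounds of removing
a uniformly chosen *current* leaf label (leafness recomputed after every
removal, so a parent whose children are all masked becomes maskable), never
dropping the last remaining label.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .ontology import (
    AnnotationMatrix,
    LabelHierarchy,
    leaf_labels_of_protein,
    true_path_closure,
)

__all__ = [
    "MaskingResult",
    "SyntheticDataset",
    "mask_leaf_labels",
    "generate_hierarchy",
    "generate_annotations",
    "generate_network",
    "make_dataset",
    "write_fixture",
]


@dataclass
class MaskingResult:
    """Outcome of the leaf-masking protocol."""

    Y_masked: AnnotationMatrix
    masked_entries: frozenset[tuple[str, str]]
    m: int
    N_m: int = field(init=False)

    def __post_init__(self) -> None:
        self.N_m = len(self.masked_entries)


@dataclass
class SyntheticDataset:
    """A complete synthetic benchmark: hierarchy, closed truth, network."""

    hierarchy: LabelHierarchy
    Y_true: AnnotationMatrix
    edges: list[tuple[str, str, float]]
    seed: int


def mask_leaf_labels(
    Y: AnnotationMatrix, hierarchy: LabelHierarchy, m: int, seed: int
) -> MaskingResult:
    """Mask up to *m* leaf labels per protein, recomputing leaves each round.

    Only the current per-protein leaf labels are eligible; once all children
    of a label are masked it becomes a leaf and may be masked in a later
    round.  Every protein keeps at least one label, so proteins with a single
    label are untouched and the masked matrix stays true-path closed.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    rng = np.random.default_rng(seed)
    masked = Y.copy()
    removed: set[tuple[str, str]] = set()
    for protein in Y.proteins:
        for _ in range(m):
            current = masked.labels_of(protein)
            if len(current) <= 1:
                break
            leaves = sorted(leaf_labels_of_protein(masked, hierarchy, protein))
            if not leaves:
                break
            pick = leaves[rng.integers(len(leaves))]
            masked.Y[masked.protein_index(protein), masked.label_index(pick)] = 0
            removed.add((protein, pick))
    return MaskingResult(masked, frozenset(removed), m)


def generate_hierarchy(
    depth: int,
    branching: int,
    seed: int,
    dag_edge_prob: float = 0.0,
) -> LabelHierarchy:
    """Random rooted hierarchy with dotted identifiers.

    Each node at depth < *depth* receives a child count drawn uniformly in
    [1, branching].  With ``dag_edge_prob > 0`` extra parents are added from
    strictly shallower non-ancestor nodes, keeping the relation acyclic.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {"1": set()}
    levels: list[list[str]] = [["1"]]
    for d in range(1, depth):
        level: list[str] = []
        for node in levels[d - 1]:
            n_children = int(rng.integers(1, branching + 1))
            for c in range(1, n_children + 1):
                child = f"{node}.{c}"
                parents[child] = {node}
                level.append(child)
        if not level:
            break
        levels.append(level)
    if dag_edge_prob > 0:
        hierarchy = LabelHierarchy(parents)
        shallow: dict[str, int] = {}
        for d, level in enumerate(levels):
            for node in level:
                shallow[node] = d
        for node in sorted(parents):
            if shallow[node] < 2 or rng.random() >= dag_edge_prob:
                continue
            candidates = [
                c
                for c in sorted(parents)
                if shallow[c] < shallow[node]
                and c not in hierarchy.ancestors(node)
                and c != node
            ]
            if candidates:
                extra = candidates[int(rng.integers(len(candidates)))]
                parents[node] = set(parents[node]) | {extra}
        return LabelHierarchy(parents)
    return LabelHierarchy(parents)


def generate_annotations(
    hierarchy: LabelHierarchy,
    n_proteins: int,
    walk_continue_prob: float,
    seed: int,
    max_walks: int = 5,
    unlabeled_fraction: float = 0.0,
    co_start_prob: float = 0.7,
) -> AnnotationMatrix:
    """Annotate proteins via top-down random walks; closed by closure.

    Each labeled protein performs 1..*max_walks* walks: descend from a
    top-level label to a uniformly chosen child with probability
    *walk_continue_prob*, stop otherwise; the walk's endpoint and all its
    ancestors are annotated.  When the hierarchy is a forest (FunCat style)
    the top-level labels are its roots; a single universal root (GO style)
    gets no annotation column, as real annotation tables never record it,
    and walks start at its children.

    Real corpora show strong *flat* co-annotation between categories with no
    shared ancestor (in yeast FunCat, over half of CELL FATE proteins also
    carry CELL TYPE DIFFERENTIATION), and the co-occurrence is specific at
    the term level, not just the category level (cross-category functional
    modules).  To emulate this, top-level labels are paired into
    co-functional partners (consecutively in sorted order); each walk after
    the first starts at the partner of the protein's first branch with
    probability *co_start_prob* (otherwise uniformly), and a partner walk
    replays the first walk's child choices (but draws its stopping depth
    independently), so particular deep terms in one category co-occur with
    particular deep terms in its partner while the two walks' specificities
    stay independent.  Each walk's child choices remain uniform marginally.

    A fraction of proteins may stay label-free to mirror real networks that
    keep unannotated proteins for structure.
    """
    if not 0.0 < walk_continue_prob < 1.0:
        raise ValueError("walk_continue_prob must be in (0, 1)")
    if not 0.0 <= co_start_prob <= 1.0:
        raise ValueError("co_start_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    root_set = hierarchy.roots()
    if len(root_set) == 1 and hierarchy.children(next(iter(root_set))):
        # GO style: a universal root, never annotated; walks start below it
        starts = set(hierarchy.children(next(iter(root_set))))
        labels = sorted(hierarchy.labels - root_set)
    else:
        # FunCat style: the roots are the annotatable top-level categories
        starts = set(root_set)
        labels = sorted(hierarchy.labels)
    lidx = {l: k for k, l in enumerate(labels)}
    tops = sorted(starts)
    partner: dict[str, str] = {}
    for a, b in zip(tops[0::2], tops[1::2]):
        partner[a], partner[b] = b, a
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    n_unlabeled = int(round(unlabeled_fraction * n_proteins))
    unlabeled = set(rng.choice(n_proteins, size=n_unlabeled, replace=False).tolist())
    Y = np.zeros((n_proteins, len(labels)), dtype=np.int8)
    def walk(i: int, start: str, record: list | None, replay: list | None) -> None:
        node = start
        Y[i, lidx[node]] = 1
        step = 0
        while True:
            children = sorted(hierarchy.children(node))
            u_cont = rng.random()  # stopping depth always independent
            if replay is not None and step < len(replay):
                u_child = replay[step]
            else:
                u_child = rng.random()
                if record is not None:
                    record.append(u_child)
            step += 1
            if not children or u_cont >= walk_continue_prob:
                break
            node = children[int(u_child * len(children))]
            Y[i, lidx[node]] = 1

    for i in range(n_proteins):
        if i in unlabeled:
            continue
        first: str | None = None
        first_draws: list[tuple[float, float]] = []
        for w in range(int(rng.integers(1, max_walks + 1))):
            if w == 0 or first not in partner or rng.random() >= co_start_prob:
                start = tops[int(rng.integers(len(tops)))]
                is_partner = False
            else:
                start = partner[first]
                is_partner = True
            if w == 0:
                first = start
                walk(i, start, first_draws, None)
            else:
                walk(i, start, None, first_draws if is_partner else None)
    return true_path_closure(AnnotationMatrix(proteins, labels, Y), hierarchy)


def generate_network(
    Y_true: AnnotationMatrix,
    n_edges: int,
    homophily: float,
    seed: int,
) -> list[tuple[str, str, float]]:
    """Sample weighted edges biased toward label-sharing protein pairs.

    Pair (i, j) is drawn with probability proportional to the mixing score

        homophily * Jaccard(labels_i, labels_j) + (1 - homophily) * J_bar,

    where J_bar is the mean pairwise Jaccard (the background co-annotation
    level), so *homophily* is the fraction of edge probability mass
    attributable to label sharing: at 1 only label-sharing pairs interact,
    at 0 sampling is uniform.  Edge weights are the mixing scores rescaled
    to (0, 1].
    """
    if not 0.0 <= homophily <= 1.0:
        raise ValueError("homophily must be in [0, 1]")
    n = Y_true.n
    pairs = list(itertools.combinations(range(n), 2))
    if n_edges > len(pairs):
        raise ValueError(f"n_edges={n_edges} exceeds the {len(pairs)} possible pairs")
    Yb = Y_true.Y.astype(bool)
    counts = Yb.sum(axis=1).astype(float)
    inter = (Yb.astype(np.int32) @ Yb.T.astype(np.int32)).astype(float)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    idx = np.array(pairs)
    pair_jac = jac[idx[:, 0], idx[:, 1]]
    background = float(pair_jac.mean()) if homophily < 1.0 else 0.0
    if homophily < 1.0 and background == 0.0:
        background = 1.0  # no co-annotation anywhere: fall back to uniform
    scores = homophily * pair_jac + (1.0 - homophily) * background
    peak = scores.max()
    if peak > 0:
        scores = scores / peak
    total = scores.sum()
    if total <= 0 or (scores > 0).sum() < n_edges:
        raise ValueError("not enough pairs with positive sampling weight")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_edges, replace=False, p=scores / total)
    edges = []
    for c in sorted(chosen.tolist()):
        i, j = pairs[c]
        edges.append((Y_true.proteins[i], Y_true.proteins[j], float(scores[c])))
    return edges


def _relabel(label: str, branch: int) -> str:
    tokens = label.split(".")
    tokens[0] = str(branch)
    return ".".join(tokens)


def generate_forest(
    n_branches: int, depth: int, branching: int, seed: int
) -> LabelHierarchy:
    """FunCat-style taxonomy: *n_branches* independent top-level subtrees.

    Each subtree comes from :func:`generate_hierarchy`; subtree roots become
    the top-level labels (no universal root, as in FunCat where e.g. '01'
    METABOLISM and '40' CELL FATE have no common parent).
    """
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {}
    for b in range(1, n_branches + 1):
        sub = generate_hierarchy(depth, branching, int(rng.integers(2**31)))
        for label in sub.labels:
            parents[_relabel(label, b)] = {_relabel(p, b) for p in sub.parents(label)}
    return LabelHierarchy(parents)


def make_dataset(
    n_proteins: int = 300,
    n_branches: int = 10,
    depth: int = 4,
    branching: int = 2,
    walk_continue_prob: float = 0.75,
    max_walks: int = 5,
    co_start_prob: float = 0.7,
    n_edges: int = 2000,
    homophily: float = 0.8,
    unlabeled_fraction: float = 0.0,
    seed: int = 0,
    label_count_band: tuple[int, int] = (45, 90),
) -> SyntheticDataset:
    """Generate a full synthetic benchmark from a single seed.

    Defaults emulate a curated yeast PPI benchmark at desk scale: a broad
    FunCat-like taxonomy (10 top-level categories, subtrees of depth 4,
    ~60-80 labels in total), ~6-8 true-path-closed labels per protein with
    flat co-annotation between partner categories, and a network of mean
    degree ~13 whose edges preferentially join label-sharing proteins.
    Sub-seeds for the three generators are derived deterministically from
    *seed*.  Because random trees with uniform child counts have
    heavy-tailed sizes, forest sub-seeds are drawn until the label count
    falls inside *label_count_band* (the closest candidate is kept if none
    does within 50 draws), so different seeds produce comparably sized
    problems.
    """
    ss = np.random.SeedSequence(seed)
    s_h, s_a, s_n = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    lo, hi = label_count_band
    h_rng = np.random.default_rng(s_h)
    best: LabelHierarchy | None = None
    target = (lo + hi) / 2
    for _ in range(50):
        cand = generate_forest(n_branches, depth, branching, int(h_rng.integers(2**31)))
        if lo <= len(cand) <= hi:
            best = cand
            break
        if best is None or abs(len(cand) - target) < abs(len(best) - target):
            best = cand
    hierarchy = best
    Y = generate_annotations(
        hierarchy,
        n_proteins,
        walk_continue_prob,
        s_a,
        max_walks=max_walks,
        unlabeled_fraction=unlabeled_fraction,
        co_start_prob=co_start_prob,
    )
    edges = generate_network(Y, n_edges, homophily, s_n)
    return SyntheticDataset(hierarchy, Y, edges, seed)


def write_fixture(dataset: SyntheticDataset, out_dir: str, params: dict | None = None) -> None:
    """Write annotation TSV, edge TSV, dotted-ID label list and a manifest."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "annotations.tsv"), "w") as fh:
        fh.write("# protein\tlabel\n")
        for i, protein in enumerate(dataset.Y_true.proteins):
            for k in np.flatnonzero(dataset.Y_true.Y[i]):
                fh.write(f"{protein}\t{dataset.Y_true.labels[k]}\n")
    with open(os.path.join(out_dir, "network.tsv"), "w") as fh:
        fh.write("# protein_a\tprotein_b\tweight\n")
        for a, b, w in dataset.edges:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
    with open(os.path.join(out_dir, "labels.txt"), "w") as fh:
        for label in sorted(dataset.hierarchy.labels):
            fh.write(label + "\n")
    manifest = {"seed": dataset.seed,
                "n_proteins": dataset.Y_true.n,
                "n_labels": dataset.Y_true.K,
                "n_edges": len(dataset.edges)}
    if params:
        manifest.update(params)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
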