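"""Function-label hierarchies and true-path-closed annotation matrices.

Protein function taxonomies come in two flavours: the MIPS Functional
Catalogue (FunCat), a tree whose dotted identifiers encode the parent
relation (``"01.03.02"`` is a child of ``"01.03"``), and the Gene Ontology,
a DAG in which a term may have several ``is_a`` parents.  Both obey the
*true path rule*: annotation with a label implies annotation with every
ancestor of that label.

This module provides :class:`LabelHierarchy` (ancestor/descendant queries
over either flavour), :class:`AnnotationMatrix` (the n x K binary matrix Y
of protein-label associations), parsers for the standard input formats, the
true-path closure operation, per-protein leaf labels, and the
parent/grandparent/uncle conditional-probability statistics that motivate
hierarchy-aware label similarity.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabelHierarchy",
    "AnnotationMatrix",
    "OntologyError",
    "parse_funcat_labels",
    "parse_obo",
    "true_path_closure",
    "leaf_labels_of_protein",
    "relationship_statistics",
    "conditional_probability",
    "annotations_from_rows",
]

#: sentinel parent used to pool top-level labels as siblings; it is never a
#: real label and never appears in ancestor sets or annotations.
VIRTUAL_ROOT = "__virtual_root__"


class OntologyError(ValueError):
    """Malformed hierarchy or annotation input."""


class LabelHierarchy:
    """Rooted DAG (or tree) of function labels with ancestor queries.

    Parameters
    ----------
    parents
        Mapping from each label to the set of its parent labels.  Labels
        with an empty parent set are roots.  The relation must be acyclic
        and every label must reach a root.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self._parents: dict[str, frozenset[str]] = {}
        for label, ps in parents.items():
            ps = frozenset(ps)
            if label in ps:
                raise OntologyError(f"label {label!r} is its own parent")
            self._parents[label] = ps
        # parents referenced but not listed become roots
        for ps in list(self._parents.values()):
            for p in ps:
                self._parents.setdefault(p, frozenset())
        self._children: dict[str, set[str]] = {l: set() for l in self._parents}
        for label, ps in self._parents.items():
            for p in ps:
                self._children[p].add(label)
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_funcat_ids(cls, labels: Iterable[str]) -> "LabelHierarchy":
        """Build a tree from dotted identifiers, adding implied prefixes."""
        parents: dict[str, set[str]] = {}
        for label in labels:
            for lab, par in _funcat_chain(label):
                parents.setdefault(lab, set())
                if par is not None:
                    parents[lab].add(par)
        return cls(parents)

    # -- basic queries --------------------------------------------------------

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self._parents)

    def __contains__(self, label: str) -> bool:
        return label in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def parents(self, label: str) -> frozenset[str]:
        try:
            return self._parents[label]
        except KeyError:
            raise OntologyError(f"unknown label: {label!r}") from None

    def children(self, label: str) -> frozenset[str]:
        if label not in self._children:
            raise OntologyError(f"unknown label: {label!r}")
        return frozenset(self._children[label])

    def roots(self) -> frozenset[str]:
        return frozenset(l for l, ps in self._parents.items() if not ps)

    def ancestors(self, label: str) -> frozenset[str]:
        """All proper ancestors of *label* (transitive over every parent)."""
        cached = self._ancestor_cache.get(label)
        if cached is not None:
            return cached
        ps = self.parents(label)
        out: set[str] = set(ps)
        for p in ps:
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[label] = result
        return result

    def descendants(self, label: str) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self.children(label))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children[c])
        return frozenset(out)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if *a* is a proper ancestor of *b*."""
        return a in self.ancestors(b)

    # -- family relations (virtual-root convention) ---------------------------

    def _parents_virtual(self, label: str) -> frozenset[str]:
        """Parents, with a shared virtual parent for top-level labels.

        Top-level labels (FunCat '01', '12', ...) have no explicit common
        parent yet behave as siblings: '12' acts as an uncle of '01.03'.
        The virtual root exists only for sibling/uncle queries; it never
        enters ancestor sets or annotations.
        """
        ps = self.parents(label)
        return ps if ps else frozenset({VIRTUAL_ROOT})

    def siblings(self, label: str) -> frozenset[str]:
        """Labels sharing a (possibly virtual) parent with *label*."""
        mine = self._parents_virtual(label)
        out: set[str] = set()
        for other in self._parents:
            if other != label and self._parents_virtual(other) & mine:
                out.add(other)
        return frozenset(out)

    def grandparents(self, label: str) -> frozenset[str]:
        out: set[str] = set()
        for p in self.parents(label):
            out |= self.parents(p)
        return frozenset(out)

    def uncles(self, label: str) -> frozenset[str]:
        """Siblings of the parents of *label* (parents themselves excluded)."""
        out: set[str] = set()
        for p in self.parents(label):
            out |= self.siblings(p)
        return frozenset(out - self.parents(label) - {label})

    # -- internals -------------------------------------------------------------

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(node: str, stack: list[str]) -> None:
            st = state.get(node)
            if st == 1:
                return
            if st == 0:
                cycle = stack[stack.index(node):] + [node]
                raise OntologyError("cyclic parent relation: " + " -> ".join(cycle))
            state[node] = 0
            stack.append(node)
            for p in self._parents[node]:
                visit(p, stack)
            stack.pop()
            state[node] = 1

        for label in self._parents:
            visit(label, [])


def _funcat_chain(label: str) -> list[tuple[str, str | None]]:
    """(label, parent) pairs for a dotted identifier and all its prefixes."""
    tokens = label.split(".")
    if not tokens or any(t == "" for t in tokens):
        raise OntologyError(f"malformed dotted identifier: {label!r}")
    out: list[tuple[str, str | None]] = []
    for i in range(1, len(tokens) + 1):
        lab = ".".join(tokens[:i])
        par = ".".join(tokens[: i - 1]) if i > 1 else None
        out.append((lab, par))
    return out


@dataclass
class AnnotationMatrix:
    """Binary protein-label association matrix.

    ``Y[i, k] == 1`` means protein ``i`` is known to carry label ``k``;
    ``0`` means the association is *unknown* (not refuted).
    """

    proteins: list[str]
    labels: list[str]
    Y: np.ndarray  # (n, K) of {0, 1}, dtype int8

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if self.Y.shape != (len(self.proteins), len(self.labels)):
            raise OntologyError(
                f"Y shape {self.Y.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.labels)} labels"
            )
        self._protein_index = {p: i for i, p in enumerate(self.proteins)}
        self._label_index = {l: k for k, l in enumerate(self.labels)}
        if len(self._protein_index) != len(self.proteins):
            raise OntologyError("duplicate protein identifiers")
        if len(self._label_index) != len(self.labels):
            raise OntologyError("duplicate label identifiers")

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def K(self) -> int:
        return len(self.labels)

    def protein_index(self, protein: str) -> int:
        try:
            return self._protein_index[protein]
        except KeyError:
            raise OntologyError(f"unknown protein: {protein!r}") from None

    def label_index(self, label: str) -> int:
        try:
            return self._label_index[label]
        except KeyError:
            raise OntologyError(f"unknown label: {label!r}") from None

    def members(self, label: str) -> frozenset[str]:
        """Set of proteins annotated with *label* (N(label))."""
        col = self.Y[:, self.label_index(label)]
        return frozenset(self.proteins[i] for i in np.flatnonzero(col))

    def member_count(self, label: str) -> int:
        return int(self.Y[:, self.label_index(label)].sum())

    def labels_of(self, protein: str) -> frozenset[str]:
        row = self.Y[self.protein_index(protein), :]
        return frozenset(self.labels[k] for k in np.flatnonzero(row))

    def copy(self) -> "AnnotationMatrix":
        return AnnotationMatrix(list(self.proteins), list(self.labels), self.Y.copy())


# ---------------------------------------------------------------------------
# parsers


def parse_funcat_labels(
    rows: Sequence[tuple[str, str]],
) -> tuple[AnnotationMatrix, LabelHierarchy]:
    """Build an annotation matrix and the implied hierarchy from dotted IDs.

    Every prefix of a dotted identifier is added to the hierarchy ("01.03.02"
    implies "01.03" and "01").  The returned matrix records only the stated
    associations; apply :func:`true_path_closure` separately.  Duplicate rows
    collapse silently.
    """
    parents: dict[str, set[str]] = {}
    proteins: list[str] = []
    seen_proteins: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for idx, (protein, label) in enumerate(rows):
        try:
            chain = _funcat_chain(label)
        except OntologyError as exc:
            raise OntologyError(f"row {idx} ({protein!r}, {label!r}): {exc}") from None
        for lab, par in chain:
            parents.setdefault(lab, set())
            if par is not None:
                parents[lab].add(par)
        if protein not in seen_proteins:
            seen_proteins.add(protein)
            proteins.append(protein)
        pairs.add((protein, label))
    hierarchy = LabelHierarchy(parents)
    labels = sorted(hierarchy.labels)
    Y = np.zeros((len(proteins), len(labels)), dtype=np.int8)
    pidx = {p: i for i, p in enumerate(proteins)}
    lidx = {l: k for k, l in enumerate(labels)}
    for protein, label in pairs:
        Y[pidx[protein], lidx[label]] = 1
    return AnnotationMatrix(proteins, labels, Y), hierarchy


def annotations_from_rows(
    rows: Sequence[tuple[str, str]],
    hierarchy: LabelHierarchy,
    extra_proteins: Sequence[str] = (),
) -> AnnotationMatrix:
    """Assemble an annotation matrix against an existing hierarchy.

    Columns cover the labels seen in *rows* plus all their ancestors (so the
    matrix can be true-path closed in place).  *extra_proteins* adds
    unannotated proteins (e.g. network nodes without labels) as all-zero
    rows.  Labels absent from the hierarchy are an error.
    """
    unknown = sorted({l for _, l in rows if l not in hierarchy})
    if unknown:
        raise OntologyError(f"labels not in hierarchy: {unknown}")
    label_set: set[str] = set()
    for _, l in rows:
        label_set.add(l)
        label_set |= hierarchy.ancestors(l)
    labels = sorted(label_set)
    proteins: list[str] = []
    seen: set[str] = set()
    for p, _ in rows:
        if p not in seen:
            seen.add(p)
            proteins.append(p)
    for p in extra_proteins:
        if p not in seen:
            seen.add(p)
            proteins.append(p)
    Y = np.zeros((len(proteins), len(labels)), dtype=np.int8)
    pidx = {p: i for i, p in enumerate(proteins)}
    lidx = {l: k for k, l in enumerate(labels)}
    for p, l in rows:
        Y[pidx[p], lidx[l]] = 1
    return AnnotationMatrix(proteins, labels, Y)


def parse_obo(obo_text: str | _io.TextIOBase, namespace: str | None = None) -> LabelHierarchy:
    """Parse an OBO 1.2 ontology into a :class:`LabelHierarchy`.

    Only ``is_a`` edges define the parent relation; other relationship types
    (``part_of`` etc.) are ignored.  Obsolete terms are excluded.  When
    *namespace* is given, only terms of that namespace are retained; an
    unknown namespace yields an empty hierarchy with a warning.
    """
    import obonet

    if isinstance(obo_text, str):
        obo_text = _io.StringIO(obo_text)
    graph = obonet.read_obo(obo_text)  # skips obsolete terms by default
    keep: set[str] = set()
    for node, data in graph.nodes(data=True):
        if namespace is None or data.get("namespace") == namespace:
            keep.add(node)
    if namespace is not None and not keep:
        warnings.warn(f"no terms in namespace {namespace!r}; hierarchy is empty")
        return LabelHierarchy({})
    parents: dict[str, set[str]] = {t: set() for t in keep}
    # obonet edges point child -> parent with the relation as the edge key
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and child in keep and parent in keep:
            parents[child].add(parent)
    return LabelHierarchy(parents)


# ---------------------------------------------------------------------------
# true path rule


def true_path_closure(Y: AnnotationMatrix, hierarchy: LabelHierarchy) -> AnnotationMatrix:
    """Propagate every annotation to all ancestor labels.

    Returns the minimal superset of the input satisfying the true path rule;
    idempotent.  Labels present in ``Y`` but absent from the hierarchy are an
    error.
    """
    missing = [l for l in Y.labels if l not in hierarchy]
    if missing:
        raise OntologyError(f"labels not in hierarchy: {sorted(missing)}")
    lidx = {l: k for k, l in enumerate(Y.labels)}
    closed = Y.Y.astype(bool)
    for label in Y.labels:
        anc_cols = [lidx[a] for a in hierarchy.ancestors(label) if a in lidx]
        if anc_cols:
            col = closed[:, lidx[label]]
            closed[np.ix_(np.flatnonzero(col), anc_cols)] = True
    return AnnotationMatrix(list(Y.proteins), list(Y.labels), closed.astype(np.int8))


def leaf_labels_of_protein(
    Y: AnnotationMatrix, hierarchy: LabelHierarchy, protein: str
) -> frozenset[str]:
    """Labels of *protein* with no annotated descendant for that protein.

    Leafness is per protein: a label with children in the hierarchy is still
    a leaf for a protein none of whose annotated labels descend from it.
    Expects a true-path-closed matrix.
    """
    labels = Y.labels_of(protein)
    return frozenset(
        l for l in labels if not (hierarchy.descendants(l) & labels)
    )


# ---------------------------------------------------------------------------
# relationship statistics


def conditional_probability(Y: AnnotationMatrix, label: str, given: str) -> float:
    """P(protein has *label* | protein has *given*) by member-count ratio."""
    given_members = Y.members(given)
    if not given_members:
        raise OntologyError(f"label {given!r} has no member proteins")
    return len(Y.members(label) & given_members) / len(given_members)


def relationship_statistics(
    Y: AnnotationMatrix,
    hierarchy: LabelHierarchy,
    drop_zeros: bool = True,
) -> pd.DataFrame:
    """Parent/grandparent/uncle conditional probabilities per label.

    For every label *s* and each of its parents, grandparents and uncles,
    one row gives the conditional probability that a protein carrying the
    relative also carries *s* (member-count ratio).  On closed annotations
    p(s|par) >= p(s|gpar) along each parent path, since members of a parent
    are a subset of the members of its own parents.  Relatives with no
    member proteins are skipped; zero probabilities are dropped by default,
    matching how the distributions are usually summarised.

    Returns a DataFrame with columns ``label``, ``relation``
    (``parent``/``grandparent``/``uncle``), ``relative``, ``probability``.
    """
    records: list[tuple[str, str, str, float]] = []
    member_cache: dict[str, frozenset[str]] = {}

    def members(l: str) -> frozenset[str]:
        if l not in member_cache:
            member_cache[l] = Y.members(l) if l in Y._label_index else frozenset()
        return member_cache[l]

    for s in Y.labels:
        if s not in hierarchy:
            continue
        ns = members(s)
        for relation, relatives in (
            ("parent", hierarchy.parents(s)),
            ("grandparent", hierarchy.grandparents(s)),
            ("uncle", hierarchy.uncles(s)),
        ):
            for rel in sorted(relatives):
                nr = members(rel)
                if not nr:
                    continue
                p = len(ns & nr) / len(nr)
                records.append((s, relation, rel, p))
    df = pd.DataFrame(records, columns=["label", "relation", "relative", "probability"])
    if drop_zeros and len(df):
        df = df[df["probability"] > 0].reset_index(drop=True)
    return df
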