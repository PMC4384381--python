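# Methods

## Problem setting

Let `Y ∈ {0,1}^{n×K}` record which of `K` hierarchically organised function
labels are known for `n` proteins, with `y_ik = 1` meaning protein *i* is
known to carry label *k* and `y_ik = 0` meaning the association is
*unknown* (never refuted — absence of annotation is not negative evidence).
The hierarchy is a rooted tree (FunCat, dotted identifiers, parent by
prefix) or DAG (GO, `is_a` edges only), and annotations are closed under
the true path rule: `y_ik = 1` implies `y_ij = 1` for every ancestor *j* of
*k*. Under that closure the labels that can actually be missing for a
protein are its per-protein **leaf** labels (labels none of whose
descendants are annotated for that protein). The task is to score every
unknown `(i,k)` entry so that genuinely missing labels rank above truly
absent ones — for partially labeled proteins (replenishment) and for
proteins with no labels at all (de novo prediction through the network).

## Label correlation

All similarities are computed from the **training** annotation state; using
the ground truth would leak the held-out labels.

* `p(k) = |N(k)| / n`, the fraction of corpus proteins carrying *k*
  (information content `−log p(k)`).
* `LinSim(s,t) = 2 log p_ca / (log p(s) + log p(t))` with
  `p_ca = min_{k ∈ ca(s,t)} p(k)` over the common (proper) ancestors.
* `HSim` replaces `ca(s,t)` by the shared-ancestor set `sa(s,t)`, which
  additionally contains *s* itself when *s* is an ancestor of *t* (and vice
  versa). Since an ancestor is more specific than anything above it,
  `HSim ≥ LinSim` on nested pairs, with equality for siblings and cousins.
* `JcdSim(s,t) = |N(s) ∩ N(t)| / |N(s) ∪ N(t)|`.
* `ComSim(s,t) = HSim(s,t)` if `p_sa(s,t) ∈ (0,1)`, else `JcdSim(s,t)`.
  The Jaccard branch covers pairs with no shared ancestor (e.g. FunCat
  top-level categories) and pairs whose most specific shared ancestor
  annotates every protein (e.g. an ontology root) — exactly the cases where
  the information-content similarity degenerates to 0 although flat
  co-annotation may be strong.

Edge conventions (degenerate cases the formulas leave open):

* Self-similarity is defined as 1 directly for any label with at least one
  member protein. Plugging the convention "`p_ca = 1` when `s = t`" into
  the Lin ratio would yield 0, contradicting the evident intent of maximal
  self-similarity, so the diagonal is special-cased.
* If `p(s) = 0` or `p(t) = 0`: similarity 0 (no annotation evidence);
  `JcdSim = 0` when both member sets are empty.
* Logarithm base cancels in the ratio; natural log is used.
* The row normalisation `C_m(s,t) = ComSim(s,t) / Σ_{t'} ComSim(s,t')`
  runs over **all** `t'` including `t' = s` (the literal reading of the
  sum); all-zero rows stay zero.

## Estimation and the quadratic objective

For a labeled protein *i*, unknown entries are estimated by
`ỹ_ik = y_iᵀ C_m(·,k)` (clipped to `[0,1]`; known entries stay 1).
Unlabeled proteins get all-zero `ỹ` rows — they carry no evidence of their
own, and the diagonal mask `U` (1 for labeled proteins) removes them from
the empirical loss; the "first *l* proteins are labeled" convention is
presentation only, `U` is an arbitrary binary mask.

The prediction matrix minimises

```
Ψ(F) = tr((F − Ỹ)ᵀ U (F − Ỹ)) + λ tr(Fᵀ (I − W)ᵀ (I − W) F),
```

with `W` the row-normalised interaction weights (symmetrised by taking the
max of duplicate directions, zero diagonal; isolated proteins keep all-zero
rows). `Ψ` is an unconstrained convex quadratic; its gradient
`2U(F − Ỹ) + 2λ(I−W)ᵀ(I−W)F` vanishes exactly at the solution of the
normal equations `(U + λ(I−W)ᵀ(I−W)) F = U Ỹ`. These are solved by sparse
LU factorisation up to `n = 20 000`, and by conjugate gradients per label
column (tolerance 1e-10) beyond that. The system is singular precisely
when some connected network component with row-stochastic weights contains
no labeled protein (constant vectors on the component are in the kernel of
both terms); this is detected up front and reported with the offending
component. No true-path post-processing is applied to `F`.

`λ` (default 1.0) balances fidelity to the estimated entries against
network smoothness. As `λ → 0` with all proteins labeled, `F → Ỹ`; as `λ`
grows the smoothness `tr(FᵀMF)` at the solution is non-increasing. The
default is a declared choice, not a fitted value.

Variants: `pill`, `pill_hsim`, `pill_lin`, `pill_jcd` differ only in the
correlation kind; `pill_fc` returns `F = Ỹ` (no network); `pill_gba`
solves the objective with `Ỹ` replaced by the raw `Y`; `naive` assigns
every protein the label-frequency vector of the labeled proteins.

## Synthetic benchmark generator

No public corpus records which labels are missing, so incomplete annotation
is simulated on synthetic data whose structure mirrors the curated
yeast benchmarks this class of methods is evaluated on.

* **Taxonomy** — a FunCat-style forest of 10 top-level categories, each a
  random subtree (depth 4, child counts uniform in [1,2]); there is no
  annotated universal root, so top-level categories share no ancestor.
  Random trees with uniform child counts have heavy-tailed sizes, so forest
  sub-seeds are redrawn until the label count lands in a 45–90 band,
  keeping problem sizes comparable across seeds (~60–85 labels). A
  single-rooted GO-style mode (with an unannotated universal root and
  optional multi-parent DAG edges) is also available.
* **Annotations** — each protein performs 1–5 top-down random walks
  (descend to a uniform child with probability 0.75); the closure of the
  walk paths is the protein's label set (~6–7 labels per protein, matching
  curated corpora at 6.5–8 labels). Real corpora show strong flat
  co-annotation between categories with no shared ancestor — in yeast
  FunCat over half the CELL FATE proteins also carry CELL TYPE
  DIFFERENTIATION — so top-level categories are paired into co-functional
  partners: each walk after the first starts in the partner of the
  protein's first category with probability 0.7, and replays the first
  walk's child choices (with an independently drawn stopping depth), so
  specific deep terms co-occur across partner categories. Measured partner
  conditional probabilities land at 0.55–0.66, the regime of the published
  yeast statistic (62.5%). A configurable fraction of proteins can remain
  label-free, mirroring networks that keep unannotated proteins for
  structure.
* **Network** — 2000 weighted edges over 300 proteins (mean degree ~13, as
  in curated co-complex networks). Pairs are sampled with probability
  proportional to `homophily · Jaccard(labels) + (1−homophily) · J̄`,
  where `J̄` is the mean pairwise Jaccard; anchoring the uniform component
  at the background co-annotation level makes `homophily` the fraction of
  edge probability mass attributable to label sharing (1 → only
  label-sharing pairs, 0 → uniform). Edge weights are the mixing scores
  rescaled to `(0,1]`.
* **Masking** — per protein, `m` rounds of removing one uniformly chosen
  *current* leaf label, recomputing the leaf set after every removal (a
  parent whose annotated children are all masked becomes maskable), never
  removing the last remaining label. The masked matrix therefore stays
  true-path closed, and `N_m` counts all removals.

What the generator does **not** model: PPI false-positive structure and
degree heterogeneity, evidence-code reliability, label-frequency skew
beyond what the walk process induces, and rich overlapping functional
modules (co-annotation here is a single partner pairing). Passing the
synthetic benchmark shows the pipeline recovers planted structure of this
kind; it does not by itself establish performance on any curated corpus.

## Evaluation

Metrics are computed on an explicit `(protein, label)` scope: for
replenishment, the entries unknown at training time on labeled proteins
(masked entries are the positives, the other unknowns negatives — entries
fixed to 1 by the estimator are excluded); for the unlabeled-protein task,
every entry of the held-out proteins (70/30 split, training side masked at
`m = 3`).

* **AvgROC** — mean per-label AUC over labels with both classes in scope.
* **1−RankLoss** — one minus the mean over proteins of the fraction of
  (positive, negative) pairs ranked discordantly; ties count one half.
* **Fmax** — max over the 101-point threshold grid {0.00, 0.01, …, 1.00}
  of the protein-averaged F1 (protein-centric); proteins without positives
  in scope are skipped.
* **MicroF1 / MacroF1** — on binarised predictions. Default binarisation
  is an oracle top-*r* cut per protein (*r* = that protein's in-scope
  positive count), a common convention in the weak-label literature; a
  fixed-threshold mode is available. Labels with a single class in scope
  are dropped from label-centric metrics.
* Repeated runs report mean ± sample (n−1) standard deviation.

## Numerical and design notes

* Similarity matrices are exact (no sampling); the pairwise loop uses
  precomputed ancestor sets and vectorised Jaccard; tests check agreement
  with an independent path-walking enumeration to 1e-12.
* The solver's relative residual `‖(U+λM)F − UỸ‖/‖UỸ‖` is reported with
  every run and asserted below 1e-8 in tests; the closed form agrees with a
  generic numerical minimiser of the objective to 1e-6 on small instances.
* Duplicate annotation rows collapse silently; protein identifiers are
  case-sensitive opaque strings.
* GO input uses `is_a` edges only (`part_of` and other relations are out of
  scope); obsolete terms are dropped; namespace filtering is available.
* For sibling/uncle statistics, top-level labels are treated as siblings
  under a virtual root (so a top-level category can be an uncle of another
  category's child); the virtual root never appears in ancestor sets or
  annotations.
* On closed annotations `p(s|par(s)) ≥ p(s|gpar(s))` holds exactly along
  each parent path (member sets are nested); the uncle inequality
  `p(s|gpar) ≥ p(s|uncle)` is reported but not asserted, since it is an
  empirical tendency rather than a theorem.

## Known limitations

* With a strongly homophilous network (homophily 0.8), the smoothness term
  alone resolves most of the cases where the correlation kinds differ, so
  `pill`, `pill_hsim` and `pill_jcd` score within ~0.003 AvgROC of each
  other on the synthetic benchmark; the correlation choice matters more
  when the network is sparse, noisy, or down-weighted (small `λ`). On
  curated corpora with noisier networks and richer co-annotation structure
  the combined similarity is the safer default.
* The estimator propagates no information *to* unlabeled proteins except
  through the network; a protein in a network component without any
  labeled protein is unscorable (and reported as such).
* Scores are not true-path consistent by construction; consumers who need
  consistent sets should apply their own reconciliation.
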