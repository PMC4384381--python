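# pill

Protein function prediction from **incomplete hierarchical labels**.

Curated annotation corpora are incomplete: a protein known to perform
`01.03` (nucleotide metabolism) may well perform `01.03.02` without anyone
having recorded it yet. Because FunCat is a tree and the Gene Ontology a
DAG, and both obey the *true path rule* (a label implies all its
ancestors), the labels that go missing in practice are the **leaf** labels
of each protein. `pill` replenishes those missing labels for partially
annotated proteins and predicts functions for entirely unannotated
proteins, using two complementary sources of evidence:

1. **Label correlation.** A combined similarity `ComSim` between function
   labels *s*, *t*:

   - information-content (Lin-style) similarity over *shared* ancestors,

     `HSim(s,t) = 2 log p_sa(s,t) / (log p(s) + log p(t))`,
     `p_sa(s,t) = min_{k in sa(s,t)} p(k)`,

     where `sa(s,t)` also contains *s* itself when *s* subsumes *t* (making
     `HSim >= LinSim` on ancestor–descendant pairs), and `p(k)` is the
     fraction of corpus proteins annotated with *k*;
   - the Jaccard coefficient `|N(s) ∩ N(t)| / |N(s) ∪ N(t)|` of the
     member-protein sets whenever `p_sa` falls outside `(0,1)` — i.e. for
     label pairs with no (informative) shared ancestor, where flat
     co-annotation is the only evidence.

   With the row-normalised correlation matrix
   `C_m(s,t) = ComSim(s,t) / Σ_t' ComSim(s,t')`, unknown entries of a
   labeled protein are estimated as `ỹ_ik = y_iᵀ C_m(·,k)`.

2. **Guilt by association.** Interacting proteins tend to share functions,
   so the final scores `F` minimise the convex quadratic

   `Ψ(F) = tr((F−Ỹ)ᵀ U (F−Ỹ)) + λ tr(Fᵀ(I−W)ᵀ(I−W)F)`,

   where `U` masks the labeled proteins and `W` is the row-normalised PPI
   weight matrix. The minimiser solves
   `(U + λ(I−W)ᵀ(I−W)) F = U Ỹ` exactly (sparse factorisation;
   conjugate gradients per label at very large n).

Ablation variants (`pill_lin`, `pill_hsim`, `pill_jcd` for the correlation
kind; `pill_fc` without the network term; `pill_gba` without the
estimation; `naive` frequency ranking) are built in, as are the five usual
evaluation metrics (MicroF1, MacroF1, AvgROC, 1−RankLoss, Fmax) computed on
an explicit masked-entry scope, and a synthetic benchmark generator
(FunCat-like taxonomy, true-path-closed annotations with realistic flat
co-annotation, homophilous weighted network, dynamic leaf masking).

## Worked example

```python
from pill import (build_weights, evaluate, make_dataset, mask_leaf_labels,
                  run_variant)

ds = make_dataset(seed=0)                       # 300 proteins, ~70 labels
masking = mask_leaf_labels(ds.Y_true, ds.hierarchy, m=3, seed=1000)
print("masked entries:", masking.N_m)

W = build_weights(ds.edges, ds.Y_true.proteins)
Y = masking.Y_masked
labeled = Y.Y.sum(axis=1) > 0
scope = (Y.Y == 0) & labeled[:, None]           # entries unknown at training
for variant in ("pill", "pill_gba", "naive"):
    r = run_variant(variant, Y, ds.hierarchy, W, labeled, lam=1.0)
    auc = evaluate(r.F, ds.Y_true, scope, ("AvgROC",))["AvgROC"]
    print(f"{variant:9s} masked-entry AvgROC = {auc:.3f}")
```

prints

```
masked entries: 794
pill      masked-entry AvgROC = 0.908
pill_gba  masked-entry AvgROC = 0.808
naive     masked-entry AvgROC = 0.500
```

794 of the 1877 true annotations were hidden; ranking every unknown
(protein, label) entry, the full model retrieves the hidden ones with
per-label AUC 0.91 on average, the network-only ablation reaches 0.81, and
frequency ranking is at chance (every protein gets identical scores, so no
label column has any ordering).

The same workflow is available from the shell:

```sh
pill simulate --seed 0 -o fixture/
pill replenish --annotations fixture/annotations.tsv \
               --network fixture/network.tsv -o out/
pill bench-replenish --seed 0 --variants all -o bench.tsv
```

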