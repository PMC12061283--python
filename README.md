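# gliorisk

Discovery of shared intra-tumor expression programs in multi-patient
glioma scRNA-seq, and marker-based survival stratification of bulk
cohorts.

Lower-grade gliomas (LGG) frequently progress to glioblastoma, and the
malignant-cell states driving that progression are visible as recurrent
co-expression programs across patients' tumors. `gliorisk` implements, as
a reusable and fully tested pipeline, the analysis recipe used to find
such a high-risk state and turn it into a prognostic score:

1. **Preprocessing** — library-size log-normalization, marker-based cell
   typing (GFAP/PTPRZ1 glioma, CD3D/CD3E T, MOG oligodendrocyte, CD68
   macrophage, RGS5 pericyte, PECAM1 endothelium), and a moving-average
   copy-number burden score relative to immune/stromal reference cells.
2. **Program discovery** — per-tumor NMF (rank 10, Frobenius loss, best of
   5 restarts) on the centered, negative-clipped glioma submatrix; each
   factor is a program summarized by its top-100 weighted genes. Programs
   from all tumors are meta-clustered into biological clusters by
   average-linkage hierarchical clustering on the pairwise Jaccard index
   `J(A, B) = |A ∩ B| / |A ∪ B|` of their top-gene sets.
3. **Bulk integration** — subpopulation proportions in bulk RNA-seq are
   estimated by simplex-constrained non-negative least squares against
   single-cell reference profiles; the cluster whose proportion best
   separates survival (worse outcome in the high group) is the high-risk
   cluster, and its markers are the cluster-exclusive top genes ranked by
   correlation with the estimated cluster proportion.
4. **Risk stratification** — the per-sample risk score is the mean of the
   markers' per-gene z-scored log expression; patients split at the
   cutpoint minimizing the log-rank p within the 10th–90th score
   percentiles, characterized by Kaplan–Meier curves, the log-rank test,
   multivariate Cox (with VIF/tolerance collinearity diagnostics) and ROC
   AUC.
5. **Signature scoring** — UCell-style rank-based per-cell scores
   (Mann–Whitney U with a rank ceiling) for gene sets, including the
   packaged 15-gene hypoxia signature, with Mann–Whitney/Kruskal–Wallis
   group comparison.

Because the cohorts such a study draws on are restricted-access, the
package includes a first-class synthetic-cohort generator
(`gliorisk.simulate`) that plants the full ground truth — cell types,
eight glioma co-expression programs, a high-risk program with three
designated marker genes and elevated hypoxia activity, an arm-level copy
gain, and bulk cohorts with survival driven by the high-risk fraction —
so every stage can be validated end to end. See `docs/methods.md` for the
generative model and all design choices.

## Worked example

```python
import gliorisk as gr

sc = gr.generate_sc_cohort(gr.SimConfig(seed=0))          # 2000 cells x 2000 genes
bulks = {
    "tcga_like": gr.generate_bulk_cohort(sc, 500, seed=11),
    "cgga_like": gr.generate_bulk_cohort(sc, 420, seed=22),
}
res = gr.run_pipeline(sc, bulks, seed=0)

print(len(res.programs), res.clusters.n_clusters)
for name, mr in res.markers.items():
    print(name, mr.selected)
m = res.risk_models["tcga_like"]
print(f"log-rank p={m.logrank_p:.2e}  AUC={m.auc:.3f}  "
      f"HR(score)={m.cox.loc['risk_score','hr']:.2f}")
print(f"hypoxia p={res.hypoxia['p']:.2e}")
```

prints

```
40 8
tcga_like ['CDC20', 'KIF20A', 'PTTG1']
cgga_like ['CDC20', 'KIF20A', 'PTTG1']
log-rank p=9.68e-14  AUC=0.598  HR(score)=1.43
hypoxia p=2.21e-32
```

Reading: the four tumors yield 40 NMF programs grouped into 8 biological
clusters; in both bulk cohorts the exclusivity/correlation procedure
ranks exactly the three planted high-risk markers on top; the high-risk
group defined by the optimal score cutpoint has significantly worse
survival with an adverse per-SD hazard ratio; and high-risk glioma cells
score significantly higher on the 15-gene hypoxia signature.

A `gliorisk` command-line interface wraps the same stages
(`gliorisk simulate sc`, `preprocess annotate`, `programs extract`,
`bulk deconvolve`, `risk stratify`, `score signature`; see `--help`).

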