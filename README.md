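# mir3d

Compact serum-miRNA biomarker panels for case/control disease prediction,
selected with the help of the 3D genome.

Circulating miRNAs are attractive early-screening biomarkers for
neurodegenerative disease, but whole-array panels are large and noisy. The
working hypothesis behind this package is that disease-relevant miRNAs are
not scattered at random in the nucleus: loci that co-localize in the 3D
genome tend to be co-regulated, so a spatial cluster of miRNA loci can be
summarized by a few well-chosen representatives. `mir3d` implements that
strategy end to end, for epigenomics researchers who want to test
3D-informed feature selection against plain correlation ranking:

1. reconstruct a 3D genome model from a binned contact matrix **C** by
   multi-restart minimization of the normalized stress
   `σ(X) = sqrt( Σ_{i<j} w_ij (‖x_i − x_j‖ − δ_ij)² / Σ_{i<j} w_ij δ_ij² )`,
   with wish distances `δ_ij = (c_ij / scale)^(−α)`;
2. map each miRNA to the model through the genome bin containing its TSS;
3. cluster the mapped miRNAs with DBSCAN (`eps = 3` in model units,
   `min_pts = 2`; noise points become standalone singleton clusters);
4. score every miRNA by Spearman correlation ρ with the 0/1 disease label
   and build four panels — all miRNAs, top-k by |ρ| (p < 0.05), miRNAs
   with 3D information, and per-cluster representatives (seats apportioned
   to clusters by largest remainder, filled by highest |ρ|);
5. evaluate each panel with leave-one-out cross-validation under SVC,
   linear and RBF SVR, and KNN regression, reporting accuracy, precision,
   recall, F1, AUPR and AUC (score cutoff 0.5 for binary calls).

A first-class synthetic-data module generates toy genomes with compact
spatial domains, Hi-C-like Poisson contacts, multi-mapped annotations, and
case/control log-normal expression whose differential signal is planted in
two spatial domains — so the whole pipeline is testable against a known
ground truth without any external download. See `docs/methods.md` for the
models and design decisions.

## Worked example

```python
from mir3d import PipelineConfig, SimConfig, EmbeddingConfig, run_pipeline
import pandas as pd

config = PipelineConfig(
    sim=SimConfig(n_case=50, n_control=50, n_mirna=150, n_informative=10,
                  n_chrom=2, bins_per_chrom=40, n_domains=10),
    embedding=EmbeddingConfig(n_restarts=5, max_iter=300),
    seed=1,
)
run_pipeline(config, "demo")
metrics = pd.read_csv("demo/metrics.csv")
print(metrics[["panel", "n_features", "model", "accuracy", "f1", "aupr", "auc"]]
      .round(3).to_string(index=False))
```

prints

```
     panel  n_features          model  accuracy    f1  aupr   auc
       all         133            svc      0.71 0.713 0.771 0.767
       all         133     svr_linear      0.66 0.660 0.737 0.718
       all         133        svr_rbf      0.70 0.712 0.787 0.778
       all         133 knn_regression      0.63 0.641 0.605 0.660
   top_scc          17            svc      0.83 0.825 0.923 0.919
   top_scc          17     svr_linear      0.85 0.831 0.908 0.920
   top_scc          17        svr_rbf      0.81 0.800 0.921 0.918
   top_scc          17 knn_regression      0.79 0.769 0.810 0.849
overlap_3d         133            svc      0.71 0.713 0.771 0.767
overlap_3d         133     svr_linear      0.66 0.660 0.737 0.718
overlap_3d         133        svr_rbf      0.70 0.712 0.787 0.778
overlap_3d         133 knn_regression      0.63 0.641 0.605 0.660
cluster_3d           9            svc      0.84 0.837 0.932 0.920
cluster_3d           9     svr_linear      0.82 0.791 0.911 0.931
cluster_3d           9        svr_rbf      0.84 0.830 0.925 0.914
cluster_3d           9 knn_regression      0.78 0.750 0.823 0.865
```

Reading the table: 133 of the 150 simulated miRNAs survive profiling
(internal-control normalization, low-expression and ambiguity filters).
Ten of them carry a planted case/control shift concentrated in two spatial
domains. The `cluster_3d` panel — nine per-cluster representatives chosen
from the DBSCAN clustering of the reconstructed 3D model — matches or
beats the 133-feature whole-matrix panel on every model family (e.g. SVC
AUC 0.920 vs 0.767): fewer but more discriminatory features. The run
directory also holds the panels, clustering, per-sample LOOCV predictions,
ROC/PR curve points and a reproducibility manifest.

The same pipeline is scriptable from a shell:

```sh
mir3d run-all --outdir demo --seed 1            # or: simulate / reconstruct /
mir3d evaluate --outdir demo                    # profile / select / evaluate
```

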