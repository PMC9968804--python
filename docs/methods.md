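# Methods

`mir3d` implements a 3D-genome-guided strategy for selecting compact serum
miRNA biomarker panels for case/control disease prediction, together with a
fully synthetic data generator so every stage can be validated against a
known planted truth. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## The pipeline

1. **Simulate** (or load) a binned toy genome, a ground-truth 3D structure,
   a Hi-C-like contact matrix, a miRNA TSS annotation and a case/control
   expression matrix.
2. **Reconstruct** a 3D genome model from the contacts by multi-restart
   stress minimization.
3. **Profile** the expression matrix: internal-control normalization,
   low-expression filtering, exclusion of ambiguously annotated miRNAs.
4. **Select** feature panels: whole matrix (`all`), top-k by Spearman
   correlation with the label (`top_scc`), miRNAs with 3D information
   (`overlap_3d`), and proportional per-cluster representatives of a DBSCAN
   clustering of the 3D-mapped miRNAs (`cluster_3d`).
5. **Evaluate** every panel with leave-one-out cross-validation under four
   model families (SVC, linear/RBF SVR, KNN regression) and six metrics
   (accuracy, precision, recall, F1, AUPR, AUC).

## 3D reconstruction

Contacts are converted to target ("wish") distances with the power law
`d_ij = (c_ij / scale) ** -alpha` (default `alpha = 1`). `scale` is the
expected count at unit distance; synthetic runs pass the generator's known
`contact_scale` so the model keeps the generating length units (external
data defaults to `scale = 1` and arbitrary model units). Zero-contact pairs
are capped at `cap_factor = 1.5` times the largest finite distance.

Coordinates minimize a normalized stress
`sqrt(sum w_ij (d_ij - delta_ij)^2 / sum w_ij delta_ij^2)` with weights
`w_ij = delta_ij^-q`. The default `q = 2` fits **relative** distance
errors; with sequencing-count noise, the absolute wish-distance error of a
zero/one-count long-range pair is of the order of the whole structure and
an unweighted fit (recoverable with `q = 0`) lets those pairs drown out
local geometry — in development runs unweighted fits shattered 20 true
domains into ~70 clusters, while the relative-error fit returns 18–20.

Each of `n_restarts` conformations is optimized with L-BFGS-B on the
analytic gradient; restart 0 starts from classical (Torgerson) MDS, which
lands in the global basin whenever the targets are near-Euclidean, and the
rest start from random Gaussian configurations. The minimum-stress
conformation is returned ("generate many, keep the best-matched"). The
library default is `n_restarts = 300`; the tests and the acceptance script
run 5 restarts at 100–200 bins, which this problem size does not need more
of (the Torgerson restart alone recovers exact targets to ~1e-14 RMSD).

Recovery is verified with similarity-Procrustes RMSD (optimal translation,
rotation, uniform scale, optionally reflection), implemented directly so the
test oracle is independent of the embedding path.

## Profiling

* `normalize_by_controls` divides each sample column by that sample's mean
  signal over exactly three designated internal-control miRNAs, then drops
  the control rows. The result is invariant to any positive rescaling of a
  raw sample column (bit-identical when the rescaling itself is exactly
  representable in floating point; to ~1e-15 otherwise).
* `filter_low_expression` keeps a miRNA iff its signal reaches `min_score`
  (default 5) in at least `min_samples` samples (default ~76% of the
  cohort). The source description of this filter can be parsed in two
  directions; the keep-expressed reading is the default and the literal
  complementary reading remains expressible via `reading="literal"`.
* `filter_ambiguous` keeps only miRNAs with a single uniquely flagged
  annotation record, mirroring the exclusion of precursor miRNAs that map
  to several loci.

Both row filters are idempotent and commute; normalization precedes
filtering, matching data that ship control-standardized.

## Selection

* **Scoring.** Mid-rank Spearman correlation between each miRNA vector and
  the 0/1 label, vectorized as rank-then-Pearson; two-sided p-values from
  the t approximation (exact permutation p-values are available for tiny
  cohorts). Constant vectors get rho = 0, p = 1, flagged. Ranking uses
  |rho|: up- and down-regulated miRNAs discriminate equally.
* **Clustering.** Standard DBSCAN on the miRNA <x, y, z> coordinates with
  `eps = 3` (in model units — the synthetic structure is calibrated so
  domains have diameter ~2.5 and gaps ~12 at that radius) and
  `min_pts = 2`, under which every non-isolated point is core, the
  partition equals the connected components of the eps-graph, and DBSCAN
  noise coincides exactly with "standalone" single-miRNA clusters, which
  are promoted to singleton clusters.
* **Representatives.** Seats are apportioned to clusters by
  largest-remainder in proportion to cluster size (ties: larger cluster
  first, then lexicographic id) and filled with each cluster's
  highest-|rho| members. Largest remainder is not house-monotone (the
  Alabama paradox), so no monotonicity in `m` is claimed. By default the
  member universe — and hence the sizes used for apportionment — is first
  restricted to miRNAs whose association survives Benjamini–Hochberg
  control at `p_max = 0.05` (`cluster_p_filter`, `p_adjust`); without some
  association filter, size-proportional seats merely sample the genome
  uniformly and per-cluster representatives cannot be enriched for signal.
  Plain unadjusted filtering and no filtering are both configurable.

## Evaluation

LOOCV with one held-out prediction per sample. SVC scores are the decision
margin passed through a logistic sigmoid so that 0.5 is the class
boundary; regressors are used raw. Binary calls threshold the continuous
score at 0.5. Features are z-scored inside each training fold for the SVM
families. Hyperparameters are the common library defaults (C = 1,
gamma = "scale", k = 5), declared in `ModelSpec` rather than hidden.

AUC is computed as the Mann–Whitney rank statistic (ties half-weighted),
AUPR as step-wise average precision. Precision is defined as 0 (flagged)
when no positive call is made.

Two selection protocols: `fixed_panel` reuses a panel selected once on the
full dataset — the simple protocol a workflow diagram of this kind
implies, which carries selection leakage, so a warning is logged on every
such run — and `nested`, which re-derives the panel inside every training
fold and provably never sees the held-out label (flipping it leaves the
fold's panel unchanged).

## Synthetic data: what it emulates, and what it does not

Study conditions (the `SimConfig` defaults, a desk-scale rendition of a
~1,300-sample serum cohort): 100 cases + 100 controls; 300 miRNAs, 10%
multi-mapped; a 4-chromosome, 200-bin genome folded into 20 compact
domains (random-walk backbone, step 4, compaction 0.9); contacts
`E[c] = k d^-beta` with `k = 100`, `beta = 1` and Poisson counting noise
(within-domain pairs then carry 40–250 expected counts); three
internal-control miRNAs with case-independent expectation; log-normal
background expression with per-miRNA log-means drawn once per dataset; and
20 informative miRNAs confined to the 2 most miRNA-rich domains, shifted in
cases by `effect_size` (default 1.0) log-SD units. A single seed fans out
into fixed per-stage substreams, so identical configs are bit-identical.

Not modeled: batch effects, missing values, array-specific noise,
miRNA-biogenesis structure, Hi-C normalization biases, cell-type mixtures.
Passing the planted-signal tests therefore shows the selection machinery
recovers a spatially coherent differential signal under clean assumptions —
not that any particular clinical cohort will behave this way. The
log-normal background is a modeling stand-in; the array's true signal
distribution is not described by the data source.

## Numerical choices and degenerate inputs

* Embedding: L-BFGS-B with `ftol = tol` (default 1e-12); non-convergence
  returns the best-so-far configuration with `converged=False` plus a
  warning, never an error. Coincident input points are rejected with the
  offending bin pair named.
* Spearman p at |rho| = 1 is exactly 0 (t → ∞); BH adjustment uses
  `scipy.stats.false_discovery_control`.
* Tie-breaks are deterministic everywhere (lexicographic ids) so reruns are
  bit-identical; libsvm solutions are order-dependent only within solver
  tolerance, so cross-order LOOCV agreement for SVMs is approximate
  (~1e-3) while KNN is exact.
* TSS binning is 0-based half-open; a TSS on a bin boundary belongs to the
  bin that starts there. Unknown chromosomes and out-of-range TSSs drop the
  record with a logged count, never fail the run.

## Known limitations

The fixed_panel default replicates a leakage-prone protocol by design (the
nested protocol is provided and recommended; the discrepancy is logged).
The embedding recovers geometry only up to a similarity transform, so
`eps` is only meaningful relative to the contact-to-distance calibration.
Largest-remainder seat counts can shift non-monotonically as the panel
size grows. Cohort-scale defaults are desk-scale; full-size generation is
configurable but the LOOCV grid is O(n_samples) model fits per cell.
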