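# Methods

This note records the models, conventions and design choices behind
`neurotax`, in the order the pipeline runs them.

## Synthetic data model

The generator (`neurotax.synthetic`) emulates the structure the analysis
assumes in real developmental data.  It is a stand-in: no generative model
exists for the real tissues, so the simulator aims for structural
faithfulness (branching, kinetics, batch design), not calibration to any
organism.  What passing tests show is that the pipeline recovers planted
structure under these conditions; they do not certify performance on real
data, where ambient RNA, doublets, nonlinear kinetics and shallow
sequencing add failure modes the generator deliberately omits.

**Branching trajectories.**  Each class is one branch.  A cell has a true
latent time `t ~ Uniform[0, 1]` along its branch (uniform placement avoids
artefactual density modes).  Cells with `t >= 0.8` act as annotated
terminal cells — the absorbing states for fate mapping — labelled
`T_<class>`; the true terminal fate of every developmental cell is its
branch's terminal class.

**Two-state transcription kinetics.**  Every dynamic gene follows
`du/dt = a(t) − beta·u`, `ds/dt = beta·u − gamma·s`, with transcription
`a(t)` at `base·gamma` outside the on-window `[t_on, t_off)` and
`base·gamma + alpha` inside it.  The closed-form solution (piecewise sums
of exponentials; the removable `beta = gamma` singularity is nudged by
1e-5) gives the expected unspliced/spliced abundance per cell, stored
noiselessly in the ground truth for parameter-recovery tests.  Rates are in
reciprocal latent-time units, drawn per gene uniformly within ±25% of
alpha = 14, beta = 8, gamma = 3.6, so unspliced signal leads spliced along
each branch and the steady-state ratio gamma/beta varies across genes.

**Gene programmes** (default 2,100 genes):

| programme | n | expression |
| --- | --- | --- |
| class TF code | 25/class | constant-high (level ≈ 3.5) in its branch from t = 0 |
| effector markers | 40/class | primed at base 1 in their branch, on-window with staggered `t_on ~ U(0, 0.6)` |
| species-specific class | 25 TFs + 30 markers private | plus half of the sister's TF code and the sister's markers |
| cell-cycle residue | 40 | on before t = 0, off at t = 0.12, half amplitude |
| pan-neuronal maturation | 40 | shared by all branches, staggered `t_on ~ U(0, 0.8)` |
| interneuron markers | GAD1/2, DLX1/2/5/6 | constant in every inhibitory branch, zero in the excitatory outgroup |
| mito (`MT-*`), ribo (`RPS*/RPL*`) | 25 + 80 | constant housekeeping levels |
| housekeeping + low-expression background | ~1,530 | constant lognormal levels |

The constant TF codes encode the model's central biological premise: an
initial class is *defined* by regional transcription factors present at or
before the final division, so classes are discrete from birth.  Sister
classes (the species-specific class and its designated sister) share half
of one TF code plus the sister's ramping markers, making them strongly
homologous yet separable — the hardest case for clustering and homology.
The staggered marker and maturation waves keep expression changing over the
whole trajectory, which is what makes a *shared* latent time identifiable
at all; the early-decaying cycle programme gives progenitor-like structure
and supplies the root-scoring signal.  The low-expression background block
matters for HVG selection: in real data the low-mean dispersion bins are
dominated by boring genes, and without that block the binned z-scores
mis-rank planted variable genes.

**Noise.**  Observed counts are negative binomial with gene-wise size
parameter `theta ~ U(8, 15)` (the standard overdispersion model for UMI
counts), cell library factors `~ clipped lognormal(0, 0.18)`, per-batch and
per-species lognormal gene factors (sigma 0.08 / 0.10), and an unspliced
capture factor of 0.45.

**Planted QC artifacts.**  An exact fraction of cells (default 8%) is
corrupted, cycling three modes: < 800 detected genes, > 15% mitochondrial,
> 40% ribosomal.  A deterministic repair pass then guarantees every
*unflagged* cell passes all thresholds with margin, so filter sensitivity
and specificity are well-defined quantities (1.0 is attainable, and any
miss is a pipeline bug, not sampling luck).

**Orthologues.**  Gene symbols are uppercase in the first species and
capitalised in the second; the species-specific class's private markers are
absent from the second species' annotation.  The orthologue table is
one-to-one over shared genes with 5% random dropout.

## QC conventions

Removal uses strict inequalities exactly as stated ("fewer than 800",
"greater than 40%/15%"), so a cell at any boundary is retained.  Detected
genes and fraction denominators use the spliced matrix only.  When a
per-droplet cell-probability column exists, droplets at or below 0.99 are
removed.  For the cluster-level rule, "the mean" is the dataset-wide mean
of each marker's normalized expression over all cells — the most common
reading; a per-cluster-mean alternative is not offered.  Cells of a failing
cluster that sit in exempt (ganglionic-eminence) batches are kept.

## Embedding and class merging

Depth normalization targets the median per-cell total (each layer
separately; the spliced layer is then log1p-transformed and z-scaled per
gene, clipped at ±10 to bound outlier leverage).  HVG selection is the
classic binned-dispersion scheme: per sequencing sample, dispersion =
variance/mean of log-normalized expression, z-scored within 20 equal-count
mean bins; a gene is variable in a sample at z > 0.5 and must be variable
in ≥ 2 samples.  PCA uses the seeded randomized solver.  The
batch-balanced graph takes each cell's k nearest cells *per batch*
(k = 3 by default; 12 when joining developmental and adult data), which
forces every batch into every neighbourhood.

Fine Leiden clusters (resolution 10) slice each class's trajectory into
maturation stages; assembling classes from them is manual, marker-guided
work in real studies.  Two automatic stand-ins are provided:

* **Default — trajectory continuity.**  Between-cluster connectivity =
  kNN-edge count normalized by `sqrt(n_i n_j)`; clusters are linked when
  connectivity ≥ 0.1 *and* ≥ half the weaker endpoint's strongest link (the
  second condition removes spurious bridges made of a couple of forced
  batch-balanced edges); classes are the connected components.  Rationale:
  differentiation is continuous, so consecutive stages of one class are
  densely linked while distinct classes are not; correlation of cluster
  means, by contrast, orders clusters by shared maturation stage and no
  fixed dendrogram cut separates classes reliably once a realistic shared
  maturation programme exists.
* **Explicit height.**  With `merge_distance` set, the complete-linkage
  dendrogram of Pearson-correlation distance (1 − r) between cluster mean
  scaled-expression vectors is cut at that height (0 keeps fine clusters;
  2 gives one class).  The dendrogram is always computed and exported as
  Newick.

Cluster means use the *scaled* layer so high-magnitude shared programmes do
not swamp class identity.  An explicit cluster→class TSV overrides both
paths.  Disconnected singleton clusters are reattached to the
best-correlated cluster.

## Velocity and latent time

The steady-state estimator fits, per gene, the zero-intercept slope of
unspliced on spliced over cells in the extreme 5% quantiles of spliced
abundance.  It is consistent only for genes whose sampled extremes sit at
steady state; for genes switching on late in the trajectory the top
quantile is still in transient induction and `gamma_hat` is biased — the
recovery tests therefore evaluate constant-expression, TF and
cycle-programme genes, which is the estimator's contract.  Velocity is the
residual `u − gamma_hat·s`, positive under induction, negative under
repression; all-zero-unspliced genes are flagged with zero velocity.

Latent time is a diffusion pseudotime: an adaptive Gaussian kernel on the
symmetrized graph (bandwidth = each cell's distance to its farthest stored
neighbour, making the construction invariant to global rescaling of PC
coordinates), symmetric normalization, the top 15 non-stationary
eigencomponents scaled by `lambda/(1 − lambda)`, and per-cell time = the
Euclidean diffusion distance to the nearest root, min-shifted and
max-normalized to [0, 1].  The Lanczos start vector is fixed for
determinism.  Roots default to the top 2% of cells by mean expression of
cycling markers (MKI67, TOP2A, CCNB1, CDK1, AURKA; case-insensitive
fallback for mouse-style symbols) — with several branches the progenitor
programme is shared, so every branch contributes its youngest cells — and
can be supplied explicitly.  Cells in components unreachable from the
roots get time 1.0 with a warning.

New-born calling uses the linear-interpolation empirical median per class
and a strict below-threshold comparison, so ties are never flagged and the
flags depend only on within-class ranks.

## Fate mapping

The transition matrix mixes a connectivity kernel (row-normalized
symmetrized adjacency) and a velocity kernel with weight 0.5 each.  The
velocity kernel is a per-row softmax over out-neighbours of the cosine
between the PC-space displacement and the cell's velocity projected through
the PCA loadings (restricted to HVGs); the softmax temperature self-tunes
to the row's median |cosine| (the cited fate-mapping tool does not publish
its exact scheme; the cosine-softmax preserves its documented structure).
Zero-velocity rows fall back to the connectivity row.

Absorption probabilities solve `(I − Q)X = R` with one sparse LU
factorization, after aggregating absorbing columns by terminal class and
excluding transient states that cannot reach any absorbing state (found by
BFS on the reversed support graph; such cells carry NaN rows rather than
crashing the solve).  Summaries subsample each initial class to ≤ 1,000
cells (seeded, uniform), rank transient cells per terminal class by
absorption probability with ties broken by cell identifier, and tabulate
the top 100 by initial class; the mean-absorption matrix averages over all
subsampled cells and is reported alongside to blunt compositional effects.

## Cross-species homology

The merged space is restricted to one-to-one orthologue pairs variable in
both species, concatenating the within-species scaled matrices (scaling
within species removes species-level shifts before comparison).  Mutuality
for MNN pairs is enforced on cross-species neighbour lists only (k = 25),
matching their use for cross-species class comparison; within-species
neighbours are not consulted.  Class-level homology reports both the MNN
count per class pair and the Pearson correlation of class mean vectors.  A
species-specific class is, by construction, indistinguishable from its
sister in the shared-orthologue space (its private genes are silent in the
other species and hence never variable there), so it can only be recognised
by the *asymmetry* of the table: it dominates no other-species class's MNN
column, while its best correlation points at the sister.  The number of
shared variable orthologues is data-dependent and logged per run, never
asserted.

## Trajectory-gene screen

Per class, ordinary least squares of depth-normalized log expression (not
z-scaled — scaling would destroy slope interpretability) on latent time;
two-tailed *P* from the t distribution with n − 2 df; constant genes get
slope 0 and the conservative convention P = 1.  Holm–Šidák correction is
applied within each class across genes (a `global` family is available);
the step-down form is `q_(j) = max_{i<=j} 1 − (1 − p_(i))^(m − i + 1)`,
clipped to 1.  Direction calls: activated (slope > 0, q < 0.05),
inactivated (slope < 0, q < 0.05), else null.  Gene sets are compared by
Jaccard index with the convention 0 for two empty sets.

## Reproducibility and problem sizes

All pipeline randomness flows from one root seed through named SHA-256
substreams (`derive_seed(root, stage)`), so any stage re-run in isolation
reproduces its draws; the manifest records the config snapshot, derived
seeds, checksums and timings of every output.  The demo configuration uses
450 cells per branch (~5,000 cells over both species) and 2,100 genes —
large enough that class structure, latent-time gradients and absorption
estimates are stable, while a full pipeline run plus all oracle comparisons
completes in minutes on a single CPU.  The Monte-Carlo absorption oracle
uses 200,000 vectorized walks per start state; the family-wise-error
simulation uses 200 null replicates of 2,000 genes by 40 cells.

## Known limitations

* The generator omits ambient RNA, doublets, and cell-free contamination;
  the corresponding published tools sit outside this pipeline's scope, and
  QC here only reproduces the threshold filters.
* The steady-state velocity estimator is biased for genes that never reach
  steady state within the sampled window; the full dynamical-model fit is
  deliberately out of scope.
* Automatic class merging is a stand-in for expert curation.  On real data
  with continuous class boundaries or strong batch structure the
  connectivity components can over- or under-merge; the explicit
  `merge_distance` and cluster→class map paths exist for exactly that case.
* Latent time is a diffusion pseudotime from scored roots, not a fitted
  transcriptional clock; it is only defined up to monotone transformation,
  which is why downstream consumers (new-born calling, the regression
  screen) use ranks or treat it as a regressor on one common scale.
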