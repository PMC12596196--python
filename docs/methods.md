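# Methods

## Model and assumptions

The pipeline models a reference-centered log₁₀(TPM + 1) expression matrix
X (genes × samples) as a sum of a small number of statistically
independent, sparse transcriptional signals plus noise, X ≈ M·A. Columns
of M are gene-weight vectors (one per module); rows of A are the modules'
activities across samples. The biological reading is that each robust
component tracks one regulatory signal (an iModulon), its heavy-weight
genes are the co-regulated set, and its activity row is a proxy for the
underlying regulator's condition-dependent activity. The key assumptions
are (i) co-regulated gene sets are sparse in gene space with
heavier-than-Gaussian weight tails, which is what both FastICA's
non-Gaussianity objective and the K² membership test exploit; (ii)
signals mix approximately linearly on the log scale; and (iii) batch
structure is removed by centering each project on its reference
condition, so what remains is biological signal plus roughly i.i.d.
noise.

Some sources print the factorization as M = X × A; with M carrying gene
weights (genes × K) and A activities (K × samples), the dimensionally
consistent form is X = M·A, which is what this package implements.

## Pipeline and parameters

1. **Normalization** (`expression`). Raw TPM → log₁₀(TPM + 1)
   (pseudocount 1; log2 conversions only at reporting time, factor
   log₂10). Centering subtracts, per project, the per-gene **mean** of
   that project's reference samples; it is idempotent and removes any
   per-gene constant. Zero-variance genes are carried through
   normalization but dropped (with a logged warning) before ICA, since
   whitening needs non-degenerate rows, and are rejected in correlations.
2. **Ensemble ICA** (`ica`). FastICA (scikit-learn, logcosh contrast,
   PCA whitening to the requested dimension), default 100 runs with
   seeds `seed..seed+n_runs−1`, tolerance 10⁻⁷, max 1000 iterations.
   Genes are observations, samples features, so sources are gene-weight
   vectors. Components are unit-L2, sign-oriented so the top-|weight|
   gene is positive. Non-convergent runs are dropped, not retried —
   reproducibility over completeness; the manifest records them.
3. **Consensus clustering**. DBSCAN over pooled components under
   d = 1 − |ρ|, ε = 0.1, `min_samples` = minimum cluster seed size = 50
   (i.e. a component family must recur in at least half of 100 runs; at
   smaller ensemble sizes use half the run count). Cluster centroid:
   members are sign-aligned to the cluster medoid (the member closest to
   all others), averaged, re-normalized — deterministic and invariant to
   run order and sign flips. Activities are refit by ordinary least
   squares of centered X on the consensus M, which makes explained
   variance (1 − ‖X − M·A‖²_F/‖X‖²_F) well defined; explained variance
   is monotone non-decreasing in the component subset when A is refit
   per subset.
4. **Dimensionality** (`dimension_sweep`). Default grid 20–300 step 20.
   For each dimension the ensemble + clustering is run and two counts
   recorded: robust components K and non-single components (those whose
   thresholding keeps > 1 member). The optimum is the largest dimension
   with K equal to the non-single count; "single" is judged after K²
   thresholding, matching the single-gene module category. If no
   dimension qualifies, the dimension maximizing K − |K − non-single| is
   returned with a warning. Only robust clusters count toward K; DBSCAN
   noise points do not. In practice, past the useful dimensionality
   FastICA increasingly fails to converge and K collapses — the
   diagnostics table makes this visible.
5. **Membership** (`membership`). Iteratively strip the gene(s) of
   largest |weight| — ties stripped together, making the result
   order-independent — and recompute the D'Agostino K² statistic of the
   **signed** remaining weights until it falls below the cutoff. The
   threshold is the largest remaining |weight|; membership is invariant
   to a global sign flip. An exactly constant remainder counts as
   K² = 0 (relevant for exactly sparse synthetic weight vectors); if
   fewer than 20 genes remain before the cutoff is met the component is
   flagged degenerate. The default cutoff is 550 on a cutoff grid of
   100–2000 (step 50). Note the K² statistic saturates on short vectors
   (a few hundred entries barely exceed ~100–500 even with extreme
   outliers), so the default is calibrated for transcriptome-scale
   (~4000-gene) vectors; benchmarks on smaller gene universes should
   scale the cutoff down. With a TRN available, `optimize_cutoff` picks
   the grid value maximizing the mean best-match F1 between thresholded
   member sets and curated regulons (ties to the lowest cutoff) — F1
   balances detecting regulon members against false members, the stated
   intent of cutoff optimization in this workflow. Category labels
   (8-label vocabulary: PULs, Uncharacterized, ECF-σ, Metabolism,
   Structural components, Functional, Stress, Single gene) are manual
   curation supplied via config, not computed.
6. **Enrichment** (`enrichment`). One-sided over-representation p-value
   per (component, regulator) pair, computed as the hypergeometric tail
   (identical to Fisher's exact, greater); background universe = all
   genes in the expression matrix, matching the decomposition's gene
   space. Benjamini–Hochberg adjustment is applied jointly across all
   pairs (the FDR procedure is unnamed in common usage; BH is the field
   default). Each component reports its best regulator (lowest q, ties
   to larger overlap then lexicographic id); regulatory flag at
   q < 10⁻⁴, term-level enrichments use 10⁻². Only single regulators are
   tested, no AND/OR combinations, and only over-representation.
   Quadrants: inclusive 0.7 cut on (iModulon recall, regulon recall) —
   some figure legends phrase the two recalls ambiguously; the
   implemented definitions (overlap/|iModulon|, overlap/|regulon|)
   follow the iModulon literature and make "regulon subset" mean the
   iModulon is a subset of a larger regulon. TRN expansion counts each
   (enriched regulator, member gene) pair once; the expanded network
   size is |known associations| + novel pairs, and the expansion
   fraction is novel/|known|.
7. **Activities** (`activity`). Ward-linkage hierarchical clustering of
   activity rows under Euclidean distance; differential activity via
   Welch's two-sample t-test (the pooled-variance test is available by
   flag; Welch is the safer default for heteroscedastic activities —
   p-values are uniform under the null by construction and are
   BH-adjusted only by batch callers). Zero-variance degenerate groups
   yield p = 1 when means agree. Per-component explained variance is
   marginal (single-component least-squares reconstruction); correlated
   components can make marginal shares sum to more than the joint
   explained variance, which is reported, not forced.

## Synthetic benchmark

`simulate.generate` emulates the structure the method assumes: K sparse
modules with weight magnitudes |N(effect, effect/5)| and random signs
(background exactly zero), each active at level 1 in a contiguous block
of non-reference conditions with N(0, 0.1) jitter, on top of a per-gene
baseline Uniform(0.5, 3.5), plus i.i.d. Gaussian noise. Default study
conditions: 4000 genes × 200 samples, 20 disjoint modules of 10–50
genes, effect 5, noise 0.25 (signal-to-noise 20). Samples group into
replicate conditions (2 per condition) within 2 projects; each project's
single reference condition carries 10 replicates. The replication of the
baseline matters: centering subtracts the reference-sample mean, and a
poorly estimated reference re-injects correlated noise of rank equal to
the project count, which at the planted dimension can displace weak
modules. Heavily replicated baselines are standard compendium design and
keep the centered matrix close to M*·A* + noise. A global constant shift
keeps the stored matrix non-negative (log-TPM semantics); any per-gene
constant vanishes under centering.

The planted TRN labels each module's regulon by the overlap geometry it
creates against a perfectly recovered module: `exact` (regulon = module
→ well-matched), `extended` (regulon ⊃ module, +60% extra targets →
regulon subset), `partial` (regulon = half the module →
unknown-containing), plus `unrelated` regulators drawn from background
genes. `match_components` scores recovery by greedy one-to-one matching
on |ρ| (default floor 0.8) and thresholded-membership F1.

What the generator does **not** emulate: count-level sampling noise
(simulation starts at log-TPM, not negative-binomial reads), gene–gene
correlation within the background, overlapping regulatory programs
(module overlap is available but defaults to 0), and compositional or
library-size artifacts. Passing the benchmark therefore demonstrates
correctness of the algorithmic chain under the model's own assumptions,
not robustness to every artifact of real RNA-seq data.

## Numerical choices and degenerate inputs

Fixed seeds everywhere: ensemble seeds default to `seed..seed+n_runs−1`
and are recorded in the manifest; the generator is bitwise reproducible
from its seed. Distances are clipped to [0, 2] before DBSCAN; clusters
are reported in a canonical order (decreasing support, then top-weight
gene position) so output is independent of run order. K = 0 (no robust
component) is a valid, logged outcome — pure-noise input typically gets
there via FastICA non-convergence at any dimension. Tiny instances
(≈10 observations) need a looser ICA tolerance (10⁻⁶) to converge.
Correlation operations reject zero-variance inputs; enrichment rejects
empty member sets; duplicated (regulator, target) pairs and targets
outside the gene universe are rejected at TRN construction.

## Problem sizes used in tests and the acceptance script

Desk-scale runs keep the full pipeline verifiable quickly: recovery at
4000 × 200 with a 25-run ensemble at the planted dimension (minimum
cluster size 12 ≈ half the runs, mirroring 50-of-100), the sweep on
1500 × 80 with 8 modules over {4, 8, 16} with 15 runs, quadrant checks
at 1200 × 100 noise-free, and 1000-replicate null calibrations. The
published-scale configuration (100 runs, dimension grid to 300,
DBSCAN 0.1/50) is the package default and is exercised against a real
compendium when one is supplied under `data/compendium/`.

## Known limitations

- The activity matrix from least-squares projection is unregularized;
  strongly correlated consensus components can trade activity between
  each other (marginal explained-variance shares make this visible).
- DBSCAN border-point assignment can in principle depend on input order
  for clusters separated by less than ε; with ε = 0.1 and the tight
  clusters that recur across ICA runs this has not been observed.
- The K² cutoff is a single global scalar; its scale depends on the
  gene-universe size (see above), and no per-component adaptation is
  attempted.
- Category assignment is curation-driven by design; the pipeline ships
  no automatic functional labeling.
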