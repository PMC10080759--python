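# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Synthetic community model

Latent per-sample log-abundances are multivariate normal under a Gaussian
copula. The correlation matrix is factor-structured: one factor per planted
module plus a shared background factor, so that

- members of a module correlate at `rho_within` (default 0.7),
- any two taxa correlate at least at `rho_between` (default 0.05),
- each connector taxon loads on ≥ 3 module factors so its correlation with
  every member of its target blocks is exactly `rho_connector`
  (default 0.4). Connectors claim disjoint block sets while blocks
  outnumber them; overlapping targets correlate the connectors with each
  other and encourage spurious module merging downstream.

The factor construction is positive definite by construction — no
nearest-PD projection step is needed — and parameter combinations whose
implied idiosyncratic variance would be negative are rejected with an
actionable message (shrink `rho_between`/`rho_connector`).

Counts are multinomial draws of the softmax-normalised latent
log-abundances at a fixed sequencing depth (default 50,000 reads), so
column sums are depth-exact. A Dirichlet-multinomial overdispersion layer
is available (`overdispersion`) and off by default: the downstream methods
work on ranks and relative abundances and are insensitive to this choice.

Group structure: two balanced groups (default n = 10 + 10, mirroring a
high- vs low-growth contrast). Differential taxa receive a natural-log
shift `delta` (alternating signs) in group H, applied to the latent layer
before count sampling. Differential taxa are drawn from the background
(non-module, non-connector) taxa so planted effects stay orthogonal to
planted correlation structure.

Scale parameters: baseline log-abundances are N(0, 1.5) (≈ 3 orders of
magnitude of abundance spread, as in real genus tables), and the marginal
latent spread across animals is `latent_sd = 0.4`, making the default
`delta = 1.0` a 2.5-standard-deviation shift — a strong but realistic
signature for taxa that differ between extreme growth-rate groups. These
two values anchor all power properties of the test suite.

Traits are noisy linear read-outs of standardised latent abundances
(`trait = Σ w_j z_j + ε`). The default couplings mimic the study design
this emulates: growth rate follows the differential taxa, SCFA traits
follow the first module, serum IgG runs opposite to the growth-associated
taxa.

What the generator does **not** emulate: taxonomic mis-assignment,
sequencing-depth variation between samples, zero-inflation beyond
multinomial sampling, phylogenetic correlation, or longitudinal structure.
Passing tests therefore demonstrate correctness of the inference chain
under a clean compositional count model, not robustness to every artefact
of real amplicon data.

## RMT threshold selection

The similarity matrix is |Pearson r| of log10-transformed relative
abundances (pseudocount = half the smallest nonzero proportion; raw
proportions would let the few most abundant taxa dominate every
correlation). Zero-variance taxa are excluded with a warning.

For each candidate threshold (grid 0.30–0.95, step 0.01) entries below the
cut are zeroed, the diagonal kept. Connected components smaller than 5
taxa are excluded from the spectrum: near fragmentation the surviving
correlations concentrate just above the cut-off and tiny cliques contribute
quasi-degenerate trivial eigenvalues that reflect the thresholding, not the
community. Scan points with fewer than `n_min = 50` remaining taxa are
unusable.

Eigenvalues are unfolded with a cubic least-squares spline fitted to the
empirical cumulative spectral count, interior knots at eigenvalue quantiles
(≈ 20 knots, fewer for small spectra). Knot count sets the smoothing
scale: enough knots to follow the spectral density, while too many would
let the spline chase individual level fluctuations and compress the
spacings. Gaussian broadening of the cumulative count is available as an alternative
unfolding.

Unfolded spacings are tested against both limit laws by chi-square
goodness of fit — Poisson `P(d) = e^(−d)` and the Wigner surmise
`P(d) = (πd/2)·e^(−πd²/4)` — on bins of width 0.1 over [0, 3] with a
pooled tail; adjacent bins are merged until every expected count reaches 5.
Both laws are fully specified (unit mean is enforced by unfolding), so
dof = bins − 1.

**Selection rule.** The chosen threshold is the lowest candidate that is
not rejected against Poisson (p > 0.05) and for which at least 75% of that
candidate and all higher usable candidates are likewise not rejected. The
75% tolerance absorbs the test's own ~5% false rejections along the scan
plus residual fragmentation artefacts; requiring literal non-rejection at
every higher candidate fails on most finite-sample matrices. If no
candidate qualifies the scan errors out, advising a wider grid or more
samples — that is the expected outcome on pure-noise data.

Networks are built at the selected threshold with edges where |r| ≥
threshold **and** the per-edge Pearson p < 0.05 (switchable off); edges
keep the signed correlation for export, and isolated taxa are dropped and
listed.

## Modules and keystone roles

Module separation uses fast-greedy (Clauset-Newman-Moore) modularity
maximisation on the unweighted graph, followed by a deterministic
single-node refinement sweep accepting only strictly Q-increasing moves —
plain CNM systematically misplaces border nodes between similar modules.
Modularity is computed in exact rational arithmetic internally.

Per node: degree k, within-module degree, `Zi` (z-score of within-module
degree against the node's module, **population** standard deviation, 0 for
degenerate modules so no infinities arise) and `Pi = 1 − Σ_s (k_is/k)²`
(0 for isolated nodes). Roles cut at Zi = 2.5 and Pi = 0.62, boundaries
inclusive on the peripheral side. These are the Guimerà-Amaral-style
cutoffs standard in microbial network analysis; peripheral nodes are
specialists, connectors/hubs the keystone candidates.

Module-trait association: each module's per-sample summary is the mean of
its member taxa's z-scored transformed abundances (so duplicating a member
changes nothing); a first-principal-component "eigengene" summary is
available via `summary="pc1"`. Pearson correlation by default, Spearman
available; modules with
fewer than 3 members are reported but not scored. Significance stars
follow the # / * / ** convention at P < 0.1 / 0.05 / 0.01.

## Screens and ordination

- Wilcoxon rank-sum: exact permutation null when n1 + n2 ≤ 12 without
  ties, otherwise normal approximation with tie and continuity
  corrections.
- Welch's t (unequal variances) for trait comparisons.
- Spearman on mid-ranks with the t-approximation p-value; missing trait
  values are deleted pairwise, never imputed.
- Benjamini-Hochberg step-up per screen family (one family = all floored
  taxa for one contrast or one trait).
- Bray-Curtis on proportions; PCoA by double-centred classical scaling with
  negative eigenvalues reported but excluded from the proportion-explained
  denominator; ANOSIM `R = (r̄_between − r̄_within)/(M/2)` with seeded
  uniform label permutation and `p = (#{R* ≥ R} + 1)/(n_perm + 1)`.

## Random-forest biomarker panel

MDA follows the R `randomForest` convention: per tree, out-of-bag accuracy
minus OOB accuracy after permuting one feature among the OOB samples;
the score is the mean over trees divided by its standard error (raw mean if
the SE is zero). It is computed on a bagged ensemble of decision trees
(`max_features='sqrt'`, 500 trees) with explicit bootstrap bookkeeping,
because sklearn's forest does not expose per-tree OOB membership. Null
calibration was checked against R `randomForest` directly: on pure noise
both implementations select 0–3 of 15 features at MDA > 2.0, so a small
amount of false selection at that threshold is expected behaviour, not a
defect.

The feature-count curve follows the rfcv recipe: within each stratified
fold, features are ranked by forest importance on the training split only,
then refit at counts m, ⌈m/2⌉, …, 1. ROC/AUC are computed on pooled
out-of-fold class probabilities (resubstitution ROC at n = 20 would be
optimistically biased); AUC by trapezoid equals U/(n1·n2) with tie credit
0.5. Single-feature AUCs are direction-folded (max(AUC, 1−AUC)) since a
biomarker enriched in either group is equally usable.

## Pipeline

One config seed fans out deterministically to per-stage seeds by hashing
the stage name, so any stage can be rerun in isolation with the stream it
saw in a full run. Every run writes `manifest.json` with versions, seeds,
the selected threshold, and all settings. Config files reject unknown keys.

## Problem sizes

The test suite and the acceptance script run at deliberately desk-scale
sizes: 300-taxon communities with groups of 10, 120-taxon planted-block
matrices at 200 samples for threshold recovery, 500-eigenvalue spectra for
the NNSD oracle, 20–50 replicate simulations per property. These sizes are
where the statistical properties under test (power, FDR, recovery rates)
are already stable.

## Known limitations

- Pearson-based similarity inherits compositional closure effects; the
  package does not implement SparCC/SPIEC-EASI-style compositionally aware
  alternatives.
- Keystone-role recovery requires correlation estimates stable enough to
  survive thresholding; at n = 10 + 10 samples connector detection is
  unreliable for any method, and the role-recovery tests therefore run at
  larger sample sizes.
- The NNSD chi-square needs ≥ ~50 eigenvalues; very small networks cannot
  be thresholded by the RMT criterion and need a manual override.
- Network bootstrap stability, consensus clustering and weighted-modularity
  variants are out of scope.
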