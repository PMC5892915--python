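# Methods

This note documents the models, parameter choices and numerical
conventions behind `colitiskit`, and what the synthetic-data design does
and does not establish about real data.

## The generative model

The simulator treats colonic inflammation as a single non-negative latent
score s per animal. Controls have s = 0 exactly; focal animals draw
s ~ U(0.35, 0.55); continuous animals draw a per-animal crypt-height
centre uniformly in the upper part of the hyperplastic range (420–550 μm
under defaults), which maps to s ≈ 0.57–0.88 through the affine relation

    height = baseline + s × (hyper_high − baseline),   baseline = 180 μm,
    hyper_high = 600 μm.

The severity bands of the two diseased classes are essentially disjoint by
design: the classes are *discrete* phenotypes, and the analyte panel can
only reflect s, so overlapping bands would make the classes unidentifiable
from molecular data alone. This is the main idealization of the generator
— real cohorts grade continuously and the focal/continuous boundary is
blurrier, so latent-space classification accuracy measured here is an
upper bound on what identical code would achieve on real panels.

**Crypt profiles.** Measurements are evenly spaced (colon length / number
of measurements; defaults 70 mm, 280 sites, i.e. one site per 250 μm),
position 0 at the distal tip, proximal/distal junction at the midpoint.
Continuous profiles put every distal height at the animal's centre ± 15 μm
Gaussian jitter, clipped into [300, 600] μm. Focal profiles elevate one
contiguous distal window whose length is 20–60% of the distal region,
placed uniformly at random; heights outside the window (and everywhere in
controls) sit at baseline ± 15 μm. The ordinal infiltrate score
co-locates with hyperplasia (0 at baseline, 2–3 where elevated, sparse 1s
elsewhere in diseased animals). Three percent of records are flagged
off-axis with inflated heights, emulating sectioning artefacts; the
cleaning step removes them, and all generator guarantees (ranges,
baselines) are stated for the cleaned records.

**Analyte panel.** A one-factor model: analyte_j = baseline_j +
loading_j × s + ε_j, ε_j ~ N(0, (0.12 × baseline_j)²), truncated at 0 for
concentration (pg/ml) channels. Loadings are weight × baseline with
weights ≈ +1 for innate-chemotaxis chemokines, inflammatory interleukins
and growth factors, ≈ 0 for Th2-type interleukins, positive for mTOR/NF-κB
phosphosites and negative for MAPK/insulin-receptor phosphosites. This is
the minimal structure reproducing the study's empirical signature — one
dominant principal component that carries most panel covariance and tracks
crypt height. What it omits: analyte-specific non-Gaussian tails,
correlated assay noise, plate effects and detection limits; the truncation
at 0 introduces negligible bias at a 12% noise scale.

**Treatment kinetics.** Deterministic per-analyte relaxation toward the
control baseline, x(t) = baseline + (x₀ − baseline)·2^(−t/τ), with τ = 1 h
for immediate-drop analytes (M-CSF and the direct mTOR readouts) and
τ = 12 h for the graded-decline chemokine group. Transient-increase
analytes (IL-6) add a bump A·(t/τ)·e^(1−t/τ) (A = 0.8·x₀) peaking at
t = τ = 8 h; by 48 h the bump has decayed and the value is at or below its
pre-treatment level. Crypt heights relax with a 24-h half-time; innate
infiltrate fractions hold for a 24-h lag and then halve every 12 h. Note
the decay acts on the *measured* value, so treated panels also shed their
measurement noise — treated cohorts are artificially tight clusters
compared with real treated animals. The 48-h treated projection results
should therefore be read directionally, not as effect sizes.

**Organoids, expression, microbiome.** Organoid condition means reuse the
panel's loading structure with condition scores mixed 0.6 / stem 0.8 /
enterocyte 0.15 / goblet 0.1, plus a goblet-specific elevation of MIP-1α
(1.5×|loading|), the one analyte that rises rather than falls with
secretory differentiation. Expression matrices are cell-type-mixture
averages of per-type signature means (log2-like scale, baseline 5, marker
gain +3) with Gaussian noise (σ = 0.25); the inflamed design raises the
transit-amplifying (TAC) proportion from 0.15 to 0.55 and depletes
goblet/enteroendocrine/enterocyte compartments, and four chemokine genes
(Cxcl1, Cxcl2, Cxcl5, Ccl20) belong to the TAC signature. Taxon tables are
multinomial draws (default depth 20,000) from Dirichlet-perturbed group
profiles (concentration 150) over 16 genera in 6 phyla; the inflamed
profile shifts toward Proteobacteria and away from *Lactobacillus* and
*Muribaculum*. Zero-proportion taxa stay at exactly zero, so
disjoint-support groups remain maximally dissimilar at any depth.

## Histomorphometry conventions

Bins are half-open [k·w, (k+1)·w) with w = 500 μm anchored at the distal
tip; a measurement on an edge joins the higher bin. Per-bin SEM is
sd/√n and undefined (NaN) for n < 2. Group profiles average animal
bin-means and take SEM *across animals*, not pooled crypts, so the group
N matches the number of animals. Extent classification calls
*continuous* when ≥ 80% of distal measurements exceed 300 μm, *control*
when < 10% do, *focal* otherwise; all three thresholds are exposed because
the underlying phenotype definition is qualitative. Spearman correlation
uses average ranks for ties.

## Latent-variable conventions

Default preprocessing is log1p followed by autoscaling for pg/ml channels
and autoscaling alone for RFU channels. Autoscaling is required for
loadings to be comparable across analytes whose dynamic ranges differ by
orders of magnitude; the log transform symmetrizes right-skewed
concentration distributions. Both are config-exposed.

PCA is computed by SVD of the preprocessed matrix. PLSR uses NIPALS with
deflation of X and the (centered, scaled) scalar response; with a
univariate response the inner loop converges in one pass, and the generic
iteration (tolerance 1e-10, cap 500) is retained for form. Component
signs are fixed by making the largest-|loading| analyte positive per
component — orientation is otherwise arbitrary, and the conventional
"inflamed scores positive" reading emerges from the data rather than
being assumed. Projection applies the stored training preprocessor and
the rotation W(PᵀW)⁻¹ (PLSR) or P (PCA); it reproduces training scores to
numerical precision and is affine in the preprocessed space. Two PLSR
components are fitted by default (the latent plane that the class regions
live in); the cytokine-only model restricts the panel to the 37 pg/ml
channels via a flag, not separate code.

Class regions are Gaussian ellipses (default 95% coverage) over the first
two training-score columns. Assignment minimizes Mahalanobis distance to
the class centroids measured in the **pooled within-class covariance**.
With 6–8 animals per class, per-class 2×2 covariances are too noisy to
define a metric: the broadest class swallows distant samples, inverting
the biology (a near-baseline treated sample would be called "continuous"
because that class sprawls along LV1). The per-class covariances are kept
on the regions for drawing; `assign_class(..., metric="class")` restores
the per-class metric. Distance ties (to 1e-10) break toward the
less-inflamed class.

## Enrichment conventions

Gene ranking uses the signal-to-noise metric (μ₁−μ₂)/(σ₁+σ₂) with each σ
floored at 0.2·|μ| (0.2 absolute when μ ≈ 0), descending, ties broken by
gene name. The enrichment score uses hit increments |metric|ᵖ/Σ|metric|ᵖ
(p = 1 by default) and miss decrements 1/(N−N_hits); ES is the signed
maximum deviation of the running sum and the leading edge runs to the
extremum. The hit-weight normalizer is summed sequentially (not pairwise)
so the walk is bit-reproducible by a plain cumulative loop.

Permutation testing defaults to phenotype (label) permutation and
auto-switches to gene permutation, with a logged warning, when fewer
distinct label shuffles exist than requested permutations — a 4-vs-6
design admits only 210. NES divides ES by the mean same-sign |permuted
ES| of its own set; nominal p is the same-sign tail fraction; FDR q is the
sign-stratified ratio of the null tail fraction to the observed tail
fraction, clipped to [0, 1]. Cell-type-specific set derivation requires
≥ 2-fold mean change and BH-adjusted Welch-t q < 0.05 against *every*
other cell type, with BH applied across genes separately per comparison;
Welch is used because per-type variances have no reason to be equal.
Derived sets may legitimately be empty at strict thresholds; curated sets
may not.

## Microbiome conventions

Bray–Curtis is computed on relative abundances, not raw counts, removing
sequencing-depth artefacts (the pairwise distances are delegated to
`scipy.spatial.distance.pdist`, which implements exactly
Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); a scalar brute-force loop serves as the oracle in the
tests). PCoA is Torgerson classical scaling: double-center −½D²,
eigendecompose, scale eigenvectors by √eigenvalue. Negative eigenvalues
(the non-Euclidean residue of Bray–Curtis) are reported and their axes
dropped, with no Cailliez/Lingoes correction; axis signs follow the same
largest-|value|-positive rule as the latent models. The paired analysis
reports within-animal pre/post, between-animal same-group, and
between-animal cross-group dissimilarity distributions with Mann–Whitney
rank-sum comparisons; animals missing a phase are excluded with a warning.

## Orchestration and determinism

One mandatory seed governs every stochastic stage through substreams
spawned from a single `SeedSequence` at fixed indices, so toggling one
stage never perturbs another's draws and identical configurations produce
byte-identical `report.json` files (floats rounded to 10 decimals on
output; wall-clock timings go to the log, not the report). Simulation
sizes used by the default pipeline and the acceptance script — 21-animal
cohorts, 25–100 cohort replicates for the Monte-Carlo summaries, 200–500
permutations for GSEA, 20,000-read taxon tables — were chosen so the full
default run completes in seconds while keeping Monte-Carlo error well
inside the margins of every property tested.

## Known limitations

- The latent score is one-dimensional: no analyte deviates from the shared
  inflammation axis, so the model cannot express, e.g., Th2-polarized
  subtypes. PC2+ of synthetic panels is pure noise.
- The weight-loss score is an abstract noisy linear readout of the latent
  score (3s + N(0, 0.3), floored at 0); it has no units and should not be
  compared to gram-scale measurements.
- Treatment kinetics are deterministic and noise-free; they model mean
  behaviour, not inter-animal variability in drug response.
- Expression matrices use Gaussian noise on a log-like scale rather than
  count noise; microarray-specific artefacts (probe effects, saturation)
  are out of scope.
- The infiltrate score scale is an arbitrary 0–3 ordinal passed through
  unchanged by the analysis code.
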