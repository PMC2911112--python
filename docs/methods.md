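# Methods

This note records the statistical models behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Differential expression: regularized t

With three arrays per condition, per-probeset variance estimates are far
too unstable for a plain t-test.  Following the Cyber-t idea, each
probeset borrows variance information from probesets of similar
expression: for group *g* with *n* replicates,

    σ₀²(i)  = mean sample variance over the w probesets nearest to i
              in mean-expression rank
    s̃²(i)   = (K·σ₀²(i) + (n−1)·s²(i)) / (K + n − 1)
    t(i)    = (x̄_a − x̄_b) / sqrt(s̃²_a/n_a + s̃²_b/n_b)

referred to Student t with `n_a + n_b + 2K − 2` degrees of freedom.

Parameter defaults and rationale:

- **w = 101** (rank window, probesets).  Wide enough to stabilize the
  background variance, narrow enough to track the variance-vs-intensity
  trend of log-scale microarray data.  Windows are centred and truncated
  at the list ends (no wrap-around); rank ties break lexicographically
  by probeset id so results are reproducible.
- **K = 10** (prior confidence, pseudo-observations).  With n = 3 per
  group the background variance then carries ~83% of the weight.
- **Shrinkage denominator K + n − 1** — the convex combination of K
  pseudo-observations with the n − 1 observed degrees of freedom.  At
  K = 0 the statistic reduces *exactly* to the classical two-sample t
  (pooled form when n_a = n_b, which is the study design; Welch's form
  otherwise).
- **Degrees of freedom n_a + n_b + 2K − 2.**  The prior contributes K
  pseudo-observations per group.  An alternative is to keep the
  classical n_a + n_b − 2; but when the shrunk variance is close to the
  true variance, the statistic is approximately standard normal, and
  evaluating it against a t with 4 df is badly conservative (null
  rejection ≈ 0.006 at α = 0.05).  With augmented df the stage is
  calibrated: measured type-I error 0.040 on homoscedastic null
  simulations (200 experiment replicates).
- Zero-variance probesets are retained when K > 0 (the background
  variance dominates); at K = 0 they are reported as missing and
  excluded from FDR correction.

Clones are pooled within condition (3 induced vs 3 uninduced arrays per
gene), treating the array as the replicate unit.  A consequence worth
knowing: clone-specific random effects cancel in the induced-minus-
uninduced contrast but still inflate the variance estimate, so with a
nonzero between-clone component the test is mildly conservative
(type-I ≈ 0.029 at the default between-clone sd of 0.1).  That is
expected behavior, not miscalibration.

**Effective/silent call.**  An experiment is *effective* when at least
`min_hits` probesets pass BH q < α (α = 0.05; a stricter 0.01 mode is
available).  `min_hits` defaults to 5: with twenty experiments screened
in parallel, BH rejects at least one null probeset per experiment with
probability ≈ α even under a global null, so requiring a single hit
would mislabel roughly one silent gene per two studies.  Requiring a
handful of coherent hits makes the call robust while leaving power for
real perturbations untouched (planted effective genes here produce ~50
significant probesets).

**Leakiness.**  Basal leakage of the inducible system is tested per gene
on the gene's own transgene probeset, parental line vs uninduced clones,
with a classical two-sample t and BH across genes.  The design's power
is predictable in closed form (noncentral t, df 4, Bonferroni-level
threshold); at the generator's default leak of 2 log2 units and noise
0.2 it is 0.985.

## Dosage-sensitivity prediction

**Basal ranking.**  A gene's basal expression is its mean over all
available arrays — with 120 arrays the estimate is tight.  Ranking is
descending, ties broken by id.

**Enrichment score.**  The classic weighted running sum over the ranked
list: hits advance by |metric|^p normalized by the total hit weight
(p = 1), misses retreat by 1/(N − N_hit); the score is the deviation of
maximum magnitude (earliest extreme wins when two deviations tie within
1e-12).  At p = 0 this is the Kolmogorov–Smirnov statistic between the
hit and miss step functions.  Significance uses a **set-permutation
null** — random same-size sets on the fixed ranking — because a single
ranking admits no phenotype permutation.  p = (1 + #{|null| ≥ |es|}) /
(n_perm + 1); the FDR q normalizes scores by the mean |null| of their
sign, as in the standard GSEA procedure.  Sets covering more than half
the profile trigger a warning (poorly calibrated null).

**Disorder.**  The disorder score is the number of residues in predicted
disordered regions: intervals are 1-based inclusive, overlapping or
adjacent intervals are merged before summation so each residue counts
once.  The classifier predicts *effective* at score ≥ θ with θ = 180
residues — dosage-sensitive proteins tend to be intrinsically
disordered.  Raising θ can only move genes from effective- to
silent-predicted.  Genes carrying non-murine (human) coding sequences
can be excluded via the `exclude` argument, since their disorder is not
comparable.  The group comparison is a Student t (equal variance) by
default with a Welch option; only "a t-test" is specified by convention,
and at 7-vs-13 group sizes the choice is immaterial for the planted
separations.

## Trisomy sign concordance

Signatures are merged at the significant-gene level: the trisomic list
is converted through an id map (several sources collapsing onto one
target keep the x of largest |value|), intersected per experiment, and
pooled with duplicate genes resolved by keeping the y of largest
magnitude.  Same-sign means strictly x·y > 0 — a zero log-ratio never
counts.

The resampling p-value draws, for each of `n_sets` sets, n x-values and
n y-values at random from the two significant log-ratio lists and
counts sets with ≥ k same-sign pairs; p is the qualifying fraction, and
a zero count is reported as the bound `< 1/n_sets`.  Draws are **with
replacement** by default ("randomly extracting" read as independent
draws); a without-replacement pairing variant sits behind a flag.  Each
variant has a closed-form oracle: with replacement the same-sign count
is Binomial(n, q) with q = f_x·f_y + (1−f_x)(1−f_y); under pairing it is
n − a − b + 2X with X hypergeometric in the positive–positive matches.
Only the signs of the drawn values matter, so the implementation samples
sign arrays; this is an exact shortcut, not an approximation.

The trend summary is a least-squares line forced through the origin,
slope A = Σxy/Σx², with the non-centered correlation
r = Σxy/√(Σx²·Σy²) tested via t = r·√((n−2)/(1−r²)) on n − 2 df.
Log base only rescales both axes and never changes signs, k/n, or r.

## 2DGE proteomics

Percent volume — each spot as a percentage of its parent gel's total —
is scale-invariant per gel and idempotent.  Ratios are t48/t0 means of
percent volumes; significance is a two-sided two-sample t across gels,
with technical replicates treated as independent by default (six gels
per condition) and a clone-averaged mode available.  A spot passes only
if p < 0.05 **and** its change exceeds 20%: up at ratio ≥ 1.2, down at
ratio ≤ 1/1.2 (symmetric on the ratio scale; a strict ≤ 0.8 variant is
available since the down-direction cutoff is conventionally ambiguous).
Protein–mRNA pairs are *concordant* when both ratios fall on the same
side of 1; a ratio exactly 1 is a boundary case, reported but excluded
from both counts.  Under the plain same-side-of-1 rule more than two
pairs of the reference ratio table are discordant; only the trend calls
stated explicitly alongside that table (Uchl1 concordant; Apoe and
Sept1 discordant) are asserted in tests.

## Synthetic-data generator

The generator reproduces the study's *structure*: 20 genes × 3 clones ×
2 conditions (120 arrays) plus 3 parental baselines; 2000 probesets of
which one per gene is its transgene reporter; 7 of 20 genes effective;
a trisomic comparison of 4 vs 4 samples; 500 2DGE spots of which 54
change.  Defaults, all on the log2 scale unless noted:

| parameter | default | meaning |
|---|---|---|
| noise_sd | 0.25 | array-level Gaussian noise |
| between_clone_sd | 0.10 | clone random effect (shared across that clone's arrays) |
| effect_size_mean/sd | 2.0 / 0.5 | planted |log2| effect magnitudes (floor 0.25) |
| targets_per_effective | 50 | probesets perturbed per effective gene |
| fraction_effective | 0.35 | 7 of 20 genes |
| basal_quantile_for_silent | 0.80 | silent transgenes drawn from the top 20% of basal means |
| trisomic_scale | log2(3/2) | 3:2 dosage scaling of the additive trisomic shift |
| leak_shift / n_leaky_genes | 2.0 / 1 | one leaky clone set |
| disorder_threshold / exception_score | 180 / 26 | planted separation and the single exception |
| n_spots / fraction_spots_changed | 500 / 0.108 | 54 changed spots |
| spot_noise_cv | 0.10 | multiplicative log-normal gel noise |
| spot_change_low/high | 1.5 / 3.0 | planted spot ratio magnitudes |

Noise is additive Gaussian on the log2 scale (the standard log-normal
intensity assumption).  Effective transgenes draw their basal level from
the lower half of the basal distribution, silent ones from the top
quantile, which is what makes the basal-ranking and enrichment analyses
recoverable.  Disorder profiles plant effective genes at N(300, 80)
clipped to ≥ 180 and silent genes at N(80, 40) clipped below 180, with
exactly one effective gene forced to score 26 — the planted analogue of
a kinase that perturbs the transcriptome despite an ordered protein.
Within- vs between-clone variance components are not reported for the
real study, so both are exposed as parameters rather than fixed.

Spot volumes are log-normal (heavy-tailed, as silver-stain volumes are).
Up/down directions of the planted changes are assigned greedily, largest
spots first, to approximately conserve each gel's total volume.  Without
this, a dominant spot's change shifts the gel total and percent-volume
normalization leaks that shift into every unchanged spot's ratio; with
it, planted ratios hold on the percent-volume scale, emulating a
loading-controlled experiment.  A side effect is that up/down counts are
volume-weighted rather than exactly balanced.

What the generator does **not** emulate: probe-level intensities and
hybridization artifacts, probe-specific effects, correlated target
modules, variance-vs-intensity trends (noise is homoscedastic),
multi-probeset genes, gel image warping, and spot-detection errors.
Passing tests therefore demonstrate the correctness and calibration of
the statistics under the stated generative assumptions, not robustness
to every artifact of real arrays or gels.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (config, seed) gives bit-identical
output, and no global random state is touched.  The test suite runs the
resampling grids at 20,000 sets per point, null-calibration sweeps at
200 simulated experiments, and recovery sweeps at 20 seeds of the
default study size; the acceptance script uses the full 10⁶ resampled
sets for the headline concordance figure.  Monte-Carlo assertions use
binomial standard-error tolerances; grids with ~100 comparison points
allow the ~0.3 three-sigma excursions expected under a correct
implementation (at most two, none beyond 4.5 SE).

## Known limitations

- The regularized-t window couples probesets; under strong
  heteroscedasticity in rank-space the background variance can be
  locally biased.  The homoscedastic calibration checks do not probe
  this.
- The set-permutation GSEA null ignores inter-gene correlation; on real
  arrays it is anti-conservative relative to phenotype permutation.
- The resampling concordance null treats the two log-ratio lists as
  fixed populations; it does not model selection of the significant
  sets themselves.
- Text writers round to 6 significant digits; round-trips are exact on
  the written text, not on full binary doubles.
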