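# Methods

## Voxel-wise mapping

The core procedure relates a cohort of binary, template-registered tumor
masks to a per-patient binary label, voxel by voxel. Spatial normalization
is assumed done upstream: masks must share one grid (affines equal to
1e-4 mm per element), and any regridding is an explicit nearest-neighbour
resample through the composed voxel-to-world transforms — never silent,
because silent resampling hides registration errors.

**Coverage filter.** Only voxels lesioned in strictly more than
`min_lesion_fraction` (default 0.05) of the analyzed cohort are tested;
rarely lesioned voxels carry almost no information and inflate the
multiple-testing burden. The denominator is the cohort actually entering
the map (e.g. the two-class subset), not any larger parent collection,
since the test statistics are computed on that subset.

**Liebermeister test.** For a 2×2 table (a, b; c, d) the positive-direction
p-value is the hypergeometric tail P(X ≥ a+1) on the table augmented in the
concordant cells, (a+1, b; c, d+1): population n+2, a+c+1 successes,
a+b+1 draws. The negative direction augments (a, b+1; c+1, d) and takes
P(X ≤ a). This quasi-exact formulation has a Bayesian motivation (it equals
the posterior probability of negative association under uniform priors) and
is uniformly less conservative than the one-sided Fisher exact test on the
raw table; the suite verifies equality with exact-rational enumeration and
the Fisher bound over all tables with n ≤ 12. The two tails on the shared
augmented margins are complementary: P(X ≥ a+1) + P(X ≤ a) = 1.

**z-maps, FDR, clusters.** One-sided p maps to z = Φ⁻¹(1 − p) with the
direction's sign; p at 0 or 1 is clamped to |z| = 8 so maps stay finite in
storage. The significance threshold is Benjamini-Hochberg step-up at
q = 0.05 across analyzed voxels only (Benjamini-Yekutieli available via
config; the BH constant is the default because voxel-wise lesion indicators
are positively dependent at worst). Significant voxels are labeled into
connected components at 26-connectivity (6/18 configurable), sorted by
size, then peak z, then lowest linear peak index, so cluster tables are
deterministic. No minimum cluster extent is imposed: the threshold is
voxel-level FDR. Subtype-specific maps are separate one-sided runs with
opposite label polarity, not a single two-sided test (a `two-sided`
direction exists for other use cases).

**Vectorization.** Per-voxel tables reduce to the pair (a, lesioned count);
p-values are evaluated once per unique pair and broadcast, which makes a
48×56×48, 125-sample map run in well under a second.

## Membership, reports, agreement

A tumor is "in the determined area" when it overlaps the significant region
by at least one voxel — the most permissive reading; the overlap fraction
is recorded so stricter cutoffs can be re-applied without re-running the
map (membership is monotone in the threshold). The 2×2
membership × subtype report emits cells, margins and the row/column
percentages rounded to integers; location summaries
(single-temporal / multi-temporal-including / other, left / right /
bilateral) print two decimals. Pearson χ² on the 2×2 uses no continuity
correction and refuses tables with a zero margin.

Inter-rater agreement is Cohen's κ with the conventional grading:
κ > 0.8 excellent, 0.6 ≤ κ ≤ 0.8 good, κ < 0.6 poor (0.8 exclusive,
0.6 inclusive; the boundary convention is documented because the verbal
rule "0.6–0.8 is good" does not fix it). Two identical constant raters have
undefined κ (chance agreement 1); this is reported as 1.0 with a warning.
The two-observer VOI volume check flags a pair for recheck when
|V₁ − V₂| / min(V₁, V₂) > 0.05 — the relative-difference reading of an
ambiguous "volume ratio" rule, chosen because it is symmetric in the
observers and strictest of the natural interpretations.

The VASARI-based survival screen keeps samples with enhancing-proportion
code F5 ≥ 7 ("> 95%"); code 9 ("indeterminate") is excluded even though it
is numerically ≥ 7, because an indeterminate proportion cannot satisfy an
enhancement cutoff. Temporal involvement means location code F1 = 2 or a
multi-lobe category that includes the temporal lobe.

## Survival

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines. Ties are handled jointly in the hypergeometric variance term;
subjects censored at an event time remain at risk through that time. No Cox
modeling or stratification is provided — the comparison of interest is the
unadjusted in/out contrast; the treatment/VASARI filter exists to
homogenize the compared groups instead. The pipeline reports both the
filtered and the unfiltered subset, logging each filter's n.

## Expression scoring

ssGSEA scores one sample at a time: rank genes by expression descending
(ties by average rank for weights, ordered by gene position), then
ES = Σₖ [P_in(k) − P_out(k)] where P_in is the rank^α-weighted in-set ECDF
and P_out the uniform out-of-set ECDF. α = 0.25 by default — the
conventional single-sample choice, configurable because reasonable
alternatives (0, 1) exist. Rank-based scoring makes ES invariant to any
strictly increasing per-sample transform, so mixed normalizations across
samples are tolerable as long as within-sample order is meaningful; a
log2(x+1) flag covers raw intensities.

The purity proxy is −(z(immune ES) + z(stromal ES))/2 across samples:
a signature-combination score, deliberately **not** the published ESTIMATE
polynomial (no formula is reproduced here); it is monotone-decreasing in
both signatures, which is the property the group contrast needs. Cell-type
"infiltration" is per-set ssGSEA on marker sets — a gene-set approximation
of support-vector deconvolution, adequate for directional group contrasts
but not for absolute composition estimates.

Differential expression between groups uses the pooled-variance t-test per
gene; the log2 fold change is out-area minus in-area mean on the log scale,
so genes up-regulated outside the region are positive. The top-k report
filters p < 0.05 and sorts by |log2FC| with ties by p then gene id. No
multiple-testing correction is applied within the per-gene report, matching
the starred single-gene presentation convention it feeds; the FDR machinery
is available to callers who want it.

## Synthetic cohorts

The generator produces the coupled structure the analysis assumes, with
ground truth:

- **Lesions**: ellipsoids (per-axis semi-axes uniform in 4–9 voxels) on a
  48×56×48 grid of 3 mm voxels, centered inside a brain-shaped ellipsoid
  (semi-axes 0.45 × grid). Positive-class lesions center inside a planted
  radius-6 spherical hotspot with probability π = 0.7, otherwise uniformly.
  Ellipsoids are not realistic tumor shapes; shape realism is irrelevant to
  the voxel-set statistics under test.
- **Classes**: 52 positive and 73 negative samples by default.
- **Truth membership** is lesion-overlaps-hotspot (≥ 1 voxel), so
  negative-class tumors can fall in the region by chance, as in real data.
- **Survival**: exponential, baseline hazard 1/400 per day in-region
  (median ≈ 280 days, a realistic glioblastoma scale) and ×2 out-of-region.
  Hazards follow *true* membership, not the recovered classification, so
  classification error propagates realistically. Censoring is exponential
  at 0.25 × baseline hazard with an administrative cap at 1730 days
  (≈ 20% censoring).
- **Expression**: 2000 genes, standard normal (log-scale analogue). A
  141-gene EMT set contains 16 genes shifted +1 SD and 4 shifted −1 SD in
  out-of-region samples; 50-gene immune and stromal signatures shift +1 SD
  out-of-region (lower purity outside); 22 cell-type marker sets of 15
  genes include two (CD8 T cells, follicular-helper T cells) depleted by
  1 SD outside.
- **Clinical**: age/sex/KPS/MGMT/treatment flags drawn to match typical
  cohort frequencies; VASARI F1/F5 codes with duplicate-rater columns that
  disagree on 5–8% of samples, giving κ in the "excellent" range.

One seed drives four named child streams (lesions, clinical, survival,
expression), so re-simulating one block leaves the others untouched.

What passing tests on this generator do **not** show: robustness to
registration error, non-ellipsoidal or multifocal tumor shapes, correlated
gene-gene structure, batch effects, non-proportional hazards, or informative
censoring. The generator is a statistical, not a biophysical, emulation.

## Validation choices and problem sizes

- Liebermeister correctness is exhaustive over all 2×2 tables with n ≤ 12
  against exact rational enumeration (and bounded by Fisher's test there).
- Null calibration uses 200 spatially null cohorts (32³ grid, 30 + 30
  samples, no hotspot attraction) and checks that the fraction of runs with
  any FDR-significant voxel stays within the binomial envelope of q = 0.05.
- Hotspot recovery uses the full default cohort; the Dice criterion (≥ 0.5
  against the planted sphere) is intentionally lenient because the
  significant region legitimately extends beyond the hotspot: lesions
  centered inside it protrude, so neighbouring voxels carry real
  association.
- Survival power uses the in/out split the membership analysis produces at
  the defaults (33/92) with hazard ratio 2 over 100 seeds; log-rank p is
  additionally checked against a label-permutation reference.
- Gene recovery uses 25 seeds of the 16-planted-up / 141-gene / 30 + 30
  configuration.

These sizes keep the complete suite under a minute while leaving Monte
Carlo error well inside the asserted margins.

## Known limitations

- Voxels are treated as independent in testing (the FDR threshold is the
  only spatial pooling); spatially smoothed or permutation-based family-wise
  approaches are out of scope.
- Anatomical naming of clusters (which lobe a region occupies) is not
  automated; cluster tables report indices and world coordinates only.
- The purity and cell-type scores are signature proxies, not calibrated
  fraction estimates.
- Masks are binary; probabilistic segmentations are thresholded at 0.5 on
  read (strict mode rejects non-binary data instead).
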