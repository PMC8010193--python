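# vlsmkit

Voxel-based lesion-symptom mapping (VLSM) and downstream radiogenomic group
comparison for brain-tumor cohorts.

## The problem

Glioblastoma transcriptomic subtypes (proneural, mesenchymal, neural,
classical) differ in prognosis and biology, and tumor location carries
information about them: tumors of one subtype may preferentially arise in a
particular anatomical region. Given a cohort of binary tumor masks (VOIs)
registered to a common template, a per-patient binary label (e.g. proneural
vs mesenchymal subtype), survival data and an expression matrix, this
package:

1. maps the voxel-wise association between lesion presence and the label,
2. splits the cohort into patients whose tumors fall **in** or **outside**
   the mapped region, and
3. compares the two groups on overall survival (Kaplan-Meier / log-rank),
   gene-set enrichment (single-sample GSEA: EMT, immune, stromal,
   cell-type marker sets), a tumor-purity proxy, and per-gene differential
   expression.

It is aimed at radiogenomics researchers who have pre-registered masks and
matched molecular data and want the whole in/out-of-region analysis as one
tested, scriptable pipeline. A coupled synthetic-cohort generator with
ground truth (planted hotspot, planted hazard ratio, planted gene shifts)
supports validation end to end.

## The statistics

At each voxel lesioned in more than 5% of the cohort (strict inequality,
configurable), the cohort forms a 2×2 table of lesion status × label

|            | label + | label − |
|------------|---------|---------|
| lesioned   | a       | b       |
| intact     | c       | d       |

scored with the **Liebermeister quasi-exact test**: augment the concordant
cells to (a+1, b; c, d+1) and take the one-sided hypergeometric tail
P(X ≥ a+1) with population n+2, a+c+1 successes and a+b+1 draws (the
opposite augmentation and lower tail for the negative direction). The test
is quasi-exact and uniformly less conservative than the one-sided Fisher
exact test; the test suite verifies both properties by exhaustive
enumeration over all tables with n ≤ 12. One-sided p-values map to signed
z-scores z = Φ⁻¹(1 − p), the voxel-wise threshold is Benjamini-Hochberg at
q = 0.05 over analyzed voxels only, and significant voxels are grouped into
26-connected clusters.

Membership ("in the area") means the tumor overlaps the significant region
by ≥ 1 voxel (threshold configurable; the overlap fraction is recorded for
sensitivity analyses). Group comparisons use the standard log-rank test,
pooled-variance t-tests, Pearson χ² and Cohen's κ (inter-rater agreement,
graded excellent / good / poor at 0.8 and 0.6). ssGSEA scores a set S in
one sample as ES = Σₖ [P_in(k) − P_out(k)] with the in-set ECDF weighted by
rank^α (α = 0.25 by default); the purity proxy is
−(z(immune ES) + z(stromal ES))/2.

## Worked example

```python
import pandas as pd
from vlsmkit import (SimConfig, simulate_cohort, run_vlsm,
                     classify_membership, contingency_report, logrank_test,
                     ssgsea_score, diff_by_group)

syn = simulate_cohort(SimConfig(seed=0))          # 52 + 73 samples, planted hotspot
labels = syn.truth["labels"].to_numpy()           # 1 = proneural-like class
res = run_vlsm(syn.lesions, labels)
print(f"significant voxels: {res.n_significant} (FDR p-threshold {res.fdr_p_threshold:.4f})")

member = classify_membership(syn.lesions, res.sig_mask.astype(bool))
rep = contingency_report(member, pd.Series(labels, index=syn.lesions.sample_ids))
print(f"in area: {rep['in_area_total']} ({rep['row_pct']['in_pos']}% proneural), "
      f"outside: {rep['out_area_total']} ({rep['row_pct']['out_pos']}% proneural)")

surv = syn.samples.rename(columns={"os_days": "time_days"})
in_area = member["in_area"].to_numpy()
chi2, p = logrank_test(surv[in_area], surv[~in_area])
print(f"log-rank: chi2 = {chi2:.2f}, p = {p:.2e}")

score = ssgsea_score(syn.expression, syn.gene_sets["EMT"])
cmp = diff_by_group(score, member.set_index("sample_id")["in_area"])
print(f"EMT score, in vs out: t = {cmp.t:.2f}, p = {cmp.p:.4f} ({cmp.stars})")
```

prints

```
significant voxels: 2473 (FDR p-threshold 0.0361)
in area: 57 (72% proneural), outside: 68 (16% proneural)
log-rank: chi2 = 12.68, p = 3.70e-04
EMT score, in vs out: t = -2.32, p = 0.0218 (*)
```

The map recovers the planted hotspot (the 2473-voxel cluster contains it);
patients whose tumors hit the region are enriched for the positive class
(72% vs 16%), survive longer (the generator plants hazard ratio 2 for
out-of-region tumors), and show the planted EMT up-shift outside the region
(negative t: the in-area group scores lower).

## Command line

```bash
vlsm simulate --seed 0 --out data/            # synthetic cohort with truth
vlsm overlay  --manifest data/manifest.csv --out overlay.nii.gz
vlsm map      --manifest data/manifest.csv --labels labels.csv --out vlsm_out/
vlsm classify --manifest data/manifest.csv --region vlsm_out/vlsm_positive_sig.nii.gz --out member.csv
vlsm survival --membership member.csv --samples data/samples.csv --out surv.json
vlsm score    --expression data/expression.tsv --gene-sets data/gene_sets.gmt --out scores.csv
vlsm run-all  --config pipeline.yaml          # all stages, deterministic outputs
```

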