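# pairedcna

Copy-number comparison of primary tumours and their matched lymph-node
metastases (LNMs) from array-CGH log2-ratio profiles.

When a breast cancer has spread to axillary lymph nodes, systemic therapy is
chosen from the primary tumour's characteristics — which is only sound if the
metastasis is genomically close to the tumour it came from. `pairedcna`
implements the complete analysis used to ask that question at the DNA
copy-number level on paired tumour/LNM aCGH cohorts:

1. **Profile smoothing** — probe-level log2 ratios are smoothed per
   chromosome with a Gaussian kernel (σ = 1 Mb by default) in normalised
   (Nadaraya–Watson) form, `s(g) = Σᵢ wᵢxᵢ / Σᵢ wᵢ` with
   `wᵢ = exp(−(posᵢ−g)²/2σ²)`, so profiles from platforms of different probe
   density are directly comparable.
2. **Clustering & concordance** — samples are clustered on the correlation
   distance `d = 1 − r` (Pearson) of their smoothed profiles with average
   linkage (UPGMA); a pair is *concordant* when the LNM's nearest neighbour
   is its own tumour.
3. **Recurrent differences** — the group difference curve
   `D(g) = mean_LNM s(g) − mean_tumour s(g)` is tested with a paired
   sign-flip permutation test on the familywise statistic `max_g |D(g)|`
   (α = 0.05, 1000 permutations; exhaustive enumeration when feasible).
4. **Delta profiles** — each pair is quantile-normalised, subtracted
   (LNM − tumour) and segmented by circular binary segmentation (CBS) with
   permutation split tests and the 2-SD breakpoint-undo rule; delta segments
   with |mean| > 0.2 log2 (optionally ≥ 10 probes) are counted per pair,
   compared between subtypes (TNBC vs ER+) by the Wilcoxon rank-sum test,
   and searched for recurrent cross-patient overlaps (|mean| > 0.1) with a
   direction-consistency check.

A synthetic paired-cohort generator (`pairedcna.synthetic_data`) produces
cohorts with a shared clonal CNA backbone per patient, subtype-dependent
aberration burden, private focal events, noisy hybridisations and biphasic
(two-component) tumours — with full ground truth, so every stage is testable
without external data.

## Worked example

```python
import numpy as np
import pairedcna as pc
from pairedcna.comparative_kc import CompareParams, permutation_test

# 10 TNBC + 10 ER+ tumour/LNM pairs, 3 x 60 Mb genome at 25 kb spacing
grid, profiles, pairs, truth = pc.simulate_cohort(10, 10, pc.SimParams(seed=42))
ids, chroms, pos, m = pc.smooth_cohort(grid, profiles)

dm = pc.correlation_distance(m, ids)
report = pc.pair_concordance(dm, pairs, pc.average_linkage(dm))
print(f"pairs: {len(pairs)}  concordance rate: {report.rate:.2f}")

res = permutation_test(m, ids, [p.meta.tissue for p in profiles],
                       chroms, pos, pairs, CompareParams(seed=1))
print(f"significant recurrent regions: {res.n_significant} "
      f"(threshold {res.threshold:.4f}, observed max |D| "
      f"{np.abs(res.difference).max():.4f})")

drep = pc.run_delta_pipeline(profiles, pairs)
counts = drep.counts.groupby("subtype")["n_segments"].mean()
print(f"mean delta segments/pair  TNBC: {counts['TNBC']:.1f}  "
      f"ER+: {counts['ERpos']:.1f}")
print(f"Wilcoxon rank-sum p: {drep.wilcoxon.p_value:.3f}")
```

prints

```
pairs: 20  concordance rate: 1.00
significant recurrent regions: 0 (threshold 0.0451, observed max |D| 0.0418)
mean delta segments/pair  TNBC: 0.8  ER+: 0.9
Wilcoxon rank-sum p: 0.965
```

Read: every LNM clusters next to its own tumour; no genomic region differs
recurrently between tumours and metastases (the observed maximum of the
difference curve stays below the permutation threshold); each pair diverges
by roughly one focal delta segment, with no excess in the genomically
unstable TNBC subtype.

The same pipeline is available from the shell:

```sh
pairedcna simulate --outdir cohort --n-tnbc 10 --n-erpos 10 --seed 42
pairedcna cluster  --matrix cohort/probe_matrix.tsv --sample-sheet cohort/sample_sheet.tsv --out-prefix out/cl
pairedcna compare  --matrix cohort/probe_matrix.tsv --sample-sheet cohort/sample_sheet.tsv --out-prefix out/cmp
pairedcna delta    --matrix cohort/probe_matrix.tsv --sample-sheet cohort/sample_sheet.tsv --outdir out/delta
pairedcna run-all  --outdir out/full --seed 42      # all stages + report.json
```

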