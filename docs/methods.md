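# Methods

This note documents the models and procedures implemented in `pairedcna`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish.

## Data model

Input is a probe-level aCGH log2-ratio matrix (probe id, chromosome,
position, one column per sample) with a sample sheet assigning each sample a
patient, a tissue (`tumour` / `lnm`) and a subtype (`TNBC` / `ERpos`).
Internally coordinates are 0-based half-open, probes are points (midpoints),
and chromosomes are opaque strings in natural order; SEG output is written
1-based inclusive and BED 0-based half-open. Probes with a missing value in
any sample are dropped globally with a logged count, so that all pairwise
arithmetic happens on identical grids. Sex chromosomes receive no special
treatment (the measurement model — tumour vs female reference DNA — gives no
reason for one here).

## Kernel smoothing

Each chromosome is smoothed onto a regular mesh with a Gaussian kernel of
scale `sigma_bp` (default 1,000,000 bp, the scale at which recurrent CNAs
rather than probe noise dominate). Two choices deserve note:

* **Normalised (Nadaraya–Watson) weights.** Kernel-convolution methods for
  CNA recurrence originally use raw kernel sums, which scale with local
  probe density. For clustering and group comparison a *mean-preserving*
  smoother is required — otherwise a dense platform and its sparse subset
  would disagree everywhere — so weights are normalised to sum to one.
  Constant profiles are then preserved exactly and chromosome edges are not
  attenuated (no padding needed). The signed log2 signal is smoothed as is;
  smoothing gains and losses separately would only matter for single-group
  recurrence testing, which is out of scope.
* **Evaluation mesh.** The mesh spacing defaults to `sigma/4` (250 kb at the
  default sigma), a standard over-sampling of a Gaussian; mesh points sit at
  `(k + 1/2) * spacing`. The kernel is truncated at 5 sigma, which changes
  results by less than 1e-6 relative to the untruncated kernel.

Smoothing is linear, so smoothing then differencing equals differencing then
smoothing (tested); the comparative stage smooths first.

## Clustering and matched-pair concordance

Samples are compared genome-wide by the correlation distance
`d = 1 − Pearson r` of their concatenated smoothed profiles and clustered
with average linkage (UPGMA), implemented directly so that ties break
deterministically by lowest cluster index (scipy's implementation serves as
an independent oracle in the tests). A constant smoothed profile has no
defined correlation and raises an error naming the sample.

Concordance is operationalised on the distance matrix, not the tree: a pair
is concordant iff the matched tumour is the *strictly* nearest neighbour of
the LNM among all other samples; exact ties count as discordant with a
warning. Dendrogram-sibling concordance (first merge partner = matched
tumour) is reported alongside for comparison. Newick export writes an
ultrametric tree with each branch carrying half the merge height.

## Paired permutation test for recurrent differences

The observed statistic is the difference curve `D(g)` (mean smoothed LNM −
mean smoothed tumour). Because the published comparative kernel-convolution
method does not pin down the statistic or its multiplicity handling, the
package adopts the conservative familywise construction: the null is built
by relabeling, the test statistic is `max_g |D(g)|`, the significance
threshold is the `(1 − alpha)` quantile (order statistic, rounded up) of the
null maxima, and significant regions are maximal runs of mesh points with
`|D(g)|` above threshold, never spanning a chromosome boundary. Each region
carries the sign of its peak and an empirical p-value with the +1 Monte
Carlo correction (`p ≥ 1/(n_perm+1)`).

Samples arrive in tumour/LNM pairs, so the default relabeling is the paired
sign flip: each pair's difference curve keeps or flips its sign
independently, giving `2^P` distinct patterns. When `2^P ≤ n_perm` the null
is enumerated exhaustively (and the +1 correction is dropped); otherwise
`n_perm` random patterns are drawn (default 1000, alpha 0.05). An unpaired
mode (group-label permutation) and a pointwise threshold mode (per-mesh
quantiles, no familywise control) exist for sensitivity analysis.

Under the generator's defaults the per-pair private events have symmetric
random signs, so sign-flip exchangeability holds on null cohorts and the
familywise type-I error is nominal (measured ~0.05 across seeded cohorts by
the acceptance script).

## CBS segmentation with SD-undo

Delta profiles are segmented per chromosome by circular binary segmentation:
the best split of an interval is the arc `(i, j]` maximising the two-sample
pooled-variance t statistic between in-arc and out-of-arc probes (arcs
constrained to `min_width = 2` probes per side; ties broken to the smallest
`(i, j)`). The split is accepted when its permutation p-value — `n_perm_split`
(default 1000) shuffles of the interval's values, `alpha_split = 0.01` —
is below threshold, and the recursion continues on the sub-intervals.
Implementation notes:

* `t²` is monotone in the between-group sum of squares
  `SSB(i,j) = (R_j − R_i)² · n/(k(n−k))` with `R` the centred partial sums,
  so the O(n²) scan is division-free (numba-compiled) and prunes whole arc
  lengths via the global range of `R`.
* The Monte-Carlo split test stops early once the exceedance count already
  guarantees `p ≥ alpha_split`. This cannot change any accept/reject
  decision; it only avoids spending the full permutation budget on clearly
  non-significant splits.
* Noise is estimated robustly as
  `sd = 1.4826 · median(|x_{i+1} − x_i|) / √2`, insensitive to true steps.
* **SD-undo.** After segmentation, the breakpoint whose flanking segment
  means are closest is removed while that gap is below `undo_sd · sd`
  (default 2 SD), the segments are merged and the mean recomputed from the
  probe values; smallest gap first, ties to the lowest index. The noise SD
  feeding the rule is the profile-wide robust estimate — per-segment SDs
  would be unstable for short segments. Note the arithmetic consequence: on
  a delta profile (noise `σ√2` for per-sample noise σ) the smallest
  retainable step is `2√2·σ`, i.e. ≈ 0.42 log2 at σ = 0.15 — events near
  that floor are removed by design.

DNAcopy-style outlier smoothing, probe weights and the "prune" undo variant
are deliberately not implemented.

## Delta pipeline

Per pair: two-sample quantile normalisation (rank-k values replaced by the
mean of the two rank-k values; tied values within a sample receive the mean
of their tied-rank replacements, so ties stay ties), subtraction
(LNM − tumour), CBS + SD-undo per chromosome with the profile-wide noise
estimate, then per-segment annotation: the delta-threshold flag
(|mean| > 0.2 log2), the probe-count flag (≥ 10 probes), and each sample's
copy-number state over the segment span (gain above +0.2, loss below −0.2 on
the normalised individual profiles). Normalisation is per pair, not
cohort-wide: the subtraction is pairwise, and quantile normalisation is only
meaningful between samples with similar value distributions. For the same
reason the pipeline flags pairs whose delta noise SD exceeds 3x the cohort
median (a noisy hybridisation) and excludes them from the group statistics
with a logged reason.

Subtype comparison: two-sided Wilcoxon rank-sum on the per-patient counts,
exact when both groups have ≤ 10 patients and no ties (scipy's exact
enumeration; a brute-force enumerator is the test oracle), tie-corrected
normal approximation otherwise; all-identical counts return the maximal
p = 1.

Recurrent overlaps: candidate segments are delta segments with
|mean| > 0.1 log2; overlapping candidates from different patients form
groups as connected components of the interval-overlap graph (transitive
chaining — a documented choice; a pairwise-only mode exists). A group
reports its members' directions (sign of the delta mean) and
`consistent_direction` = all signs equal; the group interval is the common
intersection, falling back to the deepest-coverage window when chaining
makes the full intersection empty.

## Synthetic cohorts

The generator emulates a paired FFPE aCGH study at desk scale. Defaults
(chosen once, as the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 60 Mb, 25 kb spacing (7200 probes) | large enough for σ = 1 Mb smoothing and multi-Mb CNAs, small enough for seconds-scale runs; a 5 kb "dense" preset and an every-5th-probe subset mirror a 720K/135K platform pair |
| clonal CNAs per clone | Poisson, mean 12 (TNBC) / 5 (ER+) | TNBC is the genomically unstable subtype; the contrast is what the subtype analyses consume |
| CNA lengths | log-normal, median ≈ 4 Mb (log-sd 0.8) | spans focal (~1 Mb) to arm-scale events |
| amplitudes | sign ± with p=0.5; magnitude N(0.6, 0.15) clipped at 0.2 | typical FFPE aCGH segment means for single-copy events in impure tumours |
| probe noise | i.i.d. N(0, 0.15) per probe | FFPE-grade hybridisation; "noisy hybridisation" multiplies one sample's SD by 6 |
| LNM-/tumour-private events | p = 0.8 / 0.2 per pair, 0.3–2 Mb focal spans | most pairs show some focal divergence; truth is recorded per event |
| biphasic tumours | two independent clones mixed in linear copy space, `log2(f·2^a + (1−f)·2^b)`; LNM from clone A | DNA mixes linearly in copy number, not in log space |

Each patient draws from a child stream of one root seed, so cohorts are
extensible without perturbing earlier patients, and identical seeds give
byte-identical cohorts. The LNM inherits its clone exactly; divergence
enters only through explicit private events, which keeps ground truth
unambiguous.

**What the generator does not model:** GC waves, probe-specific response,
spatially correlated FFPE artefacts (noise is i.i.d.), shared recurrent CNA
hotspots across patients (clones are independent), and copy-number-neutral
variation. Two consequences for interpreting green tests: (i) cross-patient
correlations are near zero, so nearest-neighbour concordance is easier than
on real cohorts, where samples share recurrent aberrations — a noisy
hybridisation that breaks concordance in real data stays concordant here
because i.i.d. noise shrinks by ~0.084 under 1 Mb smoothing at 25 kb
spacing while no other sample gets closer; the pipeline instead catches such
pairs via the 3x-median delta-noise exclusion; (ii) private-event recovery
rates apply to events on a realistic clonal backbone — on a featureless
background, two-sample quantile normalisation itself shrinks a private
event's amplitude toward the other sample's extreme order statistics.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run at the default 7200-probe genome with 10+10
pairs (concordance: 20 cohorts; type-I error: 100–200 cohorts at 200
permutations; recovery: 15 pairs × 2 events). CBS oracle checks run
exhaustively at n ≤ 12 and on 200–500-probe fixtures. These sizes were
chosen to keep full runs in the minutes range on a single core while leaving
every statistical margin comfortably away from its threshold.

## Known limitations

* The comparative test statistic (max |D|) is one defensible choice among
  several; pointwise thresholds are exposed but untested beyond smoke level.
* The undo rule's 2√2·σ amplitude floor on delta profiles (above) means
  marginal private events (|Δ| ≲ 0.42 at σ = 0.15) are intentionally
  invisible; lower the per-sample noise or `undo_sd` to trade sensitivity
  against false segments.
* Quantile normalisation assumes the pair's distributions are similar; the
  noisy-pair exclusion enforces this only coarsely.
* Interval overlap uses ≥ 1 bp intersection with transitive chaining; no
  reciprocal-overlap fraction is implemented.
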