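# Methods

This note documents the statistical procedures `lncarray` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Probe reannotation

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on read, BED is native. Overlap is **exon-level** by default —
probes interrogate transcribed sequence, so whole-locus spans would
over-assign across introns — with a `span` option for sensitivity analysis.
Overlap means ≥1 shared base.

Strand handling defaults to `ignore`: the assignment is defined by
chromosomal position only, since expression arrays of this generation do
not preserve strand reliably after amplification. `same` and `opposite`
modes are exposed.

Univocality is interpreted strictly: a probe overlapping *any* transcript
of the coding-like annotation is excluded (reason `overlaps_ensembl`)
regardless of biotype, and a probe overlapping exons of two distinct lncRNA
genes is excluded as `ambiguous_lnc` — one probe, one lncRNA. A
configurable biotype whitelist can exempt chosen coding-side biotypes
(e.g. entries that duplicate lncRNA records) from the exclusion set;
default off. `min_probes` for median summarization defaults to 1 (no
minimum is imposed on real data either); the per-run manifest reports the
number of detected lncRNAs so users can compare against expectations.
Probeset-level input is handled by treating the probeset id as the probe
id.

## Sample QC and batch handling

RLE and NUSE are summarized per sample by quartiles using the type-7
(linear interpolation) estimator, fixed for reproducibility. A sample
fails when |RLE q25| or |RLE q75| exceeds 0.5 (log2 units, boundary
exclusive for removal: removal requires strict exceedance) or when a NUSE
quartile leaves the band [2 − 1.05, 1.05] = [0.95, 1.05]; the published
"±1.05" is read as a band symmetric around the NUSE reference value 1,
and the bound is configurable. By default the pipeline computes RLE
**within each dataset/batch**: centering against within-batch feature
medians keeps an additive location difference between datasets — a batch
property, not an array-quality problem — out of the quality statistics.

Batch adjustment is declared as per-feature, per-batch mean centering
(grand mean added back). This removes additive batch structure exactly and
is the entire contract: no surrogate-variable estimation is attempted, so
batch effects that interact with biology (non-additive, feature-specific
direction flips) are out of scope. Batches of one sample are rejected.

## SAM (two-class, unpaired)

The canonical two-class unpaired variant with equal-variance pooled
standard error:

    d = (x̄₁ − x̄₂) / (s + s₀),
    s = sqrt[(1/n₁ + 1/n₂) · (SS₁ + SS₂)/(n₁ + n₂ − 2)]

s₀ is chosen on the grid of α-quantiles of s (α = 0, 0.05, …, 1): features
are windowed into s-quantile bins (min(100, m/5) bins), and the candidate
minimizing the coefficient of variation of the bins' MADs of d is taken.
A fixed s₀ (including 0, giving the ordinary t statistic) can be forced.

Label permutations are **exhaustive** whenever the number of distinct
group-1 index sets C(n, n₁) is within the permutation budget (default
1000), otherwise that many uniform random permutations are drawn from the
mandatory seed. s₀ is computed once from the observed labeling and reused
for permuted statistics. Sorted permuted d are averaged into the expected
order statistics d̄. For a threshold Δ, scanning outward from the origin of
the d-vs-d̄ plot, the first sorted d exceeding its expectation by ≥ Δ fixes
the upper cut (everything above is called up), and symmetrically below.
π₀ is estimated as the fraction of permuted d inside the observed
interquartile range, scaled by 2 and capped at 1.

**False-call estimator.** The estimated FDR at Δ is
π₀ · (average over permutations of the count of permuted d beyond the
cuts) / (number called), capped at 1; a feature's q-value is the minimum
FDR over all grid thresholds at which it is called. The permutation
*average* is the original formulation of the expected false-call count;
the per-Δ table also reports the permutation *median*, but the median is
not used for q-values because it is badly liberal for small call sets — at
a cut near the observed extreme, more than half of the permutations often
show zero exceedances, making the median 0 and producing spurious q = 0
calls on null data. With the average, the attainable q floor for a called
feature is ≈ π₀/B, so "q = 0" screening designs are operated at a
near-zero target (the pipeline default `q_target` is configurable).

Numerical conventions: all boundary comparisons against cut points, Δ
crossings and the π₀ interquartile window use a 1e-9 tolerance so results
are invariant to floating-point summation order, and the origin of the
cut-point scan is located with the same tolerance, which makes the calling
rule exactly mirror-symmetric under exchanging the two group labels.
Features with zero pooled variance and zero mean difference get d = 0.

Fold change is 2^(x̄₁ − x̄₂) (anti-logged group means on log2 input). The
1.5-fold variability filter keeps features whose **mean absolute log2
deviation** from their row mean is ≥ log2(1.5), boundary inclusive; an
alternative max-deviation reading is available by flag. Subgroup
contrasts run one flag-versus-rest SAM per molecular subgroup / lesion
flag on the MM samples, skipping degenerate flags; expression-quartile
stratification ranks samples by one feature, splits into four contiguous
blocks (remainders to the lower quartiles, ties broken by sample order),
and the gradual-modulation check requires strictly monotone quartile
medians.

## Progressive-trend screen

The Jonckheere–Terpstra statistic is U = Σ_{i<j} #{x ∈ Gᵢ, y ∈ Gⱼ : x < y}
with ties counted one half. `exact` mode enumerates every arrangement of
the pooled values over the group sizes (vectorized; the `auto` switch uses
exact up to 10⁵ arrangements — beyond that, enumeration cost outweighs the
approximation error). `approx` mode uses the normal approximation with the
tie-corrected null variance and a 0.5 continuity correction; on continuous
data its one-sided p is within 0.01 of exact on the small instances where
both run (asserted in the suite). On heavily tied small lattices the normal
approximation is necessarily cruder; expression values are continuous, so
this does not affect the screen. The two-sided p is 2·min(p_asc, p_desc)
capped at 1.

A feature is selected iff (i) its BH-adjusted two-sided JT p is < α,
(ii) its stage medians are **strictly** monotone along the stage order —
plateaus fail; the criterion exists to sharpen trends against the heavy
group-size imbalance (MM dominates the cohort), and a strict reading is
the sharpest consistent one — and (iii) Kruskal–Wallis p < α. BH is
applied to the JT p-values only by default (KW is a secondary unadjusted
gate); a `joint` mode adjusting both together is provided. Direction is
read from the median sequence. The screen is rank-based throughout and
therefore invariant under monotone increasing transforms.

Kruskal–Wallis uses the tie-corrected H with a χ² approximation; all
values identical gives p = 1 by convention.

## Clustering and branch enrichment

Samples are clustered by average linkage (UPGMA) on d = 1 − r (Pearson,
over the selected features, per-feature z-scored by default to match
SD-normalized expression heatmaps). Cophenetic distances reproduce merge
heights. For every internal branch and entity the one-sided hypergeometric
tail p of the entity count in the branch is reported (branch size n,
entity total K, cohort N): this formalizes "all controls cluster together"
statements. Caveat, by design: the p-values ignore the multiplicity of
branches scored and the fact that the tree was built from the same data —
they are descriptive per-branch quantities, not tree-wide tests. The best
branch per entity is reported; the root's p is 1 for every entity.

## Correlation screens

Partners are found at gene level: sense/antisense exon overlap (strand '.'
never resolves a sense/antisense call) and pseudogene→parental links from
the annotation (any chromosome). Pearson r with the two-sided t
approximation on n − 2 df; pairs whose partner is not in the expression
matrix are kept with status "NA - not detected" and missing r — missing,
never zero. The trans screen computes all lncRNA × gene correlations via
standardized matrix product and retains r **strictly greater** than the
threshold (default 0.9, following the published wording), sorted
descending. 2^−ΔCt converts qRT-PCR threshold cycles; Wilcoxon rank-sum
and Kendall τ helpers cover the group comparisons made on such data.

## Synthetic-study generator

The generator is the validation substrate: a toy one-chromosome genome of
lncRNA loci (two exons each), coding loci, a configurable number of loci
where a coding transcript overlaps a lncRNA (to exercise univocality),
probes per locus, intergenic decoy probes, and a fraction of probes given
a second placement (to exercise the cross-hyb filter). Pseudogene links
tie a subset of lncRNAs to coding "parental" genes.

Probe intensities are additive on the log2 scale:

    x(p, s) = base(locus) + fluct(locus, s) + stage_shift(locus, entity(s))
              + batch_offset(batch(s)) + affinity(p) + N(0, noise_sd)

with base ~ N(7, 1) per locus, per-sample biological fluctuation
N(0, signal_sd = 0.3) (bivariate normal with the planted ρ for correlated
pairs), probe affinities N(0, 1) drawn once per probe (what median
summarization must tolerate), additive per-batch offsets (default 0 and
+0.3 — exactly the structure batch centering removes), Gaussian noise
sd 0.5 (log2 RMA-scale residual noise), and planted stage shifts
0, δ, 2δ, 3δ, 4δ from N to PCL (ascending; negated for descending).
Defaults: quarter-scale design N=3, MGUS=5, SMM=8, MM=42, PCL=9 mirroring
the cohort proportions; MM subgroup flags drawn at the characterized
panel's proportions (48/34/19/6/22 of 129) and lesion flags at
del13 0.45, del17 0.10, gain1q 0.40; 100 lncRNA and 30 coding loci with 4
probes each, so that planted effects stay a small fraction of the feature
space — on real arrays the overwhelming majority of probes are stable,
which is what RLE-based QC assumes. The within-entity variance components
are not published; signal_sd = 0.3 is a stand-in chosen to give realistic
RLE spreads and is exposed in config. All generators are pure functions of
(config, seed); bundles round-trip through GTF/BED12/BED6/TSV/JSON with a
checksummed manifest.

What passing on this generator does **not** show: robustness to
non-additive batch effects, probe affinity × sample interactions,
cross-hybridization that is sequence-driven rather than placement-driven,
non-Gaussian heavy-tailed noise, or annotation errors. Real-data
quantities (numbers of detected lncRNAs, sizes of signature lists) depend
on the cohorts and are not reproduced here.

## Published-table fixtures

The three result tables ship as TSV transcriptions with a sha256-pinned
manifest; loading verifies the checksum and the tables' structural
invariants (unique ids, closed vocabularies, ≥3 significant comparisons
per row of the first table). The first table's normal-sample arrow column
is stored as `normal_dir`; the per-comparison calls are stored as the
disease-side direction, and a derived `disease_dir` (the inverse of the
normal arrow) avoids sign confusion in counting queries. Correlation cells
printed as NA are stored as missing. In the lesion table, the "resides on
chromosome 13" count uses the chromosome-band prefix "13" (three rows at
13q14 plus 13q12 and 13q32).

## Degenerate inputs and errors

Single-sample RLE, non-positive SEs, singleton batches, groups smaller
than 2, permutation budgets below 10, empty lncRNA annotation sets, p
values outside [0,1], fewer than 3 shared samples for correlation, fewer
than 4 samples for quartile stratification, and missing stages in the
trend screen all raise a typed `ValidationError` naming the problem;
all-true or all-false subgroup flags are skipped with a log entry rather
than failing the whole contrast run.

## Known limitations

- The SAM s₀ search and Δ grid follow one concrete, documented convention;
  other SAM releases differ in grid construction and report median-based
  FDR, so q-values are comparable in ranking but not guaranteed equal to
  any particular release's output.
- JT p-values for the full design use the normal approximation (the exact
  count of arrangements at n = 67 is astronomically large); accuracy below
  p ≈ 1e-12 is extrapolation of the normal tail.
- Branch-enrichment p-values are descriptive (see above).
- The paired diagnosis/relapse comparison machinery is limited to the
  generic two-group tests; no paired variant is provided.
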