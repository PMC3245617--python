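# Methods

`mirlineage` implements an integrated miRNA/mRNA expression analysis for a
multi-model tumor study design: several genetically engineered mouse (GEM)
mammary tumor models plus normal mammary glands, profiled on a custom miRNA
array that carries four replicate probes per mature miRNA, alongside a
standard mRNA array.  This note describes the statistical procedures, the
synthetic-data generator the package is tested against, the numeric
conventions, and the design choices that were genuinely open.

## Preprocessing

Input is a probes x samples table of log2 intensities with MAS5-style
detection calls ('P'/'M'/'A') supplied by upstream array software (the
package consumes calls; it never computes them).

1. **Probe selection.** Internal control probes, non-target-species probes
   and reverse-complement ('-' strand) probes are removed using the probe
   map's flags.
2. **Global median normalization.** Each array is scaled multiplicatively
   on the linear intensity scale so that every per-array median equals the
   median of the original per-array medians.  On the log2 scale this is an
   additive per-array shift; applying it twice changes nothing
   (idempotence to 1e-12).  A non-positive linear median is an error.
3. **Detection filter.** Probes called present or marginal in fewer than
   three arrays across the whole dataset are dropped.  'P' and 'M' count
   equally; no intensity floor is added.
4. **Per-array z-scores.** For the signature analysis each array is
   transformed to z = (x - mean)/sd across all probes on that array, using
   the sample standard deviation (n-1).  Either denominator is defensible
   and immaterial at ~1,300 probes; n-1 is the common microarray default
   and is pinned here for reproducibility.  Probes with zero variance across arrays are dropped
   with a logged warning first: they carry no comparative signal.

Z-scoring subtracts each array's mean exactly, so the signature stage is
immune to any residual per-array shift left by normalization.  The
differential stage works on the normalized log2 matrix, as the upstream
analysis convention dictates.

## Two-class differential analysis (basal vs luminal)

The moderated statistic is `d_i = (mean1_i - mean2_i) / (s_i + s0)` with
`s_i` the pooled equal-variance two-sample standard error and `s0` a fudge
constant.  `s0` defaults to the median of the `s_i` — simpler and exactly
reproducible, unlike the coefficient-of-variation percentile search of some
implementations; `s0 = 0` reduces `d` to the ordinary t statistic and the
probe ranking then matches the t ranking exactly (tested).

Significance comes from class-label permutations with the permuted
statistics pooled across probes:

    p_i = (1 + #{pooled |d*| >= |d_i|} / n_probes) / (n_perm + 1)

The pseudocount keeps p strictly positive.  When fewer distinct label
assignments exist than permutations requested, all assignments are
enumerated (the identity is then part of the null and the exact
permutation p is returned without a pseudocount).  Exceedances are counted
with a ~1e-9 relative tolerance because the observed and permuted
statistics travel through different (algebraically identical) vectorized
paths.

The FDR at a threshold is SAM's median convention: the median over
permutations of the number of permuted |d*| above the threshold, divided
by the observed count, capped at 1.  Per-probe q-values take the minimum
FDR over thresholds at or below the probe's |d| (suffix minimum), making q
monotone in |d|.  "FDR <= 0%" therefore means: in at least half of the
permutations, nothing anywhere in the matrix was as extreme.  At that
cutoff the single most extreme null probe is a boundary case by
construction — whether its median permuted exceedance count is 0 or 1 is
close to an even draw on small matrices — so zero-false-call behavior is a
property of adequately sized designs (≈1,300 probes with planted effects
present), not of tiny ones.  Fold changes are reported on the linear scale
as larger-mean/smaller-mean with a direction flag, and plain equal-variance
t-tests with Benjamini-Hochberg adjustment accompany every table.

## Model-specific signatures

A probe is model-specific for a group when (i) every sample of the group
has z > 0.75 and (ii) the group's median z exceeds the third-highest z
among all pooled samples outside the group.  For continuous data (ii) is
equivalent to "no more than two outside samples above the group median"
(property-tested on random instances).  The all-samples reading of (i) is
the conservative interpretation of "z-scores > 0.75 within the model"; a
`min_fraction` option relaxes it.  Ties at the third-highest rank resolve
by taking the value at rank 3 of a descending sort.

The rule's own decision boundary, the margin
`median_z(group) - third_highest_z(others)`, is the permutation statistic.
Group labels are reassigned uniformly at random preserving group size;
p-values use the pooled permuted-margin null with the same pseudocount
form as above.  The permutation FDR at a margin cutoff is the mean number
of permuted *rule hits* at or above the cutoff divided by the observed hit
count.  Benjamini-Hochberg control is applied per group across features
(each group's signature is reported as its own list), on each feature's
best probe p.

Feature-level reporting is any-probe: a miRNA is reported for a group when
at least one of its replicate probes passes rule + p + permutation FDR and
the feature's BH q passes.  Reported probe counts per miRNA make the
roll-up transparent.  Running the same machinery with the normal-gland
group finds normal-only miRNAs with no code change.  A group may
legitimately yield an empty signature.

**Permutation depth.** `assemble_signatures` defaults to n_perm = 1999.
With the pooled pseudocount formula the smallest attainable p is
1/(n_perm+1); at 999 permutations that floor *equals* the 0.001 selection
threshold, so the threshold could only be met with zero pooled exceedances
— and permutations that happen to nearly re-assemble a planted group
always contribute a few large permuted margins.  1999 permutations put the
floor at 0.0005 and give the threshold real resolution.

## miRNA-mRNA integration

After restricting both platforms to their common samples (error below five
shared arrays), each miRNA probe is screened against every mRNA probe:
Pearson r, with p from `t = r sqrt((n-2)/(1-r^2))` on n-2 df, two-sided;
the screen calls an mRNA probe negative when r < 0 and p <= 0.001.
Constant mRNA probes have no defined correlation and are excluded from
both margins (logged).  Genes are the enrichment unit: a gene is negative
if any of its probes passes the screen, a target if the in-silico
prediction table lists it for the miRNA.  The 2x2 table over all screened
genes is tested one-sided for enrichment of negatives among targets — the
upper hypergeometric tail, numerically identical to Fisher's exact test
with the "greater" alternative (cross-checked against both
`scipy.stats.fisher_exact` and exact rational-arithmetic enumeration).
Significance is p < 0.05; no correction is applied across miRNAs (an
option applies BH).  Candidate targets are the negative predicted targets;
the consensus set of a miRNA is the intersection of candidates across its
replicate probes.  A two-sample Kolmogorov-Smirnov comparison of the
correlation distributions (predicted targets vs all genes, per probe,
using each gene's most negative probe r) quantifies the left shift; a
shift is declared only when the target mean is lower *and* KS p < 0.05.

## Synthetic data generator

The generator emulates the study design so every stage can be exercised
and calibrated without external data.  Defaults mirror the study: nine
groups (three basal-like models, five luminal-like, one normal) of 4-7
arrays each (47 total), 334 miRNAs x 4 replicate probes = 1,336 probes,
~2,000 genes with 1-3 probes each on the mRNA side, and an mRNA platform
missing two of the samples.

Everything is additive on the log2 scale with Gaussian noise:

    value[probe, sample] = feature baseline + probe offset (sd 0.1)
                         + array effect (sd 0.2) + planted delta
                         + noise (sd 0.3)

* **Baselines** are drawn from a normal distribution centered in
  `baseline_mean_range` (default 6-12 log2) with sd = range/5, truncated
  to the range.  A unimodal log-intensity distribution is what real
  single-channel arrays show, and it is a working assumption of global
  median normalization: the per-array sample median must be a precise
  anchor.  (A flat baseline distribution makes the median estimator noisy
  enough to leave shared per-array residuals that masquerade as
  differential signal.)
* **Model-specific miRNAs** (default 5 per group, delta 2.0 log2) are
  up-shifted in one group's arrays and draw their baselines from the upper
  intensity band (default 9.5-11.5 log2): the phenomenon the z-score rule
  detects is *high* expression restricted to one model, which a species
  near the noise floor cannot exhibit on the per-array z scale regardless
  of how specific its regulation is.
* **Subtype miRNAs** (default 10, delta 2.0) are up-shifted in all basal
  (or all luminal) tumor arrays; normal glands stay at baseline.
* **Regulation.** Each regulated gene follows
  `baseline + regulation_slope x z(regulator) + noise`, where z is the
  regulator miRNA's standardized latent abundance (so the slope is
  comparable across miRNAs) and slope defaults to -0.8 with gene-level
  noise 0.5.  Regulators are planted miRNAs with *mutually distinct*
  profiles — at most one per model group and one per subtype direction —
  because two regulators with the same planted profile are statistically
  indistinguishable and their target sets would cross-recover, making the
  ground truth unidentifiable.  Each regulator's ~20 true targets are
  diluted among 130 decoy genes drawn independently of all expression
  (prediction false positives); additional decoy-only miRNAs carry pure
  decoy target sets for calibration.
* **Detection calls** are generated, not derived from intensities: a
  configurable fraction of probes (default 5%) is absent in all but at
  most two arrays — exactly the class the detection filter removes.
* **qPCR panel.** -dCt = -12 + 1.0 x (mean log2 intensity across the
  feature's probes) + noise, so array/qPCR concordance is positive by
  construction; the noise sd is the knob.

With a fixed seed every emitted table is byte-identical across runs.  A
`null_config()` helper zeroes all deltas and the slope for calibration
runs.

What the generator does **not** emulate: scanner or spatial artifacts, dye
effects, intensity-dependent (loess-type) bias, probe-sequence effects,
correlated biological co-expression modules beyond the planted effects,
and translational (protein-level) repression.  Passing tests therefore
demonstrate correctness and calibration of the statistics under the
stated generative model, not performance on real arrays.

## Problem sizes and runtime choices

Calibration runs use 20 synthetic studies of 300 miRNAs x 4 probes across
9 groups of 5 with 999 permutations; recovery runs use the study-scale
default (334 miRNAs, 47 arrays) with 1999 signature permutations.  These
sizes keep each analysis deterministic and reproducible on a single CPU in
minutes while matching the dimensions the procedures were designed for.

## Known limitations

* The permutation p-values pool across probes (the standard SAM null); a
  per-probe null is available but quadratically more expensive.
* The median-based FDR-0 cutoff is intrinsically a boundary rule; on
  matrices with only a few hundred probes the top null probe's q flips
  between 0 and a positive value across seeds.
* Fisher enrichment treats genes as exchangeable; correlated genes (e.g.
  co-regulated modules) would make the test anti-conservative on real
  data.
* The strain screen for normal glands is supported structurally (any two
  sample-sheet levels can be compared) but no multi-strain joint test is
  provided; three strains decompose into pairwise runs with BH across the
  union.
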