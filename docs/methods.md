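# Methods

This note documents the models, conventions, numerical choices and known
limitations of `clonorigin`. It describes what the code computes; every
empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted independently.

## Coordinates and formats

All genomic coordinates are 1-based and inclusive at both ends — the
convention of segmented copy-number (SEG) tables and printed clinical
reports. Converters to 0-based half-open (BED-style) coordinates exist
at the I/O boundary only and are used nowhere internally. Chromosome
labels are normalized to a `chr` prefix and compared as exact strings;
sorting uses a configurable karyotype order (chr1–chr22, chrX, chrY,
chrM by default, unknown labels after). Thousands separators in
coordinates are stripped on input and never emitted. Genome builds are
treated as opaque metadata: nothing in the pipeline converts between
builds, so all inputs of one analysis must share a build.

Invalid records (interval end before start, allele frequency outside
[0, 1], supporting reads exceeding depth, overlapping segments within
one sample) are rejected at parse time with the offending line or pair
named; nothing is silently repaired.

## Somatic-event inclusion filters

A mutation call is retained iff coverage ≥ 100×, variant-supporting
reads ≥ 5, not catalogued in dbSNP, and absent from the matched
germline sample. The bounds are read literally and inclusively: a call
at exactly 100× with exactly five supporting reads passes. Both flags
are input columns — dbSNP lookup and tumor/normal comparison happen
upstream in the caller. Whether the five-read bound counts
variant-supporting or total reads is ambiguous in common usage; the
default counts variant-supporting reads, with a config switch
(`alt_read_mode`) for the other reading. The filter is evaluated per
candidate independently — a low-support call is not rescued by being
shared across lesions — and is idempotent and monotone: tightening any
threshold can only shrink the retained set.

Gene-level CNV calls use strict symmetric thresholds on the read-depth
log2 ratio: gain above +0.7, loss below −0.7, neutral otherwise
(values at exactly ±0.7 are neutral). Lesion summaries report the
coverage standard deviation with the n−1 divisor by default
(`coverage_sd_mode="population"` switches to n), since published
summary tables rarely state which was used.

## Shared-event concordance and route inference

Mutation identity defaults to (gene, chromosome, position, ref, alt);
a relaxed mode drops the alleles and matches on gene + coordinate only.
Strict matching is the default because allele-blind matching can merge
distinct substitutions at one site; the relaxed mode exists for
compatibility with summaries tabulated that way. Chromosome-level CNVs
match only on exactly equal intervals — deliberately conservative, as
array- and sequencing-derived breakpoints rarely coincide by chance; an
optional reciprocal-overlap mode (fraction of both intervals) is
provided but off by default. Gene CNVs match on (gene, direction).

The Venn decomposition is computed by explicit set algebra on identity
keys, so inclusion–exclusion holds exactly by construction; the
`union_from_counts` helper applies the same identity to tabulated
counts when only published Venn numbers are available.

The pairwise relatedness score is the unweighted count of shared
mutations + shared CNV intervals + shared gene CNVs (weights are
config-exposed but 1 by default — the biological argument is made from
counts, and any reweighting would need calibration data we do not
have). Route inference takes the lesion with the minimal total event
burden as the origin (metastases accumulate events on top of the
founder genome), then appends remaining lesions by descending
relatedness to the current chain tail. Ties are broken
lexicographically by lesion id and flagged in the output rather than
hidden; note that under a pure truncal/lineage model the origin's
relatedness to each branch lesion is identical by construction (both
equal the truncal count), so the first hop is frequently flagged. If
every pairwise score is zero the ordering is flagged `unresolved`.
This is a greedy ordering heuristic, not phylogenetic inference; for
more than a handful of lesions a proper tree method should be used.

## Region-matrix construction

Per chromosome, every segment start and every end+1 over all samples
becomes a breakpoint (closed–closed arithmetic with the end+1 sentinel
avoids off-by-one at shared boundaries); the maximal intervals between
consecutive breakpoints covered by at least one sample form the region
set. Because region boundaries refine every sample's segmentation, a
region is covered all-or-none by any sample, and the matrix entry is
the covering segment's value or 0 (log2-neutral — segment absence means
no detected deviation; the fill value is config-exposed). Regions
covered by no sample are not emitted by default (`emit_gaps` adds
them). Values are taken as supplied; no re-centering or integer-copy
conversion is applied, since segmentation and calling are upstream
concerns.

Correctness is established against a brute-force per-base oracle: on
random genomes up to 10 kb, expanding every (region, sample) entry back
to bases reproduces the per-base value map implied by the raw segments
exactly, and the matrix footprint equals the union of segment
footprints. Construction is invariant to cohort order, and adding a
sample can only split regions, never merge them.

New samples (a patient's lesions) are projected onto an existing
cohort region set by length-weighted averaging of their segment values
over each region, counting uncovered bases as the fill value. This
reduces to the exact segment value when a single segment covers the
whole region, and shrinks partially covered regions toward neutral —
preferable to hard assignment because a projected sample's breakpoints
need not align with the cohort's.

## Signature selection

Each region is screened by one-vs-rest binomial logistic regression of
class membership on the region value; the test is the likelihood-ratio
χ²₁ against the intercept-only model, and a region's p-value is the
minimum over classes (per-class p-values and slope directions are
retained). Selection keeps regions with p < α, strict, α = 10⁻¹² by
default. The cutoff is deliberately extreme: a genome-wide screen over
~10⁵ regions needs roughly Bonferroni-level stringency, and the LRT
statistic of even a perfectly separating region is bounded by the null
deviance (≈ 2n·H(π) for class fraction π), so α = 10⁻¹² is only
attainable with at least a few dozen samples — small pilot cohorts
should relax α accordingly.

Because the screen fits one single-covariate model per region per
class, it is implemented as a Newton/IRLS iteration vectorized across
all regions at once (the per-region Hessian is a closed-form 2×2
solve). Numerical safeguards: a 10⁻⁸ ridge on the Hessian diagonal, the
linear predictor capped at ±30, at most 60 iterations with a 10⁻¹⁰
step-norm convergence tolerance, and p-values floored at the smallest
positive double. Constant-value regions get p = 1 and a `degenerate`
flag; perfectly separated regions converge to the capped (penalized)
fit, yield a finite tiny p-value, and carry a `separation` flag. The
test suite checks the scan against statsmodels' binomial GLM per region
(agreement to 10⁻⁵ relative away from separation), against a
label-permutation oracle on a strong-effect example, and for
approximate uniformity of null p-values (Kolmogorov–Smirnov). A
per-region one-way ANOVA F-test (`method="anova"`) is offered as an
alternative scorer for continuous-effect screening.

## Discriminant classification

With selected features typically outnumbering samples, the classifier
is a Gaussian discriminant with *diagonal* pooled within-class
covariance: per-class means, one pooled variance per feature (dof
n − C, floored at ε = 10⁻⁶ so constant features stay finite), and
class priors (empirical frequencies by default, uniform or explicit on
request). Prediction is the argmax of log-prior plus summed per-feature
Gaussian log-density; exact ties resolve to the earlier class label and
are flagged via `predict_verbose`. A full pooled-covariance mode
(classic LDA) is allowed only when features < samples. On one feature
and two classes the decision boundary equals the textbook LDA threshold
(μ₁+μ₂)/2 − s²(log π₁ − log π₂)/(μ₁−μ₂); the suite verifies agreement
to 10⁻⁹ by root-finding on the score gap.

Accuracy is reported under two labelled protocols: stratified k-fold
cross-validation (default k = 5) with signature selection re-run inside
every training fold — held-out samples never influence the feature set
— and resubstitution, which flatters the model but matches how
published accuracies are sometimes computed. Both appear in the origin
report, clearly labelled. All cross-validation randomness flows through
one integer seed.

## Synthetic data: what it emulates, and what it does not

The cohort generator plants, per cancer type, a disjoint set of
signature regions (default 10 per class, lengths 0.5–2 Mb on a
4 × 50 Mb genome) where that class's samples carry a log2 shift of
±0.8 plus N(0, 0.1) noise; all samples additionally receive 10
passenger segments placed uniformly with rejection against overlap,
near-neutral N(0, 0.1) values with a 5% chance of a sporadic ±0.8
shift. Default 40 samples per class across three classes — a
scaled-down stand-in for a several-hundred-sample multi-cancer training
set, chosen to keep the full pipeline fast while leaving the selection
cutoff attainable.

The patient generator produces lesions that share a truncal event set
(default 29 mutations, the origin class's full signature CNV profile,
and 5 gene CNVs), branch-shared events for lesions that diverged later
(default: a bile-duct/omentum branch with 17 mutations, 6 CNV intervals
and 2 gene CNVs), and per-lesion private events (25/38/42 mutations)
— counts chosen to echo a published three-lesion hepatobiliary/
pancreatic case. Allele frequencies are Beta(1.2, 25), putting roughly
two thirds of calls under AF 0.05 as observed in deep-sequenced, impure
FFPE tumor samples; depths are N(450, 200) truncated at 100×, and
supporting reads are floored at 5 so generated events always survive
the inclusion filters (the generator models true somatic events, not
caller noise). Mutation coordinates are drawn without replacement, so
coincidental sharing is impossible and downstream Venn counts equal the
generator's bookkeeping exactly.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: realistic CNV length/recurrence
distributions (passengers are uniform), GC/wave artefacts and
segmentation noise, subclonal mixtures and purity variation,
trinucleotide mutational signatures, caller false positives, or
convergent evolution producing coincidentally shared events. Recovery
results on synthetic data are a validity check of the machinery, not an
accuracy claim for clinical cohorts.

## Degenerate inputs and determinism

Empty mutation lists are legal everywhere except `low_af_fraction`,
which raises (the statistic is undefined). An empty cohort, a class
with fewer than two samples, a class smaller than the fold count, and
a selection round that keeps zero regions all raise explicit errors
rather than degrading silently. Every stochastic entry point takes a
seed; per-sample generator streams derive from one `SeedSequence`, so
outputs are reproducible and identical configurations produce
byte-identical reports (timestamps appear only in log lines). Pipeline
outputs embed the seed and a hash of the full configuration.

## Known limitations

- Exact-interval CNV matching between lesions is conservative and will
  miss true shared events re-segmented with slightly different
  breakpoints; the reciprocal-overlap mode trades precision for recall.
- The route heuristic assumes a monotone accumulation of events along
  the metastatic chain and cannot express polyclonal seeding or
  re-seeding.
- The diagonal covariance ignores correlation between neighboring
  regions, which inflates confidence scores (though rarely the argmax);
  region-level dependence would require a structured covariance model.
- One-vs-rest screening with a min-p summary slightly favors classes
  with extreme prevalence under empirical priors; the ANOVA scorer is
  symmetric but assumes homoscedastic Gaussian values.
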