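# Methods

## The measurement model

A two-color competitive hybridization co-hybridizes two dye-labeled cDNA
samples to one array; the per-probe quantity of interest is the log2 ratio
of the two channels.  The experimental design dissects a 2x2 treatment
layout (testosterone, MAA, both, vehicle) into four competitive
comparisons:

| comparison | numerator | denominator |
|---|---|---|
| 1 | testosterone | control |
| 2 | MAA | control |
| 3 | testosterone + MAA | testosterone |
| 4 | testosterone + MAA | MAA |

Each comparison is measured on replicate arrays — pooled biological
replicates, each pool hybridized in both dye orientations (reverse-pair /
dye-swap).  The default of two pools x two orientations = 4 arrays per
comparison is configurable: the per-comparison array count is a design
assumption, not something the analysis depends on structurally.

## Feature filtering and normalization

Features are excluded when saturated in **both** channels or flagged as
non-uniformity outliers in **either** channel; single-channel saturation is
retained.  Excluded features carry a machine-readable reason
(`saturated_both` / `nonuniform`).

For each array, M = log2(I_A / I_B) with a pseudo-intensity of 1.0 added to
both channels (guards zeros; biases a true log-ratio by ~2^-A, negligible
above A ≈ 10), negated on reverse-orientation arrays so the treatment is
always the numerator.  The intensity-dependent dye bias is estimated by
LOWESS of M on A = (log2 I_A + log2 I_B)/2 (span 0.3) and subtracted; a
flat trend reduces this to a constant shift, so "linear" normalization is
the degenerate case of the same operation.

The trend fit is deliberately two-stage: a first non-robust LOWESS pass
flags outliers at 6 robust standard deviations (MAD-based) of its
residuals, and the trend is refit on inliers only and interpolated
everywhere.  Strongly regulated genes are exactly such outliers; a
single-stage fit (including library-internal robust iterations, which
degenerate when the residual MAD is zero) lets them pull the bias curve
toward themselves and eat part of their own signal.  With an injected
smooth bias of 0.3 log2 units, residual bias per intensity decile is below
0.02 log2 units at study scale (the acceptance suite asserts < 0.05).

## Error model and replicate combination

The upstream platform's proprietary error model is not reproducible from
published information; the package uses a fully specified surrogate with
the same statistical shape — intensity-stabilized variances, error-weighted
averaging, one p-value per probe.  Per measurement,

    sigma_i^2(A) = max(sigma_floor^2,
                       2 [(sigma_mult/ln2)^2 + (sigma_add/(2^A ln2))^2])

(defaults sigma_add = 30 intensity units, sigma_mult = 0.15 on the natural
log scale, sigma_floor = 0.05 log2 units), the additive term dominating at
low intensity.  The combined estimate per probe is the inverse-variance
weighted mean; its standard error is

    SE = sqrt(max(1 / sum w_i,  s_w^2 / n))

where s_w^2 is the weighted unbiased variance of the replicate M's.  The
max() keeps over-dispersed probes from being anti-conservative at the price
of mild global conservatism: under a fully null simulation the fraction of
probes with p < 0.005 is ~0.003–0.005 rather than exactly 0.005 (measured
counts 16–33 over seeds on 6,416 probes, against 32 expected), and adding
an outlying replicate can legitimately widen the empirical term.  p-values
are two-sided normal tails of xbar/SE, floored at 1e-300.  Signed fold
change is 2^xbar for xbar >= 0 and -2^(-xbar) otherwise, so |fold| >= 1
always.  No multiple-testing correction is applied per probe; instead the
pipeline reports the expected-by-chance count (alpha x number of tests,
rounded) and the apparent FDR (100 x expected-among-selected / observed
significant calls).

## TFS classification

A comparison call is 1 (up) if fold > 2 and p < 0.005, 2 (down) if
fold < -2 and p < 0.005, else 0 — both thresholds strict, which matters
only for exactly-boundary values.  The four calls define the TFS code
`W.d1d2d3d4`: W is the sum of binary flags 1, 2, 4, 8 over non-null
comparisons; the digits give per-comparison direction.  Codes are
serialized as strings (never floats — "6.0220" must keep its trailing
zero).  All 81 digit tuples round-trip text <-> code (exhaustively tested).

Of the 80 non-null codes, 27 map to named interaction classes — I
(independent responses), IIa/IIb/IIc (one-way or mutual enhancement),
IIIa–IIId (one agent blocks the other, with or without single-agent
activity); the remaining 53 are "other".  The taxonomy is an exact lookup
table, taken as given rather than re-derived (e.g. 15.2112 sits in class I
even though it responds on all four comparisons).

Redundant probes: when several probes of one gene show the *same* code,
one representative is kept — smallest minimum p over the four comparisons,
ties broken by lexicographic probe_id (the choice of representative is
unspecified upstream; this one is deterministic).  Probes of one gene with
*different* codes are all retained.  Unannotated probes pass through
differential expression but are dropped from gene-level tables.  "Genes of
interest" (the percentage denominator) are genes with at least one
non-null call.

## Enrichment

Per TFS group and gene set: overlap k, group size m, set size K (after
intersecting the set with the universe), universe N.  p is the one-sided
Fisher's exact / hypergeometric upper tail P(X >= k); the enrichment score
is fold enrichment (k/m)/(K/N) (several "enrichment scores" circulate; fold
enrichment is the conventional observed/expected choice).  k = 0 gives
score 0, p = 1.  The universe defaults to all annotated genes entering the
analysis — the platform background, not the responsive genes.  The
procedure is overlap counting with Fisher's test, not ranked-list GSEA.
Selection keeps sets with p < 0.001 and k > 5 in at least one group, and
groups with at least one such set; a stricter display preset (p < 0.0001,
k > 10) is provided.  Surviving -log10 p matrices are ordered by
average-linkage hierarchical clustering on 1 - Pearson distance (constant
rows are assigned distance 1 to anything non-identical), deterministic with
ties resolved by input order.  No correction across sets, consistent with
the raw-p selection filter.

## Synthetic data

The generator's role is ground truth: each planted gene carries a 4-tuple
of direction calls and a target |log2 effect| (default 2.0, i.e. 4-fold —
comfortably above the 2-fold call threshold), which fixes the TFS code and
class it should receive.  Per channel,

    I = 2^(baseline + effect + bias) * exp(N(0, sigma_mult)) + N(0, sigma_add)

clipped at zero, with baseline ~ N(10, 1.5^2) log2 units per probe.  The
generator's noise parameters are by construction the same quantities the
error model estimates with, which is what makes null calibration and
planted recovery meaningful end-to-end checks.  The dye bias is a smooth
quadratic of the noiseless mean log intensity (amplitude 0.3 log2 units)
attached to channel A — i.e. to a dye, not a sample — so dye-swap
averaging cancels it and LOWESS removes it within-array.  Features are
flagged saturated-in-both (rate 0.005, intensities forced to 65535) or
non-uniform (rate 0.01, intensities corrupted 0.2–5x), so filtering is
consequential.  Redundant probes (100 genes by default) share effects but
not noise.  All randomness flows from a single integer seed through one
`numpy` Generator; identical designs give bit-identical output.

Study-scale defaults used by the analysis scripts and the acceptance
checks: 2000 genes, 300 planted uniformly across the 27 named codes plus
two "other" codes, 4 arrays per comparison; null-calibration runs use
6,416 probes, matching the scale at which an expected-by-chance count of
0.005 x 6,416 ≈ 32 is meaningful.  These sizes keep a full simulate →
classify → enrich cycle under a second while leaving ~10–15 genes per
planted TFS group.

What the generator does *not* emulate: spatial artifacts, probe-sequence
affinity effects, correlated (biological) variation between pools,
platform-specific file formats, and ratio compression at high fold change.
Passing tests therefore validate the statistical machinery, not robustness
to every failure mode of real arrays; per-probe p-values from the
surrogate error model are not expected to reproduce any proprietary
pipeline's numerically.

## Numerical and degenerate-input choices

- LOWESS requires >= 50 usable features per array; span must be in (0, 1].
- A probe with no usable measurement in a comparison gets no result there
  and is treated as not-significant when codes are formed; a probe with no
  usable measurement anywhere is absent from results.
- Empty enrichment selections produce empty matrices, not errors;
  matrices smaller than 2x2 skip clustering and keep input order.
- `expected_false_positives` rounds half away from zero to the nearest
  integer (6,416 x 0.005 = 32.08 -> 32); class percentages round the same
  way; apparent FDR is reported to 2 decimals.
- An all-null assignment table yields an empty summary (no denominator).

## Known limitations

- The error model is a documented surrogate; absolute p-values are
  calibrated only to the extent the two-component noise model matches the
  data (slightly conservative by design, see above).
- Gene identifiers are matched exactly (case-sensitive); no alias
  resolution between annotation and GMT files.
- Enrichment ignores the dependence between overlapping gene sets; p-values
  are raw by design.
- Class counts and percentages on real data depend on upstream platform
  and annotation choices that this pipeline does not attempt to emulate.
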