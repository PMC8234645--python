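# Methods

## The cleaning procedure

`atlas-scrub` curates a wide expression matrix (probes × hybridizations,
non-negative linear-scale values) by removing columns that fail either of two
indices, plus three structural checks. The rules run in a fixed priority
order; each removed column is charged to the *first* rule that catches it,
which makes the ledger a partition of the input columns and the whole
procedure idempotent (re-cleaning a cleaned matrix removes nothing):

1. **Duplicate header repair** (`duplicate_name`). Identical column headers
   are a paste error that shifts the identity of every later column. The
   first occurrence of each repeated header is kept, later ones removed
   (configurable to remove all).
2. **Duplicated data** (`duplicate_data`). Columns whose value vectors are
   exactly equal (tolerance 0 by default; text exports of pasted columns are
   bit-identical) are grouped by union-find closure and all copies removed —
   provenance is ambiguous, so neither copy is trusted. A relative tolerance
   is available for re-quantized exports; the pairwise relation is then not
   transitive, which is why closure is taken.
3. **Low-sum groups** (`low_sum`). A column whose sum over all probes falls
   below `sum_min` (default 10⁶, strict `<`) marks its whole sample as
   systematically corrupted, so every replicate of that sample is removed.
   The canonical failure mode is a study inserted after log transformation:
   sums collapse by ~two orders of magnitude.
4. **Singletons** (`singleton`). Samples with a single hybridization carry no
   replicate-concordance evidence and are dropped (configurable off).
5. **Replicate concordance** (`low_correlation_replicate`). Pearson
   correlation across all probes, on linear values, for every replicate pair
   within a sample; threshold `r_min = 0.90`. Two replicates: keep both iff
   the pair passes, else drop both. Three replicates: keep all when all three
   pairs pass; keep exactly the two columns of the highest-r passing pair
   when some but not all pairs pass; drop all when none passes. An undefined
   correlation (zero-variance column) counts as below any threshold — a flat
   column cannot demonstrate concordance. For the (rare) n > 3 case the rule
   generalizes greedily: repeatedly drop the member with the lowest mean
   correlation to the rest until all remaining pairs pass or fewer than two
   remain (then drop all).

Priority-order rationale: cheap structural defects are settled before any
correlation-based decision so that, e.g., a pasted duplicate cannot influence
a replicate-rule outcome. With non-overlapping defects the order does not
change totals; where defects overlap (a low-sum singleton, say) the order
fixes the category label deterministically (that column is `low_sum`).
Replicate correlations for QC are computed on linear values; the log/linear
choice is exposed at the co-expression layer instead, where it is an analysis
decision rather than a cleaning decision.

### Log-insertion confirmation

A low-sum group is *confirmed* as log-inserted when the antilog of its values
reproduces the sample-level means deposited alongside the atlas (those means
having been computed from the original linear values). For each candidate
base b ∈ {2, e, 10}: compute `mean over replicates of b^value` per probe and
compare with the means column; the group is confirmed if ≥ 99% of probes with
positive deposited mean agree within 1% relative deviation, and the
best-agreeing base is reported. The 99%/1% criterion is a package convention
(the underlying phenomenon is near-exact agreement); overflow during the
antilog simply disqualifies that base, which is also what rules out healthy
groups (antilog of ~400-scale linear values diverges). Without a means
matrix the verdict remains "suspected" on the low-sum evidence alone.

## Co-expression analysis

Pearson (linear or log scale), Spearman, and Kendall τ-b between probe
profiles across hybridizations. The log transform is `log2(x + 1)`; the base
is irrelevant to Pearson (log bases differ by a positive scalar and Pearson
is affine-invariant), and the pseudocount of 1 guards zeros. Rank methods are
invariant under strictly monotone transforms, so the scale argument is
ignored for them (noted in the output) — this is also why they are largely
insensitive to the outlier columns that cleaning removes. Undefined
coefficients (zero-variance probes) are reported as NaN, never as 0, and are
excluded from rankings rather than ranked last. One-vs-all rankings default
to a top-49 view for enrichment follow-up; sibling probes of the same gene
are deliberately not excluded, since a sibling ranking first is the natural
positive control. Kendall is O(probes² · columns²) in the naive all-vs-all
setting and is intended for explicit probe lists.

Differential tables are elementwise cleaned − original on identical axes;
the summary statistic is the NaN-aware mean over off-diagonal cells (square
tables) or all cells (rectangular).

## Enrichment

One-sided hypergeometric upper tail (Fisher exact, enrichment side) per term
with k ≥ 1 in the query, Benjamini–Hochberg FDR across tested terms, α = 0.05
default. The background defaults to all probes of the analysed (cleaned)
matrix; unannotated probes count toward N but no K. Terms with k = 0 are not
reported (p ≈ 1, uninformative). Ontology ancestor propagation is off by
default and available when an OBO file is supplied.

Because the test statistic is discrete, its null p-values are super-uniform
rather than uniform; the calibration test therefore applies the randomized
probability integral transform computed from the exactly enumerated
hypergeometric pmf before testing uniformity (a naive continuous KS on the
raw p-values would reject any exact discrete test by construction).

## The synthetic-atlas generator

Values follow a log-normal factor model: `log x_gst = μ_g + η_gs + ε_gst`
with per-probe baseline log-sd 0.6, per-sample effect log-sd 0.8 (shared by
replicates), replicate noise log-sd 0.05, and μ calibrated so the per-probe
mean is 2×10⁷/50,900 ≈ 393 — healthy full-size columns then sum to ≈ 2×10⁷,
and sums scale proportionally at reduced probe counts (the low-sum threshold
scales the same way via `scaled_sum_threshold`). Under these defaults healthy
replicate pairs reach sample Pearson ≈ 0.995 and a corrupted replicate
(independent redraw of η, preserving the marginal and hence the column sum —
keeping the low-sum and concordance detectors orthogonal) drops its pairs to
≈ 0.25, comfortably either side of the 0.90 threshold. The log-scale spread
is kept moderate on purpose: the sample Pearson correlation of very
heavy-tailed log-normals converges slowly, and wilder tails would let healthy
pairs fluctuate far below their population correlation.

Gene modules replace the independent sample effect by
`loading · z_s + idio_sd · noise` with a per-sample latent z, giving a
within-module log-scale correlation of `loading²/(loading² + idio_sd²)`
(≈ 0.9 at the defaults 0.9/0.3) that survives rank and log transforms.

Planted defects: column scaling or log2 insertion (stored as
`max(log2 x, 0)` so the non-negativity invariant holds; at the calibrated
expression level well under 1% of probes are clipped, absorbed by the
detector's 99% criterion), exact column copies under different sample names,
repeated header blocks (fresh draws — the defect is the name collision), and
corrupted replicates. A truth manifest records every column's category, the
module membership of every probe, and the companion sample-means matrix
(means of the linear values, which is what makes log insertion detectable).

What the generator does *not* emulate: probe-level Affymetrix noise (PM/MM),
batch effects beyond the planted defects, normalization artifacts, or the
long-range correlation structure of real transcriptomes beyond the planted
modules. Passing detector tests therefore demonstrates correctness of the
decision rules under well-separated defects, not field performance on
borderline real-world columns.

### The accounting fixture

`mtgea_accounting_fixture` builds a 716-column atlas (default 5,000 probes)
planting, category by category: two samples' 3-replicate header blocks
repeated (6 extra columns); ten samples with corrupted replicates arranged to
lose 3/3/3/2/2/2/1/1/1/1 columns under the replicate rule (19); two
log2-inserted studies of five 3-replicate samples (30); two 12-column study
blocks duplicating each other pairwise (24); thirty single-replicate samples
(30); and healthy three-replicate filler (plus one two-replicate sample) up
to 716 columns. Cleaning removes 103 columns after header repair, leaving
607. The per-sample layout of the healthy filler is a convention; 5,000
probes keeps the fixture desk-sized while the proportional threshold
preserves full-scale semantics, and a larger probe count can be requested.
Defect sets are pairwise disjoint so the per-category accounting is exact.

## Numerical conventions

- I/O is strict: ragged rows, non-numeric, non-finite or negative cells and
  duplicate probe ids are hard errors naming the offending location. Headers
  are parsed by hand so duplicate column names survive parsing (they are a
  defect to detect, not to repair silently). Values are written with the
  shortest round-tripping float repr and parsed with correctly rounded
  string→double conversion, so read → write → read is bit-identical.
- Replicate grouping strips a trailing `_<integer>` from headers
  (configurable regex); suffix-less headers form singleton samples.
- Case-(2)/(3) ties in the replicate rule (two passing pairs with equal r)
  keep the pair with the lowest column indices.
- Correlation against zero-variance vectors: NaN, with a warning.
- All simulation randomness flows through one `numpy.random.default_rng`
  seed; identical seeds give identical matrices.
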