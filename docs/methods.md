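# Methods

## Data model

All tables are pandas DataFrames with fixed schemas (`cgiscreen.io`).
Genomic intervals are stored 0-based half-open (BED convention); every
user-facing region label is rendered 1-based inclusive as `chrom:start–end`,
the notation used for CpG islands in the methylation-array literature.
β-values live in [0, 1] with NaN as the missing marker; missing values are
allowed everywhere and each downstream operation defines its own
minimum-data rule rather than imputing. Genome builds are never
interpreted: coordinates are treated as opaque and must be consistent
between the probe manifest and the region definitions.

Array normalization is out of scope: inputs are assumed-normalized β-value
matrices. Probe-type bias correction, cell-type deconvolution and de-novo
DMR detection are likewise not attempted — regions are given.

## Region screen

For region *r* and sample *s* the summary methylation is the **median** β
of member probes with at least `min_probes` (default 1) non-missing values.
Probes are assigned to every region whose half-open interval contains the
probe's CpG coordinate; regions without probes are dropped and counted.

Per matched pair *i*, Δβ(r, i) = tumor summary − normal summary; the region
effect Δβ(r) is the mean over pairs. Significance is a paired *t*-test of
the Δβ(r, i) against zero (two-sided), requiring `min_pairs` (default 3)
complete pairs; regions with identically-zero differences carry no signal
and are excluded with a warning. An alternative aggregation
(`aggregation="diff_then_median"`: per-probe paired differences, then the
region median per pair) is provided because region summarization conventions
differ between toolkits; the default summarizes per sample first, which
keeps region-level β interpretable per specimen.

Benjamini–Hochberg adjustment is applied once across **all** tested regions
(hyper- and hypomethylated together, one family), implemented directly as
the step-up rule and cross-checked in the tests against a brute-force
oracle and statsmodels. Note BH is not idempotent: re-adjusting adjusted
p-values is a user error the API does not try to detect.

Selection uses strict inequalities — adjusted p **<** `fdr_cut` (default
0.05) and Δβ **>** `delta_cut` (default 0.25) for direction `hyper` (sign
reversed for `hypo`, absolute value for `both`). Directionality is enforced
by the Δβ sign filter, never by one-sided testing. Ranking is ascending by
adjusted p, ties broken by descending |Δβ| then region id, so output order
is deterministic. `top_k` (default 10) is only a view; the selected set is
not truncated.

Where both a paired and an unpaired test could describe a tumor/normal
design, the screen uses the paired *t*-test: the design is patient-matched
and the paired test conditions on that matching. Welch's *t* (with
Welch–Satterthwaite df) is reserved for genuinely unpaired contrasts such
as smoker vs. never-smoker strata. Whether array-era pipelines computed the
region statistic on the β or a logit scale is toolkit-dependent; this
package tests on the β scale, matching how Δβ thresholds are stated.

## Statistics kernel

`paired_t` and `bh_adjust` are closed-form implementations (scipy supplies
only the t distribution); `welch_t`, `mann_whitney_u`,
`wilcoxon_signed_rank` and `pearson_r` wrap scipy.stats with explicit
behavior: rank tests use the exact permutation null when all group sizes
are ≤ 25 and the data are tie-free, and the (tie-corrected) normal
approximation otherwise; Wilcoxon drops zero differences and refuses
all-zero input. Degenerate zero-variance input with a nonzero effect
returns the continuity convention (±∞ statistic, p = 0, flagged
`degenerate`) rather than NaN, so screens on near-constant synthetic data
fail loudly in filters, not silently in arithmetic. All tests are verified
against independent oracles: brute-force BH step-up, the closed-form t,
and exhaustive enumeration of rank-test nulls (all group assignments for
Mann–Whitney, all 2ⁿ sign flips for Wilcoxon).

`log2_fold_change` floors both arguments at `detect_floor` (default 1e−3)
before the ratio: qRT-PCR non-detects must not produce infinities, and the
floor should sit at the assay's practical detection limit.

## Candidate funnel

The four criteria and their defaults:

| criterion | rule | threshold | count rule |
|---|---|---|---|
| normal expression | any normal-tissue value ≥ `detect_floor` | 1e−3 | — |
| tumor silencing | tumor/paired-normal ratio < `tumor_ratio_cut` | 0.5 | ≥ 6 of 11 |
| cell-line silencing | line/normal-reference ratio < `cell_ratio_cut` | 0.2 | ≥ 8 of 14 |
| restoration | log₂(treated/vehicle) > `restore_log2_cut` | 2 | ≥ 2 of 3 |

All ratio and fold comparisons are strict (a ratio of exactly 0.5, 0.2 or a
fold of exactly 4 does not count), matching how ">50% reduction"-style
rules read. Pairs whose normal-side expression is below `detect_floor` are
excluded from the tumor-silencing denominator — a ratio against a
non-detect is meaningless — mirroring the "very low in normal tissue"
exclusion. Genes not expressed in normal tissue short-circuit: the
remaining criteria are reported as missing and `passes_all` is false.

When a panel's actual size n differs from the default, the required count
rescales as ⌈default_count / default_panel × n⌉, which reproduces the
6/11, 8/14 and 2/3 rules exactly at the default sizes. The count rule is
the sole authority: a fraction like 4/11 never passes the tumor criterion
regardless of how source tables may have highlighted it. Passing is the
conjunction of all four criteria; the report sorts by (passes_all, number
of criteria passed, tumor fraction, gene) and is byte-deterministic.

A packaged evidence matrix (`data/ladc_candidate_evidence.tsv`) encodes the
published nine-gene evidence table from a stage-I lung-adenocarcinoma
discovery cohort; cells like `10/11 (36/37)` parse into the primary
fraction plus extended-panel metadata that is retained but never scored.
The combination-treatment (HDAC-inhibitor) arm of restoration experiments
is not modeled: the demethylating-agent arm is the criterion.

## Validation analyses

Site-level percent methylation (0–100 scale) is compared per pair with the
paired *t* or the Wilcoxon signed-rank test — normality is never
auto-tested; the caller chooses via `use_rank_test`, since automatic
normality gating makes the test that was run data-dependent and
irreproducible. BH adjustment is applied across sites. On single-probe
regions, this analysis at 100×β agrees exactly with the β-scale screen
differences (tested).

Methylation–expression correlation is Pearson's r with the t-transform
p-value, computed by default on pooled tumor + normal samples (the pooled
cloud is what exhibits the silencing gradient; per-compartment correlation
is available via `contexts`). Constant vectors and n < 3 are flagged
not-evaluable rather than erroring, since panels routinely contain
uninformative sites.

Smoking stratification compares S vs. NS within one tissue compartment
(Welch *t* or Mann–Whitney U).

## Synthetic cohorts

`SimulationConfig` defaults are the emulated study conditions: 12
tumor/normal pairs (6 smokers / 6 never-smokers), 1000 CGI regions with
3–15 probes each, baseline (non-tumorous) β ~ Beta(3, 17) — mean 0.15, the
0.1–0.2 range typical of unmethylated CGIs — 5% of regions planted, probe
noise SD 0.03, values clipped to [0.001, 0.999] to avoid degenerate
variance at the boundaries.

The hypermethylation effect is drawn **per (region, pair)** from
N(`effect_delta` = 0.3, `effect_sd` = 0.05²), on top of a per-(region,
patient) baseline shared between the tumor and normal draw of that
patient. Drawing the effect per pair (rather than one fixed shift per
region) models biological heterogeneity between patients, and it makes the
region mean Δβ concentrate near 0.3 (SE ≈ 0.05/√12), so the planted regime
sits clearly above the 0.25 selection threshold — with a single per-region
draw, ~16% of planted regions would land below the strict Δβ cut by
construction and "recovery" would measure the generator, not the screen.
`TruthLabels.true_delta` records the realized per-region mean effect.

Expression coupling (on by default): planted genes are the silenced set.
Silenced genes get tumor/normal ratios below 0.5 with probability 0.9 per
pair; exactly 10 of the 14 cell lines (identity randomized) express below
0.2 of the normal reference — the count is fixed rather than Bernoulli so
that "≈10/14 silenced lines" holds by construction and the cell-line
criterion does not randomly fail the very regime it is meant to represent;
and all 3 treated lines restore with folds drawn uniformly from 5–50.
Non-silenced genes fluctuate log-normally around parity, giving a
per-criterion pass probability low enough that false candidates are rare
(< 1% per gene). With `coupling=False` the silenced set is drawn
independently of the planted regions, decoupling expression from
methylation truth for negative controls.

The site panel (default 46 pairs, 25 S / 21 NS, 5 sites) uses the same β
model scaled to percent; smoking status has **zero** effect by
construction (the null the stratified comparison should not reject).
Coupled expression decays exponentially in the sample's mean methylation,
yielding strong inverse correlation.

All streams derive from one master seed via `numpy.random.SeedSequence`
spawning (methylation / expression / sites), so any table can be
regenerated alone. Cohort files are written only through the package's own
writers.

What the generator does **not** emulate: Infinium I/II probe chemistry and
its intensity distributions, batch and slide effects, copy-number
confounding of β, cell-type composition, correlated probes beyond the
shared region baseline, and realistic qRT-PCR replicate error. Passing
recovery tests therefore demonstrates the pipeline's statistical logic
under its stated assumptions, not robustness to array artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script use 20 cohorts of 1000 regions × 12 pairs
(the defaults), which the package processes in roughly a second per cohort;
these sizes give binomial standard errors well under the margins asserted.
Region medians use pandas' interpolating median; BH uses a stable mergesort
so tied p-values keep input order; all float output is written at 10
significant digits, making write→read→write byte-stable. Exact rank-test
nulls switch to the normal approximation above n = 25 or in the presence
of ties.

## Known limitations

- The screen assumes regions are given; it will not discover DMRs outside
  the supplied CGI set.
- One BH family across all tested regions is a fixed choice; a hyper-only
  family would change borderline counts.
- The funnel matches tumor/normal and treated/vehicle records by shared
  sample id; unmatched records are silently unusable rather than errors.
- `beta_value` is provided for completeness; the pipeline expects
  already-computed β and performs no intensity-level processing.
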