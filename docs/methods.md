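# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Plate layout and roles

A dispensing run fills the first 11 columns (A1–H11, 88 wells) of a 96-well
plate. Column 12 carries controls: blanks A12–C12 (no droplets), non-template
controls (NTCs) D12–G12 (droplets verified cell-free; the fluorescence
background), and a 400-droplet positive control H12. Well coordinates are
row-letter + 1-based column everywhere; zero-padded forms (`A01`) are
accepted on input.

## Fluorescence normalization and well calling

Raw per-channel readings are processed in two steps: (1) divide each reading
by the mean NTC intensity of its plate and channel — this removes
plate-to-plate gain differences; (2) min-max standardize each channel across
the whole experiment to [0, 1] — this puts the two fluorophores, whose
brightness differs, on one axis. A per-plate min-max is available by flag.
The two steps are applied in that order.

The positive threshold per channel is the background mean plus two
background SDs on the normalized scale. Defaults and conventions:

- *Background wells*: NTC wells serve both normalization and thresholding;
  blanks can be pooled in via `background_roles=("ntc", "blank")`. The NTCs
  are the wells the instrument actually verified empty, hence the default.
- *Boundary*: strictly greater than the threshold is positive; ties call
  negative (conservative).
- *SD denominator*: n − 1.
- A channel whose readings are constant is a degenerate-scale error, as the
  min-max map is undefined.

Classification is invariant to any positive rescaling of the raw intensities
(normalization divides it out) and, on noise-free plates, agrees with the
simulator's ground truth on every well (tested).

## Doublet (multi-cell) estimation

Two estimators invert the color-collision thinning; both are reported
relative to non-empty wells by default (a flag switches the denominator to
all dispensed wells).

**Pairwise (default).** Multi-cell wells hold exactly two cells. With green
proportion p and observed dual fraction d̂: m̂ = d̂ / (2 p̂ (1 − p̂)), capped
at 1; p̂ = green-only / (green-only + red-only), ignoring the small
same-color-doublet bias (documented, not corrected). The default is the pair
model because in the regime of interest (~5% dual wells) the dispenser's
multi-cell events are dominated by pairs; the cap and the p̂ ∈ {0, 1} error
guard the degenerate corners. When d̂ = 0 the estimate is 0 regardless of p̂.

**Zero-truncated Poisson (sensitivity).** Cells per non-empty well
k ~ Poisson(λ) truncated to k ≥ 1. P(dual) = 1 − A(p) − A(1 − p) with
A(x) = (e^{λ(x−1)} − e^{−λ})/(1 − e^{−λ}); λ is solved by bracketed root
finding on (1e−8, 10) to 1e−10, and m̂ = P(k ≥ 2 | k ≥ 1). The two
estimators agree to < 0.1 percentage points for d̂ ≤ 1% and to < 0.5 pp at
the fixture's 5.66% (tested).

**Uncertainty.** Nonparametric bootstrap: wells are resampled as a
multinomial over the four classes; the 95% percentile interval is taken on
the single-cell frequency. B = 1000 by default; deterministic given a seed.
Empirical coverage at the fixture conditions (528 wells, m = 0.115,
p = 0.5) is checked by simulation in the test suite. The pairwise bootstrap
is computed in closed form over the replicate array; the result is identical
to the per-replicate loop (tested against an independent loop).

**A deliberate discrepancy.** On tallies of 225/225/27 over 477 non-empty
wells the pair model with a 50:50 color split gives m̂ = 2 × 27/477 =
11.32%, which the package reports as 11.3%. Write-ups of this assay
sometimes quote 11.5% for the same observed fractions; that figure is not
reproducible from these counts under any documented variant of the pair
model (the exact color split or model behind it is unstated), so the
package reports its own arithmetic and notes the difference here rather
than adjusting anything to match.

## Wash-carryover kinetics

The contamination rate of a wash is leftover detection rate / original
sample detection rate (both cells/min). The decay model is geometric:
rate_i = rate_0 · r^i for 1-based wash index i. Fitting is OLS of log rate
on wash index; retention r = exp(slope). Washes where no cell was detected
(rate 0) are excluded from the log fit with a warning — they are detection-
limit censoring, and censoring-aware fitting is out of scope. A fitted
r ≥ 1 is flagged non-decaying and makes any lower target unreachable.
`washes_to_target` returns the smallest integer n with current · r^n ≤
target, with a guard against floating-point boundary error.

## Culture-success summaries

Success rate = 100 · viable / dispensed, with 88 dispensed wells by default.
Full precision internally; one decimal at display. `summarize_runs` pivots
records keyed by (sample, dilution exponent, enrichment hours, medium) into
a grid with per-row and grand totals; duplicate keys are an error, missing
combinations are NaN.

Mock-community shifts: per species, delta_r = post_r − pre_r per replicate;
the mean delta is reported in percentage points and tested two-sided against
zero with a one-sample t-test (default) or a sign-flip permutation test.
The t-test is the default simply because n is tiny (typically 3) and the
permutation null is then very coarse (2^3 sign patterns); neither choice is
claimed to reproduce any published p-value. Zero-variance deltas get p = 1
at zero mean (no evidence of change) and p = 0 otherwise (exact repeatable
shift). Percentage-point differences of relative abundance are used —
not fold changes — so the per-species mean deltas of a compositional table
sum to zero (tested).

## ANI strain/lineage clustering

Inputs are pairwise ANI and aligned-fraction tables (possibly asymmetric,
e.g. the two directions of a dnadiff comparison) and a genome-quality table.

- *QC*: drop contamination > 90% or completeness < 50% (strict
  inequalities; boundary genomes are kept).
- *Symmetrization*: arithmetic mean of the two directions, for both ANI and
  aligned fraction; the direction handling of the upstream aligner output is
  not standardized, and the mean is the least surprising choice.
- *Aligned-fraction filter*: isolate-vs-isolate pairs need ≥ 75%; reference
  (novelty) comparisons need ≥ 50%. A failing pair is *unlinked*: rather
  than assigning a large finite distance (which reappears in averages and
  creates threshold-dependent artifacts), any candidate merge containing an
  unlinked member pair is simply forbidden.
- *Clustering*: greedy average-linkage agglomeration on 100 − ANI. At each
  step the mergeable cluster pair with the smallest average pairwise
  distance merges, while that average is ≤ 100 − threshold; a pair at
  exactly the threshold ANI merges (so two genomes at exactly 99.0% ANI are
  one strain). Average linkage is reducible, so greedy stopping equals
  cutting the full dendrogram. Ties break on the lexicographically smallest
  genome ids, making results invariant to input order (tested by
  permutation). The implementation is O(n³)–O(n⁴) in genome count, which is
  ample for isolate panels (≲ a few hundred genomes); it is hand-written
  because no library agglomerator expresses the unmergeable-pair constraint.
  Its partitions are verified in the tests against an independent
  brute-force oracle on 200 random ≤ 8-genome matrices and against standard
  average linkage on matrices with no unlinked pairs.
- *Two levels*: strains at 99% ANI, lineages at 99.9%. Because both cuts
  come from the same deterministic agglomeration, the lineage partition
  refines the strain partition; a post-hoc guard still splits any violating
  lineage along strain boundaries (logged) for degenerate inputs.
- *Novelty*: a lineage is novel iff its best qualifying reference ANI is
  strictly below 99%; with no qualifying reference comparison it is flagged
  `no_reference`, never silently novel.

## Synthetic data: what it emulates, and what it does not

`simulate_plate` draws, per dispensed well: empty with probability
`empty_fraction`; otherwise ≥ 2 cells with probability `multi_fraction`
(count 2 + Poisson(`extra_cell_mean`), default 0 — the exactly-two model);
each cell green with probability `color_prop`. A channel reading is
Normal(bg_mean, bg_sd) + (cells of that color) × Normal(signal_mean,
signal_sd), truncated at 0. Defaults: multi_fraction 0.115 and color_prop
0.5 (the regime of the two-fluorophore validation experiment the package
models), empty_fraction 0.1, background 100 ± 5 and signal 1000 ± 50
arbitrary units — a ~180-SD separation typical of a plate reader measuring
overnight cultures. One global seed; per-plate substreams are spawned
deterministically.

The *fixture* (`make_dual_fluorophore_fixture`) is not a draw from that
model: it deterministically assigns exactly 225 green-only, 225 red-only,
27 dual and 51 empty wells across six plates (450 single-signal of 477
non-empty, 528 dispensed) and then adds seeded noise constructed so the
classifier's separation is exact for every seed: control wells take
bg ± 1 SD in a balanced alternating pattern (pinning the NTC sample SD near
its nominal value), dispensed backgrounds are clipped to ±1.5 SD and signal
draws to ±3 SD. The 50:50 green/red split of the single-signal wells is a
fixture convention recorded in its metadata. Use the stochastic simulator,
not the fixture, for estimator-recovery studies.

`simulate_mock_dispense` draws post-dispensing droplet counts multinomially
with probabilities ∝ input proportions × bias weights, thinned by
per-species viability. It emulates recognition bias (morphology, clumping)
as a single static weight; it does not model density-dependent effects,
droplet physics or growth competition. Default mock-community settings used
in tests: nine species at mildly uneven proportions with unit weights —
chosen as a neutral baseline since no numeric input profile is standard.

`simulate_wash_series` applies log-normal noise to an exact geometric decay;
`simulate_ani_matrix` builds block-diagonal structure with within-lineage
ANI ≥ 99.9%, same-strain/different-lineage pairs between 99% and 99.9%, and
between-strain pairs kept below 99%. Real ANI matrices are noisier and can
straddle thresholds; passing tests on these blocks shows the clustering
machinery is correct, not that 99%/99.9% are the right cuts for a given
taxon.

## Numerical conventions

- All simulators are bit-reproducible for a fixed seed (numpy Generator,
  spawned substreams).
- Percent values are rounded to one decimal (two for the dual-signal
  fraction) only at report time; internal arithmetic is full precision.
- JSON reports serialize NaN as null; human tables use one decimal.
- Bisection bracket for the truncated-Poisson λ: (1e−8, 10), tolerance
  1e−10; d̂ at or above the bracket-top dual probability is a
  model-mismatch error.
- Problem sizes in the test suite: estimator-recovery grids use 10⁵
  simulated wells; bootstrap coverage uses 500 replicates of 528 wells with
  B = 1000; the clustering oracle comparison uses 200 random matrices of
  ≤ 8 genomes. These sizes give Monte-Carlo error well inside the asserted
  tolerances while keeping the default suite fast.

## Known limitations

- The color-proportion estimator ignores same-color doublets in the
  single-signal counts; at m ≈ 0.1 the bias on p̂ is ≪ 0.01.
- The pair model underestimates m when wells with ≥ 3 cells are common;
  the truncated-Poisson variant bounds that sensitivity.
- Wash-decay fitting treats zero rates as missing rather than censored.
- The unlinked-pair rule can keep two otherwise-close clusters apart on a
  single bad alignment; inspect the aligned-fraction matrix when a split
  looks surprising.
- The abundance-shift tests assume replicates are independent dispensing
  runs of the same input community.
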