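# Methods

## Model and assumptions

`panelgc` treats each capture probe as a genomic bin and asks whether read
depth, after normalization, is a flat function of bin GC content. The
per-position normalization

    normalized_depth = log2(position_depth / mean_depth + 1)

makes libraries of different sizes comparable: the mean is taken over the
union of probed positions (each genomic position counted once, even when
probes overlap), so the back-transformed normalized depths `2^nd − 1`
average to exactly 1 for any library with nonzero coverage. The `+1` keeps
zero-depth positions finite (they map to 0) at the cost of compressing very
low depths.

Per-probe medians, then medians of those medians within each integer GC
percentile, summarize depth robustly: a single amplified or dropped-out
probe cannot move its percentile's value. Probes are assigned to percentile
`round(gc × 100)` (half up); each probe lands in exactly one percentile,
while a genomic position shared by overlapping probes is attributed to every
probe covering it — probes, not positions, are the analysis unit. GC is
computed case-insensitively over unambiguous bases only; probes more than
50% ambiguous are excluded with a warning, which avoids undefined bins
without imputing sequence content.

The LOESS depth is a tricube-weighted local polynomial regression of
median-of-medians depth on occupied GC percentile, and the scores are read
off it at two anchor percentiles (defaults 25 and 75). The relative score
`b75/25 = log2((2^b75 − 1)/(2^b25 − 1) + 1)` is the log2 of the
linear-scale depth ratio between the anchors, shifted by one so that a
balanced sample scores exactly 1; it is strictly increasing in `b75`,
strictly decreasing in `b25`, and invariant to rescaling all raw depths.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `at_anchor`, `gc_anchor` | 25, 75 (% GC) | Anchors inside the informative range: 25–75% GC brackets typical panel content; extremes are noisy and the 40–60% band is GC-neutral. Configurable per panel design. |
| LOESS `span` | 0.5 | Fraction of occupied percentiles in each local window. Chosen so that, on a dense percentile grid, the window around one anchor never crosses the 50% GC midpoint: the tricube weight vanishes at the window edge, so sharp AT/GC depth transitions are recovered exactly at the anchors. A wider span (e.g. 0.75) smears a 2-fold step by ~0.13 score units at the anchors. |
| LOESS `degree` | 2 | Local quadratics track curvature in real profiles; exact on globally quadratic data, which the tests exploit as an oracle. |
| `min_percentiles` | 10 | Fewer occupied percentiles than this is a hard error — a smoother fitted to a handful of points is not a bias profile. |
| extrapolation margin | 2 percentiles | An anchor at most 2 percentiles outside the fit domain is clamped to the nearest endpoint (warned); farther, the sample is reported unscorable rather than extrapolated. |
| `min_mapq` | 0 | Depth filter; no mapping-quality filter by default, configurable. |
| duplicates | excluded | Duplicate-flagged reads are excluded from depth by default (elevated duplication is itself a known failure mode, so the policy is explicit and logged); `--keep-duplicates` includes them. Secondary/supplementary alignments are always excluded. |
| classification thresholds | log2(3), log2(2.5), log2(5/3), log2(1.5); absolute log2(2.5) | Stored as exact expressions, not decimal prints; compared with the inclusive/exclusive comparators given in the classification rules. Failures are evaluated before warnings; if both absolute failure conditions hold at once, the direction of `b75/25` relative to 1 breaks the tie and a bidirectional-anomaly note is attached, keeping classification a total function. |
| panel gates | min 5 samples; >70% bias-free; >50% copy neutral | Strict inequalities throughout; warning classes count as *not* bias-free. Copy neutrality is the conjunction `<5 and <5%` nondiploid autosomal calls. A sample missing from a supplied CNV table counts as not copy neutral (conservative); with no table, the CNV gate is unevaluated, not failed. Which panels are batch-critical is configuration (default: all). |

Zero-coverage samples are a distinct NO_COVERAGE status upstream of the five
bias classes; batch gating treats them as not bias-free. Degenerate scores
(zero linear-scale depth at an anchor after back-transform) map to sentinel
values (+inf / a 0 floor) and fail in the corresponding direction.

## Synthetic data

The simulator builds one synthetic chromosome whose probes (default 200 ×
120 bp, GC fractions evenly spanning 0.10–0.90) are constructed by explicit
base counts, so each realized GC fraction is exact to within half a base.
Expected per-position depth is `mean_depth × w(gc)/mean(w)` with either a
step weight (`1` below 50% GC, `r` at or above — the shape used in recovery
tests because its plateaus make the closed form exact) or a log-linear
weight interpolating between the anchors. Reads span whole probes, carry
proper-pair flags with trivially placed mates, and their count per probe is
Poisson(expected depth) or its rounded value; a single seed fixes every
byte. The injected ratio `r` fixes the ground-truth score at `log2(r + 1)`.

What this emulates: controlled GC-ward and AT-ward depth tilts at
realistic panel scale, sampling noise, and depth from 5X to 100X. What it
does not: fragment-length and pair geometry, sequencing error, duplicate
structure, off-target reads, mappability, or the probe-design idiosyncrasies
of real panels — so passing recovery tests demonstrates that the metric and
its implementation are correct and well-calibrated under the stated noise
model, not that any particular real panel is bias-free.

Default problem sizes (200 probes, 30X, 20 replicates) keep a full recovery
experiment under a minute while holding the replicate-median score error
well inside ±0.05; per-replicate scores scatter with a standard deviation of
roughly 0.02–0.05 at these sizes, which is why recovery statements are made
about medians over replicates rather than individual replicates.

## Numerical choices

- LOESS windows take the `ceil(span × n)` nearest design points with a
  stable sort (deterministic ties), weight them by tricube on distance
  scaled to the window radius, and solve the local weighted least squares by
  normal equations with `lstsq` (rank-safe; the polynomial degree drops
  automatically if a window has too few points).
- The fit is unweighted by probe count per percentile: a percentile backed
  by one probe counts as much as one backed by fifty, matching the
  median-of-medians philosophy of limiting the influence of dense regions.
- The AUC difference sums LOESS predictions at integer percentiles within
  the fit domain (≥50 minus <50); it is undefined when the domain lies
  entirely on one side of 50.
- Probe GC percentile ties round half up; threshold comparisons use the
  exact expressions, never rounded decimals.
- Batch reports are deterministic JSON given an injected report id;
  the per-sample score table is byte-stable across worker counts because
  samples are scored independently and ordered by the manifest.

## Known limitations

- Detection only: no correction of depths or of downstream CNV calls is
  attempted or planned.
- FFPE libraries and amplicon panels violate the capture-probe assumptions
  in ways the simulator does not model; scores remain computable but the
  default thresholds may not transfer.
- Anchors must lie in (or within 2 percentiles of) the observed GC range;
  panels with very narrow GC distributions should choose anchors to match
  their design rather than rely on the 25/75 defaults.
- CRAM input is not targeted (BAM only is exercised), and CNV calls are
  consumed from an external caller's table, never computed.
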