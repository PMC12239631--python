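# Methods

## Scope and data model

`zfbattery` analyzes per-well tracking of single larval zebrafish in square
96-well wells. A well's record is a `FrameSeries`: strictly increasing
timestamps in milliseconds, centroid `(x, y)` in pixels (image convention:
origin top-left, y down), and a nonnegative pixel-change scalar `dpx` per
frame. Baseline acquisition is 30 fps; stimulus responses are scored from
separate 1-s windows at 285 fps. Times are always milliseconds, never frame
counts, so the two rates interoperate.

## Bout segmentation and kinematics

Bouts are maximal runs with `dpx > dpx_threshold` (default 2 px). Runs
separated by fewer than `min_gap_frames` (3) sub-threshold frames are
merged; merged runs shorter than `min_bout_frames` (2 ≈ 66 ms at 30 fps) are
discarded. Intervals are half-open and 0-based. These segmentation constants
are not biologically canonical — they are exposed in `BoutParams` and the
run config.

Per bout: displacement (start→end Euclidean), path distance *D* (sum of step
lengths), duration Δt from timestamps, mean speed *v = D/Δt* in px/ms,
revolutions *R* = Σ|wrapped heading change|/360° using only steps of at
least `heading_min_step_px` (1 px, so tracking jitter cannot accumulate
turns), and center fraction — the fraction of bout frames inside a
concentric square of half the well's linear size (25% of its area; the zone
scale is configurable since no standard definition exists).

**Seizure-like movement rule.** A bout is seizure-like iff *R* > 4 (strict),
*D* > 70 px (strict) and 0.3 ≤ *v* ≤ 1.3 px/ms (inclusive). "Distance" is
path distance, not displacement, and "speed" is distance over duration —
the wording "moving a distance" binds more naturally to path length, and a
tight circling movement would otherwise have near-zero speed. Boundary
semantics are fixed here once and tested exhaustively against an
independently coded oracle.

## Stimulus-response scoring

A response is any supra-threshold `dpx` frame in the causal 1-s window after
onset; latency is the first such frame's time minus onset, magnitude the
start→end displacement and `dpx` sum over the contiguous supra-threshold run
beginning there. The response threshold defaults to the segmentation
threshold — the original criterion is not published, and a shared activity
threshold keeps the two detectors consistent. Frames before onset never
influence the score. Response frequency is (#responded)/(#events) per block;
habituation indices divide each habituation block's per-animal frequency by
the pre-habituation block's. Per-animal values are computed first and group
statistics second, so repeated events within one animal are never treated as
independent replicates.

## Two-tier statistics

**Baseline tier (permutation LMM).** For one measure in one epoch, the model
is `value ~ intercept + genotype` with a per-animal random intercept across
time bins. The fit is profiled REML: for variance ratio λ = τ²/σ², the GLS
genotype estimate reduces to a weighted regression on per-animal means with
weights nᵢ/(1 + nᵢλ); λ is chosen on a fixed grid ({0} ∪ 40 log-spaced
points in [10⁻³, 10³]) by the REML criterion, and the observed statistic is
|β̂|/SE. Inference permutes genotype labels at the animal level
(n_perm = 999 by default), giving p = (1 + #{|t*| ≥ |t|})/(1 + n_perm) with
floor 0.001. Because the statistic is recomputed identically for every
relabeling, the p-value is exact under animal exchangeability — the grid
resolution and fitting details affect power only. Designs without
within-animal replication (a single bin) are singular; the test then falls
back to a two-sample permutation test of per-animal means and records the
fallback in the result.

**Stimulus tier.** Per-animal stimulus measures are compared by
Kruskal–Wallis (scipy's tie-corrected H with the χ² approximation); all-equal
input is defined as H = 0, p = 1 rather than 0/0.

**Effect size.** Every result carries SSMD
β = (μ_mutant − μ_control)/√(σ²_mutant + σ²_control) with n−1 variances,
computed on per-animal summaries; negative β means reduced in mutants. Both
groups constant and equal gives β = 0; constant but different gives signed
infinity (flagged by being non-finite). No multiple-testing correction is
applied across the battery by default — results are reported per measure.

Heterozygotes are handled by running the battery pairwise: each non-control
genotype against the control group.

## Bubble summarization

Related measures merge into categories (bout frequency, location preference,
bout magnitude, seizure-like, dark/light-flash response, acoustic response,
habituation; the map is overridable). Per category and per sign, significant
results (p < α, SSMD of that sign) are counted; percent significant uses the
category's **full** measure count as denominator so the paired
increased/decreased bubbles of one category are comparable, and the color
value is the mean SSMD over that signed significant subset. A sign with no
significant results produces no bubble. A significant result with SSMD
exactly 0 joins neither sign.

## Enrichment

DEG filtering keeps genes with p < 0.05 and |log2FC| > 0.2 (both strict;
up- and down-regulated combined, as the Venn partition of three genotype
comparisons mixes both directions). Ranking for GSEA defaults to
signed −log₁₀ p (sign from log2FC) with a plain log2FC alternative; ties
break lexicographically by gene id so every sort is reproducible.

The enrichment score walks the ranking: set members add |score|^p
(normalized over the set, p = 1 by default; all-zero scores degenerate to
equal weights), non-members subtract 1/(N − N_hit). ES is the extremum
farthest from zero; the leading edge is the hits at or before it (at or
after it for negative ES). Significance uses a **gene-set permutation
null** — random same-size sets on the fixed ranking — rather than phenotype
permutation, because bulk designs of a few samples per genotype cannot
support phenotype permutation; this is a deliberate deviation from the
original GSEA default. NES divides ES by the mean |null ES| of matching
sign, and p conditions on sign: (1 + #{same-sign nulls at least as
extreme})/(1 + #{same-sign nulls}), which makes null p-values uniform
overall. FDR is Benjamini–Hochberg across sets. Null ES values are computed
with an O(m) hit-position form of the running sum, tested for agreement
against the explicit walk.

Note the sign-conditioned floor is ≈ 2/n_perm, so screens of many sets that
need q < 0.05 should raise `n_perm` (the planted-set validation uses 5000;
the default is 1000, and below 50 a warning is issued).

ORA is the hypergeometric upper tail P(X ≥ overlap) over a finite universe,
BH-corrected across sets. Marker sets come from one-vs-rest two-sided
Mann–Whitney tests per gene on log-normalized counts (counts per 10k,
log1p), keeping positive-logFC genes with BH-adjusted p < 0.05, ordered by
(padj, −logFC, gene id) and truncated at k = 500.

## Synthetic data generator

The generator emulates the rig at desk scale with compressed timing so a
full plate simulates in under a second:

* **Locomotion** — an alternating renewal process: exponential rest dwells
  (mean 1.5 s) and gamma bouts (shape 3, mean 200 ms), rendered as smooth
  centroid arcs with a half-sine speed profile (peak 0.25 px/ms), a
  random-walk heading (SD 25°/step) whose initial direction points toward
  the well center with probability `center_bias`, and reflection at the
  walls. Exponential/gamma dwell laws are a tractability choice, not a
  measured fact about larvae.
* **Pixel change** — per-frame centroid displacement plus half-normal noise
  (SD 0.3 px). The real camera statistic (changed-pixel count) is not
  publicly defined; a displacement-coupled proxy preserves everything the
  segmentation needs. Consequently absolute `dpx` magnitudes are not
  comparable to real recordings.
* **Seizure bouts** — a Poisson process (rate per hour) of circular paths
  built to satisfy the classifier: 4.6–5.6 revolutions at ~10 steps per
  revolution and chord speed 0.5–1.05 px/ms, anchored at the larva's
  position and kept inside the wall margin. Ordinary bouts within 200 ms are
  dropped so segmentation cannot merge them into the seizure.
* **Stimuli** — the default compressed schedule keeps the battery's block
  structure in miniature: a light-flash block, a mixed acoustic block
  (strong/weak taps, prepulses), three habituation blocks of strong taps and
  three dark-flash blocks, evenly spaced. Responses occur with probability
  p_respond(type) × decay^(k−1) for the k-th same-type stimulus of its block
  (decay resets per block), rendered as startle-like bursts (0.8–1.5 px/ms,
  ×1.3 for dark-flash O-bends) at 15–60 ms latency.
* **Genotype effects** — named multipliers per genotype: `bout_rate` (the
  renewal rate is rescaled exactly by re-solving the rest dwell),
  `bout_duration`, `bout_peak_speed`, `turn_sd`, `center_bias`,
  `seizure_rate`, `p_respond`, `habituation_decay`.
* **Determinism** — one RNG stream per well derived from (seed, well index):
  identical configs are byte-identical on disk, and adding wells never
  perturbs existing ones. Genotypes are assigned to wells by a seeded
  uniform shuffle (the real plate layout is not modeled). Default plate
  composition mirrors a real run: 23 homozygous, 18 wild-type, 36
  heterozygous animals.

For the transcriptomic stage, `simulate_deg_table` draws null log2FC from
Normal(0, σ) with exact two-sided p-values and shifts planted sets by δ;
`simulate_cluster_matrix` draws negative-binomial counts (dispersion 5,
log-normal gene means) with marker genes up-scaled in their cluster only.

**What passing tests do and do not show.** The generator provides planted
ground truth under its own assumptions — renewal locomotion, independent
wells, clean tracking, symmetric DE nulls. Passing calibration and recovery
tests demonstrates the statistics are valid and powered *under those
assumptions*; they say nothing about tracking artifacts, multi-animal
occlusion, circadian structure, well-edge optics, or overdispersion beyond
the NB model, none of which are simulated.

## Validation sizes and numerical choices

The validation suite uses desk-scale problem sizes chosen to keep
Monte-Carlo error well inside each assertion's band: null calibration runs
100 plates of 18+18 wells × 480 s (≥ 4000 LMM and ≥ 3300 Kruskal–Wallis
p-values) with an elevated seizure rate (30/h) so per-bin seizure counts are
non-degenerate — at realistic rates the discrete permutation distribution is
heavily tied and its p-values conservative, which is correct behavior but
uninformative for a two-sided calibration check. Power uses 100 replicates
of 24+24 wells × 300 s. The large-n SSMD check uses 10⁵ draws. Permutation
defaults: n_perm = 999 (battery), 1000 (GSEA). Degenerate guards: H = 0 for
all-equal data, SSMD ±∞ on zero variance with unequal means, empty datasets
propagate as empty outputs, and a cluster below 2 cells is skipped with a
warning.

## Known limitations

* The pixel-change channel is a proxy; absolute thresholds (2 px) are
  calibrated to the generator, and real recordings will need re-tuned
  `BoutParams`.
* The LMM models a single random intercept; no serial correlation across
  bins within an animal (circadian drift would violate this, but the
  permutation wrapper keeps the p-value valid regardless).
* Habituation decays within blocks only; cross-block sensitization or
  long-term habituation is not modeled.
* GSEA uses gene-set permutation, which treats genes as exchangeable and
  ignores inter-gene correlation; NES magnitudes are therefore not
  comparable to phenotype-permutation NES from other tools.
* Revolutions are undersampled at 30 fps for genuinely fast circling; the
  generator's seizure bouts are built to remain resolvable (≥ 8 steps per
  revolution), real high-speed circling may not be.
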