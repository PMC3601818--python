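# Methods

## The measurement problem

The *C. elegans* egg-laying circuit drives Ca²⁺ transients in two vulval
muscle compartments, anterior (A) and posterior (P). In animals with intact
vm2 muscle arms the compartments are electrically coupled and fire together;
when the arms are absent the compartments decouple, firing more peaks with a
substantial A/P onset offset. `vmsync` quantifies this from dual-channel
(GCaMP/mCherry) ratiometric recordings: it extracts per-compartment ΔR/R
traces, detects transient peaks, classifies A/P synchrony, and aggregates
cohort statistics. Because no raw recordings are publicly available, the
package also ships a ground-truthed simulator whose default scenarios are
calibrated so that the expected outcome statistics equal the published
wild-type and mutant values; recovery of those values by the pipeline is the
package's primary validation.

## Ratiometric trace extraction

The measurement chain, in order:

1. **Background.** Preferably from a user-supplied background ROI (mean and
   sd of mCherry counts over the ROI, all frames); on bare stacks, a
   fallback takes the dimmest 25% of mCherry voxels per frame. The fallback
   samples the lower tail and is biased low, which only makes the subsequent
   selection more conservative.
2. **Voxel selection.** Per frame, voxels with mCherry strictly above
   `mean + 2·sd` of background. Selection is recomputed independently at
   every time point. With the default simulated geometry at 256×256 the
   muscle ROIs contribute ≈500 voxels per frame. Note that for an exactly
   Gaussian background the 2-sd rule admits ≈2.3% of background voxels by
   construction; when compartment ROIs are available the whole-muscle trace
   is therefore measured within their union, mirroring how a traced muscle
   object bounds the measurement in practice.
3. **Ratio.** Mean of per-voxel GCaMP/mCherry ratios over the selected
   voxels (mean of ratios, not ratio of channel sums). Frames with no
   selected voxel are marked missing.
4. **Smoothing.** Centered 3-point (150 ms at 20 Hz) rolling average;
   edges shrink to the available points; missing samples stay missing and
   are excluded from neighbours' windows.
5. **Baseline.** R₀ = mean of the lowest ⌈0.10·n⌉ smoothed ratio values
   (missing frames excluded); ΔR/R = (R − R₀)/R₀, stored as a fraction
   (0.15 = 15%). The baseline decile is taken over the *smoothed* ratio —
   the order of operations follows the processing chain above. Missing
   frames are linearly interpolated before peak detection so downstream
   logic is total.

Gain invariance holds throughout: scaling both channels by the same factor
leaves every ratio, and hence every ΔR/R value, unchanged.

## Transient detection and classification

- **Peaks**: local maxima of a uniformly sampled ΔR/R trace with height
  ≥ 0.15 (the 15% analysis floor), topographic prominence ≥ 0.10, and
  ≥ 250 ms separation (closer maxima resolve to the higher one). The
  prominence criterion is this package's reproducible surrogate for manual
  peak curation; both parameters are exposed.
- **Pairing**: the A and P peak trains are merged and walked
  chronologically; the earliest unmatched peak pairs with the nearest
  unmatched opposite-compartment peak within a 2.0 s window (ties to the
  earlier peak). The window operationalizes "one locomotor body bend" and
  exceeds the largest simulated onset offset (1.5 s) while staying below
  the simulator's 2 s inter-event gap. Walking the merged train rather than
  sweeping one compartment keeps pairing aligned with the underlying events
  when consecutive decoupled events interleave; on trains with ≤6 peaks per
  compartment it reproduces the exhaustive minimum-total-delay matching.
- **Synchrony**: a matched pair with |t_P − t_A| < 250 ms cannot be
  resolved into two peaks in a summed ratiometric trace and is classified
  `double_sync` with delay *defined* as 0 s; at or beyond 250 ms,
  `double_delayed` with delay |t_P − t_A| (the boundary value 250 ms counts
  as resolved). Unmatched peaks are `single_A`/`single_P`.
- **Magnitude**: transients with peak ΔR/R < 1.5 (150%) are `twitch`
  (sub-egg-laying contractions); ≥ 1.5 are `egg_laying`. The boundary
  belongs to `egg_laying`. The 15% detection floor and the 150% magnitude
  cutoff are independent knobs.
- **Summary**: `n_peaks_merged` counts a synchronous double as one peak and
  a delayed double as two, matching what a summed trace shows (compartment
  signals add, so an unresolved double appears as one larger peak).
  `peaks_per_min = n_peaks_merged / duration`. Mean delay is over all
  doubles with synchronous doubles contributing 0 s — the convention under
  which a mostly-coupled genotype shows a mean delay of tens of
  milliseconds rather than the mean of its few resolved events.

## The simulator and its calibration

`sample_events` draws event onsets from a delayed-renewal (hard-core)
process: successive gaps are a 2 s refractory interval plus an exponential
whose mean is set so the overall rate equals `event_rate_per_min ×
rate_multiplier` exactly. The refractory gap stands in for the
once-per-body-bend rhythm and prevents kernel pile-up; a plain Poisson
process thinned by the same gap would undershoot the nominal rate by ~15%
and skew the frequency fold-change, so the renewal construction is used
instead. Onsets are kept ≥2 s clear of the recording's end so no transient
peak is truncated. Each event involves both compartments with probability
`double_fraction`; a double is synchronous (offset 0) with probability
`sync_prob`, otherwise the P-minus-A onset offset is drawn from
`offset_dist` with a random sign. Amplitudes are uniform draws —
`amp_twitch` U(0.3, 1.0) with probability 0.9, `amp_egglaying` U(1.5, 3.0)
with probability 0.1 — so every event clears the 15% detection floor.

Ideal traces superpose a causal difference-of-exponentials indicator kernel
(τ_rise 50 ms, τ_decay 400 ms, rescaled to unit peak; the equal-τ limit is
the alpha function). Movies place two elliptical compartment ROIs
(together ≈500 voxels at 256×256) on a flat background: mCherry at 5000
counts in-ROI and 200 outside; GCaMP at `2000 × (1 + ΔR/R)` in-ROI; additive
Gaussian noise (sd 50 in-ROI, 20 outside); counts clipped to the 16-bit
range but stored as float32 so the noiseless ratio ground truth is exact
rather than quantized.

Scenario calibration (only outcome statistics are published, so the
generating parameters are chosen to reproduce them in expectation):

| parameter | wild type | decoupled mutant |
|---|---|---|
| event rate | 5.0 /min | 5.0 × 1.1 /min |
| double fraction | 1.0 | 1.0 |
| sync probability | 0.9 | 0.0 |
| offset distribution | U(0.5, 1.5) s | U(0.3, 1.3) s |

Expected pooled mean delay: wild type 0.9·0 + 0.1·1.0 = **0.10 s**; mutant
mean of U(0.3, 1.3) = **0.80 s**. Expected merged peaks/min: wild type
5.0·(0.9·1 + 0.1·2) = 5.5; mutant 5.5·2 = 11 — a **2.0-fold** increase.
The offset supports stay above the 250 ms resolution threshold so every
intended-resolved event is resolvable (configs enforce this), and 5
events/min is a free calibration choice in the plausible range for these
recordings. Body bends, locomotion, photobleaching, motion and focus drift
are *not* simulated; passing recovery tests therefore demonstrates the
correctness of the measurement logic under the stated noise model, not
robustness to real-world imaging artifacts.

## Statistics

- Animal-level means (peaks/min) carry t-distribution 95% CIs (n = 11–12
  animals is squarely t territory); single-animal "cohorts" report missing
  CIs rather than degenerate ones.
- The synchronous-double fraction pools transients across animals within a
  genotype and uses the Wilson score interval, matching transient-level
  n's; the delay CI is a t interval over the pooled per-double delays.
- Tests: one-way ANOVA for peak frequencies, Pearson chi-squared (no
  continuity correction) for synchrony proportions, and a
  Fisher–Freeman–Halton exact test for 2×2 / 2×3 egg-stage tables. The
  exact test enumerates all tables with the observed margins and sums the
  probabilities not exceeding the observed table's (log-probabilities
  compared with 1e-9 relative slack); totals above 500 are refused with a
  pointer to chi-squared. No multiple-testing correction is applied.

## Morphometry

Areas are shoelace areas of simple polygons (self-intersection rejected by
segment testing, since the shoelace formula silently cancels overlapping
lobes), in µm² via a user-supplied pixel size (1.0 with a warning if left
unset). The intersection angle between the muscle axis (attachment
midpoint → tip) and the vulval slit axis is folded into [0°, 90°]: an
intersection has no orientation. This module is validated purely by
geometric properties (invariances, oracles); no numeric anchor values exist
for it.

## Numerical choices and problem sizes

- Time convention: frame *i* at *i*/fps, seconds everywhere; windows are
  half-open. Coordinates are (row, col), origin top-left, 0-based.
- All randomness flows from a single integer seed per recording; identical
  seed + config gives bit-identical event logs and movies.
- Tie-breaks: baseline decile by value then time; pairing ties toward the
  earlier opposite peak; boundary 250 ms → delayed; boundary 150% →
  egg-laying.
- Statistical property tests use sizes chosen for a laptop-class single
  core: cohort recovery on 11–12 six-minute trace-mode recordings; ANOVA
  type-I error on 200 replicate two-cohort comparisons with per-animal
  rates read off ground-truth event logs; delay-CI coverage on 100
  meta-replicates of 12 full-pipeline animals; Wilson coverage on 2000
  binomial draws.

## Known limitations

- The pairing window (2 s) is a fixed surrogate for body-bend segmentation;
  recordings of animals with atypical bend periods would need it retuned.
- The Gaussian-noise model has no photon (Poisson) component, no
  photobleaching and no motion, so absolute noise floors do not transfer
  to real data.
- The auto background fallback is biased low by design; supply a background
  ROI for quantitative background statistics.
- Greedy pairing is verified optimal on physiological trains, not on
  adversarial peak configurations.
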