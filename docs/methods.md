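# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Spike-train statistics and classification

**CV₂.** The per-pair regularity statistic is the Holt-style pairwise
coefficient of variation, CV₂(i) = 2|I(i+1) − I(i)|/(I(i+1) + I(i)),
bounded in [0, 2] and zero exactly when consecutive intervals are equal.
For a Poisson train (i.i.d. exponential intervals) CV₂ is uniform on
[0, 2]: writing U = I(i)/(I(i) + I(i+1)) ~ Uniform(0, 1), CV₂ = 2|2U − 1|.
Its mean is therefore 1 and P(CV₂ > 0.5) = 0.75 — the analytic anchor
used by the calibration tests. No smoothing or windowing is applied to
the CV₂ sequence.

**Phase portrait.** Point *i* pairs the rate of the *earlier* interval
of its CV₂ pair (ISI⁻¹ = 1/I(i)) with CV₂(i); a train of N spikes gives
max(N − 2, 0) ordered points. The pairing convention is arbitrary but
fixed; it affects no invariant.

**Mean firing rate** is N/duration over the full epoch — silence counts,
so a recording with one short burst has a low mean rate. The modal rate
is the centre of the fullest 0.5-Hz histogram bin of the ISI⁻¹ values.

**Bursts** are maximal runs of consecutive ISIs ≤ 50 ms containing ≥ 3
spikes (standalone default). 50 ms cleanly separates the ~10 Hz flight
rhythm (100-ms intervals) from ≥ 20 Hz burst firing.

**Looping index** counts sign changes of CV₂ − 0.5 along the ordered
trajectory per minute of recording. Burst discharges cross repeatedly
(low CV₂ inside bursts, high at the edges). Note that an irregular
Poisson train also crosses often — its CV₂ marginal straddles the
boundary — so the looping index is a *supporting* feature for the
seizure label, not a sufficient one; the burst count is the primary
discriminator.

**Classification cascade.** (1) mean rate < 0.1 Hz → quiescent;
(2) ≥ 2 bursts with intra-burst rate ≥ 20 Hz and ≥ 5 spikes, plus a
looping index > 1/min → burst_seizure; (3) ≥ 60 % of points with
CV₂ < 0.3 and modal rate within 5–20 Hz → flight_like;
(4) otherwise grooming_like. The classification burst criterion is
deliberately stricter (5 spikes, ≥ 20 Hz) than the standalone burst
detector: three-spike runs of sub-50-ms intervals occur by chance in
irregular trains at a rate of roughly one per two minutes at 2 Hz, which
would contaminate the seizure label; runs of five are vanishingly rare
under irregular firing while real (and generated) discharges easily
exceed them. All thresholds live in `FiringConfig`; classification is
invariant to time translation and to joint rescaling of time and the
rate/time thresholds.

## Spike detection

The threshold is `threshold_k` (default 4.5) times a robust noise scale,
1.4826 × MAD of the trace — the median absolute deviation is nearly
unaffected by spikes or bursts, unlike the standard deviation. Crossings
within a 5-ms refractory window merge into one event; samples within
stimulus-artifact windows (0.5 ms after each logged stimulus) are
excluded. Each event time is then refined to the local maximum using the
vertex of a least-squares quadratic through five samples (three at array
edges), giving spike times accurate to a few microseconds at 10 kHz —
necessary because giant-fiber latencies (~1.4 ms) must be resolved to
±0.05 ms, well below the 0.1-ms sample period. Correspondingly, the
trace generator places the template's positive peak exactly at the spike
time, evaluated on the exact sample grid rather than a rounded index.

## Evoked-response assays

GF latency is the time from stimulus onset to the first detected spike
after the 0.5-ms artifact blank, searched within 10 ms. Following
ability marks a stimulus as answered when a spike falls in
(stim + 0.5 ms, stim + 4.5 ms]; each spike can answer at most one
stimulus. The 4.5-ms window is a declared choice: it is the largest
window that never overlaps the next pulse of the standard 200-Hz train.

ECS segmentation has no published numeric boundary criteria, so the
defaults are declared and configurable: the initial discharge is the
spiking run beginning within 0.5 s of stimulation end (gaps < `q_min`
keep the run going); quiescence is the first spike-free gap ≥ `q_min`
(default 2 s); the delayed discharge is the first post-quiescence epoch
whose rate over a 1-s sliding window reaches `dd_rate_min` (default
5 Hz), searched within 60 s of stimulation end. Threshold curves report
raw per-voltage DD fractions with Wilson 95 % intervals — no isotonic
smoothing, matching how such curves are conventionally plotted.

## Tracking and locomotor metrics

Background is the per-pixel median over a 50-frame sample. Because a
near-stationary animal survives the median ("ghosting"), background
pixels deviating from the scene-wide median by more than the minimum
contrast (20 intensity levels) are replaced by it; this assumes a
near-uniform arena background. Per frame, the absolute difference is
thresholded (Otsu on the sampled difference distribution by default),
the largest connected component above 4 px is kept, and the centroid is
the intensity-weighted mean of the *unthresholded* difference over the
component's padded bounding box — the soft edge carries the sub-pixel
information, giving ~0.05 px RMS error on rendered discs. Detection
gaps ≤ 15 frames are linearly interpolated; longer gaps stay missing and
split the track, and no metric is computed across a split.

Speeds are per-frame displacements × fps, boxcar-smoothed over 5 frames
by default to keep pixel jitter from counting as movement; total
distance is always the raw (unsmoothed) path length. Percent active is
the fraction of speed samples ≥ 0.5 mm/s. Average speed divides total
distance by the full recording time (pauses included); the active-only
mean speed is reported alongside, since the two answer different
questions. SCC is the lag-1 Pearson autocorrelation of the speed
sequence, undefined (not zero) for constant speeds; the qualitative
check is that tortuous, stop-start walking yields low SCC. The activity
threshold and smoothing window are configurable because no universal
values exist for these assays.

## Survival and genetics

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the tests cross-check the statistic against a hand-coded
hypergeometric-moments implementation and its p-value against a
10⁴-shuffle label-permutation oracle. The median is the first time the
curve reaches 0.5, and is reported as undefined — never extrapolated —
when the curve stays above it. Ties follow the product-limit convention
(deaths precede censorings at the same time).

Cross expectations enumerate the four gamete combinations, drop balancer
homozygotes (inviable by construction), scale classes by viability
coefficients in [0, 1], and renormalise; a balanced self-cross therefore
expects 1/3 homozygotes among viable offspring. Genotype labels are
validated against an explicit allele registry. The χ² homogeneity test
is Pearson's on the 2×2 homozygote-by-group table, continuity correction
off by default (the calibration suite verifies a 4–6 % type-I error rate
at n = 100 per group). A Bonferroni utility is provided but not baked
into any operation. The dominance contrast (mutant/WT heterozygote vs
deletion/WT hemizygote) returns the log-rank result and the median
difference; the dominant-negative / haploinsufficiency flags are
interpretive strings only — the statistics are the contract.

## Synthetic generators: what they emulate, and what not

Generators are phenomenological. Spike trains are renewal or clustered
point processes reproducing rate and regularity statistics, not membrane
dynamics; voltage traces are noise plus a single biphasic template —
no waveform variability, drift, or motion artifacts; flight bouts,
courtship song, and multi-unit activity are absent. Locomotion is a
two-state Markov chain (move/pause, per-frame transition probabilities,
default dwell ≈ 2 s) with a wrapped-normal correlated random walk while
moving (default speed 8 ± 2 mm/s, heading concentration κ = 8, circular
2-cm arena, 30 fps) and a reflective boundary — real flies wall-follow,
accelerate out of turns, and groom in place, none of which is modelled.
Survival times are Weibull with the scale set from the target median
(shape 5 for aging-like cohorts, 1 for memoryless controls), censored at
follow-up end. ECS sequences place near-rhythmic ID and (optionally) DD
segments at fixed offsets with gamma jitter. Consequently, passing tests
demonstrate that the *estimators* recover known ground truth under
realistic noise — they do not validate the biological assumptions of any
particular recording setup.

Rendered video uses a soft-edged disc (linear one-pixel coverage ramp)
so sub-pixel centroid recovery is meaningful, with contrast 140 levels
and pixel noise SD 4 by default — favourable but attainable imaging
conditions. Problem sizes in the calibration suite were chosen to keep
every check well-resolved at desk scale: 10⁴ ISIs for CV₂ calibration,
2000/1000-fly survival cohorts, 200-fly ECS cohorts, a 200-train
classification design, and a single 3-min 30-fps video round trip.

## Known limitations

- Single-unit assumption throughout: no spike sorting, no overlapping
  units, no amplitude-based separation.
- The burst/seizure label depends on configurable thresholds; recordings
  near regime boundaries (e.g. sparse short bursts) are sensitive to
  `FiringConfig`.
- ECS boundary defaults (`q_min`, DD rate) are declared, not derived;
  different rigs may need different values.
- The tracker assumes one animal on a near-uniform background; it will
  follow the largest moving blob, whatever that is.
- Arena geometry and frame rate for behavioral recording are defaults,
  not measurements; all are configurable.
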