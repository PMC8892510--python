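# flypheno

Neuro-behavioral phenotyping toolkit for *Drosophila* seizure models —
in particular knock-in lines carrying epilepsy-associated variants of the
vitamin-B6 enzyme PNPO, whose phenotypes span spontaneous seizure
discharges, altered locomotion, developmental lethality, and shortened
life span.

The package is aimed at fly neurophysiology and behavior labs that record
dorsal longitudinal muscle (DLM) spiking from tethered flies, run
giant-fiber (GF) and electroconvulsive-seizure (ECS) stimulation assays,
track single flies in open-field arenas, and score survival and
balancer-cross genetics. Every analysis stage is paired with a synthetic
data generator with known ground truth, so the whole pipeline is testable
without any recordings.

## What it computes

**Spike-train phase space.** For a spike train with interspike intervals
*I₁ … I_{N−1}*, each interior spike contributes a point pairing the
instantaneous firing rate ISI⁻¹ = 1/*Iᵢ* with the instantaneous
coefficient of variation

    CV₂(i) = 2 |I(i+1) − I(i)| / (I(i+1) + I(i))  ∈ [0, 2].

Rhythmic (flight-like, ~10 Hz) firing sits near CV₂ = 0; irregular
grooming-related firing occupies CV₂ > 0.5; seizure-associated burst
discharges trace self-similar "loops" that repeatedly cross the boundary.
A rule cascade over mean rate, high-frequency burst counts, and
phase-space occupancy labels each recording as quiescent, grooming-like,
flight-like, or burst-seizure.

**Evoked responses.** GF stimulus-to-spike latency (~1.4 ms in intact
circuits) with stimulus-artifact blanking; following ability (% of
stimuli in a train answered by a spike); ECS segmentation into initial
discharge (ID), quiescence (Q), and delayed discharge (DD); and the
seizure-threshold curve (fraction of flies with DD per stimulation
voltage, with Wilson intervals).

**Open-field locomotion.** Centroid tracking from grayscale video
(median background subtraction, Otsu threshold, largest component,
intensity-weighted centroid) and the four standard metrics: total
distance, percentage of active time, average speed, and the speed
correlation coefficient (SCC, lag-1 autocorrelation of frame-wise speed).

**Cohort statistics.** Kaplan–Meier survival with medians and day-*t*
survival, log-rank contrasts, a dominant-negative vs haploinsufficiency
survival contrast, Mendelian expectations for balancer crosses (balancer
homozygotes inviable, per-genotype viability coefficients), homozygosity
ratios with Wilson intervals, and the χ² test of homogeneity.

**Synthetic data.** Poisson (grooming-like), gamma-renewal (flight-like),
and burst (seizure-like) spike trains; voltage traces with biphasic spike
templates and saturating stimulus artifacts; ID–Q–DD discharge sequences;
two-state correlated-random-walk locomotion rendered to video; Weibull
survival cohorts; and multinomial cross offspring.

## Worked example

```python
import numpy as np
from flypheno import synthgen, spiketrain, cohortstats

# a 2-minute recording with seizure-like burst discharges
train = synthgen.gen_burst_train(burst_onset_rate=0.15, intra_rate=50,
                                 spikes_per_burst=10, duration=120, seed=5)
label = spiketrain.classify_firing(train)
print(label.label, dict(label.evidence))

# survival contrast between a wild-type-like and a short-lived line
wt = synthgen.gen_survival_cohort(150, 74, shape=5, genotype="hWT/hWT", seed=6)
mut = synthgen.gen_survival_cohort(150, 56, shape=5, genotype="hD33V/hD33V", seed=7)
print(cohortstats.km_estimate(wt).median, cohortstats.km_estimate(mut).median)
print(cohortstats.logrank_test(wt, mut))
```

prints

```
label: burst_seizure
  mean_rate_hz: 1.58        # spikes over the whole epoch, silence included
  n_bursts: 19              # high-frequency (>=20 Hz) bursts detected
  looping_per_min: 18       # CV2-boundary crossings per minute
  median_cv2: 0.0674        # most points are intra-burst (rhythmic)
KM median (hWT): 73.3 d
KM median (hD33V): 57.1 d
log-rank chi2 = 112.8, p = 2.37e-26
```

The burst recording is labelled `burst_seizure` because it has many
high-frequency bursts *and* a looping phase-space trajectory; a
grooming-like Poisson train at the same mean rate has zero qualifying
bursts and a median CV₂ near 1. The survival cohorts recover their
generating medians (74 and 56 days) to within sampling error, and the
log-rank test rejects equality decisively.

A command-line interface mirrors the library
(`flypheno synth|spikes|evoked|track|cohort --help`).

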