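# Methods

## Scope and data model

`meaflow` analyses recordings from a two-chamber microfluidic culture
device mounted on a 60-electrode MEA (8×8 grid, 200 µm pitch, corner
sites absent). The default layout assigns grid columns 1–2 to the
*Source* chamber (14 electrodes), columns 3–5 to the eight microchannels
(one channel per grid row, 3 electrodes per channel ordered by rank from
the Source junction, 24 in total) and columns 6–8 to the *Target*
chamber (22 electrodes). The device itself fixes only the 14/24/22
partition; which grid rows and columns fall in each region depends on
how the chip is manually aligned to the array, so the layout is always
read from a JSON file and the default is one plausible, internally
consistent assignment.

Time is seconds (float64) throughout the library; user-facing summaries
convert to milliseconds. Spike logs are HDF5 (one dataset per electrode,
duration and sample-rate attributes) or CSV (`electrode,time_s` with
`# duration_s=` header); bursts, stimuli and trajectories are plain CSV;
configuration is YAML.

## Spike detection

The noise level of a trace is σ = median(|x|)/0.6745, the Gaussian-
calibrated median absolute deviation; it is insensitive to the spikes
themselves, unlike the sample SD. Spikes are crossings of ±k·σ
(negative polarity by default), time-stamped at the waveform extremum
within ±1 ms of the crossing, with a refractory dead time suppressing
secondary crossings. Defaults k = 8 and dead time 1 ms are conventional
for MEA recordings; the multiplier is a config knob because published
practice varies (k = 5–8). A σ of exactly 0 (constant trace) is rejected
rather than silently yielding a zero threshold. An optional
median-centering pre-step makes detection invariant to a DC offset.

## Network-burst detection

Spikes of all electrodes of a chamber are pooled into 50 ms bins. A
burst is a maximal run of bins with count ≥ threshold, extended to the
first/last spike inside the run; bursts closer than 100 ms are merged;
bursts with fewer than 50 spikes are discarded. The burst *onset* — the
reference point for every propagation delay — is the time of the first
spike of the burst.

The default threshold is max(10 spikes/bin, 5 × median bin count). The
median over **all** bins tracks the background level (it is zero for a
silent background, where the 10-spike floor applies alone) while staying
far below within-burst counts; a median over only the nonzero bins would
be dominated by the burst bins themselves on clean recordings and reject
every burst. All four knobs (bin, threshold, min spikes, merge gap) are
exposed in the configuration, since the exact constants used with any
given culture preparation are a matter of tuning.

## Burst-propagation matching

A cross-chamber burst pair is a candidate propagation when

1. |Δ| ≤ 500 ms, where Δ = onset(target burst) − onset(source burst), and
2. the later burst starts no later than the earlier one ends (the
   initiator is still spiking when the response begins).

Sign of Δ gives the direction (Δ > 0 forward). Matching is one-to-one
*per role*: every burst initiates at most one response and responds to
at most one initiator. This admits relay chains (a burst evoked from the
opposite chamber may itself evoke the next burst) while forbidding a
burst to have two causes or to cause two responses in one direction.
A session in which 170 of 193 source bursts propagate forward while 143
of 409 target bursts propagate backward requires such chains — under a
strictly single-use rule those counts would need 313 distinct source
bursts — so the per-role rule is the one consistent with the
propagation-probability convention below. Conflicts are resolved
greedily in order of increasing |Δ|, with ties broken on the pair's
earlier then later onset so that the result is invariant under swapping
the chamber labels. A windowed candidate search (binary search over
sorted onsets) keeps matching O(n log n + candidates); an exhaustive
O(n·m) brute-force matcher serves as the test oracle.

With n_S and n_T the chamber burst totals,

    PP_S→T = #{Δ > 0 pairs} / n_S,   PP_T→S = #{Δ < 0 pairs} / n_T,
    DPI = PP_S→T / PP_T→S.

Both denominators count *all* bursts of the initiating chamber,
including those that were themselves evoked from the other side; the
probabilities therefore understate the per-spontaneous-burst coupling
when reverse propagation exists. DPI with PP_T→S = 0 is reported as the
`inf` sentinel (never a division error), and summaries always carry the
(PP_S→T, PP_T→S) pair because the ratio alone is unstable when the
denominator is small.

## Surrogate significance of the delay structure

The null hypothesis is that the observed delays arise from two unrelated
burst processes. Surrogates jitter every target burst onset by
U(−J, +J) with J = 10 s (half-width ≫ the typical inter-burst interval;
configurable), preserve durations, re-sort, and re-match. Per 50 ms
delay bin on [−500, 500] ms, the matched-pair probability (pairs per
target burst) is accumulated over 1000 iterations (configurable). A bin
is significant when

    p_obs > mean_surr + 5 · SD_surr.

The mean-offset form is the conservative standard reading of a
"5 × SD" criterion; the literal form p_obs > 5·SD_surr is available via
`sig_rule="sd_only"`. Jittered onsets falling outside the recording are
clipped to it. Calibration on independent Poisson burst processes flags
≤ 1% of bins (verified over 100 seeds in the acceptance suite, using 200
surrogates per seed to keep the suite fast).

Stimulus-evoked propagation uses the same matching: an evoked burst is
the first burst in the stimulated chamber within a window (100 ms
default) after the stimulus, and the evoked PP is the fraction of evoked
initiator bursts with a matched pair in the tested direction; a
direction with no evoked bursts is reported as missing rather than 0.

## Activity profiles and conduction velocity

Firing-rate profiles are peri-burst time histograms (20 ms bins, window
−100…+500 ms around burst onset) averaged over bursts, per electrode
group (source / channels / target). Spatial frames place per-electrode
counts on the 8×8 grid in 5 ms bins; corner cells stay empty.

Channel conduction velocity chains single spikes across a channel's
rank-ordered electrodes when successive lags lie in (0, 2 ms] (200 µm
pitch at ≥ 100 mm/s implies lags ≤ 2 ms); each chain's velocity is the
least-squares slope of electrode position (rank × pitch) against spike
time, and the per-channel estimate is the mean ± SD over chains, with
reversed-order chains counted separately as backward events and
estimates from fewer than two chains flagged insufficient. Both the
per-event velocities and their mean are reported, since averaging
conventions differ between studies.

## Growth morphometrics

Tip trajectories are time-stamped positions along the channel axis
(x = 0 at the Source junction, x = L = 600 µm at the Target junction),
piecewise-linearly interpolated. The *meeting point* is the position
where the backward tip first crosses the forward tip, reported as the
distance the backward neurite covered from the Target end as % of L; if
the forward tip reaches the End with no crossing the meeting point is
0%, and tracks that never coexist in time yield an undefined (None)
result. *Maximum backward growth* is (L − min x)/L × 100 over the
backward track. Per-segment growth velocity divides the segment length
by the interpolated entry→exit time of each fully traversed segment.
The bottleneck exit angle uses 2-D samples: the angle between the
channel axis and the displacement from the bottleneck crossing to the
first path point 10 µm away from it (0° straight forward, up to 180°
for reversal). Along-channel metrics deliberately ignore the lateral
coordinate; only the angle needs it. All metrics are invariant under
resampling of the same path.

## Synthetic data: what it emulates, and what it does not

`simulate_recording` generates, per chamber, spontaneous network bursts
as a Poisson process (6 bursts/min default) with envelope durations
U(100, 200) ms, separated by at least a 300 ms quiescent gap (network
bursts in culture are separated by silent periods; without the gap two
true bursts could sit closer than the detector's merge rule and would be
unresolvable in principle). A source burst evokes a target burst with
probability p_fwd at a delay drawn from N(130 ms, 80 ms) truncated to
(0, 500 ms) — the defaults mirror the reported 129 ± 83 ms — and target
bursts evoke source bursts with the weaker p_bwd. When the sampled
delay outlasts the initiator's envelope, the initiator keeps spiking at
a flat rate until 80 ms past the response onset, so that every generated
link satisfies the overlap condition and the ground truth is recoverable
by the matching rules; a link whose response cannot be placed without
colliding with a neighbouring burst is dropped from the ground truth
rather than distorted. Spontaneous onsets are kept clear of the final
~0.8 s of the recording so links are never cut off by the recording end.

Within a burst each chamber electrode fires as an inhomogeneous Poisson
process under a half-sine envelope (mean 50 spikes/s/electrode). During
every link, each microchannel relays axonal spike events (50 events/s
of initiator burst) across its three electrodes with offsets
distance/velocity at 400 mm/s (the reported scale is 398 ± 98.8 mm/s).
Background spikes (0.2 spikes/s/electrode) are superposed everywhere.
One seeded generator drives everything; identical seeds give
bit-identical event lists.

`simulate_raw_trace` plants a stereotyped biphasic ~1 ms waveform
(negative lobe, 35% positive rebound) on Gaussian noise at 20 kHz.
`simulate_tip_trajectories` produces piecewise-linear tip paths
(defaults 10 µm/h forward, 6 µm/h backward, backward halt at 46% of the
channel from the Target end, 20-min sampling); an optional crossing
position is realized by delaying the backward track's entry.

The generator does not model biophysics: no membrane dynamics, no LFPs,
no synaptic plasticity, no spike-amplitude structure in the spike logs,
no burst-shape diversity beyond the half-sine, no correlated noise on
the raw traces, and no axon-guidance mechanics in the growth paths.
Passing tests therefore demonstrate that the *analysis* recovers known
generating parameters under realistic event statistics — not that the
generator reproduces every feature of real MEA data.

## Numerical choices and degenerate inputs

Delay-bin width 50 ms and jitter half-width 10 s are configurable
defaults (neither is prescribed by the quantities they estimate).
Matching ties at equal |Δ| are broken deterministically and
swap-symmetrically. Detection with σ = 0 raises; propagation with zero
chamber bursts raises; evoked analysis with no stimuli raises, and a
stimulated direction without evoked bursts reports None. Burst lists
are validated sorted and disjoint per chamber. The empty spike file is
valid input (all-empty trains with duration from the header).

## Problem sizes used in validation

The test suite simulates 10–60 minutes of activity (hundreds of bursts,
~10⁵–2.5×10⁵ spikes) for recovery checks, 100 seeds × 200 surrogates for
null calibration, 10⁶ samples for the noise-σ check and 1000 random
instances for matcher/brute-force equivalence; the whole suite runs in
well under a minute on one core.
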