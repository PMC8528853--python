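# Methods

This note documents the models, parameter choices and numerical conventions
behind `ensemblelat`, stage by stage, and what the synthetic generator does
and does not emulate.

## Synthetic sessions

The generator produces the two-session structure the analyses expect: an
exploration session on a 150 cm linear track followed by a rest session with
bilateral LFP.

**Exploration.** Position sweeps end-to-end for `n_laps` traversals at
`run_speed` (default 15 cm/s) with a short dwell (`end_dwell_s`, default 1 s)
at each end, sampled at 50 Hz. Each unit fires as an inhomogeneous Poisson
process whose intensity is a direction-specific Gaussian tuning curve
(`field_width` = SD, default 8 cm; `peak_rate` default 10 Hz; baseline
0.2 Hz), simulated by exact thinning against the interpolated intensity.
Assemblies add synchronous excess events: each assembly (default 8 assemblies
of 4 members among 60 units, 30 per hemisphere) receives Poisson co-activation
events at 2 Hz, and every member emits one extra spike per event with 5 ms
Gaussian latency jitter. Merged trains pass through a 2 ms absolute
refractory (keep-first): without it, chance collisions between the
independently generated component processes alone would push units past the
0.5% ISI-violation inclusion gate that real (refractory) neurons satisfy.

**Rest.** Position is stationary with ~0.02 cm tracker noise, so the 2 cm/s
immobility gate is exercised but always satisfied. Each hemisphere's LFP is
Gaussian noise (`noise_sd`, default 0.05 mV, 1 kHz) plus sinusoidal bursts at
`ripple_band_freq` (default 140 Hz, inside the 90–250 Hz detection band) with
a Tukey(α=0.25) amplitude envelope. A flat-topped envelope is used rather
than a full raised cosine because the detector defines event edges at the
2 SD power crossings: a slowly rising envelope would place those crossings
tens of ms inside the burst and make sub-10 ms edge recovery impossible by
construction rather than by detector quality. Burst amplitude is calibrated
against the detector's own statistic — the band RMS at burst peak sits
`ripple_amplitude_sd` (default 8) SDs above the background mean, measured
with the same filter and RMS window the detector uses. Right-hemisphere
burst midpoints equal left midpoints plus N(0, `lr_ripple_jitter_ms`)
(default 5 ms, a tightly coordinated "control-like" regime);
`lr_independent_fraction` adds unpaired per-side events, and 50 ms jitter
plus extras gives the decoordinated "mutant-like" regime.

**Replay content.** A configurable fraction (default 0.8) of ripples carry a
time-compressed trajectory at `replay_speed` (default 8 m/s): every
participating unit emits 1–3 spikes (5 ms jitter) when the trajectory crosses
its field centre. Participants come from both hemispheres
(`replay_cell_scope="both"`) or only from the event's hemisphere
(`"event_side"`), which is what makes hemisphere-conditioned decoding
comparisons testable. Rest background firing is 0.5 Hz/unit Poisson.

**What is not emulated:** theta rhythmicity and phase precession, biophysical
LFP (sharp-wave component, 1/f background), rate remapping, bursting,
waveform-level properties, and behavioural irregularity (variable run speeds,
mid-track stops). Passing recovery tests therefore shows the analysis chain
is correct and well-calibrated under its stated assumptions — not that it is
robust to every pathology of real recordings.

All randomness derives from a single seed through named child streams;
identical seed + config reproduces sessions bit-identically.

## Place fields

Velocity is estimated by central differences smoothed with a 0.25 s boxcar
(the estimator is otherwise unspecified); direction is its sign where the
magnitude exceeds 1 cm/s. Units are excluded for >0.5% ISIs < 2 ms, <75 total
spikes, or <75 spikes at >5 cm/s. Maps use 100 half-open bins over the track
(last bin closed); spike and occupancy maps are smoothed separately with a
5 cm SD Gaussian using reflection padding (avoids rate deflation at the
ends; conserves total spike mass and occupancy exactly) before division.
Unvisited bins (zero smoothed occupancy) carry rate 0 and are excluded from
the spatial-information sum, whose 0·log 0 terms are defined as 0. Spatial
information is computed per running direction and reported per direction;
no SI cutoff defines "place cell" — any filtered unit with computable SI
qualifies.

## Assemblies

Counts in 25 ms bins are z-scored per unit (zero-variance units dropped and
recorded); detection is run separately per running direction in the pipeline.
The correlation matrix is `Z Zᵀ / B` (unit diagonal). The number of patterns
is the count of eigenvalues above `(1 + √(n/B))²`. Because the bound is the
asymptotic spectral edge, an independent population still exceeds it with
probability ≈ 6–7% (edge fluctuations), almost always by a single eigenvalue;
users should treat a lone marginal pattern in featureless data accordingly.
fastICA is randomized, so it is restarted 20 times from seeded states and the
run with the largest summed |excess kurtosis| of its sources is kept;
convergence settings and the winning score are recorded in the diagnostics.
Weight vectors are unit-normalised and sign-fixed (largest-|weight| entry
positive); membership (weight > mean + 2 SD, strict) is computed after sign
fixing and is therefore sign-invariant. Note the member rule needs the
member fraction of the population below ~20%, else equal-weight members sit
exactly at the threshold.

Laterality: unilateral iff all members share a hemisphere; dominant side is
the majority, ties labelled "tied" and excluded from side-conditioned
analyses. The member-shuffle null redraws each assembly as a same-size sample
without replacement from the recorded pool, independently across assemblies,
1000 times.

Activation strength uses z-scores convolved with a 1-bin (25 ms) SD Gaussian
truncated at 4 SD — the narrowest smoothing that still regularises single-bin
noise — both on the track and at rest (the same smoothed signal is used
everywhere). `R_k(t)` is evaluated as `(v·z)² − Σ v_i² z_i²`, the
zero-diagonal quadratic form. Reactivation events are strict local maxima
above 5, plateaus taking their first bin; assemblies with overall peak rate
< 0.01/s are flagged excluded from group statistics.

## Ripples

Band-pass 90–250 Hz with an odd-length Hamming FIR (~3 cycles of 90 Hz),
applied forward-backward (zero-phase). Power is the RMS in a 12.5 ms sliding
boxcar (~one cycle pair: a compromise between latency and variance). The
background mean and SD are estimated per trace over immobility samples only,
using median and 1.4826·MAD rather than moments: the events being detected
are part of the trace, and a moment estimator's operating point would drift
with event density and amplitude. Peaks must exceed mean + 5 SD, edges are
the 2 SD crossings, peaks closer than 50 ms merge transitively (union of
extents, strongest peak kept — a fixed point, independent of processing
order), and events whose peak falls at ≥ 2 cm/s are discarded. Amplitude is
the Hilbert envelope maximum of the band signal (mV). Peak frequency uses a
DPSS multitaper spectrum (time-bandwidth 2, 3 tapers); events shorter than 3
cycles at 90 Hz are flagged without a frequency, and a spectral peak below 5×
the median in-band power is flagged low-confidence. The cross-correlogram
counts opposite-hemisphere midpoints in ±100 ms around each reference
midpoint (1 ms bins), normalised to SWRs/s (counts / n_ref / bin width) and
smoothed with a 4-bin SD Gaussian; its summary statistic is the peak rate
within ±10 ms of zero.

## Replay

Candidates are SWRs of 50–300 ms with ≥ 5 place cells firing ≥ 1 spike.
Windows are cut into non-overlapping 20 ms bins, the final partial bin
dropped (constant τ). Templates are floored at 0.01 Hz so a zero-rate bin
cannot annihilate the likelihood; decoding runs in log space with per-column
max subtraction (stable for any realistic count). Both direction templates
are always decoded; the direction with the smaller Monte Carlo P is kept,
ties broken by larger |r| then by fixed direction order (rightward first).
Shuffle exceedances are counted two-sided (`|r_null| > |r_obs|`), matching
the |r|-based sequence score; the two per-direction decodings use independent
seeded shuffle sets. Circular shuffles shift each cell's template by an
independent uniform integer number of spatial bins.

Kinematics use per-bin argmax positions (ties to the lowest bin): distance is
max − min, mean jump the mean |step|, and speed the distance over the decoded
extent (M·τ). With M bins the peak positions sample the trajectory at bin
centres, so speed is underestimated by roughly (M−1)/M (~10% at M = 10) — a
discretisation property of the estimator, visible in the recovery numbers.

PCC: participants are cells with more than one spike in the event. Each
shuffled single-cell decode is scored against the event's all-cell null
(same mean/SD as the observed rZ), and
`PCC = (rZ_obs − mean shuffled rZ) × n_participants` — the score is
multiplied by the participant count, following the defining formula of the
statistic. Hemisphere-conditioned comparisons re-run the full pipeline per
cell subset (ipsilateral / contralateral to the detecting hemisphere) with
the same inclusion gates, dropping an event from an arm whose subset has
fewer than 5 active cells, and compare arms with a two-sided rank-sum test.

## Problem sizes in the test suite

Validation uses desk-scale sessions chosen to keep the full suite within a
few minutes while leaving each statistic well-powered: ~10-minute
explorations for assembly recovery (B ≈ 22 000 bins), 120–300 s rest sessions
(~25–60 ripples/hemisphere), 200 shuffles where the shuffle count only
widens Monte Carlo resolution (the package default stays 1000), 200-event
null batches for the type-I check, and 10-seed batteries for regime
discrimination. Held-out decoding validation uses 0.5 s bins (behavioural
timescale); replay decoding itself always uses 20 ms.

## Known limitations

- The Marčenko–Pastur count has the ~6–7% single-eigenvalue false-positive
  rate noted above; a finite-size edge correction would remove it at the cost
  of departing from the standard closed form.
- Detection thresholds are per-trace (per hemisphere signal), not per
  tetrode; sessions mixing electrodes with very different noise floors would
  need per-channel detection.
- The weighted-correlation score only measures *linear* position–time
  structure; curved or piecewise trajectories score low by design.
- Speed estimates carry the (M−1)/M discretisation bias; unbiased estimates
  would need a line-fitting decoder, which is out of scope.
- The generator's replay is one constant-speed pass; multi-segment or
  reverse-then-forward events are not synthesised.
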