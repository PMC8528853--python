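# ensemblelat

Bilateral hippocampal ensemble analysis: place-field metrics, PCA/ICA
cell-assembly detection, sharp-wave-ripple (SWR) detection with bilateral
synchrony, and Bayesian replay decoding with shuffle-based sequence scoring —
plus a seeded synthetic-session generator that provides ground truth for every
stage.

## The problem

Dual-site tetrode recordings from the left and right hippocampal CA1 make it
possible to ask how spatial coding, co-activation assemblies, ripples and
replay are coordinated *across hemispheres*, and how that coordination
degrades when inputs (e.g. CA3 transmission) are silenced. Answering that
requires a fairly long analysis chain — unit inclusion, directional rate maps,
eigenvalue-bounded ICA, band-power event detection, Poisson decoding, circular
shuffles — in which every stage has tunable constants and failure modes. This
package implements that chain as a tested, reusable library for
electrophysiologists, with a synthetic generator so every stage can be
validated by parameter recovery instead of by eye.

## The statistics at the core

**Spatial information** (bits/spike) of a directional rate map with occupancy
probabilities `p_i`, per-bin rates `λ_i` and mean rate `λ`:

    SI = Σ_i p_i (λ_i / λ) log2(λ_i / λ)

**Cell assemblies.** Spike trains are binned (25 ms) and z-scored into an
`n × B` matrix `Z`. The number of genuine co-activation patterns is the number
of eigenvalues of the correlation matrix `Z Zᵀ / B` above the Marčenko–Pastur
bound `λ_max = (1 + √(n/B))²`; `Z` is projected onto those components and
fastICA unmixes them into weight vectors `v_k`. Members are units whose weight
exceeds mean + 2 SD. Activation strength at time `t` is the quadratic form
`R_k(t) = z(t)ᵀ P_k z(t)` with `P_k = v_k v_kᵀ` (zero diagonal), and a
member-shuffle null calibrates the fraction of single-hemisphere (unilateral)
assemblies.

**SWRs.** The LFP is band-passed 90–250 Hz (zero-phase Hamming FIR); events
are RMS-power excursions above mean + 5 SD with edges at 2 SD, merged when
peaks are closer than 50 ms, and only accepted during immobility (< 2 cm/s).
Bilateral synchrony is the ±100 ms cross-correlogram of event midpoints
(1 ms bins, Gaussian-smoothed, SD 4 bins, in SWRs/s).

**Replay.** Candidate SWRs (50–300 ms, ≥ 5 active place cells) are decoded in
20 ms bins under a Poisson observation model,
`Pr(pos|spikes) ∝ (Π_i f_i(pos)^{sp_i}) e^{−τ Σ_i f_i(pos)}`, using
exploration templates `f_i`. Sequence structure is the posterior-weighted
position–time correlation `r`; circularly shifting every cell's template
(1000×) gives a null, the score `rZ = (|r| − mean|r_null|)/SD|r_null|`, and a
Monte Carlo `P = (n_exceed + 1)/(n_shuffles + 1)`. Per-cell contribution
shuffles one cell's template at a time:
`PCC = (rZ_obs − mean rZ_single-cell-shuffle) × n_participants`.

## Worked example

```python
from ensemblelat import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    synth=SimulationConfig(seed=7, n_laps=10, rest_duration=200.0),
    seed=7, n_shuffles=200)
res = run_pipeline(cfg, "out/")
```

This generates a bilateral 60-unit session (10 track laps, then 200 s of
rest with ripples and replay), runs every stage and writes all tables to
`out/`. Summarising `res` prints:

```
place cells: 60  median SI: 1.31 bits/spike
SWRs (left): 39  occurrence: 0.20/s  median peak freq: 139.6 Hz
bilateral xcorr central rate: 47.73 SWRs/s
assemblies: 21  unilateral fraction: 0.05  null 95th pct: 0.29
candidate events: 72  significant replay: 64  median rZ: 4.15  median speed: 6.94 m/s
```

Reading it: all 60 synthetic units pass the inclusion gates and carry ~1.3
bits/spike of positional information; ripple detection recovers the generated
0.2/s event rate and the 140 Hz carrier; the tall central cross-correlogram
rate reflects the 5 ms left/right ripple jitter of a "control-like" session;
the observed unilateral assembly fraction (0.05) sits well below the shuffle
null's 95th percentile (0.29), i.e. no lateralization; and most candidate
ripples contain decodable replay near the generated 8 m/s (the small
underestimate is the expected peak-position discretisation bias). The same
pipeline is available from the shell: `ensemblelat run --seed 7 --out out/`.

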