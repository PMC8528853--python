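"""Seeded synthetic bilateral recordings with known ground truth.

Emulates the study conditions every analysis stage is validated against: two
populations of directional place cells on a 150 cm linear track (exploration,
inhomogeneous-Poisson spiking from Gaussian tuning curves with embedded
co-activation assemblies), followed by a rest session whose two LFP channels
contain ripple-band bursts with controllable left/right timing jitter and
time-compressed replay sequences inside designated ripples.

All randomness flows from ``SimulationConfig.seed`` through named child
streams, so identical seed + config gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal.windows import tukey

from . import ripples as _ripples
from .config import AssemblySpec, ConfigError, SimulationConfig
from .placefields import position_trace
from .types import DecodingTemplate, PositionTrace, UnitSpikeTrain

__all__ = [
    "GroundTruth",
    "unit_rate_series",
    "generate_exploration",
    "generate_rest",
    "sample_bilateral_ripple_times",
    "make_pcc_probe_event",
]

# child-stream tags appended to the user seed
_STREAM_FIELDS = 1
_STREAM_EXPLORATION = 2
_STREAM_REST = 3


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests."""

    field_centers: Optional[np.ndarray] = None      # (n_units, 2): rightward, leftward
    field_width: float = np.nan
    peak_rate: float = np.nan
    assembly_members: List[tuple] = dc_field(default_factory=list)
    ripple_intervals: dict = dc_field(default_factory=dict)   # hemisphere -> (n, 2)
    ripple_midpoints: dict = dc_field(default_factory=dict)   # hemisphere -> (n,)
    replay_events: List[dict] = dc_field(default_factory=list)

    def validate(self, n_units: int) -> None:
        for members in self.assembly_members:
            if any(m < 0 or m >= n_units for m in members):
                raise ValueError("assembly member refers to a non-existent unit")
        for ev in self.replay_events:
            hemi = ev.get("hemisphere", "L")
            ivals = self.ripple_intervals.get(hemi)
            inside = ivals is not None and np.any(
                (ivals[:, 0] <= ev["t_start"] + 1e-9) & (ivals[:, 1] >= ev["t_stop"] - 1e-9))
            if not inside:
                raise ValueError("replay event outside every true ripple interval")


def _field_centers(config: SimulationConfig) -> np.ndarray:
    """Per-unit, per-direction field centres (deterministic child stream)."""
    if config.field_centers is not None:
        return np.asarray(config.field_centers, dtype=float)
    rng = np.random.default_rng([config.seed, _STREAM_FIELDS])
    return rng.uniform(0.0, config.track_length, size=(config.n_units, 2))


def _assembly_specs(config: SimulationConfig) -> List[AssemblySpec]:
    if config.assemblies is not None:
        return list(config.assemblies)
    rng = np.random.default_rng([config.seed, _STREAM_FIELDS, 7])
    specs = []
    for k in range(config.n_assemblies):
        if config.assembly_mode == "unilateral":
            if k % 2 == 0:
                pool = np.arange(config.n_units_left)
            else:
                pool = np.arange(config.n_units_left, config.n_units)
        else:
            pool = np.arange(config.n_units)
        members = rng.choice(pool, size=min(config.assembly_size, pool.size), replace=False)
        specs.append(AssemblySpec(members=tuple(sorted(int(m) for m in members)),
                                  rate_hz=config.assembly_rate_hz,
                                  jitter_ms=config.assembly_jitter_ms))
    return specs


def _exploration_position(config: SimulationConfig) -> PositionTrace:
    """Back-and-forth traversals with a short dwell at each track end."""
    fs, L, v = config.position_fs, config.track_length, config.run_speed
    end_dwell_s = config.end_dwell_s
    t_run = L / v
    segs = []  # (duration, x_from, x_to)
    pos = 0.0
    for lap in range(config.n_laps):
        target = L if pos == 0.0 else 0.0
        segs.append((t_run, pos, target))
        segs.append((end_dwell_s, target, target))
        pos = target
    duration = sum(s[0] for s in segs)
    times = np.arange(0.0, duration, 1.0 / fs)
    x = np.empty_like(times)
    t0 = 0.0
    for dur, a, b in segs:
        sel = (times >= t0) & (times < t0 + dur)
        x[sel] = a + (b - a) * (times[sel] - t0) / dur
        t0 += dur
    return position_trace(times, x, track_length=L)


def _enforce_refractory(times: np.ndarray, refractory_ms: float = 2.0) -> np.ndarray:
    """Greedy keep-first enforcement of an absolute refractory period.

    The generator's component processes (tuning-curve spikes, assembly
    co-activation, replay content, rest background) are merged independently;
    without this step chance collisions alone would push units past the
    0.5% ISI-violation inclusion gate, which real refractory neurons do not.
    """
    t = np.unique(times)
    if t.size < 2:
        return t
    gap = refractory_ms * 1e-3
    keep = np.ones(t.size, dtype=bool)
    last = t[0]
    for i in range(1, t.size):
        if t[i] - last <= gap:
            keep[i] = False
        else:
            last = t[i]
    return t[keep]


def _thin_inhomogeneous(rng: np.random.Generator, times: np.ndarray,
                        rate: np.ndarray, lam_max: float) -> np.ndarray:
    """Exact thinning of an inhomogeneous Poisson process.

    ``rate`` is the intensity sampled on ``times``; candidates are drawn from
    a homogeneous process at ``lam_max`` and accepted with probability
    rate(t)/lam_max (linear interpolation between samples).
    """
    duration = times[-1] - times[0]
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(times[0], times[-1], size=n_cand))
    accept = rng.uniform(0.0, 1.0, size=n_cand) < np.interp(cand, times, rate) / lam_max
    return cand[accept]


def unit_rate_series(config: SimulationConfig, centers: np.ndarray,
                     position: PositionTrace, unit: int) -> np.ndarray:
    """Instantaneous firing rate of one unit along a trajectory (Hz).

    Baseline everywhere plus the direction-matched Gaussian field bump; this
    is the exact intensity the exploration generator thins against, so its
    time integral is the expected spike count before co-activation extras.
    """
    x, direction = position.x, position.direction
    rate = np.full(x.size, config.baseline_rate)
    for d_idx, d in enumerate((1, -1)):
        sel = direction == d
        rate[sel] += (config.peak_rate - config.baseline_rate) * np.exp(
            -0.5 * ((x[sel] - centers[unit, d_idx]) / config.field_width) ** 2)
    return rate


def generate_exploration(config: SimulationConfig
                         ) -> Tuple[PositionTrace, List[UnitSpikeTrain], GroundTruth]:
    """Synthetic exploration session (track running + assembly co-activation).

    Each unit fires as an inhomogeneous Poisson process whose intensity is a
    direction-specific Gaussian tuning curve evaluated along the trajectory;
    assembly members receive additional synchronous events at the configured
    co-activation rate with per-member Gaussian latency jitter.
    """
    centers = _field_centers(config)
    specs = _assembly_specs(config)
    position = _exploration_position(config)
    rng = np.random.default_rng([config.seed, _STREAM_EXPLORATION])

    t = position.times
    lam_max = config.peak_rate + config.baseline_rate
    spike_lists: List[np.ndarray] = []
    for i in range(config.n_units):
        rate = unit_rate_series(config, centers, position, i)
        spike_lists.append(_thin_inhomogeneous(rng, t, rate, lam_max))

    duration = t[-1]
    for spec in specs:
        n_ev = rng.poisson(spec.rate_hz * duration)
        ev_times = rng.uniform(0.0, duration, size=n_ev)
        for m in spec.members:
            extra = ev_times + rng.normal(0.0, spec.jitter_ms * 1e-3, size=n_ev)
            spike_lists[m] = np.concatenate([spike_lists[m], np.clip(extra, 0.0, duration)])

    units = [UnitSpikeTrain(unit_id=i, hemisphere=config.hemisphere_of(i),
                            spike_times=_enforce_refractory(spike_lists[i]))
             for i in range(config.n_units)]
    truth = GroundTruth(field_centers=centers, field_width=config.field_width,
                        peak_rate=config.peak_rate,
                        assembly_members=[s.members for s in specs])
    truth.validate(config.n_units)
    return position, units, truth


def sample_bilateral_ripple_times(rng: np.random.Generator, duration: float,
                                  rate: float, jitter_ms: float,
                                  independent_fraction: float = 0.0,
                                  pad: float = 0.5) -> Tuple[np.ndarray, np.ndarray, list]:
    """Left/right ripple midpoints: a paired Poisson train plus optional extras.

    Right midpoints of paired events are the left midpoints offset by
    N(0, jitter_ms); ``independent_fraction`` adds that multiple of the base
    rate as unpaired events on each side. Returns (left, right, pairs) where
    pairs lists (t_left, t_right, side_tag) for paired events.
    """
    n = rng.poisson(rate * (duration - 2 * pad))
    left = np.sort(rng.uniform(pad, duration - pad, size=n))
    offs = rng.normal(0.0, jitter_ms * 1e-3, size=n) if jitter_ms > 0 else np.zeros(n)
    right = left + offs
    pairs = list(zip(left.tolist(), right.tolist()))
    extras = {"L": np.array([]), "R": np.array([])}
    if independent_fraction > 0:
        for h in ("L", "R"):
            m = rng.poisson(independent_fraction * rate * (duration - 2 * pad))
            extras[h] = np.sort(rng.uniform(pad, duration - pad, size=m))
    left_all = np.sort(np.concatenate([left, extras["L"]]))
    right_all = np.sort(np.concatenate([right, extras["R"]]))
    return left_all, right_all, {"pairs": pairs, "extras": extras}


def _calibrated_burst_amplitude(noise: np.ndarray, fs: float, target_sd: float) -> float:
    """Peak amplitude putting the burst's band RMS ``target_sd`` SDs above the
    background band RMS mean (measured with the detector's own filter/window)."""
    band = _ripples.bandpass_filter(noise, fs)
    power = _ripples.rms_power(band, fs)
    return float(np.sqrt(2.0) * (power.mean() + target_sd * power.std()))


def _inject_burst(lfp: np.ndarray, times: np.ndarray, fs: float, mid: float,
                  duration_s: float, freq: float, amplitude: float) -> None:
    i0 = int(np.searchsorted(times, mid - duration_s / 2))
    i1 = int(np.searchsorted(times, mid + duration_s / 2))
    i0, i1 = max(i0, 0), min(i1, lfp.size)
    n = i1 - i0
    if n < 2:
        return
    env = tukey(n, alpha=0.25)
    lfp[i0:i1] += amplitude * env * np.sin(2 * np.pi * freq * (times[i0:i1] - times[i0]))


def generate_rest(config: SimulationConfig, templates: Optional[np.ndarray] = None, *,
                  replay_cell_scope: Optional[str] = None
                  ) -> Tuple[PositionTrace, List[UnitSpikeTrain], np.ndarray, np.ndarray, GroundTruth]:
    """Synthetic rest session: bilateral LFP with ripple bursts and replay.

    Parameters
    ----------
    templates : ndarray, optional
        (n_units, 2) per-direction preferred positions used to synthesise
        replay content. Defaults to the same field centres the exploration
        generator draws for this seed, so exploration-derived templates and
        rest replay content agree.
    replay_cell_scope : {"both", "event_side"}
        "both": replay participants come from both hemispheres (coordinated,
        control-like). "event_side": each replay's participants are restricted
        to one hemisphere (the event's side; lateralized, mutant-like).

    Returns ``(position, units, lfp_left, lfp_right, truth)``. LFP traces are
    sampled at ``config.lfp_fs``; Gaussian background noise plus
    Tukey-enveloped sinusoidal bursts at the configured ripple frequency,
    amplitude-calibrated so the band RMS at burst peak sits
    ``config.ripple_amplitude_sd`` SDs above the background mean.
    """
    if config.lfp_fs < 500:
        raise ConfigError("lfp_fs: must be >= 500 Hz to carry the 250 Hz band edge")
    if replay_cell_scope is None:
        replay_cell_scope = config.replay_cell_scope
    if replay_cell_scope not in ("both", "event_side"):
        raise ConfigError("replay_cell_scope: must be 'both' or 'event_side'")
    centers = _field_centers(config) if templates is None else np.asarray(templates, float)
    rng = np.random.default_rng([config.seed, _STREAM_REST])
    duration = config.rest_duration

    # position: stationary in the middle of the sleep box, tiny tracker noise
    t_pos = np.arange(0.0, duration, 1.0 / config.position_fs)
    x = config.track_length / 2 + rng.normal(0.0, 0.02, size=t_pos.size)
    position = position_trace(t_pos, np.clip(x, 0, config.track_length),
                              track_length=config.track_length)

    burst_s = config.ripple_duration_ms * 1e-3
    left_mid, right_mid, info = sample_bilateral_ripple_times(
        rng, duration, config.ripple_rate, config.lr_ripple_jitter_ms,
        config.lr_independent_fraction, pad=0.5 + burst_s)

    t_lfp = np.arange(0.0, duration, 1.0 / config.lfp_fs)
    lfp = {h: config.noise_sd * rng.standard_normal(t_lfp.size) for h in ("L", "R")}
    amp = _calibrated_burst_amplitude(lfp["L"], config.lfp_fs, config.ripple_amplitude_sd)
    for h, mids in (("L", left_mid), ("R", right_mid)):
        for m in mids:
            _inject_burst(lfp[h], t_lfp, config.lfp_fs, m, burst_s,
                          config.ripple_band_freq, amp)

    intervals = {h: np.column_stack([mids - burst_s / 2, mids + burst_s / 2])
                 for h, mids in (("L", left_mid), ("R", right_mid))}

    # replay content inside designated ripples
    speed_cm = config.replay_speed * 100.0
    spike_lists: List[np.ndarray] = [np.array([]) for _ in range(config.n_units)]
    replay_truth: List[dict] = []
    slots: List[tuple] = []  # (left midpoint, right midpoint, side tag)
    for tl, tr in info["pairs"]:
        slots.append((tl, tr, "L" if rng.random() < 0.5 else "R"))
    for h in ("L", "R"):
        for m in info["extras"][h]:
            slots.append((float(m), float(m), h))
    slots.sort()
    for t_left, t_right, side in slots:
        if rng.random() >= config.replay_fraction:
            continue
        # window: the true interval on the content side ("both" scope uses left)
        hemi = side if replay_cell_scope == "event_side" else "L"
        mid = t_left if hemi == "L" else t_right
        w0, w1 = mid - burst_s / 2, mid + burst_s / 2
        win_dur = w1 - w0
        direction = 1 if rng.random() < config.replay_direction_mix else -1
        d_idx = 0 if direction == 1 else 1
        t_traj = min(win_dur, config.track_length / speed_cm)
        traj0 = w0 + (win_dur - t_traj) / 2
        path_len = speed_cm * t_traj
        if direction == 1:
            x0 = rng.uniform(0.0, config.track_length - path_len)
            x1 = x0 + path_len
            lo, hi = x0, x1
        else:
            x0 = rng.uniform(path_len, config.track_length)
            x1 = x0 - path_len
            lo, hi = x1, x0
        if replay_cell_scope == "event_side":
            pool = (np.arange(config.n_units_left) if side == "L"
                    else np.arange(config.n_units_left, config.n_units))
        else:
            pool = np.arange(config.n_units)
        participants = []
        for i in pool:
            c = centers[i, d_idx]
            if not (lo <= c <= hi):
                continue
            tc = traj0 + abs(c - x0) / speed_cm
            n_sp = int(rng.integers(1, 4))
            sp = tc + rng.normal(0.0, config.replay_spike_jitter_ms * 1e-3, size=n_sp)
            spike_lists[i] = np.concatenate([spike_lists[i], np.clip(sp, w0, w1 - 1e-4)])
            participants.append(int(i))
        if len(participants) == 0:
            continue
        replay_truth.append(dict(t_start=w0, t_stop=w1, hemisphere=hemi, side=side,
                                 direction=direction, x_start=x0, x_end=x1,
                                 distance_cm=path_len, speed_m_s=config.replay_speed,
                                 participants=participants))

    # background rest firing
    for i in range(config.n_units):
        n_bg = rng.poisson(config.rest_baseline_rate * duration)
        bg = rng.uniform(0.0, duration, size=n_bg)
        spike_lists[i] = np.unique(np.concatenate([spike_lists[i], bg]))

    units = [UnitSpikeTrain(unit_id=i, hemisphere=config.hemisphere_of(i),
                            spike_times=_enforce_refractory(spike_lists[i]))
             for i in range(config.n_units)]
    truth = GroundTruth(field_centers=centers, field_width=config.field_width,
                        peak_rate=config.peak_rate,
                        ripple_intervals=intervals,
                        ripple_midpoints={"L": left_mid, "R": right_mid},
                        replay_events=replay_truth)
    truth.validate(config.n_units)
    return position, units, lfp["L"], lfp["R"], truth


def make_pcc_probe_event(seed: int = 0, *, n_anchor_bins: int = 4,
                         cells_per_anchor: int = 3, n_pos: int = 100,
                         track_length: float = 150.0, tau: float = 0.020,
                         peak_rate: float = 20.0, field_width_cm: float = 6.0
                         ) -> dict:
    """Construct a synthetic replay event with one pivotal sequence cell.

    The decoded trajectory is a line across ``n_anchor_bins + 1`` temporal
    bins. Every anchor bin is constrained redundantly by ``cells_per_anchor``
    cells with coincident place fields, while the middle bin is constrained by
    a single "carrier" cell: shuffling the carrier's template destroys that
    bin's position entirely, whereas shuffling any one redundant cell leaves
    its bin anchored by its field-mates. The carrier is therefore the event's
    dominant sequence-carrying cell.

    Returns a dict with ``window`` (t_start, t_stop), ``units``, ``template``,
    ``carrier_id``, and the planted trajectory positions.
    """
    rng = np.random.default_rng([seed, 11])
    M = n_anchor_bins + 1
    mid_bin = M // 2
    traj = np.linspace(0.2 * track_length, 0.8 * track_length, M)
    cells: List[tuple] = []  # (center_cm, temporal_bin)
    for k in range(M):
        n_c = 1 if k == mid_bin else cells_per_anchor
        for _ in range(n_c):
            cells.append((traj[k], k))
    carrier_idx = next(i for i, (_, k) in enumerate(cells) if k == mid_bin)

    bin_centers = (np.arange(n_pos) + 0.5) * track_length / n_pos
    rates = np.array([peak_rate * np.exp(-0.5 * ((bin_centers - c) / field_width_cm) ** 2)
                      for c, _ in cells])
    template = DecodingTemplate(unit_ids=np.arange(len(cells)), rates=rates,
                                bin_centers=bin_centers, direction=1, tau=tau)
    t0 = 1.0
    units = []
    for i, (_, k) in enumerate(cells):
        center_t = t0 + (k + 0.5) * tau
        sp = np.sort(center_t + rng.uniform(-0.4 * tau, 0.4 * tau, size=2))
        units.append(UnitSpikeTrain(unit_id=i, hemisphere="L", spike_times=np.unique(sp)))
    return dict(window=(t0, t0 + M * tau), units=units, template=template,
                carrier_id=carrier_idx, trajectory_cm=traj)
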