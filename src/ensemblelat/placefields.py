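"""Place-field analyses: unit inclusion, rate maps, spatial information.

The track is divided into 100 equal bins; spike and occupancy maps are each
smoothed with a Gaussian kernel (SD 5 cm, reflected at the track ends) before
division, so unvisited bins can be flagged rather than producing 0/0. Spatial
information is the classic bits-per-spike measure

    SI = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda),

with p_i the occupancy probability of bin i, lambda_i the rate in bin i and
lambda the occupancy-weighted mean rate. Analyses are direction-specific:
leftward and rightward traversals are treated as separate conditions.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .types import PositionTrace, RateMap, UnitSpikeTrain

__all__ = [
    "kinematics",
    "position_trace",
    "filter_units",
    "compute_ratemap",
    "spatial_information",
    "firing_rate_summaries",
]


def kinematics(times: np.ndarray, x: np.ndarray, boxcar_s: float = 0.25,
               direction_min: float = 1.0) -> tuple:
    """Velocity (signed, cm/s) and per-sample direction from raw position.

    Velocity is estimated by central differences and smoothed with a boxcar
    of ``boxcar_s`` seconds. Direction is the sign of the smoothed velocity
    where its magnitude exceeds ``direction_min`` cm/s, else 0.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 position samples")
    v = np.gradient(x, times)
    dt = float(np.median(np.diff(times)))
    width = max(1, int(round(boxcar_s / dt)))
    v = uniform_filter1d(v, size=width, mode="nearest")
    direction = np.zeros(v.size, dtype=int)
    direction[v > direction_min] = 1
    direction[v < -direction_min] = -1
    return v, direction


def position_trace(times: np.ndarray, x: np.ndarray, track_length: float = 150.0,
                   boxcar_s: float = 0.25) -> PositionTrace:
    """Build a :class:`PositionTrace` with derived velocity and direction."""
    v, d = kinematics(times, x, boxcar_s=boxcar_s)
    return PositionTrace(times=times, x=np.clip(x, 0.0, track_length),
                         velocity=v, direction=d, track_length=track_length)


def _speed_at(position: PositionTrace, t: np.ndarray) -> np.ndarray:
    return np.abs(np.interp(t, position.times, position.velocity))


def isi_violation_fraction(unit: UnitSpikeTrain, isi_threshold_ms: float = 2.0) -> float:
    """Fraction of inter-spike intervals shorter than the refractory bound."""
    if unit.n_spikes < 2:
        return 0.0
    isis = np.diff(unit.spike_times)
    return float(np.mean(isis < isi_threshold_ms * 1e-3))


def filter_units(units: Sequence[UnitSpikeTrain], position: PositionTrace, *,
                 min_total_spikes: int = 75, min_movement_spikes: int = 75,
                 max_isi_violation: float = 0.005, isi_threshold_ms: float = 2.0,
                 movement_velocity: float = 5.0) -> List[UnitSpikeTrain]:
    """Spike-time-based unit inclusion.

    Drops units with an ISI-violation fraction above ``max_isi_violation``
    (ISI < 2 ms), fewer than 75 total spikes, or fewer than 75 spikes while
    the animal moved faster than 5 cm/s; survivors are returned unchanged.
    """
    kept = []
    for u in units:
        if u.n_spikes < min_total_spikes:
            continue
        if isi_violation_fraction(u, isi_threshold_ms) > max_isi_violation:
            continue
        moving = _speed_at(position, u.spike_times) > movement_velocity
        if int(moving.sum()) < min_movement_spikes:
            continue
        kept.append(u)
    return kept


def compute_ratemap(unit: UnitSpikeTrain, position: PositionTrace, direction: int, *,
                    n_bins: int = 100, smoothing_sd_cm: float = 5.0,
                    movement_velocity: float = 5.0) -> RateMap:
    """Occupancy-normalised rate map for one running direction.

    Only samples moving in ``direction`` faster than the movement gate enter
    the occupancy map; spikes are assigned to the position interpolated at
    their time and kept under the same gate. Spike and occupancy maps are
    smoothed (reflection padding) before division. Bins are half-open
    [edge, next); the last bin is closed.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 (rightward) or -1 (leftward)")
    sel = (position.direction == direction) & (np.abs(position.velocity) > movement_velocity)
    if not np.any(sel):
        raise ValueError("empty direction: no movement samples in that direction")
    edges = np.linspace(0.0, position.track_length, n_bins + 1)
    dt = np.median(np.diff(position.times))
    occupancy = np.histogram(position.x[sel], bins=edges)[0].astype(float) * dt

    t = unit.spike_times
    t = t[(t >= position.times[0]) & (t <= position.times[-1])]
    sp_dir = np.interp(t, position.times, position.direction.astype(float))
    sp_v = np.abs(np.interp(t, position.times, position.velocity))
    sp_ok = (np.sign(sp_dir) == direction) & (np.abs(sp_dir) > 0.5) & (sp_v > movement_velocity)
    sp_x = np.interp(t[sp_ok], position.times, position.x)
    spikes = np.histogram(sp_x, bins=edges)[0].astype(float)

    bin_w = edges[1] - edges[0]
    if smoothing_sd_cm > 0:
        sd_bins = smoothing_sd_cm / bin_w
        occ_s = gaussian_filter1d(occupancy, sd_bins, mode="reflect")
        spk_s = gaussian_filter1d(spikes, sd_bins, mode="reflect")
    else:
        occ_s, spk_s = occupancy, spikes
    visited = occ_s > 0
    rate = np.zeros(n_bins)
    rate[visited] = spk_s[visited] / occ_s[visited]
    return RateMap(direction=direction, bin_edges=edges, occupancy_s=occ_s,
                   rate_hz=rate, smoothing_sd_cm=smoothing_sd_cm, visited=visited)


def spatial_information(ratemap: RateMap) -> float:
    """Spatial information of a rate map, in bits per spike.

    Unvisited bins carry zero occupancy probability and are excluded; the
    0*log(0) terms of silent visited bins contribute 0. Raises for a silent
    unit (mean rate 0), for which the quantity is undefined.
    """
    p = ratemap.occupancy_p[ratemap.visited]
    p = p / p.sum()
    lam_i = ratemap.rate_hz[ratemap.visited]
    lam = float(np.sum(p * lam_i))
    if lam <= 0:
        raise ValueError("silent unit: mean rate is zero")
    ratio = lam_i / lam
    terms = np.zeros_like(ratio)
    nz = ratio > 0
    terms[nz] = p[nz] * ratio[nz] * np.log2(ratio[nz])
    return float(terms.sum())


def _spikes_in_intervals(unit: UnitSpikeTrain, intervals: Iterable[tuple]) -> int:
    n = 0
    for a, b in intervals:
        n += unit.count_in(a, b)
    return n


def firing_rate_summaries(unit: UnitSpikeTrain, *,
                          exploration_window: Optional[tuple] = None,
                          rest_window: Optional[tuple] = None,
                          ripple_intervals: Optional[Sequence[tuple]] = None) -> dict:
    """Mean firing rates per session context.

    Each entry is spike count in the context divided by total context
    duration; ``fr_in_swr`` pools all ripple intervals of the rest session.
    """
    out = {}
    for key, win in (("fr_exploration", exploration_window), ("fr_rest", rest_window)):
        if win is None:
            continue
        a, b = win
        if b <= a:
            raise ValueError(f"{key}: zero-duration context")
        out[key] = unit.count_in(a, b) / (b - a)
    if ripple_intervals is not None:
        total = float(sum(b - a for a, b in ripple_intervals))
        if total <= 0:
            raise ValueError("fr_in_swr: zero-duration context")
        out["fr_in_swr"] = _spikes_in_intervals(unit, ripple_intervals) / total
    return out
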