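"""Core in-memory containers shared by every analysis stage.

All times are seconds, positions centimetres, rates Hz, LFP millivolts.
Containers are plain dataclasses wrapping numpy arrays; each validates the
invariants it is responsible for at construction time so downstream code can
assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "UnitSpikeTrain",
    "PositionTrace",
    "RateMap",
    "BinnedSpikeMatrix",
    "AssemblyPattern",
    "ActivationTrace",
    "RippleEvent",
    "RippleCrossCorrelogram",
    "DecodingTemplate",
    "PosteriorMatrix",
    "ReplayEvent",
]


@dataclass
class UnitSpikeTrain:
    """Spike timestamps of one sorted unit.

    Parameters
    ----------
    unit_id : int
        Session-unique identifier.
    hemisphere : {"L", "R"}
        Recording hemisphere.
    spike_times : ndarray
        Strictly increasing spike times in seconds.
    """

    unit_id: int
    hemisphere: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike_times must be strictly increasing")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def count_in(self, t_start: float, t_stop: float) -> int:
        """Number of spikes in the half-open window [t_start, t_stop)."""
        lo, hi = np.searchsorted(self.spike_times, [t_start, t_stop])
        return int(hi - lo)


@dataclass
class PositionTrace:
    """1-D tracked position on the linear track with derived kinematics.

    ``direction`` holds +1 (rightward, increasing x), -1 (leftward) or 0
    (no sustained movement) per sample.
    """

    times: np.ndarray
    x: np.ndarray
    velocity: np.ndarray
    direction: np.ndarray
    track_length: float = 150.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.direction = np.asarray(self.direction, dtype=int)
        if not (self.times.size == self.x.size == self.velocity.size == self.direction.size):
            raise ValueError("times, x, velocity, direction must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("position times must be strictly increasing")
        if self.x.size and (self.x.min() < -1e-9 or self.x.max() > self.track_length + 1e-9):
            raise ValueError("position outside track bounds")

    @property
    def fs(self) -> float:
        """Median sampling rate (Hz)."""
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class RateMap:
    """Direction-specific occupancy-normalised firing-rate map.

    ``occupancy_s`` and ``rate_hz`` are both already smoothed (the smoothing
    kernel is applied to the spike and occupancy maps separately, before
    division). ``visited`` flags bins with non-zero smoothed occupancy; the
    rate of unvisited bins is 0 by convention.
    """

    direction: int
    bin_edges: np.ndarray
    occupancy_s: np.ndarray
    rate_hz: np.ndarray
    smoothing_sd_cm: float = 5.0
    visited: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.occupancy_s = np.asarray(self.occupancy_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        n = self.bin_edges.size - 1
        if self.occupancy_s.size != n or self.rate_hz.size != n:
            raise ValueError("occupancy/rate length must match bin count")
        if np.any(self.occupancy_s < -1e-12) or np.any(self.rate_hz < -1e-9):
            raise ValueError("occupancy and rate must be non-negative")
        if self.visited is None:
            self.visited = self.occupancy_s > 0
        self.visited = np.asarray(self.visited, dtype=bool)

    @property
    def n_bins(self) -> int:
        return int(self.rate_hz.size)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupancy_p(self) -> np.ndarray:
        """Occupancy probabilities over visited bins (sum to 1)."""
        tot = self.occupancy_s.sum()
        if tot <= 0:
            raise ValueError("empty occupancy")
        return self.occupancy_s / tot


@dataclass
class BinnedSpikeMatrix:
    """Z-scored binned spike counts (units x time bins).

    Rows of ``Z`` have mean 0 and SD 1; units whose count vector had zero
    variance are dropped and listed in ``dropped_unit_ids``.
    """

    Z: np.ndarray
    bin_times: np.ndarray
    unit_ids: np.ndarray
    direction: Optional[int] = None
    dropped_unit_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    bin_ms: float = 25.0

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-D (units x bins)")
        if self.Z.shape[0] != self.unit_ids.size:
            raise ValueError("row count must match unit_ids")
        if self.Z.shape[1] != self.bin_times.size:
            raise ValueError("column count must match bin_times")

    @property
    def n_units(self) -> int:
        return int(self.Z.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.Z.shape[1])


@dataclass
class AssemblyPattern:
    """One ICA co-activation pattern.

    ``weights`` is the unit-norm weight vector over ``unit_ids`` (sign-fixed so
    its largest-magnitude entry is positive). ``members`` are units whose
    weight exceeds the population mean by more than 2 SD. The projection
    matrix used for activation tracking is the outer product of the weight
    vector with its diagonal zeroed.
    """

    assembly_id: int
    unit_ids: np.ndarray
    weights: np.ndarray
    members: frozenset
    laterality: str = "undefined"  # unilateral-L | unilateral-R | bilateral | undefined
    dominant_side: str = "tied"    # L | R | tied
    direction: Optional[int] = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.unit_ids.size != self.weights.size:
            raise ValueError("weights must align with unit_ids")
        nrm = np.linalg.norm(self.weights)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError(f"weight vector must have unit norm, got {nrm}")
        if not self.members <= set(self.unit_ids.tolist()):
            raise ValueError("members must be a subset of unit_ids")

    @property
    def projection_matrix(self) -> np.ndarray:
        """Outer product of the weight vector with zero diagonal."""
        P = np.outer(self.weights, self.weights)
        np.fill_diagonal(P, 0.0)
        return P


@dataclass
class ActivationTrace:
    """Time course of one assembly's activation strength.

    ``peaks`` holds (time, strength) for strict local maxima whose strength
    exceeds the reactivation threshold (5 by default).
    """

    assembly_id: int
    times: np.ndarray
    strength: np.ndarray
    peak_times: np.ndarray
    peak_strengths: np.ndarray
    threshold: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strength = np.asarray(self.strength, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_strengths = np.asarray(self.peak_strengths, dtype=float)
        if self.peak_strengths.size and self.peak_strengths.min() <= self.threshold:
            raise ValueError("all recorded peaks must exceed the threshold")


@dataclass
class RippleEvent:
    """One detected sharp-wave-ripple event."""

    hemisphere: str
    t_start: float
    t_stop: float
    t_peak: float
    amplitude_mv: float = np.nan
    peak_freq_hz: float = np.nan
    event_id: int = -1

    def __post_init__(self) -> None:
        if not (self.t_start <= self.t_peak <= self.t_stop):
            raise ValueError("require t_start <= t_peak <= t_stop")
        if self.t_stop <= self.t_start:
            raise ValueError("duration must be positive")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_stop)

    @property
    def duration_ms(self) -> float:
        return 1e3 * (self.t_stop - self.t_start)


@dataclass
class RippleCrossCorrelogram:
    """Rate of opposite-hemisphere ripple midpoints around reference midpoints.

    Lags span -100..+100 ms at 1 ms resolution; ``rate`` is SWRs/s per lag bin
    after Gaussian smoothing (SD 4 bins).
    """

    lags_ms: np.ndarray
    rate: np.ndarray
    n_reference: int
    smoothing_sd_bins: float = 4.0

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.lags_ms.size != self.rate.size:
            raise ValueError("lags and rate must align")
        if np.any(self.rate < -1e-12):
            raise ValueError("rate must be non-negative")

    @property
    def central_rate(self) -> float:
        """Peak rate within +-10 ms of zero lag."""
        sel = np.abs(self.lags_ms) <= 10.0
        return float(self.rate[sel].max())


@dataclass
class DecodingTemplate:
    """Per-direction firing-rate templates used for Bayesian decoding.

    ``rates`` is (n_cells x n_pos_bins), one smoothed exploration rate curve
    per included place cell; ``tau`` is the decoding bin width in seconds.
    """

    unit_ids: np.ndarray
    rates: np.ndarray
    bin_centers: np.ndarray
    direction: int
    tau: float = 0.020
    rate_floor: float = 0.01

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[0] != self.unit_ids.size:
            raise ValueError("rates must be (n_cells, n_pos_bins)")
        if np.any(self.rates < 0):
            raise ValueError("template rates must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def n_pos(self) -> int:
        return int(self.rates.shape[1])

    def floored_rates(self) -> np.ndarray:
        """Rates with the floor applied (avoids zero-probability annihilation)."""
        return np.maximum(self.rates, self.rate_floor)


@dataclass
class PosteriorMatrix:
    """Decoded posterior, (n_pos_bins x n_temporal_bins); columns sum to 1."""

    Pr: np.ndarray
    bin_times: np.ndarray
    bin_centers_cm: np.ndarray
    event_id: int = -1

    def __post_init__(self) -> None:
        self.Pr = np.asarray(self.Pr, dtype=float)
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        if self.Pr.ndim != 2:
            raise ValueError("Pr must be 2-D (pos x time)")
        if self.Pr.shape[1] != self.bin_times.size:
            raise ValueError("columns must match bin_times")
        colsum = self.Pr.sum(axis=0)
        if self.Pr.size and not np.allclose(colsum, 1.0, atol=1e-6):
            raise ValueError("posterior columns must sum to 1")

    @property
    def n_time(self) -> int:
        return int(self.Pr.shape[1])

    @property
    def n_pos(self) -> int:
        return int(self.Pr.shape[0])


@dataclass
class ReplayEvent:
    """Scored candidate replay event (one ripple, best direction)."""

    event_id: int
    ripple_hemisphere: str
    t_start: float
    t_stop: float
    direction: int
    r: float
    rz: float
    p_mc: float
    significant: bool
    distance_cm: float
    speed_m_s: float
    mean_jump_cm: float
    n_participants: int
    participants: tuple = ()
    posterior: Optional[PosteriorMatrix] = None
    pcc: Optional[dict] = None

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not (-1 - 1e-9 <= self.r <= 1 + 1e-9):
            raise ValueError("weighted correlation must lie in [-1, 1]")
        if self.distance_cm < 0 or self.mean_jump_cm < 0:
            raise ValueError("distances must be non-negative")
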