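"""Configuration objects for the synthetic generator and the pipeline.

Pipeline stage defaults are the protocol's reference constants (25 ms assembly
bins, 100 spatial bins with 5 cm smoothing, 90-250 Hz ripple band with 5/2 SD
thresholds and 50 ms merging, 2 and 5 cm/s velocity gates, 20 ms decoding
bins, 50-300 ms candidate windows with >=5 cells, 1000 shuffles, alpha 0.05,
activation-peak threshold 5, 0.01/s reactivation-rate floor). Overriding any
of them is explicit and recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

__all__ = ["AssemblySpec", "SimulationConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class AssemblySpec:
    """One embedded co-activation assembly.

    members are unit ids; rate_hz is the rate of synchronous excess events;
    jitter_ms the SD of each member's latency within an event.
    """

    members: tuple
    rate_hz: float = 2.0
    jitter_ms: float = 5.0

    def __post_init__(self) -> None:
        self.members = tuple(int(m) for m in self.members)
        if len(self.members) < 2:
            raise ConfigError("assemblies: each assembly needs >= 2 members")
        if self.rate_hz <= 0:
            raise ConfigError("assemblies.rate_hz: must be strictly positive")
        if self.jitter_ms < 0:
            raise ConfigError("assemblies.jitter_ms: must be non-negative")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic bilateral recording session.

    The defaults emulate the study conditions: a 150 cm linear track explored
    for 20 laps, ~30 pyramidal units per hemisphere with Gaussian directional
    place fields, embedded co-activation assemblies, and a rest session whose
    two LFP channels carry ripple-band bursts with controllable left/right
    timing jitter and time-compressed replay content.
    """

    seed: int = 0
    # track + exploration
    track_length: float = 150.0
    n_units_left: int = 30
    n_units_right: int = 30
    field_centers: Optional[np.ndarray] = None   # (n_units, 2) cm, per direction
    field_width: float = 8.0                     # cm, SD of Gaussian tuning
    peak_rate: float = 10.0                      # Hz at field centre
    baseline_rate: float = 0.2                   # Hz off-field floor
    run_speed: float = 15.0                      # cm/s
    n_laps: int = 20
    end_dwell_s: float = 1.0                     # pause at each track end
    position_fs: float = 50.0                    # Hz tracker rate
    # assemblies
    assemblies: Optional[Sequence[AssemblySpec]] = None
    n_assemblies: int = 8
    assembly_size: int = 4
    assembly_rate_hz: float = 2.0
    assembly_jitter_ms: float = 5.0
    assembly_mode: str = "bilateral"             # "bilateral" | "unilateral"
    # rest / LFP
    rest_duration: float = 600.0                 # s
    rest_baseline_rate: float = 0.5              # Hz per unit during rest
    ripple_rate: float = 0.2                     # events/s per hemisphere
    ripple_band_freq: float = 140.0              # Hz carrier of synthetic bursts
    ripple_duration_ms: float = 200.0            # burst extent
    ripple_amplitude_sd: float = 8.0             # band RMS at burst peak, in SDs of background
    lr_ripple_jitter_ms: float = 5.0             # SD of R-vs-L midpoint offset
    lr_independent_fraction: float = 0.0         # extra unpaired events per side
    lfp_fs: float = 1000.0
    noise_sd: float = 0.05                       # mV background
    # replay content
    replay_fraction: float = 0.8                 # fraction of ripples carrying replay
    replay_speed: float = 8.0                    # m/s along the track
    replay_direction_mix: float = 0.5            # fraction forward (rightward template)
    replay_spike_jitter_ms: float = 5.0
    replay_cell_scope: str = "both"              # "both" | "event_side"

    def __post_init__(self) -> None:
        positive = [
            "track_length", "field_width", "peak_rate", "run_speed", "position_fs",
            "rest_duration", "ripple_rate", "ripple_band_freq", "ripple_duration_ms",
            "ripple_amplitude_sd", "lfp_fs", "noise_sd", "replay_speed",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be strictly positive")
        for name in ["baseline_rate", "rest_baseline_rate", "lr_ripple_jitter_ms",
                     "assembly_jitter_ms", "replay_spike_jitter_ms",
                     "lr_independent_fraction"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        if self.n_laps < 1:
            raise ConfigError("n_laps: must be >= 1")
        if self.n_units_left < 0 or self.n_units_right < 0:
            raise ConfigError("n_units_left/n_units_right: must be non-negative")
        if not (0.0 <= self.replay_fraction <= 1.0):
            raise ConfigError("replay_fraction: must lie in [0, 1]")
        if not (0.0 <= self.replay_direction_mix <= 1.0):
            raise ConfigError("replay_direction_mix: must lie in [0, 1]")
        if self.assembly_mode not in ("bilateral", "unilateral"):
            raise ConfigError("assembly_mode: must be 'bilateral' or 'unilateral'")
        if self.replay_cell_scope not in ("both", "event_side"):
            raise ConfigError("replay_cell_scope: must be 'both' or 'event_side'")
        if self.field_centers is not None:
            fc = np.asarray(self.field_centers, dtype=float)
            if fc.shape != (self.n_units, 2):
                raise ConfigError("field_centers: must have shape (n_units, 2)")
            if fc.min() < 0 or fc.max() > self.track_length:
                raise ConfigError("field_centers: must lie on the track")
            self.field_centers = fc

    @property
    def n_units(self) -> int:
        return self.n_units_left + self.n_units_right

    def hemisphere_of(self, unit_id: int) -> str:
        return "L" if unit_id < self.n_units_left else "R"


_REFERENCE_DEFAULTS = dict(
    assembly_bin_ms=25.0,
    n_spatial_bins=100,
    smoothing_sd_cm=5.0,
    movement_velocity=5.0,
    min_total_spikes=75,
    min_movement_spikes=75,
    max_isi_violation=0.005,
    isi_threshold_ms=2.0,
    ripple_band=(90.0, 250.0),
    ripple_peak_sd=5.0,
    ripple_edge_sd=2.0,
    ripple_merge_ms=50.0,
    immobility_velocity=2.0,
    tau=0.020,
    candidate_min_ms=50.0,
    candidate_max_ms=300.0,
    min_cells=5,
    n_shuffles=1000,
    alpha=0.05,
    strength_threshold=5.0,
    min_reactivation_rate=0.01,
)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: synthetic-session block + stage constants."""

    synth: SimulationConfig = dc_field(default_factory=SimulationConfig)
    seed: int = 0
    assembly_bin_ms: float = 25.0
    n_spatial_bins: int = 100
    smoothing_sd_cm: float = 5.0
    movement_velocity: float = 5.0      # cm/s gate for place-field analyses
    min_total_spikes: int = 75
    min_movement_spikes: int = 75
    max_isi_violation: float = 0.005    # fraction of ISIs < isi_threshold_ms
    isi_threshold_ms: float = 2.0
    ripple_band: tuple = (90.0, 250.0)
    ripple_peak_sd: float = 5.0
    ripple_edge_sd: float = 2.0
    ripple_merge_ms: float = 50.0
    immobility_velocity: float = 2.0    # cm/s gate for ripple detection
    tau: float = 0.020                  # s, decoding bin
    candidate_min_ms: float = 50.0
    candidate_max_ms: float = 300.0
    min_cells: int = 5
    n_shuffles: int = 1000
    alpha: float = 0.05
    strength_threshold: float = 5.0
    min_reactivation_rate: float = 0.01
    ica_restarts: int = 20

    def non_default(self) -> dict:
        """Stage parameters that differ from the reference defaults (for the manifest)."""
        out = {}
        for name, default in _REFERENCE_DEFAULTS.items():
            if tuple(np.atleast_1d(getattr(self, name))) != tuple(np.atleast_1d(default)):
                out[name] = getattr(self, name)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        synth = d.pop("synth")
        if isinstance(synth.get("field_centers"), np.ndarray):
            synth["field_centers"] = synth["field_centers"].tolist()
        if synth.get("assemblies") is not None:
            synth["assemblies"] = [dataclasses.asdict(a) if dataclasses.is_dataclass(a) else dict(a)
                                   for a in synth["assemblies"]]
        d["synth"] = synth
        d["ripple_band"] = list(d["ripple_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = dict(d.pop("synth", {}))
        if synth.get("assemblies") is not None:
            synth["assemblies"] = [AssemblySpec(**a) for a in synth["assemblies"]]
        if synth.get("field_centers") is not None:
            synth["field_centers"] = np.asarray(synth["field_centers"], dtype=float)
        if "ripple_band" in d:
            d["ripple_band"] = tuple(d["ripple_band"])
        return cls(synth=SimulationConfig(**synth), **d)
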