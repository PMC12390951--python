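"""Configuration objects for the preprocessing and statistics stages.

Every numeric default either restates a protocol/analysis constant of the
study design (band edges, artifact thresholds, epoch window, trial-rejection
limits, permutation counts) or is an explicitly documented package choice
(DPF values, filter order, extinction table).  All of them are plain dataclass
fields so a run configuration round-trips losslessly through YAML/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Any

import numpy as np
import yaml

#: Acquisition sampling rate of the frequency-domain NIRS instrument (Hz).
SAMPLING_RATE_HZ = 10.1215

#: Acquisition wavelengths (nm).
WAVELENGTHS_NM = (690, 830)


def load_extinction_table() -> dict:
    """Pinned molar extinction coefficients (cm^-1 M^-1) for HbO/HbR."""
    with resources.files("neorhythm.data").joinpath(
        "extinction_coefficients.json"
    ).open() as fh:
        return json.load(fh)


def extinction_matrix(table: dict | None = None) -> np.ndarray:
    """2x2 matrix E with E[i, :] = (eps_HbO, eps_HbR) at wavelength i.

    Row order follows :data:`WAVELENGTHS_NM`. Units cm^-1 M^-1.
    """
    table = table or load_extinction_table()
    return np.array(
        [[table["hbo"][str(w)], table["hbr"][str(w)]] for w in WAVELENGTHS_NM],
        dtype=float,
    )


@dataclass
class PreprocessConfig:
    """Parameters of the signal chain from raw intensity to condition averages.

    band_hz
        Band-pass edges for the optical-density filter, Hz.
    dpf
        Differential pathlength factor per wavelength (age-adapted neonatal
        values; dimensionless).
    artifact_abs_threshold
        Motion threshold on |dHbO| x separation, Molar x mm.
    artifact_window_s
        Total width of the window masked around each exceedance, s.
    artifact_channel_count
        If more than this many channels flag the same sample, the sample is
        masked on every channel.
    z_reject
        Trial rejection: any within-trial |z| above this rejects the trial.
    gradient_step_s / gradient_threshold
        Trial rejection: |z(t + step) - z(t)| above the threshold rejects.
    auc_min
        Trial rejection: signed integral of z-scored HbO over the post-onset
        window (z*s) below this rejects.
    max_rejected_fraction
        Channel x condition exclusion: excluded iff the rejected-trial
        fraction strictly exceeds this.
    epoch_s
        Epoch window relative to stimulus onset, s (half-open).
    min_participants_per_channel
        Group analyses drop channels with fewer contributors.
    downsample_hz
        Rate of the analysis-stage epochs (1-s bin averages).
    snr_cv_max
        Automated channel screen: coefficient of variation of raw intensity
        above this marks the channel as bad (stands in for visual screening).
    """

    band_hz: tuple[float, float] = (0.03, 0.5)
    filter_order: int = 3
    dpf: dict[int, float] = field(default_factory=lambda: {690: 5.4, 830: 4.7})
    artifact_abs_threshold: float = 0.01
    artifact_window_s: float = 3.0
    artifact_channel_count: int = 10
    z_reject: float = 3.0
    gradient_step_s: float = 0.4
    gradient_threshold: float = 1.5
    auc_min: float = 10.0
    auc_mode: str = "abs"  # "abs": integral of |z|; "signed": plain integral
    max_rejected_fraction: float = 0.80
    epoch_s: tuple[float, float] = (-5.0, 25.0)
    min_participants_per_channel: int = 4
    downsample_hz: float = 1.0
    snr_cv_max: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi < SAMPLING_RATE_HZ / 2):
            raise ValueError(f"band_hz must satisfy 0 < lo < hi < fs/2, got {self.band_hz}")
        for name in ("artifact_abs_threshold", "artifact_window_s", "z_reject",
                     "gradient_step_s", "gradient_threshold", "auc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.max_rejected_fraction <= 1:
            raise ValueError("max_rejected_fraction must lie in (0, 1]")


@dataclass
class ClusterConfig:
    """Parameters of the cluster-based permutation tests."""

    n_permutations: int = 5000
    alpha_cluster_forming: float = 0.05
    alpha_final: float = 0.05
    min_neighbors: int = 1
    min_cluster_size: int = 1
    neighbor_radius_mm: float | None = None  # None: smallest radius giving >=2 neighbors
    exhaustive_max_n: int = 12

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.alpha_cluster_forming, self.alpha_final):
            if not 0 < a < 1:
                raise ValueError("alpha values must lie in (0, 1)")


@dataclass
class SynthConfig:
    """Cohort-simulation parameters (amplitudes in uM, rates per session)."""

    n_participants: int = 11
    hbo_amplitude_um: float = 1.0
    effect_fraction: float = 0.6          # rhythmic amplitude = base * (1 + effect)
    hbr_ratio: float = 1.0 / 3.0
    hrf_peak_s: float = 10.0
    subject_sigma_log: float = 0.3        # lognormal inter-participant scale
    cardiac_um: float = 0.4
    cardiac_hz: float = 2.5
    respiratory_um: float = 0.4
    respiratory_hz: float = 1.0
    mayer_um: float = 0.5
    mayer_hz: float = 0.1
    white_um: float = 0.3
    drift_um: float = 0.3
    n_spikes: int = 2
    n_shifts: int = 1
    spike_factor_range: tuple[float, float] = (2.0, 10.0)
    spike_duration_s: tuple[float, float] = (0.5, 2.0)


@dataclass
class StimulusConfig:
    """Stimulus-design constants (time units, tempi, pitches)."""

    tempi_ms: tuple[int, ...] = (140, 185, 230)
    pitches_hz: tuple[int, ...] = (440, 880)
    sample_rate: int = 44100
    tone_tail_s: float = 0.5
    isi_range_s: tuple[float, float] = (25.0, 35.0)
    n_blocks: int = 60


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    seed: int = 0
    outdir: str = "neorhythm_run"
    write_wav: bool = True
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sub = {
            "stimulus": StimulusConfig,
            "synth": SynthConfig,
            "preprocess": PreprocessConfig,
            "cluster": ClusterConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in sub:
                val = dict(val)
                kwargs[key] = sub[key](**{k: _tuplify(v) for k, v in val.items()})
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
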