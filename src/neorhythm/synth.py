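"""Synthetic neonatal fNIRS session generator.

Produces dual-wavelength (690/830 nm) intensity time series at the
instrument rate of 10.1215 Hz over the bilateral montage, by running the
hemodynamic model *forward*: block-design HbO/HbR responses (gamma-shaped
response peaking near 10 s, HbR as a scaled negative copy of HbO) plus
physiological noise (cardiac, respiratory, Mayer waves, 1/f-like drift,
white noise) and seeded motion artifacts (spikes and baseline steps), then
the modified Beer-Lambert law maps chromophore changes to optical density
and intensity (I = I0 * 10^-OD, I0 = 1 in arbitrary units).

Because the forward model uses the same extinction table and DPF values as
the preprocessing stage, a noise-free session round-trips exactly through
the inverse chain — the basis of the pipeline's recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .config import (
    SAMPLING_RATE_HZ,
    WAVELENGTHS_NM,
    PreprocessConfig,
    StimulusConfig,
    SynthConfig,
    extinction_matrix,
)
from .montage import Montage, build_montage
from .stimuli import BlockProtocol, build_protocol, render_stimulus_sets

CONDITIONS = ("rhythmic", "arrhythmic")

#: default placement of the condition effect (rhythmic > arrhythmic),
#: emulating a sensorimotor/premotor beat-sensitivity topography
DEFAULT_EFFECT_ROIS = (("right", "sensorimotor"), ("left", "premotor"))


def neonatal_hrf(
    fs: float = SAMPLING_RATE_HZ,
    amplitude: float = 1.0,
    peak_s: float = 10.0,
    duration_s: float = 25.0,
    hbr_ratio: float = 1.0 / 3.0,
    shape: float = 9.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled HbO/HbR impulse-response pair.

    A single gamma kernel with its mode at ``peak_s``, scaled so the HbO
    peak equals ``amplitude``; HbR is the negative copy scaled by
    ``hbr_ratio``.  With the default shape the kernel has decayed to <2 % of
    its peak by 25 s.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    scale = peak_s / (shape - 1)
    h = spst.gamma.pdf(t, a=shape, scale=scale)
    peak = h.max()
    hbo = amplitude * (h / peak if peak > 0 else h)
    return hbo, -hbr_ratio * hbo


@dataclass
class GroundTruth:
    """Injected per-channel response amplitudes and artifact bookkeeping."""

    hbo_amplitude_um: np.ndarray  # (n_channels, 2) columns follow CONDITIONS
    hbr_ratio: float = 1.0 / 3.0
    hrf_peak_s: float = 10.0
    effect_channels: np.ndarray | None = None  # bool (n_channels,)

    def __post_init__(self) -> None:
        self.hbo_amplitude_um = np.asarray(self.hbo_amplitude_um, dtype=float)
        if self.hbo_amplitude_um.ndim != 2 or self.hbo_amplitude_um.shape[1] != 2:
            raise ValueError("hbo_amplitude_um must have shape (n_channels, 2)")


def make_ground_truth(
    montage: Montage,
    cfg: SynthConfig,
    effect: str = "default",
    subject_scale: float = 1.0,
) -> GroundTruth:
    """Amplitude map for one participant.

    ``effect='default'`` raises the rhythmic amplitude by ``effect_fraction``
    on right-sensorimotor and left-premotor channels; ``effect='null'`` makes
    the two conditions identical everywhere (auditory responses present, no
    condition difference).
    """
    n = montage.n_channels
    base = cfg.hbo_amplitude_um * subject_scale
    amp = np.full((n, 2), base)
    mask = np.zeros(n, dtype=bool)
    if effect == "default":
        for hemi, roi in DEFAULT_EFFECT_ROIS:
            for ch in montage.channels_of(hemisphere=hemi, region=roi):
                mask[ch.index] = True
        amp[mask, CONDITIONS.index("rhythmic")] = base * (1 + cfg.effect_fraction)
    elif effect != "null":
        raise ValueError("effect must be 'default' or 'null'")
    return GroundTruth(
        hbo_amplitude_um=amp,
        hbr_ratio=cfg.hbr_ratio,
        hrf_peak_s=cfg.hrf_peak_s,
        effect_channels=mask,
    )


@dataclass
class RawSession:
    """One participant's raw recording plus simulation ground truth."""

    intensities: np.ndarray  # (n_channels, n_samples, 2) wavelengths 690/830
    fs: float
    events: BlockProtocol
    montage: Montage
    participant_id: str
    truth: GroundTruth | None = None
    spike_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_channels: list[np.ndarray] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def hb_to_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    montage: Montage,
    config: PreprocessConfig,
) -> np.ndarray:
    """Forward modified Beer-Lambert law: concentration (uM) to OD.

    OD_lambda = (eps_HbO * dHbO + eps_HbR * dHbR) * L_cm * DPF_lambda with
    concentrations in Molar and extinction in cm^-1 M^-1.
    """
    ext = extinction_matrix()  # (2 wavelengths, 2 chromophores)
    conc_m = np.stack([hbo_um, hbr_um], axis=-1) * 1e-6  # (..., n_t, 2)
    sep_cm = montage.separations_mm / 10.0
    dpf = np.array([config.dpf[w] for w in WAVELENGTHS_NM])
    od = np.einsum("ctk,wk->ctw", conc_m, ext)
    od *= sep_cm[:, None, None] * dpf[None, None, :]
    return od


def _block_regressor(
    protocol: BlockProtocol,
    condition: str,
    n_samples: int,
    fs: float,
    hrf: np.ndarray,
) -> np.ndarray:
    """Unit-peak response time course for all blocks of one condition.

    Each block contributes one unit-peak HRF aligned to its onset: the
    neonatal response to these long auditory blocks is non-sustained, peaking
    near 10 s and returning to baseline within the epoch regardless of block
    duration, so the block response is the impulse response itself (a
    duration-long boxcar drive would instead keep rising for the whole
    stimulus).  A channel amplitude of A uM therefore yields block responses
    peaking at exactly A uM.
    """
    stick = np.zeros(n_samples)
    for b in protocol.blocks:
        if b.condition != condition:
            continue
        k0 = int(round(b.onset_s * fs))
        if k0 < n_samples:
            stick[k0] = 1.0
    return sps.fftconvolve(stick, hrf)[:n_samples]


def simulate_session(
    montage: Montage,
    truth: GroundTruth,
    protocol: BlockProtocol,
    noise_cfg: SynthConfig | None = None,
    seed: int = 0,
    participant_id: str = "sub-01",
    preprocess_config: PreprocessConfig | None = None,
    noise: bool = True,
    artifacts: bool = True,
) -> RawSession:
    """Forward-simulate one dual-wavelength session."""
    cfg = noise_cfg or SynthConfig()
    pcfg = preprocess_config or PreprocessConfig()
    for name in ("cardiac_um", "respiratory_um", "mayer_um", "white_um", "drift_um"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed)
    fs = SAMPLING_RATE_HZ
    n_t = int(round((protocol.total_duration_s + 30.0) * fs))
    n_ch = montage.n_channels
    hrf, _ = neonatal_hrf(fs=fs, amplitude=1.0, peak_s=truth.hrf_peak_s)

    hbo = np.zeros((n_ch, n_t))
    for ci, cond in enumerate(CONDITIONS):
        reg = _block_regressor(protocol, cond, n_t, fs, hrf)
        hbo += truth.hbo_amplitude_um[:, ci : ci + 1] * reg[None, :]

    if noise:
        t = (np.arange(n_t) / fs).astype(np.float32)
        for amp, freq in (
            (cfg.cardiac_um, cfg.cardiac_hz),
            (cfg.respiratory_um, cfg.respiratory_hz),
            (cfg.mayer_um, cfg.mayer_hz),
        ):
            f = (freq * rng.uniform(0.95, 1.05, n_ch)).astype(np.float32)
            phase = rng.uniform(0, 2 * np.pi, n_ch).astype(np.float32)
            hbo += amp * np.sin(2 * np.pi * f[:, None] * t[None, :] + phase[:, None])
        hbo += cfg.white_um * rng.standard_normal((n_ch, n_t))
        drift = np.cumsum(rng.standard_normal((n_ch, n_t)), axis=1)
        drift -= drift.mean(axis=1, keepdims=True)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        hbo += cfg.drift_um * drift / sd

    hbr = -truth.hbr_ratio * hbo

    spike_times: list[float] = []
    spike_channels: list[np.ndarray] = []
    if artifacts:
        sep_mm = montage.separations_mm
        thresh_um = pcfg.artifact_abs_threshold / (sep_mm * 1e-6)  # M*mm -> uM
        for _ in range(cfg.n_spikes):
            t0 = rng.uniform(30.0, n_t / fs - 30.0)
            dur = rng.uniform(*cfg.spike_duration_s)
            factor = rng.uniform(*cfg.spike_factor_range)
            group = rng.choice(n_ch, size=rng.integers(3, 9), replace=False)
            k0 = int(round(t0 * fs))
            k1 = min(k0 + int(round(dur * fs)), n_t)
            bump = np.sin(np.linspace(0, np.pi, k1 - k0))
            sign = rng.choice([-1.0, 1.0])
            for ch in group:
                hbo[ch, k0:k1] += sign * factor * thresh_um[ch] * bump
                hbr[ch, k0:k1] += sign * factor * thresh_um[ch] * bump * 0.5
            spike_times.append(t0 + dur / 2)
            spike_channels.append(np.sort(group))
        for _ in range(cfg.n_shifts):
            t0 = rng.uniform(30.0, n_t / fs - 30.0)
            group = rng.choice(n_ch, size=rng.integers(3, 9), replace=False)
            k0 = int(round(t0 * fs))
            step = rng.uniform(0.1, 0.4)
            for ch in group:
                hbo[ch, k0:] += step * thresh_um[ch] * rng.choice([-1.0, 1.0])

    od = hb_to_od(hbo, hbr, montage, pcfg)
    intensities = 10.0 ** (-od)  # I0 = 1 (arbitrary units cancel in OD)
    return RawSession(
        intensities=intensities,
        fs=fs,
        events=protocol,
        montage=montage,
        participant_id=participant_id,
        truth=truth,
        spike_times_s=np.array(spike_times),
        spike_channels=spike_channels,
    )


def simulate_cohort(
    n_participants: int = 11,
    effect: str = "default",
    seed: int = 0,
    cfg: SynthConfig | None = None,
    montage: Montage | None = None,
    stimulus_config: StimulusConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> list[RawSession]:
    """Simulate a cohort; each participant gets a fresh constrained block
    order of the same 60 stimuli and a lognormal overall amplitude scale."""
    cfg = cfg or SynthConfig()
    montage = montage or build_montage()
    scfg = stimulus_config or StimulusConfig()
    root = np.random.SeedSequence(seed)
    stim_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
    rhythmic, arrhythmic = render_stimulus_sets(
        seed=stim_seed, config=scfg, synthesize_audio=False
    )
    stimuli = rhythmic + arrhythmic
    sessions = []
    for p, ss in enumerate(root.spawn(n_participants + 1)[1:]):
        s1, s2, s3 = (int(x % 2**31) for x in ss.generate_state(3))
        protocol = build_protocol(stimuli, seed=s1, config=scfg)
        scale = float(np.exp(np.random.default_rng(s2).normal(0, cfg.subject_sigma_log)))
        truth = make_ground_truth(montage, cfg, effect=effect, subject_scale=scale)
        sessions.append(
            simulate_session(
                montage,
                truth,
                protocol,
                noise_cfg=cfg,
                seed=s3,
                participant_id=f"sub-{p + 1:02d}",
                preprocess_config=preprocess_config,
            )
        )
    return sessions
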