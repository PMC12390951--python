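"""Signal chain from raw dual-wavelength intensities to condition averages.

Stages, in order: intensity -> optical density (relative to the channel's
temporal mean), zero-phase band-pass (0.03-0.5 Hz), modified Beer-Lambert
inversion to HbO/HbR concentration changes (uM), motion-artifact masking,
whole-recording z-scoring per channel, epoching (-5 to +25 s around each
block onset, linear detrend then baseline correction), the four
trial-rejection rules, channel-per-condition exclusion at >80 % rejected
trials, averaging over tempi and pitches, and 1 Hz downsampling by 1-s bin
means.  Group-level channel retention requires at least 4 contributing
participants.

The chain is deterministic: identical input and configuration give
bit-identical condition averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .config import SAMPLING_RATE_HZ, WAVELENGTHS_NM, PreprocessConfig, extinction_matrix
from .montage import Montage
from .synth import RawSession

REJECTION_CODES = ("kept", "z_exceeded", "gradient", "auc", "artifact_overlap")
CONDITIONS = ("rhythmic", "arrhythmic")


@dataclass
class HbSeries:
    """Channel x time chromophore concentration changes with artifact mask."""

    hbo: np.ndarray  # (n_channels, n_samples), uM (or z after z-scoring)
    hbr: np.ndarray
    fs: float
    separations_mm: np.ndarray
    mask: np.ndarray | None = None  # True = artifact sample

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.hbo.shape, dtype=bool)
        if self.mask.shape != self.hbo.shape:
            raise ValueError("mask shape must match the data")


def intensity_to_od(raw: RawSession) -> np.ndarray:
    """Optical density relative to each channel's temporal mean intensity."""
    inten = raw.intensities
    bad = inten <= 0
    if bad.any():
        ch, t, w = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity at channel {ch}, sample {t}, wavelength "
            f"{WAVELENGTHS_NM[w]} nm"
        )
    ref = inten.mean(axis=1, keepdims=True)
    return -np.log10(inten / ref)


def bandpass(
    od: np.ndarray,
    fs: float = SAMPLING_RATE_HZ,
    band: tuple[float, float] = (0.03, 0.5),
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 1)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, od, axis=1)


def od_to_hb(od: np.ndarray, montage: Montage, config: PreprocessConfig) -> HbSeries:
    """Invert the modified Beer-Lambert law to HbO/HbR changes in uM."""
    ext = extinction_matrix()
    if abs(np.linalg.det(ext)) < 1e-12:
        raise ValueError("extinction matrix is singular; check the coefficient table")
    inv = np.linalg.inv(ext)
    dpf = np.array([config.dpf[w] for w in WAVELENGTHS_NM])
    sep_cm = montage.separations_mm / 10.0
    scaled = od / (sep_cm[:, None, None] * dpf[None, None, :])
    conc_m = np.einsum("ctw,kw->ctk", scaled, inv)
    conc_um = conc_m * 1e6
    return HbSeries(
        hbo=conc_um[..., 0],
        hbr=conc_um[..., 1],
        fs=SAMPLING_RATE_HZ,
        separations_mm=montage.separations_mm.copy(),
    )


def detect_motion(hb: HbSeries, config: PreprocessConfig) -> np.ndarray:
    """Motion-artifact mask from the Molar x mm exceedance rule.

    The detection statistic per channel is |dHbO| (Molar) times the
    source-detector separation (mm).  A window of ``artifact_window_s``
    centered on every exceedance is masked on that channel; samples flagged
    on more than ``artifact_channel_count`` channels are masked everywhere.
    """
    stat = np.abs(hb.hbo) * 1e-6 * hb.separations_mm[:, None]
    exceed = stat > config.artifact_abs_threshold
    half = int(round(config.artifact_window_s / 2 * hb.fs))
    size = 2 * half + 1
    grown = ndimage.maximum_filter1d(exceed.astype(np.uint8), size=size, axis=1) > 0
    common = exceed.sum(axis=0) > config.artifact_channel_count
    if common.any():
        spread = ndimage.maximum_filter1d(common.astype(np.uint8), size=size) > 0
        grown |= spread[None, :]
    return grown


def zscore_channels(hb: HbSeries) -> HbSeries:
    """Standardize each channel over its unmasked samples (mean 0, SD 1)."""
    keep = ~hb.mask
    n = keep.sum(axis=1, keepdims=True).astype(float)
    n[n == 0] = np.nan

    def _z(x: np.ndarray) -> np.ndarray:
        xk = np.where(keep, x, 0.0)
        mu = xk.sum(axis=1, keepdims=True) / n
        var = np.where(keep, (x - mu) ** 2, 0.0).sum(axis=1, keepdims=True) / n
        sd = np.sqrt(var)
        mu = np.nan_to_num(mu)
        sd = np.nan_to_num(sd)
        sd[sd <= 0] = 1.0
        return (x - mu) / sd

    return HbSeries(
        hbo=_z(hb.hbo),
        hbr=_z(hb.hbr),
        fs=hb.fs,
        separations_mm=hb.separations_mm,
        mask=hb.mask.copy(),
    )


@dataclass
class EpochSet:
    """Per-trial HbO epochs with trial metadata and rejection codes."""

    hbo: np.ndarray  # (n_trials, n_channels, n_samples)
    fs: float
    times_s: np.ndarray  # (n_samples,), relative to stimulus onset
    condition: np.ndarray  # (n_trials,), str
    tempo_ms: np.ndarray
    pitch_hz: np.ndarray
    rejection: np.ndarray  # (n_trials, n_channels), str codes

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[0]


def epoch_samples(config: PreprocessConfig, fs: float = SAMPLING_RATE_HZ) -> tuple[int, int]:
    """(pre-onset samples, total epoch samples) for the configured window."""
    pre = int(round(-config.epoch_s[0] * fs))
    total = int(round((config.epoch_s[1] - config.epoch_s[0]) * fs))
    return pre, total


def epoch_and_clean(hb: HbSeries, events, config: PreprocessConfig) -> EpochSet:
    """Cut epochs, detrend/baseline-correct, and apply the rejection rules.

    Rules, evaluated in order on each detrended, baseline-corrected trial and
    channel (the first triggered rule is recorded):

    1. ``z_exceeded``: any within-trial |z| > ``z_reject``;
    2. ``gradient``: any |z(t + step) - z(t)| > ``gradient_threshold``;
    3. ``auc``: area under the post-onset curve (z*s; integral of |z| in the
       default ``abs`` mode, plain integral in ``signed`` mode) < ``auc_min``;
    4. ``artifact_overlap``: the trial overlaps the motion-artifact mask.
    """
    fs = hb.fs
    pre, total = epoch_samples(config, fs)
    n_ch, n_t = hb.hbo.shape
    step = int(round(config.gradient_step_s * fs))
    epochs, conds, tempos, pitches, rejections = [], [], [], [], []
    for b in events.blocks:
        k0 = int(round(b.onset_s * fs)) - pre
        if k0 < 0 or k0 + total > n_t:
            warnings.warn(
                f"block {b.index} at {b.onset_s:.1f}s lies outside the recording; skipped"
            )
            continue
        seg = hb.hbo[:, k0 : k0 + total].copy()
        seg = sps.detrend(seg, axis=1, type="linear")
        seg -= seg[:, :pre].mean(axis=1, keepdims=True)
        mseg = hb.mask[:, k0 : k0 + total]
        codes = np.full(n_ch, "kept", dtype=object)
        z_bad = (np.abs(seg) > config.z_reject).any(axis=1)
        grad_bad = (
            np.abs(seg[:, step:] - seg[:, :-step]) > config.gradient_threshold
        ).any(axis=1)
        post = np.abs(seg[:, pre:]) if config.auc_mode == "abs" else seg[:, pre:]
        auc = post.sum(axis=1) / fs
        auc_bad = auc < config.auc_min
        art_bad = mseg.any(axis=1)
        codes[art_bad] = "artifact_overlap"
        codes[auc_bad] = "auc"
        codes[grad_bad] = "gradient"
        codes[z_bad] = "z_exceeded"
        epochs.append(seg)
        conds.append(b.condition)
        tempos.append(b.tempo_unit_ms)
        pitches.append(b.pitch_hz)
        rejections.append(codes)
    times = (np.arange(total) - pre) / fs
    return EpochSet(
        hbo=np.stack(epochs),
        fs=fs,
        times_s=times,
        condition=np.array(conds),
        tempo_ms=np.array(tempos),
        pitch_hz=np.array(pitches),
        rejection=np.stack(rejections),
    )


@dataclass
class ConditionAverage:
    """Per-participant condition-averaged HbO at 1 Hz."""

    participant_id: str
    data: np.ndarray  # (n_channels, 2 conditions, n_bins); NaN where excluded
    counts: np.ndarray  # contributing trials, (n_channels, 2)
    excluded: np.ndarray  # bool (n_channels, 2)
    times_s: np.ndarray  # 1 Hz bin left edges relative to onset
    rejection_summary: dict[str, int] = field(default_factory=dict)


def downsample_epoch(x: np.ndarray, fs: float, out_hz: float, t0_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Average consecutive 1/out_hz-second bins along the last axis."""
    width = fs / out_hz
    n_bins = int(np.floor(x.shape[-1] / width))
    edges = np.round(np.arange(n_bins + 1) * width).astype(int)
    out = np.stack(
        [x[..., edges[k] : edges[k + 1]].mean(axis=-1) for k in range(n_bins)], axis=-1
    )
    times = t0_s + np.arange(n_bins) / out_hz
    return out, times


def exclude_and_average(
    epochs: EpochSet,
    config: PreprocessConfig,
    participant_id: str = "sub-01",
) -> ConditionAverage:
    """Apply the >80 % rejection rule, average kept trials, downsample."""
    n_ch = epochs.hbo.shape[1]
    kept = epochs.rejection == "kept"
    data = np.full((n_ch, len(CONDITIONS), epochs.hbo.shape[2]), np.nan)
    counts = np.zeros((n_ch, len(CONDITIONS)), dtype=int)
    excluded = np.zeros((n_ch, len(CONDITIONS)), dtype=bool)
    for ci, cond in enumerate(CONDITIONS):
        sel = epochs.condition == cond
        n_trials = int(sel.sum())
        if n_trials == 0:
            excluded[:, ci] = True
            continue
        k = kept[sel, :]  # (trials, channels)
        n_kept = k.sum(axis=0)
        excl = (1 - n_kept / n_trials) > config.max_rejected_fraction
        excluded[:, ci] = excl
        counts[:, ci] = np.where(excl, 0, n_kept)
        masked = np.where(k[:, :, None], epochs.hbo[sel], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(masked, axis=0)
        data[~excl, ci] = means[~excl]
    ds, times = downsample_epoch(data, epochs.fs, config.downsample_hz, config.epoch_s[0])
    codes, ncodes = np.unique(epochs.rejection, return_counts=True)
    return ConditionAverage(
        participant_id=participant_id,
        data=ds,
        counts=counts,
        excluded=excluded,
        times_s=times,
        rejection_summary=dict(zip(codes.tolist(), ncodes.tolist())),
    )


def screen_channels(raw: RawSession, config: PreprocessConfig) -> np.ndarray:
    """Automated SNR screen: channels whose raw-intensity coefficient of
    variation (worst wavelength) exceeds the limit are marked bad."""
    inten = raw.intensities[:, ::5, :]  # strided subsample; CV is a coarse screen
    cv = inten.std(axis=1) / inten.mean(axis=1)
    return cv.max(axis=-1) > config.snr_cv_max


def preprocess_session(
    raw: RawSession,
    config: PreprocessConfig | None = None,
) -> tuple[ConditionAverage, EpochSet]:
    """Run the full chain on one session."""
    config = config or PreprocessConfig()
    od = intensity_to_od(raw)
    od = bandpass(od, fs=raw.fs, band=config.band_hz, order=config.filter_order)
    hb = od_to_hb(od, raw.montage, config)
    hb.mask = detect_motion(hb, config)
    bad = screen_channels(raw, config)
    z = zscore_channels(hb)
    epochs = epoch_and_clean(z, raw.events, config)
    avg = exclude_and_average(epochs, config, participant_id=raw.participant_id)
    if bad.any():
        avg.excluded[bad, :] = True
        avg.data[bad, :, :] = np.nan
    return avg, epochs


def stack_cohort(
    averages: list[ConditionAverage],
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-participant averages and apply group channel retention.

    Returns ``(stack, retained, times)`` where ``stack`` has shape
    (n_participants, n_channels, 2, n_bins) with NaN at excluded cells, and
    ``retained`` marks channels with at least ``min_participants_per_channel``
    participants contributing to both conditions.
    """
    config = config or PreprocessConfig()
    stack = np.stack([a.data for a in averages])
    contributing = np.stack([~a.excluded.any(axis=1) for a in averages])
    retained = contributing.sum(axis=0) >= config.min_participants_per_channel
    return stack, retained, averages[0].times_s
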