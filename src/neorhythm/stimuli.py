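"""Auditory rhythm stimulus design.

Beat-based sequences are built from four onset-to-onset interval categories,
expressed in integer time units where the fastest interval is 1 unit and the
others are 2, 3 and 4 units.  Each base sequence is rendered at three tempi
(1 unit = 140, 185 or 230 ms) and two pitches (440/880 Hz), giving 30
rhythmic stimuli; every base also has a matched arrhythmic counterpart in
which, per interval category, a random third of the intervals is shortened by
20/25/33 %, a third kept, a third lengthened by 20/25/33 %, after which all
intervals are shuffled.  The transform destroys beat periodicity while
preserving interval count and, in expectation, total duration and envelope
energy; :func:`validate_stimulus_sets` checks the latter two with paired
t-tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft
from scipy import signal as sps
from scipy import stats as spst

from .config import StimulusConfig

INTERVAL_CATEGORIES = (1, 2, 3, 4)
PERTURBATION_FACTORS = (0.20, 0.25, 0.33)
#: total time units allowed for a base sequence so that every tempo rendering
#: (including the 0.5 s tone tail) lands in the 13-24 s duration window
TOTAL_UNITS_RANGE = (94, 102)
N_INTERVALS_RANGE = (42, 45)
BEAT_UNITS = 2
MIN_BEAT_ALIGNMENT = 0.80

#: rendering analysis constants for the envelope spectrum
ENVELOPE_FS = 100.0
ENVELOPE_NFFT = 4096
ENVELOPE_BAND_HZ = (0.0, 10.0)


class PairingError(ValueError):
    """Raised when rhythmic/arrhythmic stimulus lists cannot be paired."""


@dataclass(frozen=True)
class RhythmSequence:
    """A beat-based sequence of integer inter-onset intervals (time units)."""

    base_id: int
    intervals: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(i in INTERVAL_CATEGORIES for i in self.intervals):
            raise ValueError("intervals must be drawn from {1,2,3,4} time units")
        lo, hi = N_INTERVALS_RANGE
        if not lo <= len(self.intervals) <= hi:
            raise ValueError(f"need {lo}-{hi} intervals, got {len(self.intervals)}")
        lo, hi = TOTAL_UNITS_RANGE
        if not lo <= sum(self.intervals) <= hi:
            raise ValueError(
                f"total units {sum(self.intervals)} outside [{lo}, {hi}]"
            )

    @property
    def n_tones(self) -> int:
        return len(self.intervals) + 1

    @property
    def total_units(self) -> int:
        return int(sum(self.intervals))

    @property
    def onsets_units(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.intervals, dtype=float)])


@dataclass(frozen=True)
class ArrhythmicSequence:
    """Shuffled, per-category-perturbed counterpart of a rhythmic sequence.

    ``perturbation_log`` records, in final (shuffled) order, the source
    category, the label (``shortened``/``same``/``lengthened``) and the factor
    applied to each interval.
    """

    source_base_id: int
    intervals: tuple[float, ...]
    perturbation_log: tuple[tuple[int, str, float | None], ...]

    @property
    def total_units(self) -> float:
        return float(sum(self.intervals))

    @property
    def onsets_units(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.intervals, dtype=float)])


def beat_alignment(intervals: Sequence[float], beat_units: int = BEAT_UNITS) -> float:
    """Fraction of isochronous grid beats that coincide with a tone onset.

    The grid runs at ``beat_units`` spacing from 0 to the total duration
    (exclusive); an onset counts as on-beat when it matches a grid point to
    within 1e-9 units.
    """
    onsets = np.concatenate([[0.0], np.cumsum(intervals, dtype=float)])
    total = onsets[-1]
    grid = np.arange(0, total - 1e-9, beat_units, dtype=float)
    if grid.size == 0:
        return 1.0
    hit = np.isclose(grid[:, None], onsets[None, :], atol=1e-9).any(axis=1)
    return float(hit.mean())


def compose_rhythmic_bases(seed: int = 0, n_sequences: int = 5) -> list[RhythmSequence]:
    """Generate beat-based base sequences satisfying the design constraints.

    Sequences are assembled from 2-unit beat cells: ``2`` and ``1+1`` keep an
    onset on the beat, while the two-beat cells ``4``, ``3+1`` and ``1+3``
    skip one grid beat each.  Bounding the number of beat-skipping cells keeps
    the on-beat fraction at or above 0.8 by construction; the cell shuffle
    provides the variety between the five bases.
    """
    rng = np.random.default_rng(seed)
    out: list[RhythmSequence] = []
    for base_id in range(1, n_sequences + 1):
        out.append(_compose_one(base_id, rng))
    return out


def _compose_one(base_id: int, rng: np.random.Generator) -> RhythmSequence:
    while True:
        n_beats = int(rng.integers(TOTAL_UNITS_RANGE[0] // 2, TOTAL_UNITS_RANGE[1] // 2 + 1))
        n_intervals = int(rng.integers(N_INTERVALS_RANGE[0], N_INTERVALS_RANGE[1] + 1))
        deficit = n_beats - n_intervals  # = (#"4" cells) - (#"1+1" cells)
        if deficit < 1:
            continue
        c4 = int(rng.integers(deficit, deficit + 4))
        s11 = c4 - deficit
        c3 = int(rng.integers(1, 5))
        s2 = n_beats - 2 * c4 - 2 * c3 - s11
        if s2 < 1:
            continue
        if c4 + c3 > math.floor((1 - MIN_BEAT_ALIGNMENT) * n_beats):
            continue
        cells: list[tuple[int, ...]] = (
            [(4,)] * c4
            + [((3, 1) if rng.random() < 0.5 else (1, 3)) for _ in range(c3)]
            + [(2,)] * s2
            + [(1, 1)] * s11
        )
        rng.shuffle(cells)
        intervals = tuple(i for cell in cells for i in cell)
        seq = RhythmSequence(base_id=base_id, intervals=intervals)
        assert beat_alignment(seq.intervals) >= MIN_BEAT_ALIGNMENT
        return seq


def make_arrhythmic(seq: RhythmSequence, seed: int = 0) -> ArrhythmicSequence:
    """Perturb and shuffle a rhythmic sequence into its arrhythmic control.

    Within each interval category, members are split into shortened / same /
    lengthened thirds (remainder assigned randomly when the category size is
    not divisible by 3), factors drawn uniformly from 20/25/33 %, then the
    full interval list is shuffled uniformly.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[int, str, float | None, float]] = []
    for cat in INTERVAL_CATEGORIES:
        members = [i for i in seq.intervals if i == cat]
        if not members:
            continue
        n = len(members)
        base, rem = divmod(n, 3)
        counts = np.array([base, base, base])
        counts[rng.choice(3, size=rem, replace=False)] += 1
        # shorten/lengthen share one factor multiset so the category's total
        # duration change cancels (up to the +/-1 count remainder), keeping
        # arrhythmic sequence lengths matched to their rhythmic sources
        n_pert = int(max(counts[0], counts[2]))
        factors = rng.choice(PERTURBATION_FACTORS, size=n_pert)
        cat_records: list[tuple[int, str, float | None, float]] = []
        for f in factors[: counts[0]]:
            cat_records.append((cat, "shortened", float(f), cat * (1 - f)))
        cat_records.extend((cat, "same", None, float(cat)) for _ in range(counts[1]))
        for f in factors[: counts[2]]:
            cat_records.append((cat, "lengthened", float(f), cat * (1 + f)))
        records.extend(cat_records)
    order = rng.permutation(len(records))
    records = [records[k] for k in order]
    return ArrhythmicSequence(
        source_base_id=seq.base_id,
        intervals=tuple(r[3] for r in records),
        perturbation_log=tuple((r[0], r[1], r[2]) for r in records),
    )


@dataclass
class RenderedStimulus:
    """A sequence rendered at a tempo and pitch, with onset times and audio."""

    condition: str  # "rhythmic" | "arrhythmic"
    base_id: int
    tempo_unit_ms: int
    pitch_hz: int
    onsets_s: np.ndarray
    duration_s: float
    sample_rate: int
    waveform: np.ndarray | None = None

    @property
    def beat_hz(self) -> float:
        """Frequency of the 2-unit beat at this tempo."""
        return 1000.0 / (BEAT_UNITS * self.tempo_unit_ms)

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.base_id, self.tempo_unit_ms, self.pitch_hz)


def _tone(pitch_hz: float, sample_rate: int, tail_s: float, tau_s: float = 0.060) -> np.ndarray:
    """Percussive tone: 5 ms linear attack, exponential decay (tau = 60 ms)."""
    t = np.arange(int(round(tail_s * sample_rate))) / sample_rate
    env = np.minimum(t / 0.005, 1.0) * np.exp(-t / tau_s)
    return env * np.sin(2 * np.pi * pitch_hz * t)


def render(
    seq: RhythmSequence | ArrhythmicSequence,
    tempo_unit_ms: int,
    pitch_hz: int,
    config: StimulusConfig | None = None,
    synthesize_audio: bool = True,
) -> RenderedStimulus:
    """Render a sequence at one tempo/pitch setting.

    ``synthesize_audio=False`` skips waveform synthesis (onsets and duration
    only) for callers that only need event timing, e.g. protocol simulation.
    """
    config = config or StimulusConfig()
    if tempo_unit_ms not in config.tempi_ms:
        raise ValueError(f"tempo_unit_ms must be one of {config.tempi_ms}")
    if pitch_hz not in config.pitches_hz:
        raise ValueError(f"pitch_hz must be one of {config.pitches_hz}")
    onsets = seq.onsets_units * (tempo_unit_ms / 1000.0)
    duration = float(onsets[-1] + config.tone_tail_s)
    condition = "rhythmic" if isinstance(seq, RhythmSequence) else "arrhythmic"
    base_id = seq.base_id if isinstance(seq, RhythmSequence) else seq.source_base_id
    waveform = None
    if synthesize_audio:
        sr = config.sample_rate
        n = int(round(duration * sr))
        waveform = np.zeros(n)
        # per-tone amplitude (~1 dB) and decay-time (~10 %) variation, as in
        # naturally produced percussive strikes; deterministic per stimulus
        jit = np.random.default_rng(
            zlib.crc32(f"{condition}|{base_id}|{tempo_unit_ms}|{pitch_hz}".encode())
        )
        for onset in onsets:
            gain = 10 ** (jit.normal(0, 1.0) / 20)
            tau = 0.060 * float(np.exp(jit.normal(0, 0.1)))
            tone = gain * _tone(pitch_hz, sr, config.tone_tail_s, tau_s=tau)
            k = int(round(onset * sr))
            seg = tone[: n - k]
            waveform[k : k + seg.size] += seg
        # constant-loudness normalization (stimuli were presented at a fixed
        # comfortable level): scale to a common RMS, with a peak safety cap
        rms = float(np.sqrt(np.mean(waveform**2)))
        if rms > 0:
            waveform *= 0.15 / rms
        peak = np.abs(waveform).max()
        if peak > 0.99:
            waveform *= 0.99 / peak
    return RenderedStimulus(
        condition=condition,
        base_id=base_id,
        tempo_unit_ms=tempo_unit_ms,
        pitch_hz=pitch_hz,
        onsets_s=onsets,
        duration_s=duration,
        sample_rate=config.sample_rate,
        waveform=waveform,
    )


def render_stimulus_sets(
    seed: int = 0,
    config: StimulusConfig | None = None,
    synthesize_audio: bool = True,
    equivalence_alpha: float = 0.05,
    max_attempts: int = 25,
) -> tuple[list[RenderedStimulus], list[RenderedStimulus]]:
    """Full stimulus set: 30 rhythmic and 30 matched arrhythmic renderings.

    The two returned lists are index-aligned on (base, tempo, pitch).  The
    arrhythmic draw is accepted only if the paired duration test (and, when
    audio is synthesized, the 0-10 Hz envelope-power test) does not detect a
    difference at ``equivalence_alpha`` — the same stimulus-validation gate
    the experimental design imposes; otherwise the perturbation is redrawn
    with the next derived seed (deterministic given ``seed``).
    """
    config = config or StimulusConfig()
    rng = np.random.default_rng(seed)
    bases = compose_rhythmic_bases(int(rng.integers(2**31)))
    for _ in range(max_attempts):
        arrs = [make_arrhythmic(b, int(rng.integers(2**31))) for b in bases]
        rhythmic, arrhythmic = [], []
        for b, a in zip(bases, arrs):
            for tempo in config.tempi_ms:
                for pitch in config.pitches_hz:
                    rhythmic.append(render(b, tempo, pitch, config, synthesize_audio))
                    arrhythmic.append(render(a, tempo, pitch, config, synthesize_audio))
        dur_r = np.array([s.duration_s for s in rhythmic])
        dur_a = np.array([s.duration_s for s in arrhythmic])
        if not np.allclose(dur_r - dur_a, 0):
            if spst.ttest_rel(dur_r, dur_a).pvalue <= equivalence_alpha:
                continue
        if synthesize_audio:
            if validate_stimulus_sets(rhythmic, arrhythmic)["p_power"] <= equivalence_alpha:
                continue
        return rhythmic, arrhythmic
    raise RuntimeError(
        f"no duration/power-matched arrhythmic set found in {max_attempts} draws"
    )


@dataclass
class EnvelopeSpectrum:
    """Power spectrum of the Hilbert amplitude envelope on a shared grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    mean_power_0_10: float


def envelope_power(stim: RenderedStimulus) -> EnvelopeSpectrum:
    """Spectrum of the waveform's amplitude envelope.

    The analytic-signal magnitude is decimated to 100 Hz and zero-padded to a
    single 4096-point FFT shared by all stimuli, so spectra of unequal-length
    stimuli live on one frequency grid and the 0-10 Hz average is comparable
    across the set.  Power is |X|^2 normalized by the unpadded envelope
    length, making it invariant to padding and (up to scale) to global gain.
    """
    if stim.waveform is None or stim.waveform.size == 0:
        raise ValueError("stimulus has no waveform; render with synthesize_audio=True")
    w = stim.waveform
    if not np.any(w):
        freqs = np.fft.rfftfreq(ENVELOPE_NFFT, d=1 / ENVELOPE_FS)
        return EnvelopeSpectrum(freqs, np.zeros(freqs.size), 0.0)
    n_fast = int(fft.next_fast_len(w.size))
    env = np.abs(sps.hilbert(w, N=n_fast))[: w.size]
    decim = int(round(stim.sample_rate / ENVELOPE_FS))
    env = sps.resample_poly(env, 1, decim)
    if env.size > ENVELOPE_NFFT:
        raise ValueError("stimulus too long for the fixed envelope FFT grid")
    spec = np.fft.rfft(env, n=ENVELOPE_NFFT)
    power = (np.abs(spec) ** 2) / env.size
    freqs = np.fft.rfftfreq(ENVELOPE_NFFT, d=1 / ENVELOPE_FS)
    band = (freqs >= ENVELOPE_BAND_HZ[0]) & (freqs <= ENVELOPE_BAND_HZ[1])
    return EnvelopeSpectrum(freqs, power, float(power[band].mean()))


def band_power(spec: EnvelopeSpectrum, center_hz: float, half_width_hz: float = 0.1) -> float:
    """Peak envelope power within ``center_hz`` +/- ``half_width_hz``."""
    sel = np.abs(spec.freqs_hz - center_hz) <= half_width_hz
    return float(spec.power[sel].max())


def validate_stimulus_sets(
    rhythmic: Sequence[RenderedStimulus],
    arrhythmic: Sequence[RenderedStimulus],
) -> dict[str, float]:
    """Paired t-tests for duration and 0-10 Hz envelope-power equivalence.

    Pairs are matched on (base, tempo, pitch); a mismatch raises
    :class:`PairingError`.  Returns ``{"p_duration": ..., "p_power": ...,
    "t_duration": ..., "t_power": ...}``.  Zero differences give t = 0, p = 1.
    """
    if len(rhythmic) != len(arrhythmic):
        raise PairingError("stimulus lists differ in length")
    arr_by_key = {s.key: s for s in arrhythmic}
    if len(arr_by_key) != len(arrhythmic):
        raise PairingError("duplicate (base, tempo, pitch) keys in arrhythmic list")
    pairs = []
    for r in rhythmic:
        if r.key not in arr_by_key:
            raise PairingError(f"no arrhythmic match for {r.key}")
        pairs.append((r, arr_by_key[r.key]))

    def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        d = x - y
        if np.allclose(d, 0):
            return 0.0, 1.0
        res = spst.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue)

    dur_r = np.array([r.duration_s for r, _ in pairs])
    dur_a = np.array([a.duration_s for _, a in pairs])
    t_dur, p_dur = _paired_t(dur_r, dur_a)
    pow_r = np.array([envelope_power(r).mean_power_0_10 for r, _ in pairs])
    pow_a = np.array([envelope_power(a).mean_power_0_10 for _, a in pairs])
    t_pow, p_pow = _paired_t(pow_r, pow_a)
    return {
        "t_duration": t_dur,
        "p_duration": p_dur,
        "t_power": t_pow,
        "p_power": p_pow,
    }


@dataclass(frozen=True)
class Block:
    """One protocol block: which stimulus plays, when, and the gap after it."""

    index: int
    condition: str
    base_id: int
    tempo_unit_ms: int
    pitch_hz: int
    onset_s: float
    duration_s: float
    isi_s: float


@dataclass
class BlockProtocol:
    """Ordered 60-block presentation schedule with jittered silent gaps."""

    blocks: list[Block]

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def total_duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s + last.isi_s

    def max_condition_run(self) -> int:
        run = best = 0
        prev = None
        for b in self.blocks:
            run = run + 1 if b.condition == prev else 1
            prev = b.condition
            best = max(best, run)
        return best


def build_protocol(
    stimuli: Sequence[RenderedStimulus],
    seed: int = 0,
    config: StimulusConfig | None = None,
    start_s: float = 15.0,
    max_retries: int = 10_000,
) -> BlockProtocol:
    """Order the 60 stimuli into a constrained random block schedule.

    Constraints: no run of three or more same-condition blocks, and no two
    consecutive blocks from the same base rhythm under a different tempo or
    pitch.  The order is found by seeded rejection sampling — greedy random
    construction (uniform choice among the non-violating remaining stimuli at
    each position) restarted from scratch whenever it dead-ends.  Gaps are
    drawn uniformly from the configured inter-stimulus silence range.
    """
    config = config or StimulusConfig()
    n_r = sum(s.condition == "rhythmic" for s in stimuli)
    n_a = sum(s.condition == "arrhythmic" for s in stimuli)
    if len(stimuli) != config.n_blocks or n_r != n_a or n_r != config.n_blocks // 2:
        raise ValueError(
            f"need {config.n_blocks // 2} + {config.n_blocks // 2} stimuli, "
            f"got {n_r} rhythmic + {n_a} arrhythmic"
        )
    rng = np.random.default_rng(seed)
    order = None
    for _ in range(max_retries):
        cand = _greedy_order(stimuli, rng)
        if cand is not None and _order_ok([stimuli[i] for i in cand]):
            order = cand
            break
    if order is None:
        raise RuntimeError(f"no valid block order found in {max_retries} tries")
    lo, hi = config.isi_range_s
    isis = rng.uniform(lo, hi, size=len(stimuli))
    blocks = []
    t = start_s
    for idx, (i, isi) in enumerate(zip(order, isis)):
        s = stimuli[i]
        blocks.append(
            Block(
                index=idx,
                condition=s.condition,
                base_id=s.base_id,
                tempo_unit_ms=s.tempo_unit_ms,
                pitch_hz=s.pitch_hz,
                onset_s=t,
                duration_s=s.duration_s,
                isi_s=float(isi),
            )
        )
        t += s.duration_s + isi
    return BlockProtocol(blocks=blocks)


def _greedy_order(
    stimuli: Sequence[RenderedStimulus], rng: np.random.Generator
) -> np.ndarray | None:
    remaining = list(range(len(stimuli)))
    order: list[int] = []
    run = 0
    prev: RenderedStimulus | None = None
    while remaining:
        ok = []
        for i in remaining:
            s = stimuli[i]
            if prev is not None:
                if s.condition == prev.condition and run >= 2:
                    continue
                if prev.base_id == s.base_id and (
                    prev.tempo_unit_ms != s.tempo_unit_ms or prev.pitch_hz != s.pitch_hz
                ):
                    continue
            ok.append(i)
        if not ok:
            return None
        i = ok[rng.integers(len(ok))]
        s = stimuli[i]
        run = run + 1 if prev is not None and s.condition == prev.condition else 1
        prev = s
        remaining.remove(i)
        order.append(i)
    return np.array(order)


def _order_ok(seq: list[RenderedStimulus]) -> bool:
    run = 0
    prev_cond = None
    for k, s in enumerate(seq):
        run = run + 1 if s.condition == prev_cond else 1
        prev_cond = s.condition
        if run > 2:
            return False
        if k:
            p = seq[k - 1]
            if p.base_id == s.base_id and (
                p.tempo_unit_ms != s.tempo_unit_ms or p.pitch_hz != s.pitch_hz
            ):
                return False
    return True
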