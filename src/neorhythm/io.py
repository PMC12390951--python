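"""On-disk formats: WAV stimuli, SNIRF (HDF5) sessions, events TSV, CSV tables.

SNIRF files follow the v1.0 container layout (``/nirs/data1`` with a
channel-major measurement list, ``/nirs/probe`` with 2-D optode positions,
``/nirs/stim1..2`` per condition); only the subset of the standard needed to
round-trip this pipeline's sessions is written.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .config import SAMPLING_RATE_HZ, WAVELENGTHS_NM
from .montage import Montage, build_montage
from .stimuli import Block, BlockProtocol, RenderedStimulus
from .synth import RawSession


def write_wav(stim: RenderedStimulus, path: str | Path) -> None:
    """16-bit PCM WAV of a rendered stimulus."""
    if stim.waveform is None:
        raise ValueError("stimulus was rendered without audio")
    pcm = np.clip(stim.waveform, -1, 1)
    wavfile.write(str(path), stim.sample_rate, (pcm * 32767).astype(np.int16))


def write_stimulus_sidecar(
    stim: RenderedStimulus, path: str | Path, labels: list[str] | None = None
) -> None:
    """Per-stimulus CSV: tone onsets, inter-onset intervals in time units,
    and perturbation labels when provided (arrhythmic stimuli)."""
    units = np.diff(stim.onsets_s) / (stim.tempo_unit_ms / 1000.0)
    df = pd.DataFrame(
        {
            "onset_s": stim.onsets_s,
            "interval_units": np.concatenate([[np.nan], units]),
        }
    )
    if labels is not None:
        df["perturbation"] = ["none"] + list(labels)
    df.to_csv(path, index=False)


def protocol_to_frame(protocol: BlockProtocol) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                block_index=b.index,
                condition=b.condition,
                base_id=b.base_id,
                tempo_ms=b.tempo_unit_ms,
                pitch_hz=b.pitch_hz,
                onset_s=b.onset_s,
                duration_s=b.duration_s,
                isi_s=b.isi_s,
            )
            for b in protocol.blocks
        ]
    )


def write_protocol_csv(protocol: BlockProtocol, path: str | Path) -> None:
    protocol_to_frame(protocol).to_csv(path, index=False)


def write_events_tsv(protocol: BlockProtocol, path: str | Path) -> None:
    df = protocol_to_frame(protocol)[["onset_s", "duration_s", "condition"]]
    df.columns = ["onset", "duration", "trial_type"]
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> BlockProtocol:
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for k, row in df.iterrows():
        nxt = df.onset.iloc[k + 1] if k + 1 < len(df) else row.onset + row.duration + 30.0
        blocks.append(
            Block(
                index=int(k),
                condition=str(row.trial_type),
                base_id=0,
                tempo_unit_ms=0,
                pitch_hz=0,
                onset_s=float(row.onset),
                duration_s=float(row.duration),
                isi_s=float(nxt - row.onset - row.duration),
            )
        )
    return BlockProtocol(blocks=blocks)


def write_montage_json(montage: Montage, path: str | Path) -> None:
    doc = {
        "emitters": {h: montage.emitters[h].tolist() for h in montage.emitters},
        "detectors": {h: montage.detectors[h].tolist() for h in montage.detectors},
        "channels": [
            dict(
                index=c.index,
                hemisphere=c.hemisphere,
                emitter=c.emitter,
                detector=c.detector,
                midpoint_mm=list(c.midpoint_mm),
                separation_mm=c.separation_mm,
                region=c.region,
            )
            for c in montage.channels
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_snirf(session: RawSession, path: str | Path) -> None:
    """Write one session as a SNIRF v1.0 HDF5 container."""
    m = session.montage
    hemis = ("left", "right")
    src = np.vstack([m.emitters[h] for h in hemis])
    det = np.vstack([m.detectors[h] for h in hemis])
    src_off = {"left": 0, "right": m.emitters["left"].shape[0]}
    det_off = {"left": 0, "right": m.detectors["left"].shape[0]}
    n_ch = m.n_channels
    n_t = session.n_samples
    data = np.empty((n_t, n_ch * 2))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in {
            "SubjectID": session.participant_id,
            "MeasurementDate": "unknown",
            "MeasurementTime": "unknown",
            "LengthUnit": "mm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
        }.items():
            meta.create_dataset(k, data=v)
        d1 = nirs.create_group("data1")
        col = 0
        for wi in range(2):
            for c in m.channels:
                data[:, col] = session.intensities[c.index, :, wi]
                ml = d1.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=src_off[c.hemisphere] + c.emitter + 1)
                ml.create_dataset("detectorIndex", data=det_off[c.hemisphere] + c.detector + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=session.times_s)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(WAVELENGTHS_NM, dtype=float))
        probe.create_dataset("sourcePos2D", data=src)
        probe.create_dataset("detectorPos2D", data=det)
        for si, cond in enumerate(("rhythmic", "arrhythmic")):
            blocks = [b for b in session.events.blocks if b.condition == cond]
            stim = nirs.create_group(f"stim{si + 1}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset(
                "data",
                data=np.array([[b.onset_s, b.duration_s, 1.0] for b in blocks]),
            )


def read_snirf(path: str | Path, montage: Montage | None = None) -> RawSession:
    """Read a session written by :func:`write_snirf` (or a compatible file)."""
    montage = montage or build_montage()
    n_ch = montage.n_channels
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        d1 = nirs["data1"]
        data = d1["dataTimeSeries"][()]
        time = d1["time"][()]
        sid = nirs["metaDataTags/SubjectID"][()]
        if isinstance(sid, bytes):
            sid = sid.decode()
        blocks = []
        idx = 0
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            name = nirs[key]["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for onset, dur, _ in nirs[key]["data"][()]:
                blocks.append(
                    Block(
                        index=idx, condition=name, base_id=0, tempo_unit_ms=0,
                        pitch_hz=0, onset_s=float(onset), duration_s=float(dur),
                        isi_s=0.0,
                    )
                )
                idx += 1
    blocks.sort(key=lambda b: b.onset_s)
    blocks = [
        Block(index=i, condition=b.condition, base_id=b.base_id,
              tempo_unit_ms=b.tempo_unit_ms, pitch_hz=b.pitch_hz,
              onset_s=b.onset_s, duration_s=b.duration_s, isi_s=b.isi_s)
        for i, b in enumerate(blocks)
    ]
    fs = 1.0 / np.median(np.diff(time)) if time.size > 1 else SAMPLING_RATE_HZ
    inten = np.empty((n_ch, data.shape[0], 2))
    inten[:, :, 0] = data[:, :n_ch].T
    inten[:, :, 1] = data[:, n_ch:].T
    return RawSession(
        intensities=inten,
        fs=float(fs),
        events=BlockProtocol(blocks=blocks),
        montage=montage,
        participant_id=str(sid),
    )


def cluster_result_to_frame(result, label: str = "") -> pd.DataFrame:
    rows = [
        dict(
            label=label,
            cluster=i,
            members=" ".join(map(str, c.members.tolist())),
            size=c.members.size,
            t_sum=c.t_sum,
            p_perm=c.p_perm,
        )
        for i, c in enumerate(result.clusters)
    ]
    return pd.DataFrame(rows, columns=["label", "cluster", "members", "size", "t_sum", "p_perm"])
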