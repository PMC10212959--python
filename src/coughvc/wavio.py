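"""Mono WAV read/write for voltage waveforms.

Two on-disk encodings: 32-bit float samples holding volts directly, or
16-bit PCM with a stated full-scale voltage recorded in a JSON sidecar
(``<name>.wav.json``) so the voltage scale survives the round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .acoustics import Waveform

__all__ = ["write_wav", "read_wav"]


def write_wav(
    path: str | Path,
    w: Waveform,
    encoding: str = "float32",
    full_scale_voltage: float | None = None,
) -> None:
    path = Path(path)
    fs = int(round(w.fs))
    if encoding == "float32":
        wavfile.write(path, fs, w.samples.astype(np.float32))
        sidecar = {"encoding": "float32", "units": "V"}
    elif encoding == "pcm16":
        if full_scale_voltage is None:
            full_scale_voltage = float(np.max(np.abs(w.samples))) or 1.0
        scaled = np.clip(w.samples / full_scale_voltage, -1.0, 1.0)
        wavfile.write(path, fs, (scaled * 32767.0).astype(np.int16))
        sidecar = {
            "encoding": "pcm16",
            "units": "V",
            "full_scale_voltage": full_scale_voltage,
        }
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    sidecar.update(
        {"participant_id": w.participant_id, "trial_index": w.trial_index}
    )
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_wav(path: str | Path) -> Waveform:
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected a mono WAV file")
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if data.dtype == np.int16:
        full_scale = meta.get("full_scale_voltage")
        if full_scale is None:
            raise ValueError(
                f"{path}: 16-bit PCM requires a sidecar declaring full_scale_voltage"
            )
        samples = data.astype(float) / 32767.0 * full_scale
    else:
        samples = data.astype(float)
    return Waveform(
        samples=samples,
        fs=float(fs),
        participant_id=str(meta.get("participant_id", path.stem)),
        trial_index=int(meta.get("trial_index", 0)),
    )
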