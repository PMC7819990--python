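"""Flat-binary recording I/O.

Recordings are stored the way acquisition systems write them: a flat
16-bit integer binary file in time-major order ([time x channel]) next to a
JSON sidecar with the sampling rate, the microvolt-per-bit quantization
step and the channel order.  SpikeGLX-style key names are accepted when
reading the sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Recording", "write_recording", "read_recording"]

INT16_MIN, INT16_MAX = -32768, 32767

# accepted sidecar key spellings (native first, then SpikeGLX dialects)
_RATE_KEYS = ("sampling_rate_hz", "imSampRate", "niSampRate", "sRateHz")
_NCHAN_KEYS = ("n_channels", "nSavedChans", "snsApLfSy")
_UVBIT_KEYS = ("uv_per_bit", "uV_per_bit", "imAiRangeMax_over_gain")


@dataclass
class Recording:
    """A multichannel recording in microvolts with its acquisition metadata."""

    matrix_uV: np.ndarray  # [time x channel]
    sampling_rate_hz: float
    uv_per_bit: float
    probe_name: str = ""
    channel_order: list[int] | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix_uV.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix_uV.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def quantize(matrix_uV: np.ndarray, uv_per_bit: float) -> tuple[np.ndarray, int]:
    """Round microvolts to integer counts, clipping to the int16 range.

    Returns the int16 array and the number of clipped samples.
    """
    q = np.round(np.asarray(matrix_uV) / uv_per_bit)
    clipped = int(np.sum((q < INT16_MIN) | (q > INT16_MAX)))
    q = np.clip(q, INT16_MIN, INT16_MAX)
    return q.astype(np.int16), clipped


def write_recording(
    matrix_uV: np.ndarray,
    path_stem: str | Path,
    sampling_rate_hz: float,
    uv_per_bit: float,
    probe_name: str = "",
    channel_order: list[int] | None = None,
) -> tuple[Path, Path, int]:
    """Write ``<stem>.bin`` (int16, time-major) and ``<stem>.meta.json``.

    Returns the two paths and the count of samples clipped to int16.
    """
    matrix_uV = np.asarray(matrix_uV)
    if not np.all(np.isfinite(matrix_uV)):
        raise ValueError("matrix contains non-finite values")
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    ints, n_clipped = quantize(matrix_uV, uv_per_bit)
    bin_path = stem.with_suffix(".bin")
    ints.tofile(bin_path)
    meta = {
        "sampling_rate_hz": sampling_rate_hz,
        "uv_per_bit": uv_per_bit,
        "n_channels": int(matrix_uV.shape[1]),
        "n_samples": int(matrix_uV.shape[0]),
        "probe_name": probe_name,
        "channel_order": channel_order
        or list(range(matrix_uV.shape[1])),
        "dtype": "int16",
        "order": "time_major",
        "n_clipped": n_clipped,
    }
    meta_path = stem.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return bin_path, meta_path, n_clipped


def _lookup(meta: dict, keys: tuple[str, ...], what: str):
    for k in keys:
        if k in meta:
            return meta[k]
    raise KeyError(f"sidecar missing {what} (tried keys {keys})")


def read_recording(path_stem: str | Path) -> Recording:
    """Read a flat int16 binary with its JSON sidecar back into microvolts."""
    stem = Path(path_stem)
    if stem.suffix == ".bin":
        stem = stem.with_suffix("")
    meta = json.loads(stem.with_suffix(".meta.json").read_text())
    fs = float(_lookup(meta, _RATE_KEYS, "sampling rate"))
    n_chan = int(_lookup(meta, _NCHAN_KEYS, "channel count"))
    uv_per_bit = float(_lookup(meta, _UVBIT_KEYS, "uv-per-bit gain"))
    raw = np.fromfile(stem.with_suffix(".bin"), dtype=np.int16)
    if raw.size % n_chan:
        raise ValueError("binary size is not a multiple of channel count")
    matrix = raw.reshape(-1, n_chan).astype(float) * uv_per_bit
    return Recording(
        matrix_uV=matrix,
        sampling_rate_hz=fs,
        uv_per_bit=uv_per_bit,
        probe_name=meta.get("probe_name", ""),
        channel_order=meta.get("channel_order"),
    )
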