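"""In vivo noise-floor estimation from slow-wave down states.

Under ketamine/xylazine or urethane anesthesia, cortical populations fall
silent for hundreds of milliseconds during down states.  The band-passed,
rectified multiunit activity (MUA) summed over channels and smoothed with a
50 Hz low-pass gives an envelope whose low phases mark those silent
windows; the RMS of a short segment centered in each sufficiently long
down state approximates the recording noise floor.

The estimate is known to run above a saline (in vitro) measurement of the
same hardware — residual distant spiking and biological background remain
in the down states — so it is meant for comparisons between site groups,
not as an absolute hardware noise figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import FilteredRecording

__all__ = [
    "StateSegmentation",
    "NoiseEstimate",
    "summed_mua",
    "smooth_envelope",
    "detect_states",
    "estimate_noise",
]


@dataclass
class StateSegmentation:
    """Alternating up/down intervals with the envelope that produced them."""

    intervals: list[tuple[float, float, str]]  # (start_s, end_s, up|down)
    envelope: np.ndarray
    threshold_value: float
    sampling_rate_hz: float

    def down_intervals(self, min_down_s: float = 0.0):
        return [(s, e) for s, e, lab in self.intervals
                if lab == "down" and (e - s) >= min_down_s]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals,
                            columns=["start_s", "end_s", "label"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class NoiseEstimate:
    """Down-state RMS noise estimate; invalid when no window qualified."""

    per_channel_rms_uV: np.ndarray
    mean_rms_uV: float
    n_windows: int
    window_s: float = 0.05
    min_down_s: float = 0.2

    @property
    def valid(self) -> bool:
        return self.n_windows >= 1


def _matrix(x) -> np.ndarray:
    m = x.matrix if isinstance(x, FilteredRecording) else np.asarray(x)
    return m[:, None] if m.ndim == 1 else m


def summed_mua(mua: np.ndarray) -> np.ndarray:
    """Sample-wise sum of the rectified MUA across channels."""
    return _matrix(mua).sum(axis=1)


def smooth_envelope(summed: np.ndarray, sampling_rate_hz: float,
                    cutoff_hz: float = 50.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass of the summed MUA (DC gain 1)."""
    if cutoff_hz >= sampling_rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff_hz, btype="lowpass",
                        fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(summed, dtype=float))


def _runs(above: np.ndarray) -> list[list]:
    """[start, end) index runs of constant boolean value, with the value."""
    edges = np.flatnonzero(np.diff(above)) + 1
    bounds = np.concatenate([[0], edges, [above.size]])
    return [[int(bounds[i]), int(bounds[i + 1]), bool(above[bounds[i]])]
            for i in range(len(bounds) - 1)]


def detect_states(
    envelope: np.ndarray,
    sampling_rate_hz: float,
    min_down_s: float = 0.2,
    min_up_s: float = 0.1,
    threshold: float | None = None,
    threshold_fraction: float = 0.2,
    baseline_margin: float | None = 1.5,
) -> StateSegmentation:
    """Threshold the smoothed MUA envelope into up and down states.

    The default threshold sits at ``threshold_fraction`` of the way from
    the envelope's 10th to its 90th percentile, capped at
    ``baseline_margin`` times the 10th percentile.  The down-state
    envelope baseline is narrow while up-state activity is strongly
    right-skewed, so a split close to the baseline (default 0.2)
    classifies weakly active up periods correctly — a midpoint split would
    absorb them into down states and contaminate the noise windows — and
    the multiplicative cap keeps the threshold anchored to the baseline
    when up-state spikes are very large, making state detection invariant
    to the overall spike-amplitude scale.  Sub-threshold runs of at least
    ``min_down_s`` are down states and supra-threshold runs of at least
    ``min_up_s`` are up states; shorter runs are merged into the enclosing
    state (shortest first), so brief envelope dips or blips do not
    fragment the segmentation.
    """
    env = np.asarray(envelope, dtype=float)
    fs = sampling_rate_hz
    if env.size < max(min_down_s, min_up_s) * fs:
        raise ValueError("envelope shorter than the minimum state duration")
    if threshold is None:
        p10, p90 = np.percentile(env, [10, 90])
        if p90 - p10 <= 0:
            raise ValueError(
                "envelope has zero dynamic range; segmentation invalid")
        threshold = p10 + threshold_fraction * (p90 - p10)
        if baseline_margin is not None and p10 > 0:
            threshold = min(threshold, baseline_margin * p10)
    above = env > threshold
    if above.all() or (~above).all():
        runs = _runs(above)
    else:
        runs = _runs(above)
        min_len = {True: int(round(min_up_s * fs)),
                   False: int(round(min_down_s * fs))}
        while len(runs) > 1:
            lengths = [(r[1] - r[0], i) for i, r in enumerate(runs)
                       if r[1] - r[0] < min_len[r[2]]]
            if not lengths:
                break
            _, i = min(lengths)
            runs[i][2] = not runs[i][2]  # absorb into the enclosing state
            merged: list[list] = []
            for r in runs:
                if merged and merged[-1][2] == r[2]:
                    merged[-1][1] = r[1]
                else:
                    merged.append(r)
            runs = merged
    intervals = [(r[0] / fs, r[1] / fs, "up" if r[2] else "down")
                 for r in runs]
    return StateSegmentation(intervals, env, float(threshold), fs)


def estimate_noise(
    mua: np.ndarray | FilteredRecording,
    segmentation: StateSegmentation,
    window_s: float = 0.05,
    min_down_s: float = 0.2,
) -> NoiseEstimate:
    """RMS of a centered window in every sufficiently long down state.

    For each down state of at least ``min_down_s``, a ``window_s`` segment
    centered on the state's midpoint is taken; per channel, the RMS of each
    window is computed and averaged across windows, then the channel means
    are averaged.  RMS is invariant to rectification, so rectified and raw
    band-passed input give identical results.
    """
    matrix = _matrix(mua)
    fs = segmentation.sampling_rate_hz
    half = int(round(window_s * fs / 2))
    window_rms: list[np.ndarray] = []
    for s, e in segmentation.down_intervals(min_down_s):
        mid = int(round((s + e) / 2 * fs))
        a, b = mid - half, mid + half
        if a < 0 or b > matrix.shape[0]:
            continue
        seg = matrix[a:b]
        window_rms.append(np.sqrt(np.mean(np.square(seg), axis=0)))
    if not window_rms:
        return NoiseEstimate(
            per_channel_rms_uV=np.full(matrix.shape[1], np.nan),
            mean_rms_uV=float("nan"),
            n_windows=0,
            window_s=window_s,
            min_down_s=min_down_s,
        )
    per_channel = np.mean(window_rms, axis=0)
    return NoiseEstimate(
        per_channel_rms_uV=per_channel,
        mean_rms_uV=float(np.mean(per_channel)),
        n_windows=len(window_rms),
        window_s=window_s,
        min_down_s=min_down_s,
    )
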