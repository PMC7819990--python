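"""Post-sorting single-unit quality metrics and selection.

Spike sorting itself (e.g. Kilosort) and manual curation are upstream of
this module: it consumes sorted output — spike-time vectors per cluster —
plus the recording, and computes the well-isolation criteria, peak-to-peak
spike amplitude, isolation distance, unit yield and the edge-vs-center
unit-amplitude threshold scan.

A unit is *well isolated* when all of the following hold (strict
inequalities):

* fewer than 2% of its spikes follow another by less than 2 ms,
* its firing rate exceeds 0.05 Hz or it has at least 100 spikes,
* its mean-waveform peak-to-peak amplitude exceeds 60 uV on its best
  channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .amplitude import ScanResult, cumulative_scan

__all__ = [
    "UnitRecord",
    "UnitQuality",
    "refractory_fraction",
    "p2p_amplitude",
    "compute_quality",
    "select_well_isolated",
    "isolation_distance",
    "isolation_features",
    "unit_amplitude_scan",
    "unit_yield",
    "units_table",
    "cut_mean_waveform",
    "units_from_sorting",
    "load_phy_sorting",
]

REFRACTORY_MS = 2.0
MAX_REFRACTORY_FRACTION = 0.02
MIN_RATE_HZ = 0.05
MIN_SPIKES = 100
MIN_P2P_UV = 60.0


@dataclass
class UnitRecord:
    """One sorted unit: spike train, mean waveform and bookkeeping."""

    unit_id: int
    spike_times_s: np.ndarray
    mean_waveform_uV: np.ndarray  # [channel x waveform-sample]
    recording_duration_s: float
    group_label: str = ""
    recording_id: str = ""
    best_channel: int = -1

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size and (
                self.spike_times_s.min() < 0
                or self.spike_times_s.max() > self.recording_duration_s):
            raise ValueError("spike times outside [0, duration]")
        self.mean_waveform_uV = np.atleast_2d(
            np.asarray(self.mean_waveform_uV, dtype=float))
        if self.best_channel < 0 and self.mean_waveform_uV.size:
            self.best_channel = _best_channel(self.mean_waveform_uV)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def firing_rate_hz(self) -> float:
        return self.n_spikes / self.recording_duration_s


@dataclass
class UnitQuality:
    """Quality metrics entering the well-isolation decision."""

    refractory_fraction: float
    firing_rate_hz: float
    p2p_uV: float
    isolation_distance: float | None = None
    well_isolated: bool = False


def refractory_fraction(spike_times_s: np.ndarray,
                        refractory_ms: float = REFRACTORY_MS) -> float:
    """Fraction of spikes whose preceding inter-spike interval is short.

    Counted as (#ISIs below ``refractory_ms``) / n_spikes.  Fewer than two
    spikes yield 0 by convention.
    """
    t = np.sort(np.asarray(spike_times_s, dtype=float))
    if t.size < 2:
        return 0.0
    violations = int(np.sum(np.diff(t) < refractory_ms * 1e-3))
    return violations / t.size


def _channel_p2p(waveform: np.ndarray) -> np.ndarray:
    """Per-channel trough-to-positive-peak amplitude.

    The positive peak is the largest positive value (baseline 0 when the
    waveform never goes positive) and the trough the minimum (baseline 0
    for an atypical all-positive bump).
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    pos = np.maximum(w.max(axis=1), 0.0)
    trough = np.minimum(w.min(axis=1), 0.0)
    return pos - trough


def _best_channel(waveform: np.ndarray) -> int:
    return int(np.argmax(_channel_p2p(waveform)))


def p2p_amplitude(mean_waveform: np.ndarray) -> tuple[float, int]:
    """Peak-to-peak amplitude on the best channel.

    Returns ``(p2p_uV, best_channel)`` where the best channel maximizes the
    per-channel trough-to-positive-peak difference.
    """
    w = np.atleast_2d(np.asarray(mean_waveform, dtype=float))
    if w.size == 0:
        raise ValueError("empty waveform")
    p2p = _channel_p2p(w)
    best = int(np.argmax(p2p))
    if w[best].min() >= 0 and p2p[best] > 0:
        warnings.warn("waveform has no trough; peak-to-peak measured "
                      "against a zero baseline", stacklevel=2)
    return float(p2p[best]), best


def compute_quality(unit: UnitRecord,
                    refractory_ms: float = REFRACTORY_MS) -> UnitQuality:
    p2p, _ = p2p_amplitude(unit.mean_waveform_uV) \
        if unit.mean_waveform_uV.size else (0.0, -1)
    rf = refractory_fraction(unit.spike_times_s, refractory_ms)
    rate = unit.firing_rate_hz
    q = UnitQuality(refractory_fraction=rf, firing_rate_hz=rate, p2p_uV=p2p)
    q.well_isolated = (
        rf < MAX_REFRACTORY_FRACTION
        and (rate > MIN_RATE_HZ or unit.n_spikes >= MIN_SPIKES)
        and p2p > MIN_P2P_UV
    )
    return q


def select_well_isolated(
    units: Sequence[UnitRecord],
    qualities: Sequence[UnitQuality] | None = None,
) -> list[UnitRecord]:
    """Keep units passing all three well-isolation criteria."""
    if qualities is None:
        qualities = [compute_quality(u) for u in units]
    return [u for u, q in zip(units, qualities) if q.well_isolated]


def isolation_distance(cluster_features: np.ndarray,
                       other_features: np.ndarray,
                       regularize: float = 1e-6) -> float | None:
    """Isolation distance of a cluster in a shared feature space.

    The squared Mahalanobis distance — under the cluster's own mean and
    covariance — of the n-th closest non-cluster spike, where n is the
    cluster size.  Undefined (None) when there are fewer other spikes than
    cluster spikes.  A singular covariance is diagonally loaded by
    ``regularize * trace / d``.
    """
    cluster = np.atleast_2d(np.asarray(cluster_features, dtype=float))
    other = np.atleast_2d(np.asarray(other_features, dtype=float))
    n, d = cluster.shape
    if other.shape[0] < n:
        return None
    mu = cluster.mean(axis=0)
    cov = np.cov(cluster, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + np.eye(d) * regularize * np.trace(cov) / d
        chol = np.linalg.cholesky(cov)
    diff = other - mu
    sol = np.linalg.solve(chol, diff.T)
    d2 = np.sum(sol ** 2, axis=0)
    return float(np.sort(d2)[n - 1])


def isolation_features(
    recording_matrix: np.ndarray,
    sampling_rate_hz: float,
    spikes_by_cluster: Mapping[int, np.ndarray],
    channel_positions: np.ndarray | None = None,
    n_pc: int = 3,
    n_neighbor_channels: int = 3,
    window_ms: float = 2.0,
) -> dict[int, np.ndarray]:
    """Per-spike waveform features for isolation-distance computation.

    For each cluster: spikes are cut on the cluster's best channel and its
    ``n_neighbor_channels`` nearest channels, each channel's waveforms are
    projected on the first ``n_pc`` principal components (fit over all
    spikes in the recording on that channel), and the projections are
    concatenated (default 12-d).
    """
    matrix = np.asarray(recording_matrix)
    fs = sampling_rate_hz
    half = int(round(window_ms * 1e-3 * fs / 2))
    n_samp, n_chan = matrix.shape

    def cut(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.round(np.asarray(times) * fs).astype(int)
        ok = (idx - half >= 0) & (idx + half <= n_samp)
        idx = idx[ok]
        wins = np.stack([matrix[i - half:i + half] for i in idx]) \
            if idx.size else np.empty((0, 2 * half, n_chan))
        return wins, ok

    # best channel per cluster from its mean waveform
    all_wins: dict[int, np.ndarray] = {}
    best: dict[int, int] = {}
    for cid, times in spikes_by_cluster.items():
        wins, _ = cut(times)
        all_wins[cid] = wins
        if wins.shape[0] == 0:
            best[cid] = 0
            continue
        mean_wf = wins.mean(axis=0).T  # [channel x sample]
        best[cid] = _best_channel(mean_wf)

    if channel_positions is None:
        channel_positions = np.column_stack(
            [np.zeros(n_chan), np.arange(n_chan)])

    features: dict[int, np.ndarray] = {}
    for cid, wins in all_wins.items():
        b = best[cid]
        dist = np.linalg.norm(channel_positions - channel_positions[b],
                              axis=1)
        chans = np.argsort(dist, kind="stable")[:n_neighbor_channels + 1]
        # PCA per channel fit on every spike in the recording
        per_chan_proj = []
        pooled = np.concatenate([w for w in all_wins.values()
                                 if w.shape[0]], axis=0)
        for ch in chans:
            pca = PCA(n_components=min(n_pc, pooled.shape[1]))
            pca.fit(pooled[:, :, ch])
            per_chan_proj.append(pca.transform(wins[:, :, ch])
                                 if wins.shape[0] else
                                 np.empty((0, pca.n_components_)))
        features[cid] = np.hstack(per_chan_proj) if wins.shape[0] else \
            np.empty((0, n_pc * (n_neighbor_channels + 1)))
    return features


def compute_isolation_distances(
    features: Mapping[int, np.ndarray],
) -> dict[int, float | None]:
    """Isolation distance of every cluster against all other spikes."""
    out: dict[int, float | None] = {}
    for cid, feats in features.items():
        others = [f for k, f in features.items() if k != cid and f.shape[0]]
        if not others or feats.shape[0] < 2:
            out[cid] = None
            continue
        out[cid] = isolation_distance(feats, np.concatenate(others, axis=0))
    return out


def unit_amplitude_scan(
    edge_units: Sequence[UnitRecord],
    center_units: Sequence[UnitRecord],
    start_uV: float = 60.0,
    limit_uV: float = 1000.0,
    n_steps: int = 100,
    alpha: float = 0.05,
) -> ScanResult:
    """Reverse-cumulative binomial scan of unit peak-to-peak amplitudes.

    The amplitude-distribution scan machinery applied to well-isolated
    units' spike amplitudes in the positive direction, with thresholds
    starting at the 60 uV selection floor.
    """
    if not edge_units or not center_units:
        raise ValueError("both unit groups must be nonempty")
    amps_e = np.array([p2p_amplitude(u.mean_waveform_uV)[0]
                       for u in edge_units])
    amps_c = np.array([p2p_amplitude(u.mean_waveform_uV)[0]
                       for u in center_units])
    thresholds = np.linspace(start_uV, limit_uV, n_steps)
    return cumulative_scan(amps_e, amps_c, side="positive", alpha=alpha,
                           thresholds_uV=thresholds)


def units_table(
    units: Sequence[UnitRecord],
    qualities: Sequence[UnitQuality] | None = None,
    isolation: Mapping[int, float | None] | None = None,
) -> pd.DataFrame:
    """Per-unit summary table (one row per unit, CSV-ready)."""
    if qualities is None:
        qualities = [compute_quality(u) for u in units]
    rows = []
    for u, q in zip(units, qualities):
        iso = (isolation or {}).get(u.unit_id, q.isolation_distance)
        rows.append({
            "unit_id": u.unit_id,
            "recording_id": u.recording_id,
            "group_label": u.group_label,
            "n_spikes": u.n_spikes,
            "firing_rate_hz": u.firing_rate_hz,
            "p2p_uV": q.p2p_uV,
            "refractory_fraction": q.refractory_fraction,
            "isolation_distance": iso,
            "well_isolated": q.well_isolated,
        })
    return pd.DataFrame(rows)


def unit_yield(units: Sequence[UnitRecord]) -> pd.DataFrame:
    """Well-isolated unit counts per recording x site group.

    Groups sharing a recording are counted independently (adjacent edge
    and center files sorted separately will contain partly redundant
    units; that redundancy is deliberate — each group is treated as its
    own probe).
    """
    if not units:
        return pd.DataFrame(columns=["recording_id", "group_label", "n_units"])
    df = pd.DataFrame(
        [(u.recording_id, u.group_label) for u in units],
        columns=["recording_id", "group_label"],
    )
    counts = (df.value_counts().rename("n_units").reset_index()
              .sort_values(["recording_id", "group_label"])
              .reset_index(drop=True))
    return counts


# ---------------------------------------------------------------------------
# sorted-output ingestion


def cut_mean_waveform(
    recording_matrix: np.ndarray,
    spike_times_s: np.ndarray,
    sampling_rate_hz: float,
    window_ms: float = 2.0,
) -> np.ndarray:
    """Mean waveform [channel x sample], 2 ms window centered on the trough
    reference time of each spike."""
    matrix = np.asarray(recording_matrix)
    half = int(round(window_ms * 1e-3 * sampling_rate_hz / 2))
    idx = np.round(np.asarray(spike_times_s) * sampling_rate_hz).astype(int)
    idx = idx[(idx - half >= 0) & (idx + half <= matrix.shape[0])]
    if idx.size == 0:
        return np.zeros((matrix.shape[1], 2 * half))
    wins = np.stack([matrix[i - half:i + half] for i in idx])
    return wins.mean(axis=0).T


def units_from_sorting(
    recording_matrix: np.ndarray,
    sampling_rate_hz: float,
    spikes_by_cluster: Mapping[int, np.ndarray],
    group_label: str = "",
    recording_id: str = "",
    window_ms: float = 2.0,
) -> list[UnitRecord]:
    """Build UnitRecords from spike-time vectors and the recording itself."""
    duration = recording_matrix.shape[0] / sampling_rate_hz
    out = []
    for cid in sorted(spikes_by_cluster):
        times = np.sort(np.asarray(spikes_by_cluster[cid], dtype=float))
        wf = cut_mean_waveform(recording_matrix, times, sampling_rate_hz,
                               window_ms)
        out.append(UnitRecord(
            unit_id=int(cid),
            spike_times_s=times,
            mean_waveform_uV=wf,
            recording_duration_s=duration,
            group_label=group_label,
            recording_id=recording_id,
        ))
    return out


def load_phy_sorting(directory: str | Path,
                     sampling_rate_hz: float) -> dict[int, np.ndarray]:
    """Read Phy-style sorted output into spike times (s) per cluster.

    Accepts ``spike_times.npy`` (sample indices) + ``spike_clusters.npy``,
    or a ``spikes.csv`` with columns ``cluster`` (or ``neuron_id``) and
    ``time_s`` (or ``sample``).
    """
    d = Path(directory)
    npy = d / "spike_times.npy"
    if npy.exists():
        times = np.load(npy).astype(float).ravel() / sampling_rate_hz
        clusters = np.load(d / "spike_clusters.npy").astype(int).ravel()
    else:
        csv = d / "spikes.csv"
        if not csv.exists():
            raise FileNotFoundError(
                f"no spike_times.npy or spikes.csv in {d}")
        df = pd.read_csv(csv)
        cluster_col = "cluster" if "cluster" in df else "neuron_id"
        clusters = df[cluster_col].to_numpy(dtype=int)
        if "time_s" in df:
            times = df["time_s"].to_numpy(dtype=float)
        else:
            times = df["sample"].to_numpy(dtype=float) / sampling_rate_hz
    out: dict[int, np.ndarray] = {}
    for cid in np.unique(clusters):
        out[int(cid)] = np.sort(times[clusters == cid])
    return out
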