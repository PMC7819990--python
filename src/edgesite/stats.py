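"""Group-level nonparametric statistics and pipeline orchestration.

Rank-based tests compare the quality features between site groups:
Mann-Whitney U for two groups, Kruskal-Wallis for three or more (the
laterality analysis), Dunn's test with Bonferroni correction post hoc.
Effect sizes follow the rank-test convention r = Z / sqrt(N), N the total
sample size.  All tests are two-sided at a 0.05 significance level.

``run_pipeline`` wires the whole analysis together on one recording
(synthetic or on-disk): site grouping, band-pass filtering, amplitude
pools, the binomial threshold scans, the Brown-Forsythe power comparison,
down-state noise estimation and unit quality metrics, and returns a
serializable summary report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from scipy import stats as sps

from . import amplitude as amp
from . import noise as noise_mod
from . import preprocess as pre
from . import units as units_mod
from .io import read_recording
from .probes import build_layout, classify_edge_center, split_recording
from .synth import SimConfig, generate_recording

__all__ = [
    "GroupComparison",
    "SummaryReport",
    "PipelineConfig",
    "PipelineError",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "run_pipeline",
]


@dataclass
class GroupComparison:
    """One rank-test result with its effect size."""

    test: str  # mann_whitney | kruskal_wallis | dunn
    statistic: float
    z_score: float | None
    p_value: float
    n_total: int
    effect_size_r: float | None
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.effect_size_r is not None and abs(self.effect_size_r) > 1:
            raise ValueError("|r| must be <= 1")


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided Mann-Whitney U test with Z-based effect size.

    Exact p-value by enumeration for small tie-free samples, otherwise the
    tie-corrected normal approximation.  Z is signed so that a positive
    value means the first group is stochastically larger; r = Z / sqrt(N)
    with N the combined sample size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n
    method = "exact" if (not has_ties and max(n1, n2) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = 0.0 if sigma2 <= 0 else (u1 - mu) / np.sqrt(sigma2)
    r = z / np.sqrt(n)
    return GroupComparison(
        test="mann_whitney",
        statistic=u1,
        z_score=float(z),
        p_value=float(res.pvalue),
        n_total=n,
        effect_size_r=float(np.clip(r, -1.0, 1.0)),
        groups=labels,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   labels: Sequence[str] | None = None) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected) for three or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in arrays if g.size]
    if len(arrays) == 2:
        raise ValueError("two groups supplied; use mann_whitney instead")
    if len(nonempty) < 2:
        raise ValueError("need at least two nonempty groups")
    h, p = sps.kruskal(*nonempty)
    labels = tuple(labels) if labels else tuple(
        f"g{i}" for i in range(len(arrays)))
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        z_score=None,
        p_value=float(p),
        n_total=int(sum(g.size for g in arrays)),
        effect_size_r=None,
        groups=labels,
    )


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None,
                 kruskal_p: float | None = None,
                 alpha: float = 0.05) -> list[GroupComparison]:
    """Dunn's test for all pairs, Bonferroni-corrected.

    Pairwise z statistics compare mean ranks over the pooled sample with
    the tie-corrected variance; each two-sided p-value is multiplied by
    the number of pairs and capped at 1.
    """
    import warnings

    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    labels = list(labels) if labels else [f"g{i}" for i in range(k)]
    if kruskal_p is not None and kruskal_p >= alpha:
        warnings.warn("Dunn post hoc requested without a significant "
                      "Kruskal-Wallis result", stacklevel=2)
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for g in arrays:
        mean_ranks.append(ranks[i0:i0 + g.size].mean() if g.size else np.nan)
        i0 += g.size
    tie = _tie_term(pooled)
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    m = k * (k - 1) // 2
    out: list[GroupComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = arrays[i].size, arrays[j].size
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
            r = z / np.sqrt(ni + nj)
            out.append(GroupComparison(
                test="dunn",
                statistic=float(z),
                z_score=float(z),
                p_value=float(p),
                n_total=ni + nj,
                effect_size_r=float(np.clip(r, -1.0, 1.0)),
                groups=(labels[i], labels[j]),
            ))
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Inputs and toggles for one end-to-end analysis run."""

    sim: SimConfig | None = None  # synthetic input ...
    recording_path: str | None = None  # ... or a flat-binary stem
    probe: str | None = None  # layout name when loading from disk
    equalize: bool = True
    band_hz: tuple[float, float] = (500.0, 5000.0)
    filter_order: int = 3
    subsample_step: int = 50
    limit_uV: float = 1000.0
    scan_steps: int = 100
    alpha: float = 0.05
    noise_window_s: float = 0.05
    min_down_s: float = 0.2
    min_up_s: float = 0.1
    analyze_noise: bool = True
    analyze_units: bool = True
    bad_sites: tuple[int, ...] = ()
    reference_sites: tuple[int, ...] = ()
    omit_groups: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "sim"}
        if self.sim is not None:
            sim = self.sim
            d["sim"] = {
                "duration_s": sim.duration_s,
                "probe": sim.layout.probe_name,
                "sampling_rate_hz": sim.sampling_rate_hz,
                "decay_lambda_um": sim.decay_lambda_um,
                "noise_rms_uV": sim.noise_rms_uV,
                "up_mean_s": sim.up_mean_s,
                "down_mean_s": sim.down_mean_s,
                "edge_gain": sim.edge_gain,
                "uv_per_bit": sim.uv_per_bit,
                "seed": sim.seed,
                "neurons": [
                    [n.neuron_id, list(n.position_um), n.peak_amplitude_uV,
                     n.rate_up_hz, n.rate_down_hz, n.template_id]
                    for n in sim.neurons
                ],
            }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial results are attached."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class SummaryReport:
    """Losslessly serializable summary of one pipeline run."""

    data: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.data, sort_keys=True, indent=1,
                          default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SummaryReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(json.loads(text))

    def __getitem__(self, key):
        return self.data[key]


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _mean_sd_n(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()) if v.size else None,
        "sd": float(v.std(ddof=1)) if v.size > 1 else None,
        "n": int(v.size),
    }


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "test": c.test,
        "statistic": c.statistic,
        "z_score": c.z_score,
        "p_value": c.p_value,
        "n_total": c.n_total,
        "effect_size_r": c.effect_size_r,
        "groups": list(c.groups),
    }


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> SummaryReport:
    """Execute the full edge-vs-center comparison on one recording.

    Stages: load/simulate -> site grouping -> zero-phase band-pass ->
    amplitude pools (sides pooled per position) -> RMS + Brown-Forsythe ->
    negative and positive binomial threshold scans -> down-state noise
    estimate per group -> (synthetic input only) ground-truth unit quality
    and edge-vs-center unit statistics.  Deterministic given the config.

    With ``out_dir`` set, writes ``report.json`` plus per-threshold scan
    tables ``tables/scan_<side>.csv``.
    """
    partial: dict = {"provenance": {"config_hash": config.hash(),
                                    "seed": getattr(config.sim, "seed", None),
                                    "input": config.recording_path}}

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - stage identity matters
                raise PipelineError(name, exc, partial) from exc
        return wrap

    # --- input
    if config.sim is not None:
        matrix, gt = stage("simulate")(generate_recording, config.sim)
        layout = config.sim.layout
        fs = config.sim.sampling_rate_hz
    elif config.recording_path is not None:
        rec = stage("load")(read_recording, config.recording_path)
        matrix = rec.matrix_uV
        fs = rec.sampling_rate_hz
        layout = build_layout(config.probe or rec.probe_name)
        gt = None
    else:
        raise ValueError("config needs either sim or recording_path")

    # --- grouping and split
    grouping = stage("grouping")(
        classify_edge_center, layout, config.bad_sites,
        config.reference_sites, config.omit_groups)
    groups = stage("split")(split_recording, matrix, layout, grouping,
                            config.equalize)
    partial["groups"] = {k: v.shape[1] for k, v in groups.items()}

    # --- filter + pools
    low, high = config.band_hz
    filtered = {
        label: stage("filter")(pre.bandpass, sub, fs, low, high,
                               config.filter_order)
        for label, sub in groups.items()
    }
    pools = {
        label: stage("pools")(pre.subsample_pool, f, None,
                              config.subsample_step, config.limit_uV, label)
        for label, f in filtered.items()
    }
    edge_labels = [l for l in pools if l.startswith("edge")]
    center_labels = [l for l in pools if l == "center"]
    edge_samples = np.concatenate(
        [pools[l].samples_uV for l in edge_labels])
    center_samples = np.concatenate(
        [pools[l].samples_uV for l in center_labels])

    # --- power + scans
    power = stage("power")(amp.brown_forsythe, edge_samples, center_samples)
    scans = {
        side: stage("scan")(amp.cumulative_scan, edge_samples,
                            center_samples, side, config.scan_steps,
                            config.alpha, config.limit_uV)
        for side in ("negative", "positive")
    }
    partial["rms_uV"] = {"edge": power.rms_edge_uV,
                         "center": power.rms_center_uV}
    partial["brown_forsythe"] = {"F": power.brown_forsythe_F,
                                 "p_value": power.p_value,
                                 "n_edge": power.n_edge,
                                 "n_center": power.n_center}
    partial["scan"] = {
        side: {
            "threshold_edge_uV": s.threshold_edge_uV,
            "pct_edge": s.pct_edge,
            "pct_center": s.pct_center,
            "n_significant_edge": int(s.sig_edge.sum()),
            "n_significant_center": int(s.sig_center.sum()),
            "alpha_corrected": s.alpha_corrected,
        }
        for side, s in scans.items()
    }

    # --- noise per group
    if config.analyze_noise:
        noise_out = {}
        for label, f in filtered.items():
            try:
                mua = pre.rectify(f)
                env = noise_mod.smooth_envelope(
                    noise_mod.summed_mua(mua), fs)
                seg = noise_mod.detect_states(env, fs, config.min_down_s,
                                              config.min_up_s)
                est = noise_mod.estimate_noise(mua, seg,
                                               config.noise_window_s,
                                               config.min_down_s)
                noise_out[label] = {
                    "mean_rms_uV": est.mean_rms_uV if est.valid else None,
                    "n_windows": est.n_windows,
                }
            except ValueError as exc:
                noise_out[label] = {"mean_rms_uV": None, "n_windows": 0,
                                    "error": str(exc)}
        partial["noise"] = noise_out

    # --- unit quality (ground-truth sorting for synthetic input)
    tests: list[dict] = []
    if config.analyze_units and gt is not None:
        unit_summary = {}
        units_by_pos: dict[str, list] = {"edge": [], "center": []}
        chan = {sid: i for i, sid in enumerate(layout.channel_order())}
        for label, sids in grouping.groups.items():
            cols = [chan[s] for s in sids]
            sub = matrix[:, cols]
            units = stage("units")(
                units_mod.units_from_sorting, sub, fs, gt.spike_times_s,
                label, "sim")
            kept = units_mod.select_well_isolated(units)
            unit_summary[label] = {
                "n_sorted": len(units),
                "n_well_isolated": len(kept),
                "p2p_uV": _mean_sd_n(
                    [units_mod.p2p_amplitude(u.mean_waveform_uV)[0]
                     for u in kept]),
            }
            pos = "edge" if label.startswith("edge") else "center"
            units_by_pos[pos].extend(kept)
        partial["units"] = unit_summary
        amps_e = [units_mod.p2p_amplitude(u.mean_waveform_uV)[0]
                  for u in units_by_pos["edge"]]
        amps_c = [units_mod.p2p_amplitude(u.mean_waveform_uV)[0]
                  for u in units_by_pos["center"]]
        if len(amps_e) >= 2 and len(amps_c) >= 2:
            tests.append(_comparison_dict(mann_whitney(
                amps_e, amps_c, ("edge", "center"))))

    partial["tests"] = tests
    report = SummaryReport(partial)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        for side, s in scans.items():
            s.to_dataframe().to_csv(out / "tables" / f"scan_{side}.csv",
                                    index=False)
    return report
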