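"""Ground-truth synthetic extracellular recordings.

The generator emulates the statistical structure of acute cortical
recordings under ketamine/xylazine or urethane anesthesia:

* slow-wave alternation of up states (active firing) and down states
  (near-complete neuronal silence), with gamma-distributed state durations;
* spikes from point neurons whose extracellular amplitude decays
  exponentially with neuron-to-site distance (lambda ~ 28 um by default);
* an additive Gaussian noise floor of a few microvolts RMS per channel;
* 16-bit quantization at a configurable microvolt-per-bit step
  (0.195 uV/bit for the 20 kHz passive-probe front end, 2.34 uV/bit for
  Neuropixels variants);
* an optional multiplicative ``edge_gain`` on edge-column sites, giving a
  directly controllable edge-vs-center effect size (1.0 = null hypothesis).

Every draw derives from a single seed, so identical configurations yield
bit-identical recordings and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io import quantize, write_recording
from .probes import ProbeLayout

__all__ = [
    "NeuronSpec",
    "SimConfig",
    "GroundTruth",
    "generate_states",
    "generate_recording",
    "spike_template",
    "default_neurons",
    "cortical_population",
    "amplitude_population",
    "write_simulation",
]

REFRACTORY_S = 0.002  # enforced minimum inter-spike interval
STATE_GAMMA_SHAPE = 4.0  # shape of the state-duration distribution


@dataclass(frozen=True)
class NeuronSpec:
    """A point neuron near the shank plane.

    ``position_um`` is (lateral x, longitudinal y, depth z off the shank
    plane); sites lie in the z = 0 plane.
    """

    neuron_id: int
    position_um: tuple[float, float, float]
    peak_amplitude_uV: float  # spike trough depth at zero distance
    rate_up_hz: float
    rate_down_hz: float = 0.0
    template_id: int = 0

    def __post_init__(self) -> None:
        if self.peak_amplitude_uV <= 0:
            raise ValueError("peak_amplitude_uV must be positive")
        if self.rate_down_hz > self.rate_up_hz:
            raise ValueError("rate_down_hz must not exceed rate_up_hz")


@dataclass
class SimConfig:
    """Full description of one synthetic recording."""

    duration_s: float
    layout: ProbeLayout
    neurons: list[NeuronSpec]
    sampling_rate_hz: float = 20_000.0
    decay_lambda_um: float = 28.0
    noise_rms_uV: float = 5.0
    up_mean_s: float = 0.5
    down_mean_s: float = 0.4
    edge_gain: float = 1.0
    uv_per_bit: float | None = None  # default depends on the probe
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_rms_uV < 0:
            raise ValueError("noise_rms_uV must be nonnegative")
        if self.edge_gain <= 0:
            raise ValueError("edge_gain must be positive")
        if self.uv_per_bit is None:
            self.uv_per_bit = (
                2.34 if self.layout.probe_name.startswith("neuropixels")
                else 0.195)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    spike_times_s: dict[int, np.ndarray]
    site_amplitudes_uV: dict[int, np.ndarray]  # per neuron, channel order
    states: list[tuple[float, float, str]]  # (start_s, end_s, up|down)
    noise_rms_uV: float
    n_clipped: int = 0


def generate_states(
    duration_s: float,
    up_mean_s: float,
    down_mean_s: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float, str]]:
    """Alternating up/down intervals tiling [0, duration_s].

    Durations are gamma-distributed (shape 4) with the given means; the
    first interval's type is random and the last interval is truncated at
    the recording end.
    """
    if up_mean_s <= 0 or down_mean_s <= 0:
        raise ValueError("state duration means must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    label = "up" if rng.random() < 0.5 else "down"
    t = 0.0
    out: list[tuple[float, float, str]] = []
    while t < duration_s:
        mean = up_mean_s if label == "up" else down_mean_s
        dur = rng.gamma(STATE_GAMMA_SHAPE, mean / STATE_GAMMA_SHAPE)
        end = min(t + dur, duration_s)
        out.append((t, end, label))
        t = end
        label = "down" if label == "up" else "up"
    return out


def spike_template(sampling_rate_hz: float,
                   template_id: int = 0) -> tuple[np.ndarray, int]:
    """Biphasic action-potential template with unit trough depth.

    1.2 ms support: a negative trough followed by a smaller positive
    after-peak; the trough depth is normalized to 1 so a neuron's
    ``peak_amplitude_uV`` is its spike trough in microvolts.  Returns the
    template and the trough sample index (the spike-time reference).
    """
    n = max(int(round(1.2e-3 * sampling_rate_hz)), 8)
    t = np.arange(n) / sampling_rate_hz * 1e3  # ms
    # template_id nudges the trough width so distinct cells are separable
    w_tr = 0.10 + 0.02 * (template_id % 3)
    trough_t, peak_t = 0.35, 0.70
    w = (-np.exp(-0.5 * ((t - trough_t) / w_tr) ** 2)
         + 0.35 * np.exp(-0.5 * ((t - peak_t) / 0.18) ** 2))
    w /= -w.min()
    return w, int(np.argmin(w))


def _inside_shank(pos: Sequence[float], layout: ProbeLayout) -> bool:
    x, _, z = pos
    return (0.0 < x < layout.shank_width_um
            and -layout.shank_thickness_um < z < 0.0)


def _edge_site_ids(layout: ProbeLayout) -> set[int]:
    return {sid for c in layout.edge_columns() for sid in layout.columns[c]}


def _poisson_spikes(rng: np.random.Generator,
                    states: list[tuple[float, float, str]],
                    rate_up: float, rate_down: float) -> np.ndarray:
    times: list[np.ndarray] = []
    for start, end, label in states:
        rate = rate_up if label == "up" else rate_down
        if rate <= 0:
            continue
        n = rng.poisson(rate * (end - start))
        if n:
            times.append(start + rng.random(n) * (end - start))
    if not times:
        return np.empty(0)
    t = np.sort(np.concatenate(times))
    keep = [0]
    for i in range(1, t.size):
        if t[i] - t[keep[-1]] >= REFRACTORY_S:
            keep.append(i)
    return t[keep]


def generate_recording(config: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a multichannel recording and return it with its ground truth.

    The signal is the sum over neurons and spikes of the spike template,
    scaled per site by ``peak_amplitude_uV * exp(-d / decay_lambda_um)``
    (d = Euclidean neuron-to-site distance) times ``edge_gain`` on
    edge-column sites, plus white Gaussian noise, quantized to
    ``uv_per_bit`` and de-quantized.
    """
    layout = config.layout
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    n_chan = layout.n_sites
    rng = np.random.default_rng(config.seed)

    for nrn in config.neurons:
        if _inside_shank(nrn.position_um, layout):
            raise ValueError(
                f"neuron {nrn.neuron_id} lies inside the shank volume")

    states = generate_states(config.duration_s, config.up_mean_s,
                             config.down_mean_s, rng)

    pos = layout.site_positions()  # (n_chan, 2) in channel order
    site_xyz = np.column_stack([pos, np.zeros(len(pos))])
    edge_ids = _edge_site_ids(layout)
    gains = np.array([
        config.edge_gain if sid in edge_ids else 1.0
        for sid in layout.channel_order()
    ])

    # float32 assembly: rounding (~1e-7 relative) is far below the
    # 16-bit quantization step applied at the end
    if config.noise_rms_uV > 0:
        sig = rng.standard_normal((n_samples, n_chan), dtype=np.float32)
        sig *= np.float32(config.noise_rms_uV)
    else:
        sig = np.zeros((n_samples, n_chan), dtype=np.float32)

    # spike trains and per-site amplitudes; waveforms are laid down by one
    # delta-train convolution per template so the cost is independent of
    # the spike count
    spike_times: dict[int, np.ndarray] = {}
    site_amps: dict[int, np.ndarray] = {}
    deltas: dict[int, np.ndarray] = {}  # channel-major [channel x time]
    for nrn in config.neurons:
        d = np.linalg.norm(site_xyz - np.asarray(nrn.position_um), axis=1)
        amps = nrn.peak_amplitude_uV * np.exp(
            -d / config.decay_lambda_um) * gains
        site_amps[nrn.neuron_id] = amps
        t = _poisson_spikes(rng, states, nrn.rate_up_hz, nrn.rate_down_hz)
        spike_times[nrn.neuron_id] = t
        if t.size == 0:
            continue
        idx = np.round(t * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n_samples)]
        tid = nrn.template_id % 3
        if tid not in deltas:
            deltas[tid] = np.zeros((n_chan, n_samples), dtype=np.float32)
        np.add.at(deltas[tid], (slice(None), idx),
                  np.broadcast_to(amps[:, None].astype(np.float32),
                                  (n_chan, idx.size)))
    for tid, delta in deltas.items():
        template, i_trough = spike_template(fs, tid)
        conv = signal.fftconvolve(delta, template[None, :].astype(
            np.float32), axes=1)
        sig += conv[:, i_trough:i_trough + n_samples].T

    ints, n_clipped = quantize(sig, config.uv_per_bit)
    matrix = ints.astype(float) * config.uv_per_bit
    gt = GroundTruth(
        spike_times_s=spike_times,
        site_amplitudes_uV=site_amps,
        states=states,
        noise_rms_uV=config.noise_rms_uV,
        n_clipped=n_clipped,
    )
    return matrix, gt


def default_neurons(
    layout: ProbeLayout,
    n_neurons: int,
    seed: int | np.random.Generator = 0,
    rate_up_hz: tuple[float, float] = (2.0, 10.0),
    rate_down_hz: float = 0.0,
    amplitude_uV: tuple[float, float] = (120.0, 400.0),
    max_offset_um: float = 60.0,
    min_depth_um: float = 10.0,
    id_offset: int = 0,
) -> list[NeuronSpec]:
    """Scatter neurons around the site array, outside the shank volume.

    Lateral and longitudinal positions cover the site array plus a margin;
    the off-plane depth is at least ``min_depth_um`` in front of the
    sites, so no neuron sits inside the shank.  Amplitudes are log-uniform
    over the given range — a heavy single-unit band over the noise floor.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pos = layout.site_positions()
    y_lo, y_hi = pos[:, 1].min() - 30, pos[:, 1].max() + 30
    out = []
    for i in range(n_neurons):
        x = rng.uniform(-max_offset_um / 2,
                        layout.shank_width_um + max_offset_um / 2)
        y = rng.uniform(y_lo, y_hi)
        z = rng.uniform(min_depth_um, max_offset_um)
        amp = float(np.exp(rng.uniform(np.log(amplitude_uV[0]),
                                       np.log(amplitude_uV[1]))))
        out.append(NeuronSpec(
            neuron_id=id_offset + i,
            position_um=(float(x), float(y), float(z)),
            peak_amplitude_uV=amp,
            rate_up_hz=float(rng.uniform(*rate_up_hz)),
            rate_down_hz=rate_down_hz,
            template_id=i % 3,
        ))
    return out


def _background_neurons(layout: ProbeLayout, n: int,
                        rng: np.random.Generator,
                        id_offset: int) -> list[NeuronSpec]:
    """Distant, small-amplitude, high-rate multiunit background.

    Sized so the summed-MUA envelope rises well above the noise baseline
    in up states, as it does in vivo."""
    return default_neurons(
        layout, n, rng,
        rate_up_hz=(20.0, 60.0),
        amplitude_uV=(20.0, 90.0),
        max_offset_um=120.0,
        min_depth_um=30.0,
        id_offset=id_offset,
    )


def cortical_population(
    layout: ProbeLayout,
    seed: int | np.random.Generator = 0,
    n_single: int = 30,
    n_background: int = 400,
) -> list[NeuronSpec]:
    """Sortable single units plus a distant multiunit background.

    Cortical up states are marked by vigorous population firing well beyond
    the handful of sortable nearby cells; the background component — many
    farther, small-amplitude, higher-rate neurons — reproduces the
    sustained up-state elevation of the summed multiunit activity that
    slow-wave state detection relies on, while staying silent in down
    states.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    single = default_neurons(layout, n_single, rng)
    background = _background_neurons(layout, n_background, rng,
                                     id_offset=n_single)
    return single + background


def amplitude_population(
    layout: ProbeLayout,
    seed: int | np.random.Generator = 0,
    n_neurons: int = 1200,
    n_background: int = 400,
) -> list[NeuronSpec]:
    """A numerous, sparsely firing population for amplitude-distribution
    experiments.

    Cortical firing rates are lognormal-sparse: most cells fire well below
    1 Hz, and a recording site senses hundreds of them.  For the binomial
    threshold scan this matters — when a handful of high-rate cells
    dominate a channel, their spike trains form persistent correlated
    clusters of beyond-threshold samples, and an ``edge_gain`` of 1.0 is
    then not a true null for the sample-level binomial statistic.  Many
    neurons contributing a few spikes each keep the channels statistically
    exchangeable, so the gain alone sets the edge-vs-center effect size.
    The multiunit background component again carries the slow-wave
    envelope.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dense = default_neurons(
        layout, n_neurons, rng,
        rate_up_hz=(0.05, 0.5),
        amplitude_uV=(80.0, 350.0),
        max_offset_um=80.0,
    )
    background = _background_neurons(layout, n_background, rng,
                                     id_offset=n_neurons)
    return dense + background


def write_simulation(matrix: np.ndarray, config: SimConfig,
                     ground_truth: GroundTruth,
                     out_dir: str | Path) -> dict[str, Path]:
    """Write the recording (flat int16 + sidecar) and ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bin_path, meta_path, _ = write_recording(
        matrix, out / "recording", config.sampling_rate_hz,
        config.uv_per_bit, config.layout.probe_name,
        config.layout.channel_order())
    spikes = pd.DataFrame(
        [(nid, t) for nid, ts in ground_truth.spike_times_s.items()
         for t in ts],
        columns=["neuron_id", "time_s"],
    )
    spikes.to_csv(out / "spikes.csv", index=False)
    amps = pd.DataFrame(
        {nid: a for nid, a in ground_truth.site_amplitudes_uV.items()}
    )
    amps.insert(0, "site_id", config.layout.channel_order())
    amps.to_csv(out / "site_amplitudes.csv", index=False)
    states = pd.DataFrame(ground_truth.states,
                          columns=["start_s", "end_s", "label"])
    states.to_csv(out / "states.csv", index=False)
    return {
        "bin": bin_path,
        "meta": meta_path,
        "spikes": out / "spikes.csv",
        "site_amplitudes": out / "site_amplitudes.csv",
        "states": out / "states.csv",
    }
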