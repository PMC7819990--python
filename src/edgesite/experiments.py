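"""Canonical synthetic-recording experiments.

These functions fix the study conditions under which the pipeline's
statistical behavior is characterized: recovery of a known edge-gain
effect, false-positive behavior under the exact null, and noise-floor
recovery at known noise levels.  Tests, reproduction scripts and examples
all call the same entry points so the conditions cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import amplitude as amp
from . import noise as noise_mod
from . import preprocess as pre
from .probes import build_layout, classify_edge_center, split_recording
from .synth import (
    NeuronSpec,
    SimConfig,
    amplitude_population,
    cortical_population,
    generate_recording,
)

__all__ = [
    "ScanExperimentResult",
    "edge_center_scan_experiment",
    "noise_recovery_experiment",
]


@dataclass
class ScanExperimentResult:
    rms_edge_uV: float
    rms_center_uV: float
    threshold_negative_uV: float | None
    n_significant_negative: int
    pct_edge: float | None
    pct_center: float | None

    @property
    def effect_detected(self) -> bool:
        """Edge power above center power and a significant negative
        threshold found."""
        return (self.rms_edge_uV > self.rms_center_uV
                and self.threshold_negative_uV is not None)


def edge_center_scan_experiment(
    seed: int,
    edge_gain: float = 1.3,
    duration_s: float = 60.0,
    noise_rms_uV: float = 5.0,
    probe: str = "neuronexus32",
) -> ScanExperimentResult:
    """One seeded recording -> edge/center RMS and the negative scan.

    A sparse-firing population (so ``edge_gain = 1`` is a true null for
    the binomial scan) is simulated for ``duration_s``, split into edge
    and center groups, band-passed, subsampled and scanned.
    """
    layout = build_layout(probe)
    rng = np.random.default_rng(seed)
    neurons = amplitude_population(layout, rng)
    sim = SimConfig(
        duration_s=duration_s,
        layout=layout,
        neurons=neurons,
        noise_rms_uV=noise_rms_uV,
        edge_gain=edge_gain,
        seed=int(rng.integers(2 ** 31)),
    )
    matrix, _ = generate_recording(sim)
    grouping = classify_edge_center(layout)
    parts = split_recording(matrix, layout, grouping, equalize=True)
    pools = {
        label: pre.subsample_pool(
            pre.bandpass(sub, sim.sampling_rate_hz), group_label=label)
        for label, sub in parts.items()
    }
    edge = np.concatenate([p.samples_uV for l, p in pools.items()
                           if l.startswith("edge")])
    center = pools["center"].samples_uV
    scan = amp.cumulative_scan(edge, center, "negative")
    return ScanExperimentResult(
        rms_edge_uV=amp.rms(edge),
        rms_center_uV=amp.rms(center),
        threshold_negative_uV=scan.threshold_edge_uV,
        n_significant_negative=int(scan.sig_edge.sum()),
        pct_edge=scan.pct_edge,
        pct_center=scan.pct_center,
    )


def noise_recovery_experiment(
    sigma_uV: float,
    seed: int,
    duration_s: float = 40.0,
    probe: str = "neuronexus32",
    amplitude_scale: float = 1.0,
) -> tuple[float, float, int]:
    """Estimate the noise floor of a silent-down-state simulation.

    Returns ``(estimated_mean_rms, band_limited_truth, n_windows)``.  The
    truth is the injected white-noise RMS attenuated by the zero-phase
    band-pass power fraction.  ``amplitude_scale`` multiplies every
    neuron's spike amplitude (spike times and noise are unchanged), for
    robustness checks of the estimator against up-state spike power.
    """
    layout = build_layout(probe)
    rng = np.random.default_rng(seed)
    neurons = cortical_population(layout, rng)
    if amplitude_scale != 1.0:
        neurons = [
            NeuronSpec(n.neuron_id, n.position_um,
                       n.peak_amplitude_uV * amplitude_scale,
                       n.rate_up_hz, n.rate_down_hz, n.template_id)
            for n in neurons
        ]
    sim = SimConfig(
        duration_s=duration_s,
        layout=layout,
        neurons=neurons,
        noise_rms_uV=sigma_uV,
        seed=int(rng.integers(2 ** 31)),
    )
    matrix, _ = generate_recording(sim)
    fs = sim.sampling_rate_hz
    mua = pre.rectify(pre.bandpass(matrix, fs))
    env = noise_mod.smooth_envelope(noise_mod.summed_mua(mua), fs)
    seg = noise_mod.detect_states(env, fs)
    est = noise_mod.estimate_noise(mua, seg)
    truth = sigma_uV * np.sqrt(pre.zero_phase_power_fraction(fs))
    return est.mean_rms_uV, truth, est.n_windows
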