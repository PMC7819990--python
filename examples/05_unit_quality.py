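"""Compute single-unit quality metrics on ground-truth sorted spikes.

The generator's spike times act as a perfect sorting; units are built by
averaging 2 ms waveform windows, then screened with the well-isolation
criteria (refractory violations < 2%, rate > 0.05 Hz or >= 100 spikes,
peak-to-peak amplitude > 60 uV on the best channel).  Isolation distance
measures cluster separation as the n-th closest non-cluster spike's
squared Mahalanobis distance.
"""

from edgesite import (
    SimConfig,
    build_layout,
    cortical_population,
    generate_recording,
)
from edgesite.units import (
    compute_quality,
    compute_isolation_distances,
    isolation_features,
    select_well_isolated,
    units_from_sorting,
)

layout = build_layout("neuronexus32")
config = SimConfig(
    duration_s=30.0,
    layout=layout,
    neurons=cortical_population(layout, seed=3, n_single=12,
                                n_background=200),
    noise_rms_uV=4.0,
    seed=3,
)
matrix, truth = generate_recording(config)

# perfect sorting for the 12 sortable single units
spikes = {nid: t for nid, t in truth.spike_times_s.items() if nid < 12}
units = units_from_sorting(matrix, config.sampling_rate_hz, spikes,
                           group_label="all")
qualities = [compute_quality(u) for u in units]
kept = select_well_isolated(units, qualities)
print(f"{len(kept)} of {len(units)} ground-truth units pass the "
      "well-isolation criteria\n")

features = isolation_features(matrix, config.sampling_rate_hz, spikes)
iso = compute_isolation_distances(features)
print("unit  spikes  rate(Hz)  p2p(uV)  refr.%  isolation  kept")
kept_ids = {u.unit_id for u in kept}
for u, q in zip(units, qualities):
    iso_txt = f"{iso[u.unit_id]:8.1f}" if iso[u.unit_id] else "     n/a"
    print(f"{u.unit_id:4d}  {u.n_spikes:6d}  {u.firing_rate_hz:7.2f}  "
          f"{q.p2p_uV:7.1f}  {100 * q.refractory_fraction:5.2f}  "
          f"{iso_txt}  {'yes' if u.unit_id in kept_ids else 'no'}")
print("\nUnits fail mostly on amplitude: distant neurons' spikes decay"
      "\nbelow the 60 uV floor before reaching the probe.")
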