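"""Estimate the in vivo noise floor from slow-wave down states.

Cortical populations fall silent for hundreds of milliseconds during the
down states of anesthesia-induced slow waves.  The estimator rectifies
the band-passed signal, sums it across channels, smooths it at 50 Hz,
thresholds the envelope into up/down states, and takes the RMS of a 50 ms
window centered in every down state of at least 200 ms.  On synthetic
recordings with a known injected noise level the estimate can be compared
with the band-limited truth.
"""

from edgesite.experiments import noise_recovery_experiment

print("sigma (uV)  estimate (uV RMS)  band-limited truth  error   windows")
for sigma in (2.0, 4.0, 8.0):
    est, truth, n_windows = noise_recovery_experiment(sigma, seed=0)
    print(f"{sigma:8.1f}  {est:14.3f}  {truth:14.3f}  "
          f"{100 * (est / truth - 1):+6.2f}%  {n_windows:5d}")
print("\nThe estimate tracks the injected noise across levels; on real"
      "\nrecordings it runs above a saline measurement because residual"
      "\ndistant activity remains in the down states.")
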