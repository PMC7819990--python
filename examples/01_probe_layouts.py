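"""Build probe layouts and split a recording by site position.

Each built-in layout models one of five single-shank planar probes; sites
are classified as edge (outermost columns, a few um from the shank edge)
or center (middle columns).  Splitting a multichannel matrix by group,
with equalization, reproduces the per-position recording files used in
edge-vs-center comparisons: note the 12-site center column of the 32-site
probe is trimmed to 10 channels to match its edge files.
"""

import numpy as np

from edgesite import build_layout, classify_edge_center, split_recording

for name in ("neuronexus32", "neuroseeker128", "neuroseeker255",
             "neuropixels70", "neuropixels50"):
    layout = build_layout(name)
    cols = sorted(len(v) for v in layout.columns.values())
    print(f"{name:15s} {layout.n_sites:3d} sites, "
          f"{len(layout.columns):2d} columns {cols}, "
          f"shank {layout.shank_width_um:.0f} um wide")

layout = build_layout("neuronexus32")
grouping = classify_edge_center(layout)
recording = np.zeros((1000, layout.n_sites))  # [time x channel]
parts = split_recording(recording, layout, grouping, equalize=True)
print("\n32-site probe split (equalized):")
for label, sub in parts.items():
    print(f"  {label:10s} -> {sub.shape[1]} channels")
print(f"  (center column holds {len(grouping.groups['center'])} sites "
      "before trimming)")
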