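"""Planar silicon-probe geometries and recording-site grouping.

Five built-in single-shank layouts are provided, spanning shank widths from
50 to 125 um, all with sites both near the shank edge and in its center:

``neuronexus32``
    32 circular sites (177 um^2) in three equidistant columns of 10/12/10,
    50 um center-to-center pitch, 125 um x 50 um shank cross-section.
``neuroseeker128``
    128 square 20 um x 20 um sites in four columns of 32, 2.5 um gaps
    (22.5 um pitch), 100 um x 50 um shank.  The oversized internal-reference
    pad above the array is not part of the 128 recorded channels and is not
    modeled.
``neuroseeker255``
    255 square 5 um x 5 um sites in a dense 17-row x 15-column grid with
    6 um pitch, 100 um x 50 um shank.
``neuropixels70`` / ``neuropixels50``
    384 square 12 um x 12 um sites in a checkerboard of 4 staggered columns
    (two sites per 20 um row), 40 um same-column vertical spacing; 70 um and
    50 um shank widths respectively.

Coordinates: ``x_um`` is lateral distance from the left shank edge, ``y_um``
is longitudinal distance from the probe tip, both in micrometers.
Recordings are channel-ordered by ``site_id`` ascending unless a channel map
says otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SiteSpec",
    "ProbeLayout",
    "SiteGrouping",
    "BUILTIN_PROBES",
    "build_layout",
    "classify_edge_center",
    "per_column_grouping",
    "split_recording",
    "longitudinal_grouping",
    "load_layout_json",
    "layout_to_json",
]

#: a column whose site boundary is within this many um of the shank edge is
#: an edge column (covers the built-in probes' 5-6.25 um margins)
EDGE_MARGIN_RULE_UM = 10.0


@dataclass(frozen=True)
class SiteSpec:
    """One recording site on the shank plane."""

    site_id: int
    x_um: float
    y_um: float
    area_um2: float
    role: str = "recording"  # or "internal_reference"
    functional: bool = True

    @property
    def half_extent_um(self) -> float:
        """Half of the site's lateral extent (square-equivalent)."""
        return math.sqrt(self.area_um2) / 2.0


@dataclass
class ProbeLayout:
    """Site geometry of a single-shank planar probe."""

    probe_name: str
    shank_width_um: float
    shank_thickness_um: float
    sites: list[SiteSpec]
    columns: dict[int, list[int]]  # column index -> site_ids ordered by y
    edge_margin_um: float

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate site_id in layout")
        for s in self.sites:
            if not (0.0 <= s.x_um <= self.shank_width_um):
                raise ValueError(
                    f"site {s.site_id}: x={s.x_um} um outside shank "
                    f"[0, {self.shank_width_um}]"
                )
        in_cols = [sid for col in self.columns.values() for sid in col]
        if sorted(in_cols) != sorted(ids):
            raise ValueError("columns must partition the layout's sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, site_id: int) -> SiteSpec:
        return self._by_id[site_id]

    @property
    def _by_id(self) -> dict[int, SiteSpec]:
        return {s.site_id: s for s in self.sites}

    def channel_of(self, site_id: int) -> int:
        """Channel index of a site (site_id-ascending channel order)."""
        order = sorted(s.site_id for s in self.sites)
        return order.index(site_id)

    def channel_order(self) -> list[int]:
        return sorted(s.site_id for s in self.sites)

    def site_positions(self) -> np.ndarray:
        """(n_sites, 2) array of (x, y) in channel order."""
        by = self._by_id
        return np.array(
            [[by[sid].x_um, by[sid].y_um] for sid in self.channel_order()]
        )

    def edge_columns(self) -> list[int]:
        """Column indices whose site boundaries lie near a shank edge."""
        out = []
        by = self._by_id
        for ci, sids in self.columns.items():
            xs = [by[s].x_um for s in sids]
            he = max(by[s].half_extent_um for s in sids)
            left = min(xs) - he
            right = self.shank_width_um - (max(xs) + he)
            if left <= EDGE_MARGIN_RULE_UM or right <= EDGE_MARGIN_RULE_UM:
                out.append(ci)
        return sorted(out)

    def center_columns(self) -> list[int]:
        """The middle column (odd column count) or middle two (even)."""
        cols = sorted(self.columns)
        k = len(cols)
        if k % 2 == 1:
            return [cols[k // 2]]
        return [cols[k // 2 - 1], cols[k // 2]]


@dataclass
class SiteGrouping:
    """Disjoint site groups plus the sites excluded from every group."""

    scheme: str  # edge_center | per_column | longitudinal
    groups: dict[str, list[int]]
    excluded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, sids in self.groups.items():
            overlap = seen.intersection(sids)
            if overlap:
                raise ValueError(f"groups not disjoint: {sorted(overlap)}")
            seen.update(sids)
            bad = self.excluded.intersection(sids)
            if bad:
                raise ValueError(
                    f"excluded sites present in group {label!r}: {sorted(bad)}"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


# ---------------------------------------------------------------------------
# built-in layouts


def _neuronexus32() -> ProbeLayout:
    # three equidistant columns (10 / 12 / 10), circular 15-um sites,
    # 50 um pitch; center column lowest site 100 um from the tip, edge
    # columns staggered by half a pitch (poly3 arrangement)
    area = 177.0
    width = 125.0
    radius = 7.5
    x_left = 5.0 + radius
    x_center = width / 2.0
    x_right = width - 5.0 - radius
    sites: list[SiteSpec] = []
    columns: dict[int, list[int]] = {0: [], 1: [], 2: []}
    sid = 0
    for k in range(10):  # left edge column
        sites.append(SiteSpec(sid, x_left, 125.0 + 50.0 * k, area))
        columns[0].append(sid)
        sid += 1
    for k in range(12):  # center column
        sites.append(SiteSpec(sid, x_center, 100.0 + 50.0 * k, area))
        columns[1].append(sid)
        sid += 1
    for k in range(10):  # right edge column
        sites.append(SiteSpec(sid, x_right, 125.0 + 50.0 * k, area))
        columns[2].append(sid)
        sid += 1
    return ProbeLayout("neuronexus32", width, 50.0, sites, columns, 5.0)


def _neuroseeker(n_cols: int, n_rows: int, pitch: float, site_um: float,
                 name: str, y0: float = 300.0) -> ProbeLayout:
    width = 100.0
    area = site_um * site_um
    span = (n_cols - 1) * pitch + site_um
    x0 = (width - span) / 2.0 + site_um / 2.0
    sites: list[SiteSpec] = []
    columns: dict[int, list[int]] = {c: [] for c in range(n_cols)}
    sid = 0
    for c in range(n_cols):
        for r in range(n_rows):
            sites.append(SiteSpec(sid, x0 + c * pitch, y0 + r * pitch, area))
            columns[c].append(sid)
            sid += 1
    margin = x0 - site_um / 2.0
    return ProbeLayout(name, width, 50.0, sites, columns, margin)


def _neuroseeker128() -> ProbeLayout:
    return _neuroseeker(4, 32, 22.5, 20.0, "neuroseeker128")


def _neuroseeker255() -> ProbeLayout:
    return _neuroseeker(15, 17, 6.0, 5.0, "neuroseeker255")


def _neuropixels(width: float, row_pitch_um: float, stagger_um: float,
                 n_rows: int, y0: float, name: str) -> ProbeLayout:
    # checkerboard: two sites per row, alternate rows offset laterally;
    # 4 nominal column positions, 40 um same-column vertical spacing
    site_um = 12.0
    area = site_um * site_um
    gap = 5.0
    x_first = gap + site_um / 2.0
    # column x positions: even rows use columns 0 and 2, odd rows 1 and 3
    xcol = [x_first, x_first + stagger_um,
            x_first + row_pitch_um, x_first + row_pitch_um + stagger_um]
    sites: list[SiteSpec] = []
    columns: dict[int, list[int]] = {c: [] for c in range(4)}
    sid = 0
    for r in range(n_rows):
        cols = (0, 2) if r % 2 == 0 else (1, 3)
        for c in cols:
            sites.append(SiteSpec(sid, xcol[c], y0 + 20.0 * r, area))
            columns[c].append(sid)
            sid += 1
    return ProbeLayout(name, width, 20.0, sites, columns, gap)


def _neuropixels70() -> ProbeLayout:
    return _neuropixels(70.0, 32.0, 16.0, 192, 195.0, "neuropixels70")


def _neuropixels50() -> ProbeLayout:
    return _neuropixels(50.0, 21.0, 7.0, 192, 137.0, "neuropixels50")


BUILTIN_PROBES = {
    "neuronexus32": _neuronexus32,
    "neuroseeker128": _neuroseeker128,
    "neuroseeker255": _neuroseeker255,
    "neuropixels70": _neuropixels70,
    "neuropixels50": _neuropixels50,
}


def build_layout(probe_name: str | Path) -> ProbeLayout:
    """Return a built-in layout by name, or load a layout JSON file.

    Parameters
    ----------
    probe_name
        One of ``BUILTIN_PROBES`` or a path to a layout JSON file (native
        or probeinterface-style).
    """
    key = str(probe_name)
    if key in BUILTIN_PROBES:
        return BUILTIN_PROBES[key]()
    p = Path(probe_name)
    if p.suffix == ".json" or p.exists():
        return load_layout_json(p)
    raise ValueError(
        f"unknown probe {probe_name!r}; expected one of "
        f"{sorted(BUILTIN_PROBES)} or a JSON layout path"
    )


# ---------------------------------------------------------------------------
# grouping


def _reference_neighbors(layout: ProbeLayout, ref_ids: set[int]) -> set[int]:
    """Sites in the same row or an adjacent row of a reference site."""
    ys = sorted({s.y_um for s in layout.sites})
    neighbors: set[int] = set()
    for rid in ref_ids:
        ry = layout.site(rid).y_um
        i = ys.index(ry)
        rows = {ys[j] for j in (i - 1, i, i + 1) if 0 <= j < len(ys)}
        neighbors.update(
            s.site_id for s in layout.sites if s.y_um in rows
        )
    return neighbors - ref_ids


def classify_edge_center(
    layout: ProbeLayout,
    bad_sites: Iterable[int] = (),
    reference_sites: Iterable[int] = (),
    omit_groups: Iterable[str] = (),
    exclude_reference_neighbors: bool | None = None,
) -> SiteGrouping:
    """Label sites as edge (outermost columns) or center (middle columns).

    A column is an edge column when its site boundaries lie within 10 um of
    a lateral shank edge; center sites are those of the middle column (odd
    column count) or the middle two columns.  For the dense 17x15 grid this
    picks the 8th column as the center group.  Bad sites, internal reference
    sites and (for checkerboard Neuropixels-style layouts) the reference
    sites' same/adjacent-row neighbors are excluded.

    Parameters
    ----------
    omit_groups
        Group labels (``edge_left``, ``edge_right``, ``center``) to drop
        entirely, e.g. an edge column dominated by unfunctional channels.
    exclude_reference_neighbors
        Defaults to True for Neuropixels-style layouts, else False.
    """
    bad = set(bad_sites)
    refs = set(reference_sites)
    refs.update(s.site_id for s in layout.sites
                if s.role == "internal_reference")
    bad.update(s.site_id for s in layout.sites if not s.functional)
    if exclude_reference_neighbors is None:
        exclude_reference_neighbors = layout.probe_name.startswith(
            "neuropixels")
    excluded = bad | refs
    if refs and exclude_reference_neighbors:
        excluded |= _reference_neighbors(layout, refs)

    edge_cols = layout.edge_columns()
    center_cols = [c for c in layout.center_columns() if c not in edge_cols]
    by = layout._by_id

    def col_sites(cols: Sequence[int]) -> list[int]:
        sids = [sid for c in cols for sid in layout.columns[c]
                if sid not in excluded]
        return sorted(sids, key=lambda sid: (by[sid].y_um, sid))

    def side(ci: int) -> str:
        xs = [by[s].x_um for s in layout.columns[ci]]
        return "left" if np.mean(xs) < layout.shank_width_um / 2 else "right"

    omit = set(omit_groups)
    groups: dict[str, list[int]] = {}
    left_cols = [c for c in edge_cols if side(c) == "left"]
    right_cols = [c for c in edge_cols if side(c) == "right"]
    if "edge_left" not in omit and left_cols:
        groups["edge_left"] = col_sites(left_cols)
    if "edge_right" not in omit and right_cols:
        groups["edge_right"] = col_sites(right_cols)
    if "center" not in omit:
        groups["center"] = col_sites(center_cols)
    if not groups:
        raise ValueError("all groups omitted")
    for label, sids in groups.items():
        if not sids:
            raise ValueError(f"group {label!r} is empty after exclusions")
    # sites of omitted groups and of columns that are neither edge nor
    # center are excluded too, so groups + excluded partition the layout
    in_groups = {sid for sids in groups.values() for sid in sids}
    excluded |= {s.site_id for s in layout.sites
                 if s.site_id not in in_groups}
    return SiteGrouping("edge_center", groups, excluded)


def per_column_grouping(
    layout: ProbeLayout,
    bad_sites: Iterable[int] = (),
    reference_sites: Iterable[int] = (),
) -> SiteGrouping:
    """One group per site column, ordered left to right."""
    excluded = set(bad_sites) | set(reference_sites)
    excluded.update(s.site_id for s in layout.sites if not s.functional)
    excluded.update(s.site_id for s in layout.sites
                    if s.role == "internal_reference")
    by = layout._by_id
    groups = {}
    for ci in sorted(layout.columns):
        sids = [s for s in layout.columns[ci] if s not in excluded]
        groups[f"column_{ci + 1}"] = sorted(
            sids, key=lambda sid: (by[sid].y_um, sid))
    groups = {k: v for k, v in groups.items() if v}
    if not groups:
        raise ValueError("all columns empty after exclusions")
    return SiteGrouping("per_column", groups, excluded)


def longitudinal_grouping(
    layout: ProbeLayout,
    n_groups: int,
    bad_sites: Iterable[int] = (),
) -> SiteGrouping:
    """Group sites into ``n_groups`` bands by longitudinal (y) position.

    Group 1 is closest to the tip.  Rows that do not fill a whole band are
    dropped from the top of the shank.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    excluded = set(bad_sites)
    excluded.update(s.site_id for s in layout.sites if not s.functional)
    excluded.update(s.site_id for s in layout.sites
                    if s.role == "internal_reference")
    keep = [s for s in layout.sites if s.site_id not in excluded]
    rows = sorted({s.y_um for s in keep})
    rows_per_group = len(rows) // n_groups
    if rows_per_group == 0:
        raise ValueError("fewer site rows than requested groups")
    n_used = rows_per_group * n_groups
    dropped_rows = set(rows[n_used:])  # remainder dropped from the top
    excluded.update(s.site_id for s in keep if s.y_um in dropped_rows)
    groups: dict[str, list[int]] = {}
    for g in range(n_groups):
        band = set(rows[g * rows_per_group:(g + 1) * rows_per_group])
        sids = [s.site_id for s in keep if s.y_um in band]
        groups[f"long_{g + 1}"] = sorted(
            sids, key=lambda sid: (layout.site(sid).y_um, sid))
    return SiteGrouping("longitudinal", groups, excluded)


def split_recording(
    recording: np.ndarray,
    layout: ProbeLayout,
    grouping: SiteGrouping,
    equalize: bool = False,
) -> dict[str, np.ndarray]:
    """Split a [time x channel] matrix into one sub-matrix per site group.

    With ``equalize=True`` larger groups are trimmed symmetrically — sites
    removed alternately from the top and the bottom of the shank — down to
    the smallest group's channel count, emulating the construction of
    equal-channel recording files from unequal columns (e.g. a 10-channel
    file from a 12-site center column).
    """
    recording = np.asarray(recording)
    if recording.ndim != 2 or recording.shape[1] != layout.n_sites:
        raise ValueError(
            f"recording has {recording.shape[1] if recording.ndim == 2 else '?'}"
            f" channels but layout has {layout.n_sites} sites"
        )
    order = layout.channel_order()
    chan = {sid: i for i, sid in enumerate(order)}
    groups = {label: list(sids) for label, sids in grouping.groups.items()}
    if equalize:
        n_min = min(len(s) for s in groups.values())
        for label, sids in groups.items():
            extra = len(sids) - n_min
            # sids are ordered tip -> top; drop extra alternately from the
            # top and the bottom, starting at the top
            lo, hi = 0, len(sids)
            for i in range(extra):
                if i % 2 == 0:
                    hi -= 1
                else:
                    lo += 1
            groups[label] = sids[lo:hi]
    return {
        label: recording[:, [chan[sid] for sid in sids]]
        for label, sids in groups.items()
    }


# ---------------------------------------------------------------------------
# JSON I/O


def layout_to_json(layout: ProbeLayout, path: str | Path | None = None) -> dict:
    """Serialize a layout to the native JSON schema (optionally to a file)."""
    obj = {
        "probe_name": layout.probe_name,
        "shank_width_um": layout.shank_width_um,
        "shank_thickness_um": layout.shank_thickness_um,
        "edge_margin_um": layout.edge_margin_um,
        "columns": {str(k): v for k, v in layout.columns.items()},
        "sites": [
            {
                "site_id": s.site_id,
                "x_um": s.x_um,
                "y_um": s.y_um,
                "area_um2": s.area_um2,
                "role": s.role,
                "functional": s.functional,
            }
            for s in layout.sites
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=1))
    return obj


def _layout_from_probeinterface(obj: Mapping) -> ProbeLayout:
    probe = obj["probes"][0]
    pos = np.asarray(probe["contact_positions"], dtype=float)
    shapes = probe.get("contact_shape_params", [{}] * len(pos))
    areas = []
    for sp in shapes:
        if "radius" in sp:
            areas.append(math.pi * sp["radius"] ** 2)
        elif "width" in sp:
            areas.append(sp["width"] * sp.get("height", sp["width"]))
        else:
            areas.append(100.0)
    x = pos[:, 0]
    x0 = float(x.min())
    width = probe.get("probe_planar_contour_width")
    xs = sorted(set(np.round(x - x0, 3)))
    if width is None:
        width = float(x.max() - x0) + 2 * math.sqrt(max(areas))
    sites = [
        SiteSpec(i, float(x[i] - x0 + (width - (x.max() - x0)) / 2),
                 float(pos[i, 1] - pos[:, 1].min()), areas[i])
        for i in range(len(pos))
    ]
    shift = sites[0].x_um - xs[0]
    columns: dict[int, list[int]] = {}
    for s in sites:
        ci = int(np.argmin([abs(s.x_um - (v + shift)) for v in xs]))
        columns.setdefault(ci, []).append(s.site_id)
    name = probe.get("annotations", {}).get("name", "probeinterface")
    margin = min(min(s.x_um for s in sites),
                 width - max(s.x_um for s in sites))
    return ProbeLayout(name, float(width), probe.get("thickness_um", 20.0),
                       sites, columns, float(margin))


def load_layout_json(path: str | Path) -> ProbeLayout:
    """Load a layout from native or probeinterface-style JSON."""
    obj = json.loads(Path(path).read_text())
    if "probes" in obj:
        return _layout_from_probeinterface(obj)
    sites = [
        SiteSpec(
            int(s["site_id"]), float(s["x_um"]), float(s["y_um"]),
            float(s["area_um2"]), s.get("role", "recording"),
            bool(s.get("functional", True)),
        )
        for s in obj["sites"]
    ]
    if "columns" in obj:
        columns = {int(k): list(v) for k, v in obj["columns"].items()}
    else:  # infer columns from distinct x positions
        xs = sorted({s.x_um for s in sites})
        columns = {}
        for s in sites:
            columns.setdefault(xs.index(s.x_um), []).append(s.site_id)
    return ProbeLayout(
        obj["probe_name"],
        float(obj["shank_width_um"]),
        float(obj.get("shank_thickness_um", 20.0)),
        sites,
        columns,
        float(obj.get("edge_margin_um", min(
            min(s.x_um for s in sites),
            obj["shank_width_um"] - max(s.x_um for s in sites)))),
    )
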