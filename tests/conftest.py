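import numpy as np
import pytest

from edgesite.probes import ProbeLayout, SiteSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mini_layout(n_cols: int = 2, n_rows: int = 2,
                     pitch_um: float = 30.0,
                     width_um: float = 70.0) -> ProbeLayout:
    """A tiny user-defined layout for cheap simulation tests."""
    sites = []
    columns = {}
    sid = 0
    x0 = 5.0
    for c in range(n_cols):
        columns[c] = []
        for r in range(n_rows):
            sites.append(SiteSpec(sid, x0 + c * pitch_um,
                                  100.0 + r * pitch_um, 100.0))
            columns[c].append(sid)
            sid += 1
    return ProbeLayout("mini", width_um, 20.0, sites, columns, x0)


@pytest.fixture
def mini_layout():
    return make_mini_layout()
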