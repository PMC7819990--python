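"""Rank-based group statistics, effect sizes and the pipeline report."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from edgesite.amplitude import brown_forsythe
from edgesite.stats import (
    PipelineConfig,
    SummaryReport,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    run_pipeline,
)
from edgesite.synth import SimConfig, cortical_population
from conftest import make_mini_layout


# --- hand-rolled reference computations (independent of scipy's tests) ----

def ref_u_statistic(a, b):
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def ref_mw_exact_p(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = ref_u_statistic(a, b)
    mu = n1 * (len(b)) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = set(comb)
        aa = [pooled[i] for i in sel]
        bb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = ref_u_statistic(aa, bb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def ref_kruskal_h(groups):
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    i0 = 0
    for g in groups:
        r = ranks[i0:i0 + len(g)]
        h += r.sum() ** 2 / len(g)
        i0 += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / c


def ref_levene_median_f(groups):
    z = [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    k = len(z)
    n = sum(len(g) for g in z)
    zbar = np.concatenate(z).mean()
    num = sum(len(g) * (g.mean() - zbar) ** 2 for g in z) / (k - 1)
    den = sum(((g - g.mean()) ** 2).sum() for g in z) / (n - k)
    return num / den


def ref_dunn(groups):
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, i0 = [], 0
    for g in groups:
        mean_ranks.append(ranks[i0:i0 + len(g)].mean())
        i0 += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    k = len(groups)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            out.append((z, min(1.0, 2 * sps.norm.sf(abs(z)) * m)))
    return out


class TestMannWhitney:
    def test_identical_groups_null(self):
        x = list(range(1, 11))
        res = mann_whitney(x, x)
        assert res.p_value > 0.9
        assert abs(res.effect_size_r) < 0.05

    def test_separated_groups_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = mann_whitney(a, b)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(ref_mw_exact_p(a, b), abs=1e-12)

    def test_effect_size_is_z_over_sqrt_n(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 1, size=25)
        res = mann_whitney(a, b)
        assert res.effect_size_r == pytest.approx(
            res.z_score / np.sqrt(55), abs=1e-12)

    def test_z_sign_convention(self):
        res = mann_whitney([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert res.z_score > 0  # first group stochastically larger

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        g = list(range(10))
        res = kruskal_wallis([g, g, g])
        assert res.p_value > 0.99

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis([[1, 2], [3, 4]])

    def test_h_statistic_matches_rank_formula(self, rng):
        groups = [rng.normal(i, 1, size=12) for i in range(3)]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(ref_kruskal_h(groups),
                                              abs=1e-8)
        assert res.p_value == pytest.approx(
            sps.chi2.sf(res.statistic, 2), abs=1e-12)


class TestDunn:
    def test_pair_count(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        assert len(dunn_posthoc(groups)) == 6

    def test_identical_groups_all_corrected_to_one(self):
        g = list(np.arange(10.0))
        out = dunn_posthoc([g, g, g])
        assert all(c.p_value == 1.0 for c in out)

    def test_three_group_fixture_matches_hand_formula(self):
        groups = [[1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0, 8.0],
                  [10.0, 11.0, 12.0, 13.0]]
        out = dunn_posthoc(groups)
        expected = ref_dunn(groups)
        for got, (z, p) in zip(out, expected):
            assert got.z_score == pytest.approx(z, abs=1e-8)
            assert got.p_value == pytest.approx(p, abs=1e-8)

    def test_warns_without_significant_omnibus(self, rng):
        groups = [list(rng.normal(size=6)) for _ in range(3)]
        with pytest.warns(UserWarning, match="significant"):
            dunn_posthoc(groups, kruskal_p=0.8)


class TestCrossValidation:
    def test_fifty_random_fixtures_match_references(self):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            sizes = rng.integers(5, 25, size=3)
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                                 size=s) for s in sizes]
            # Mann-Whitney on the first two groups
            mw = mann_whitney(groups[0], groups[1])
            assert mw.statistic == pytest.approx(
                ref_u_statistic(groups[0], groups[1]), abs=1e-8)
            sp = sps.mannwhitneyu(groups[0], groups[1],
                                  alternative="two-sided")
            # same U as scipy's first-sample statistic
            assert mw.statistic == pytest.approx(float(sp.statistic),
                                                 abs=1e-8)
            # Kruskal-Wallis
            kw = kruskal_wallis(groups)
            assert kw.statistic == pytest.approx(ref_kruskal_h(groups),
                                                 abs=1e-8)
            # Brown-Forsythe
            bf = brown_forsythe(groups[0], groups[1])
            assert bf.brown_forsythe_F == pytest.approx(
                ref_levene_median_f(groups[:2]), abs=1e-8)
            # Dunn
            for got, (z, p) in zip(dunn_posthoc(groups), ref_dunn(groups)):
                assert got.z_score == pytest.approx(z, abs=1e-8)
                assert got.p_value == pytest.approx(p, abs=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_effect_size_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3),
                       size=rng.integers(2, 40))
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3),
                       size=rng.integers(2, 40))
        res = mann_whitney(a, b)
        assert abs(res.effect_size_r) <= 1.0


class TestPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_config():
        lay = make_mini_layout(n_cols=3, n_rows=4, pitch_um=25.0,
                               width_um=80.0)
        sim = SimConfig(duration_s=8.0, layout=lay,
                        neurons=cortical_population(lay, seed=4,
                                                    n_single=10,
                                                    n_background=60),
                        noise_rms_uV=4.0, edge_gain=1.2, seed=11)
        return PipelineConfig(sim=sim)

    def test_report_structure(self, small_config):
        rep = run_pipeline(small_config)
        assert set(rep["rms_uV"]) == {"edge", "center"}
        assert rep["brown_forsythe"]["n_edge"] > 0
        assert {"negative", "positive"} <= set(rep["scan"])
        assert rep["provenance"]["config_hash"]

    def test_determinism_and_roundtrip(self, small_config, tmp_path):
        r1 = run_pipeline(small_config, out_dir=tmp_path)
        r2 = run_pipeline(small_config)
        assert r1.to_json() == r2.to_json()
        back = SummaryReport.from_json(tmp_path / "report.json")
        assert back.to_json() == r1.to_json()  # byte-stable round trip
        import pandas as pd
        scan = pd.read_csv(tmp_path / "tables" / "scan_negative.csv")
        assert len(scan) == 100

    def test_disk_route_matches_sim_route(self, small_config, tmp_path):
        from edgesite.synth import generate_recording, write_simulation
        rep_sim = run_pipeline(small_config)
        mat, gt = generate_recording(small_config.sim)
        write_simulation(mat, small_config.sim, gt, tmp_path)
        import json
        lay_path = tmp_path / "layout.json"
        from edgesite.probes import layout_to_json
        layout_to_json(small_config.sim.layout, lay_path)
        cfg = PipelineConfig(recording_path=str(tmp_path / "recording"),
                             probe=str(lay_path), analyze_units=False)
        rep_disk = run_pipeline(cfg)
        assert rep_disk["rms_uV"] == rep_sim["rms_uV"]
        assert rep_disk["scan"] == rep_sim["scan"]

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError, match="sim or recording_path"):
            run_pipeline(PipelineConfig())
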