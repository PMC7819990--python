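"""Single-unit quality metrics, selection and the unit-amplitude scan."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from edgesite.synth import SimConfig, cortical_population, generate_recording
from edgesite.units import (
    UnitRecord,
    compute_quality,
    isolation_distance,
    load_phy_sorting,
    p2p_amplitude,
    refractory_fraction,
    select_well_isolated,
    unit_amplitude_scan,
    unit_yield,
    units_from_sorting,
    units_table,
)


def make_unit(n_spikes, duration_s, p2p=100.0, isi_s=0.010,
              group="edge_left", rec="r0", uid=0):
    """A unit with a clean biphasic waveform and regular spike train."""
    t = np.arange(n_spikes) * isi_s + 0.1
    wf = np.zeros((4, 40))
    wf[1, 18] = -p2p * 0.7
    wf[1, 25] = p2p * 0.3
    return UnitRecord(uid, t, wf, duration_s, group_label=group,
                      recording_id=rec)


class TestRefractory:
    def test_regular_train_no_violations(self):
        t = np.arange(100) * 0.010
        assert refractory_fraction(t) == 0.0

    def test_counting_convention(self):
        t = np.arange(100) * 0.010
        t[50] = t[49] + 0.001  # a single 1 ms ISI
        assert refractory_fraction(np.sort(t)) == pytest.approx(0.01)

    def test_few_spikes_zero_by_convention(self):
        assert refractory_fraction(np.array([1.0])) == 0.0
        assert refractory_fraction(np.array([])) == 0.0


class TestP2P:
    def test_trough_to_positive_peak(self):
        wf = np.zeros((1, 30))
        wf[0, 10] = -80.0
        wf[0, 20] = 30.0
        value, best = p2p_amplitude(wf)
        assert value == 110.0
        assert best == 0

    def test_best_channel_argmax(self):
        wf = np.zeros((2, 30))
        wf[0, 10], wf[0, 20] = -20.0, 20.0  # p2p 40
        wf[1, 10], wf[1, 20] = -60.0, 35.0  # p2p 95
        value, best = p2p_amplitude(wf)
        assert (value, best) == (95.0, 1)

    def test_positive_bump_measured_from_baseline(self):
        wf = np.full((1, 30), 0.0)
        wf[0, 15] = 50.0
        with pytest.warns(UserWarning, match="no trough"):
            value, _ = p2p_amplitude(wf)
        assert value == 50.0

    def test_all_zero_waveform(self):
        value, _ = p2p_amplitude(np.zeros((2, 30)))
        assert value == 0.0


class TestSelection:
    DUR = 1800.0

    def test_amplitude_boundary_strict(self):
        # 55 uV and exactly 60 uV rejected, 61 uV kept
        for p2p, kept in [(55.0, False), (60.0, False), (61.0, True)]:
            u = make_unit(9000, self.DUR, p2p=p2p)
            assert compute_quality(u).well_isolated is kept

    def test_rate_or_count_criterion(self):
        # 120 spikes in 1800 s: 0.067 Hz > 0.05 -> kept
        assert compute_quality(make_unit(120, self.DUR)).well_isolated
        # 90 spikes in 1800 s: 0.05 Hz exactly, < 100 spikes -> rejected
        assert not compute_quality(make_unit(90, self.DUR)).well_isolated
        # 100 spikes in 10000 s: 0.01 Hz but >= 100 spikes -> kept
        assert compute_quality(make_unit(100, 10_000.0)).well_isolated

    def test_refractory_criterion(self):
        u = make_unit(970, self.DUR)
        doublets = u.spike_times_s[:30] + 0.001  # 30 of 1000 ISIs at 1 ms
        u.spike_times_s = np.sort(
            np.concatenate([u.spike_times_s, doublets]))
        q = compute_quality(u)
        assert q.refractory_fraction >= 0.02
        assert not q.well_isolated

    def test_select_filters_list(self):
        good = make_unit(1000, self.DUR, p2p=100.0, uid=1)
        bad = make_unit(1000, self.DUR, p2p=40.0, uid=2)
        kept = select_well_isolated([good, bad])
        assert [u.unit_id for u in kept] == [1]


class TestIsolationDistance:
    def test_brute_force_oracle(self, rng):
        cluster = rng.normal(0, 1, size=(60, 3))
        other = rng.normal(0, 4, size=(200, 3))
        got = isolation_distance(cluster, other)
        # independent path: scipy cdist Mahalanobis + explicit sort
        vi = np.linalg.inv(np.cov(cluster, rowvar=False))
        d = cdist(other, cluster.mean(axis=0)[None, :],
                  metric="mahalanobis", VI=vi).ravel()
        expected = np.sort(d ** 2)[cluster.shape[0] - 1]
        assert got == pytest.approx(expected, abs=1e-8)

    def test_undefined_when_too_few_others(self, rng):
        cluster = rng.normal(size=(50, 3))
        other = rng.normal(size=(49, 3))
        assert isolation_distance(cluster, other) is None

    def test_affine_invariance(self, rng):
        cluster = rng.normal(0, 1, size=(40, 4))
        other = rng.normal(0, 3, size=(120, 4))
        base = isolation_distance(cluster, other)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        mapped = isolation_distance(cluster @ A + b, other @ A + b)
        assert mapped == pytest.approx(base, rel=1e-8)

    def test_monotone_in_other_spike_distance(self, rng):
        cluster = rng.normal(0, 1, size=(40, 3))
        other = rng.normal(0, 2, size=(100, 3))
        values = [isolation_distance(cluster, other * s)
                  for s in (1.0, 1.5, 2.0, 3.0)]
        assert values == sorted(values)

    def test_singular_covariance_regularized(self, rng):
        cluster = np.zeros((30, 3))
        cluster[:, 0] = rng.normal(size=30)  # rank-deficient
        other = rng.normal(0, 5, size=(60, 3))
        value = isolation_distance(cluster, other)
        assert value is not None and value > 0


class TestUnitScan:
    def test_identical_multisets_null(self, rng):
        amps = rng.uniform(70, 300, size=200)
        units_a = [make_unit(500, 600.0, p2p=a, uid=i)
                   for i, a in enumerate(amps)]
        units_b = [make_unit(500, 600.0, p2p=a, uid=i)
                   for i, a in enumerate(amps)]
        res = unit_amplitude_scan(units_a, units_b)
        assert not res.sig_edge.any()
        assert res.thresholds_uV[0] == 60.0

    def test_shifted_edge_amplitudes_detected(self, rng):
        base = rng.uniform(70, 250, size=500)
        edge = [make_unit(500, 600.0, p2p=a + 40.0, uid=i)
                for i, a in enumerate(base)]
        center = [make_unit(500, 600.0, p2p=a, uid=i)
                  for i, a in enumerate(base)]
        res = unit_amplitude_scan(edge, center)
        assert res.sig_edge.any()
        assert res.threshold_edge_uV is not None
        # brute-force check of one significant threshold's p-value
        from scipy import stats as sps
        i = int(np.flatnonzero(res.sig_edge)[0])
        x = res.thresholds_uV[i]
        amps_e = np.array([p2p_amplitude(u.mean_waveform_uV)[0]
                           for u in edge])
        amps_c = np.array([p2p_amplitude(u.mean_waveform_uV)[0]
                           for u in center])
        k_e, k_c = int((amps_e > x).sum()), int((amps_c > x).sum())
        n = k_e + k_c
        p = float(sps.binom.pmf(np.arange(k_e, n + 1), n, 0.5).sum())
        assert res.p_edge_direction[i] == pytest.approx(p, abs=1e-10)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            unit_amplitude_scan([], [make_unit(10, 60.0)])


class TestYield:
    def test_empty(self):
        assert unit_yield([]).empty

    def test_counts_per_recording_and_group(self):
        units = (
            [make_unit(10, 60.0, group="edge_left", rec="r0", uid=i)
             for i in range(3)]
            + [make_unit(10, 60.0, group="center", rec="r0", uid=i)
               for i in range(2)]
            + [make_unit(10, 60.0, group="center", rec="r1", uid=9)]
        )
        table = unit_yield(units)
        lookup = {(r, g): n for r, g, n in table.itertuples(index=False)}
        assert lookup == {("r0", "edge_left"): 3, ("r0", "center"): 2,
                          ("r1", "center"): 1}


class TestUnitsTable:
    def test_one_row_per_unit_with_metrics(self):
        units = [make_unit(1000, 600.0, p2p=120.0, uid=1),
                 make_unit(50, 600.0, p2p=30.0, uid=2, group="center")]
        table = units_table(units, isolation={1: 12.5, 2: None})
        assert len(table) == 2
        row = table.set_index("unit_id").loc[1]
        assert row["well_isolated"]
        assert row["isolation_distance"] == 12.5
        assert not table.set_index("unit_id").loc[2, "well_isolated"]


class TestGroundTruthRecovery:
    def test_injected_strong_units_are_retained(self, mini_layout):
        cfg = SimConfig(duration_s=30.0, layout=mini_layout,
                        neurons=cortical_population(mini_layout, seed=3,
                                                    n_single=6,
                                                    n_background=40),
                        noise_rms_uV=3.0, seed=9)
        mat, gt = generate_recording(cfg)
        units = units_from_sorting(mat, cfg.sampling_rate_hz,
                                   gt.spike_times_s, group_label="all")
        qualities = [compute_quality(u) for u in units]
        kept_ids = {u.unit_id for u in select_well_isolated(units,
                                                            qualities)}
        for u, q in zip(units, qualities):
            if (q.refractory_fraction < 0.02 and q.p2p_uV > 60
                    and (q.firing_rate_hz > 0.05 or u.n_spikes >= 100)):
                assert u.unit_id in kept_ids
        assert kept_ids  # at least one strong unit recovered


class TestPhyLoader:
    def test_npy_and_csv_dialects(self, tmp_path, rng):
        times = np.sort(rng.integers(0, 20_000, size=50))
        clusters = rng.integers(0, 3, size=50)
        np.save(tmp_path / "spike_times.npy", times)
        np.save(tmp_path / "spike_clusters.npy", clusters)
        by_cluster = load_phy_sorting(tmp_path, 20_000.0)
        assert sum(len(v) for v in by_cluster.values()) == 50
        import pandas as pd
        csv_dir = tmp_path / "csv"
        csv_dir.mkdir()
        pd.DataFrame({"cluster": clusters,
                      "time_s": times / 20_000.0}).to_csv(
            csv_dir / "spikes.csv", index=False)
        by_cluster2 = load_phy_sorting(csv_dir, 20_000.0)
        for cid in by_cluster:
            np.testing.assert_allclose(by_cluster[cid], by_cluster2[cid])
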