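import numpy as np
import pandas as pd
import pytest

from minidials.reflections import OUTLIER, ReflectionTable
from minidials.scale import (
    ScaleParams,
    ScalingError,
    delta_cc_half,
    exclude_images,
    merge_stats,
    refine_error_model_arrays,
    resolution_limit,
    scale_and_filter,
    scale_datasets,
)
from minidials.simulate import SimConfig, simulate_intensity_tables


def tiny_table(I_pairs):
    """One unique reflection per pair of observations."""
    rows = []
    for u, obs in enumerate(I_pairs):
        for i in obs:
            rows.append({"h": u + 1, "k": 0, "l": 0, "id": 0,
                         "intensity_sum_value": float(i),
                         "intensity_sum_variance": 1.0,
                         "d": 3.0 + 0.01 * u, "z_frame": 0.5,
                         "phi_deg": 0.5})
    return ReflectionTable(pd.DataFrame(rows))


class TestMergeFormulas:
    def test_hand_example_two_observations(self):
        # observations 10 and 12 of one reflection
        t = tiny_table([[10.0, 12.0]])
        st = merge_stats(t, n_bins=1, seed=0)
        assert st.overall["r_merge"] == pytest.approx(2.0 / 22.0)
        assert st.overall["r_meas"] == pytest.approx(np.sqrt(2) * 2.0 / 22.0)
        assert st.overall["r_pim"] == pytest.approx(np.sqrt(1.0) * 2.0 / 22.0)

    def test_duplicated_halves_give_cc_one(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(50, 40)
        t = tiny_table([[v, v] for v in vals])
        # force one observation of each pair into each half
        labels = np.tile([0, 1], 40)
        st = merge_stats(t, n_bins=1, seed=0, half_labels=labels)
        assert st.overall["cc_half"] == pytest.approx(1.0)

    def test_r_ordering(self):
        cfg = SimConfig(space_group="P222", n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=5)
        st = merge_stats(tables[0], n_bins=5, space_group="P222", seed=1)
        assert st.overall["r_merge"] <= st.overall["r_meas"]
        assert st.overall["r_pim"] <= st.overall["r_meas"]
        b = st.bins.dropna(subset=["r_meas"])
        assert np.all(b["r_merge"] <= b["r_meas"] + 1e-12)
        assert np.all(b["r_pim"] <= b["r_meas"] + 1e-12)

    def test_cc_half_reproducible_and_stable(self):
        cfg = SimConfig(space_group="P222", n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=5)
        a = merge_stats(tables[0], space_group="P222", seed=3).overall["cc_half"]
        b = merge_stats(tables[0], space_group="P222", seed=3).overall["cc_half"]
        assert a == b
        across = [merge_stats(tables[0], space_group="P222", seed=s
                              ).overall["cc_half"] for s in range(6)]
        assert np.std(across) < 0.02

    def test_full_p1_sphere_complete(self):
        from minidials.model import A_from_cell_orientation
        from minidials.predict import enumerate_hkl

        cell = (20.0, 22.0, 24.0, 90.0, 90.0, 90.0)
        A = A_from_cell_orientation(cell, np.eye(3))
        hkl = enumerate_hkl(A, 4.0)
        d = 1.0 / np.linalg.norm(hkl @ A.T, axis=1)
        df = pd.DataFrame({
            "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "id": 0,
            "intensity_sum_value": 100.0, "intensity_sum_variance": 10.0,
            "d": d, "z_frame": 0.0, "phi_deg": 0.0,
        })
        st = merge_stats(ReflectionTable(df), n_bins=1, space_group="P1",
                         cell=cell, d_min=4.0, seed=0)
        assert st.overall["completeness"] == pytest.approx(1.0)


class TestScaling:
    def test_null_model_recovery(self):
        cfg = SimConfig(space_group="P222", scale_amplitude=0.0)
        tables, truth = simulate_intensity_tables(cfg, seed=3)
        scaled, models = scale_datasets(tables, ScaleParams(space_group="P222"))
        phi = tables[0]["phi_deg"]
        assert np.abs(models[0].k_of_phi(phi) - 1).max() < 0.02
        assert np.abs(models[0].B_of_phi(phi)).max() < 0.5

    def test_sinusoidal_scale_recovery(self):
        cfg = SimConfig(space_group="P222")
        tables, truth = simulate_intensity_tables(cfg, seed=7)
        scaled, models = scale_datasets(tables, ScaleParams(space_group="P222"))
        phi = tables[0]["phi_deg"]
        s2 = 1.0 / (4.0 * tables[0]["d"] ** 2)
        g_true = truth.inverse_scale(phi, s2, 0)
        g_fit = scaled[0]["inverse_scale"]
        assert np.corrcoef(g_fit, g_true)[0, 1] > 0.99

    def test_gauge_times_seven(self):
        cfg = SimConfig(space_group="P222", scale_amplitude=0.0)
        tables, truth = simulate_intensity_tables(cfg, seed=9)
        t2 = tables[0].copy()
        t2["intensity_sum_value"] = t2["intensity_sum_value"] * 7.0
        t2["intensity_sum_variance"] = t2["intensity_sum_variance"] * 49.0
        _, m1 = scale_datasets([tables[0]], ScaleParams(space_group="P222"))
        _, m2 = scale_datasets([t2], ScaleParams(space_group="P222"))
        phi = tables[0]["phi_deg"]
        assert np.allclose(m1[0].k_of_phi(phi), m2[0].k_of_phi(phi), atol=0.01)

    def test_empty_raises(self):
        t = tiny_table([[1.0, 2.0]])
        t.set_flags(np.ones(len(t), bool), OUTLIER)
        with pytest.raises(ScalingError):
            scale_datasets([t], ScaleParams())


class TestErrorModel:
    def _make(self, n_uniq=400, mult=6, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        true = rng.exponential(2000.0, n_uniq)
        I, sig, uniq = [], [], []
        for u, t in enumerate(true):
            for _ in range(mult):
                counts = rng.poisson(max(t, 0))
                v = counts * (1 + jitter * rng.standard_normal())
                I.append(v)
                sig.append(np.sqrt(max(t, 1)))
                uniq.append(u)
        return np.array(I), np.array(sig), np.array(uniq)

    def test_pure_poisson(self):
        I, sig, uniq = self._make()
        a, b = refine_error_model_arrays(I, sig, uniq)
        assert abs(a - 1.0) < 0.1
        assert b < 0.01

    def test_multiplicative_jitter_recovered(self):
        I, sig, uniq = self._make(jitter=0.05, seed=1)
        a, b = refine_error_model_arrays(I, sig, uniq)
        assert abs(b - 0.05) / 0.05 < 0.4

    def test_sigma_scale_equivariance(self):
        I, sig, uniq = self._make(seed=2)
        a1, _ = refine_error_model_arrays(I, sig, uniq)
        a2, _ = refine_error_model_arrays(I, 2.0 * sig, uniq)
        assert a2 == pytest.approx(a1 / 2.0, rel=0.1)

    def test_all_singletons_degenerate(self):
        I = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning):
            a, b = refine_error_model_arrays(I, np.sqrt(I), np.arange(10))
        assert (a, b) == (1.0, 0.0)


class TestResolutionLimit:
    def _stats_from_curve(self, cc_of_s, n_bins=12, smin=0.1, smax=0.5):
        edges_s = np.linspace(smin, smax, n_bins + 1)
        rows = []
        for i in range(n_bins):
            s_mid = 0.5 * (edges_s[i] + edges_s[i + 1])
            rows.append({"d_max": 1 / edges_s[i], "d_min": 1 / edges_s[i + 1],
                         "cc_half": cc_of_s(s_mid), "bin": i})
        from minidials.scale import MergeStats

        return MergeStats(overall={}, bins=pd.DataFrame(rows))

    def test_always_high_flags_no_crossing(self):
        st = self._stats_from_curve(lambda s: 0.99)
        d, flag = resolution_limit(st)
        assert flag == "no crossing"
        assert d == pytest.approx(2.0, rel=0.01)  # 1/s_max

    def test_exact_crossing_at_known_s(self):
        # construct a tanh curve crossing 0.3 at s = 0.4 exactly
        c0, s0, r = 1.0, 0.35, 0.08
        s_cross = s0 + r * np.arctanh(1 - 0.6 / c0)
        shift = 0.4 - s_cross

        def curve(s):
            return c0 / 2 * (1 - np.tanh((s - (s0 + shift)) / r))

        st = self._stats_from_curve(curve)
        d, flag = resolution_limit(st)
        assert flag == ""
        assert d == pytest.approx(2.5, rel=0.02)

    def test_noise_robustness(self):
        c0, s0, r = 1.0, 0.35, 0.08
        s_cross = s0 + r * np.arctanh(1 - 0.6 / c0)
        shift = 0.4 - s_cross
        rng = np.random.default_rng(0)

        def noisy(s):
            return (c0 / 2 * (1 - np.tanh((s - (s0 + shift)) / r))
                    + rng.normal(0, 0.02))

        st = self._stats_from_curve(noisy)
        d, flag = resolution_limit(st)
        assert abs(d - 2.5) / 2.5 < 0.05


class TestDeltaCCHalf:
    def test_clean_datasets_near_zero(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=4, seed=2)
        deltas, cc_all = delta_cc_half(tables, seed=1, space_group="P222")
        assert len(deltas) == 4
        assert max(abs(d) for _, d in deltas) < 0.01

    def test_scrambled_dataset_most_negative(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=5, seed=3,
                                                  outlier=True)
        deltas, _ = delta_cc_half(tables, seed=1, space_group="P222")
        worst = min(deltas, key=lambda t: t[1])
        assert worst[0] == truth.outlier_dataset
        assert worst[1] < -0.008

    def test_remove_and_readd_reproduces(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=3, seed=4)
        _, cc1 = delta_cc_half(tables, seed=9, space_group="P222")
        _, cc2 = delta_cc_half(tables, seed=9, space_group="P222")
        assert cc1 == cc2


class TestScaleAndFilter:
    def test_clean_input_one_cycle(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=4, seed=6)
        kept, ids, history = scale_and_filter(
            tables, ScaleParams(space_group="P222"), seed=1)
        assert len(history) == 1
        assert history[0].removed is None
        assert len(kept) == 4

    def test_planted_outlier_removed_then_converges(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=5, seed=7,
                                                  outlier=True)
        kept, ids, history = scale_and_filter(
            tables, ScaleParams(space_group="P222"), seed=1)
        removed = [h.removed for h in history if h.removed is not None]
        assert removed == [truth.outlier_dataset]
        assert truth.outlier_dataset not in ids

    def test_removal_guard(self):
        cfg = SimConfig(space_group="P222", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=4, seed=8)
        kept, ids, history = scale_and_filter(
            tables, ScaleParams(space_group="P222"), seed=1)
        assert history[-1].frac_removed <= 0.3


class TestExcludeImages:
    def _table(self):
        cfg = SimConfig(space_group="P222", n_images=180)
        tables, _ = simulate_intensity_tables(cfg, seed=10)
        return tables[0]

    def test_exclusion_range_semantics(self):
        t = self._table()
        t2 = exclude_images(t, 0, 101, 120)
        img = np.floor(t["z_frame"]).astype(int) + 1
        inside = (img >= 101) & (img <= 120)
        assert np.array_equal(t2.get_flags(OUTLIER), inside)

    def test_out_of_scan_noop(self):
        t = self._table()
        with pytest.warns(UserWarning):
            t2 = exclude_images(t, 0, 500, 600)
        assert not t2.get_flags(OUTLIER).any()

    def test_exclude_everything_then_scaling_fails(self):
        t = self._table()
        t2 = exclude_images(t, 0, 1, 180)
        with pytest.raises(ScalingError, match="no observations"):
            scale_datasets([t2], ScaleParams(space_group="P222"))
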