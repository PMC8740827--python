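import numpy as np
import pandas as pd
import pytest

from minidials.post import (
    MergedDataset,
    build_report,
    centric_flags,
    export_hklf4,
    export_unmerged_text,
    format_cell_esd,
    french_wilson,
    merge,
    read_hklf4,
    read_unmerged_text,
    two_theta_refine,
    validate_report,
    write_report,
)
from minidials.reflections import ReflectionTable
from minidials.simulate import SimConfig, simulate_intensity_tables


class TestFrenchWilson:
    def test_strong_signal_limit(self):
        F, sF = french_wilson([10000.0], [1.0], [1e9])
        assert F[0] == pytest.approx(100.0, abs=1e-3)
        assert sF[0] == pytest.approx(1.0 / (2 * 100.0), rel=0.05)

    def test_negative_intensity_positive_amplitude(self):
        F, _ = french_wilson([-5.0], [2.0], [100.0])
        assert F[0] > 0

    def test_monotone_in_intensity(self):
        I = np.linspace(-10, 50, 40)
        F, _ = french_wilson(I, np.full_like(I, 2.0), np.full_like(I, 80.0))
        assert np.all(np.diff(F) > -1e-9)

    def test_matches_fine_quadrature_oracle(self):
        sig = 3.0
        worst = 0.0
        for ios in (-2, -0.5, 0.5, 2, 5, 20, 100):
            for ioS in (0.01, 0.1, 1.0):
                I = ios * sig
                Sigma = max(abs(I), sig) / ioS
                for centric in (False, True):
                    F1, _ = french_wilson([I], [sig], [Sigma], centric)
                    F2, _ = french_wilson([I], [sig], [Sigma], centric,
                                          n_points=20000)
                    worst = max(worst, abs(F1[0] - F2[0]) / F2[0])
        assert worst < 1e-4

    def test_bad_sigma_raises(self):
        with pytest.raises(ValueError):
            french_wilson([10.0], [0.0], [100.0])


class TestMerge:
    def _scaled_table(self):
        cfg = SimConfig(space_group="P222", n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=2)
        t = tables[0]
        t["inverse_scale"] = np.ones(len(t))
        return t, truth

    def test_single_observation_mean(self):
        df = pd.DataFrame({
            "h": [1], "k": [2], "l": [3], "id": [0],
            "intensity_sum_value": [42.0], "intensity_sum_variance": [4.0],
            "d": [3.0],
        })
        md = merge(ReflectionTable(df))
        assert md.df["I"].iloc[0] == pytest.approx(42.0)
        assert md.df["multiplicity"].iloc[0] == 1

    def test_weighted_mean_hand_example(self):
        # (10, sigma 1) and (30, sigma 3) -> (10/1 + 30/9)/(1/1 + 1/9) = 12
        df = pd.DataFrame({
            "h": [1, 1], "k": [0, 0], "l": [0, 0], "id": [0, 0],
            "intensity_sum_value": [10.0, 30.0],
            "intensity_sum_variance": [1.0, 9.0],
            "d": [3.0, 3.0],
        })
        md = merge(ReflectionTable(df))
        assert md.df["I"].iloc[0] == pytest.approx(12.0)

    def test_multiplicities_conserve_observations(self):
        t, truth = self._scaled_table()
        md = merge(t, space_group="P222")
        assert md.df["multiplicity"].sum() == len(t)

    def test_amplitudes_positive(self):
        t, truth = self._scaled_table()
        md = merge(t, space_group="P222")
        assert (md.df["F"] > 0).all()
        assert (md.df["sigF"] >= 0).all()

    def test_centric_flags(self):
        # P222: reflections on the (0, k, l) style planes are centric
        hkl = np.array([[0, 2, 3], [1, 2, 3], [4, 0, 2], [1, 1, 1]])
        flags = centric_flags(hkl, "P222")
        assert list(flags) == [True, False, True, False]
        assert not centric_flags(hkl, "P1").any()


class TestExporters:
    def test_hklf4_layout(self, tmp_path):
        md = MergedDataset(
            df=pd.DataFrame({"h": [1], "k": [2], "l": [3], "I": [216.0],
                             "sigI": [14.7], "F": [1.0], "sigF": [0.1],
                             "multiplicity": [1], "centric": [False],
                             "d": [3.0]}),
            space_group="P1", anomalous=False)
        path = tmp_path / "out.hkl"
        export_hklf4(md, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "   1   2   3  216.00   14.70"
        assert lines[-1] == "   0   0   0    0.00    0.00"

    def test_hklf4_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 50
        df = pd.DataFrame({
            "h": rng.integers(-20, 20, n), "k": rng.integers(-20, 20, n),
            "l": rng.integers(-20, 20, n),
            "I": rng.uniform(-10, 5000, n).round(2),
            "sigI": rng.uniform(0.5, 60, n).round(2),
            "F": np.ones(n), "sigF": np.ones(n),
            "multiplicity": np.ones(n, dtype=int),
            "centric": np.zeros(n, dtype=bool), "d": np.full(n, 3.0),
        })
        md = MergedDataset(df=df, space_group="P1", anomalous=False)
        path = tmp_path / "rt.hkl"
        export_hklf4(md, path)
        back = read_hklf4(path)
        assert np.allclose(back["I"], df["I"], atol=0.01)
        assert np.allclose(back["sigI"], df["sigI"], atol=0.01)
        assert np.array_equal(back[["h", "k", "l"]], df[["h", "k", "l"]])

    def test_hklf4_overflow(self, tmp_path):
        md = MergedDataset(
            df=pd.DataFrame({"h": [1000], "k": [0], "l": [0], "I": [1.0],
                             "sigI": [1.0], "F": [1.0], "sigF": [1.0],
                             "multiplicity": [1], "centric": [False],
                             "d": [1.0]}),
            space_group="P1", anomalous=False)
        with pytest.raises(ValueError, match="overflow"):
            export_hklf4(md, tmp_path / "x.hkl")

    def test_unmerged_text_round_trip_statistics(self, tmp_path):
        from minidials.model import Experiment
        from minidials.scale import merge_stats

        cfg = SimConfig(space_group="P222", n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=5)
        t = tables[0]
        t["inverse_scale"] = np.ones(len(t))
        e = Experiment()
        path = tmp_path / "unmerged.txt"
        export_unmerged_text(t, e, path, cell=truth.cell, symmetry="P222")
        df, header = read_unmerged_text(path)
        assert len(df) == len(t)
        assert header["symmetry"] == "P222"
        # re-merging the exported data reproduces the statistics bit for bit
        t2 = ReflectionTable(pd.DataFrame({
            "h": df["h"], "k": df["k"], "l": df["l"], "id": 0,
            "intensity_sum_value": df["I"],
            "intensity_sum_variance": df["sigI"] ** 2,
            "d": df["d"], "z_frame": df["batch"] - 1, "phi_deg": df["phi"],
        }))
        s1 = merge_stats(t, space_group="P222", seed=3).overall
        s2 = merge_stats(t2, space_group="P222", seed=3).overall
        assert s1["cc_half"] == pytest.approx(s2["cc_half"], abs=1e-9)
        assert s1["r_meas"] == pytest.approx(s2["r_meas"], abs=1e-9)

    def test_deterministic_bytes(self, tmp_path):
        md = MergedDataset(
            df=pd.DataFrame({"h": [1, 2], "k": [0, 1], "l": [0, 1],
                             "I": [5.0, 6.0], "sigI": [1.0, 1.0],
                             "F": [1.0, 2.0], "sigF": [0.1, 0.1],
                             "multiplicity": [1, 1],
                             "centric": [False, False], "d": [3.0, 2.9]}),
            space_group="P1", anomalous=False)
        export_hklf4(md, tmp_path / "a.hkl")
        export_hklf4(md, tmp_path / "b.hkl")
        assert (tmp_path / "a.hkl").read_bytes() == (tmp_path / "b.hkl").read_bytes()


class TestTwoTheta:
    def test_exact_data_fixed_point(self):
        from minidials.simulate import (build_experiment,
                                        generate_ground_truth,
                                        predict_reflections)

        cfg = SimConfig(space_group="P4")
        truth = generate_ground_truth(cfg, seed=2)
        expt = build_experiment(cfg, U=truth.U_list[0])
        pred = predict_reflections(expt, cfg.d_min)
        pred.df["x_px"] = pred["x_cal_px"]
        pred.df["y_px"] = pred["y_cal_px"]
        res = two_theta_refine(pred, expt, system="tetragonal")
        assert np.allclose(res.cell[:3], truth.cell[:3], atol=1e-4)
        assert res.cell[0] == res.cell[1]
        assert res.cell[3:] == (90.0, 90.0, 90.0)
        assert max(res.esd) < 1e-6

    def test_esd_shrinks_with_n(self):
        from minidials.simulate import (build_experiment,
                                        generate_ground_truth,
                                        predict_reflections)

        rng = np.random.default_rng(4)
        cfg = SimConfig(space_group="P4")
        truth = generate_ground_truth(cfg, seed=2)
        expt = build_experiment(cfg, U=truth.U_list[0])
        pred = predict_reflections(expt, cfg.d_min)
        pred.df["x_px"] = pred["x_cal_px"] + rng.normal(0, 0.3, len(pred))
        pred.df["y_px"] = pred["y_cal_px"] + rng.normal(0, 0.3, len(pred))
        esds = []
        for n in (200, 1800):
            sub = pred.select(np.arange(n))
            res = two_theta_refine(sub, expt, system="tetragonal")
            esds.append(res.esd[0])
        ratio = esds[0] / esds[1]
        assert 2.0 < ratio < 4.5  # ~ sqrt(9) = 3

    def test_too_few_observations(self):
        from minidials.simulate import (build_experiment,
                                        generate_ground_truth,
                                        predict_reflections)

        cfg = SimConfig(space_group="P4")
        truth = generate_ground_truth(cfg, seed=2)
        expt = build_experiment(cfg, U=truth.U_list[0])
        pred = predict_reflections(expt, cfg.d_min)
        pred.df["x_px"] = pred["x_cal_px"]
        pred.df["y_px"] = pred["y_cal_px"]
        with pytest.raises(ValueError):
            two_theta_refine(pred.select(np.arange(5)), expt)


class TestEsdFormat:
    @pytest.mark.parametrize("value,esd,expect", [
        (57.75947, 0.00004, "57.75947(4)"),
        (149.88010, 0.00014, "149.88010(14)"),
        (90.01671, 0.00005, "90.01671(5)"),
    ])
    def test_parenthesis_notation(self, value, esd, expect):
        assert format_cell_esd(value, esd) == expect


class TestReport:
    def test_incremental_sections(self):
        rep = build_report(spotfinding={"n_spots": 10,
                                        "per_image_spot_count": [[1, 2]]})
        assert "spotfinding" in rep and "scaling" not in rep
        assert validate_report(rep) == []

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError):
            build_report(bogus={"x": 1})

    def test_schema_validation(self, tmp_path):
        rep = build_report(refinement={"rmsd_x_mm": "oops"})
        assert validate_report(rep)
        with pytest.raises(ValueError):
            write_report(rep, tmp_path / "r.json")

    def test_full_pipeline_report_valid(self, pipeline_result, tmp_path):
        rep = pipeline_result["report"]
        assert validate_report(rep) == []
        write_report(rep, tmp_path / "report.json")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["format"] == "minidials-report"
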