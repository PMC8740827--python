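import numpy as np
import pytest

from minidials.integrate import (
    ProfileModel,
    build_reference_profiles,
    estimate_background,
    estimate_profile_params,
    extract_shoeboxes,
    integrate,
    integrate_prf,
    integrate_sum,
    predict_and_box,
    _region_of,
)
from minidials.reflections import (
    INTEGRATED_SUM,
    MASK_BACKGROUND,
    MASK_FOREGROUND,
    PARTIAL,
    Shoebox,
)
from minidials.simulate import (
    SimConfig,
    build_experiment,
    generate_ground_truth,
    render_images,
)


def make_shoebox(fg_counts, bg_counts, fg_shape=(3, 3, 3), pad=1):
    """Cuboid with a foreground core of ``fg_counts`` per pixel surrounded
    by a ring of ``bg_counts`` per pixel."""
    nz, ny, nx = (s + 2 * pad for s in fg_shape)
    data = np.full((nz, ny, nx), float(bg_counts))
    mask = np.full((nz, ny, nx), MASK_BACKGROUND, dtype=np.int8)
    core = (slice(pad, pad + fg_shape[0]), slice(pad, pad + fg_shape[1]),
            slice(pad, pad + fg_shape[2]))
    data[core] = fg_counts
    mask[core] = MASK_FOREGROUND
    return Shoebox(bbox=(0, nx, 0, ny, 0, nz), data=data, mask=mask)


class TestBackground:
    def test_flat_background_unbiased(self):
        rng = np.random.default_rng(0)
        box = make_shoebox(0, 0, fg_shape=(3, 3, 3), pad=2)
        bg_sel = box.mask == MASK_BACKGROUND
        box.data[bg_sel] = rng.poisson(2.0, bg_sel.sum())
        _, b, _ = estimate_background(box)
        n = bg_sel.sum()
        assert abs(b - 2.0) <= 3 * np.sqrt(2.0 / n) + 0.2

    def test_hot_pixel_rejected(self):
        rng = np.random.default_rng(1)
        box = make_shoebox(0, 0, pad=2)
        bg_sel = box.mask == MASK_BACKGROUND
        box.data[bg_sel] = rng.poisson(2.0, bg_sel.sum())
        zz, yy, xx = np.argwhere(bg_sel)[0]
        clean_mean = box.data[bg_sel].mean()
        box.data[zz, yy, xx] = 1e6
        _, b, _ = estimate_background(box)
        assert abs(b - clean_mean) < 0.5

    def test_all_zero_background(self):
        box = make_shoebox(10, 0, pad=2)
        _, b, _ = estimate_background(box)
        assert b == 0.0

    def test_too_few_background_pixels(self):
        box = make_shoebox(5, 1, fg_shape=(3, 3, 3), pad=0)
        box.mask[:] = MASK_FOREGROUND
        with pytest.raises(ValueError):
            estimate_background(box)


class TestSummation:
    def test_arithmetic_identity(self):
        # 27 foreground px of 10 counts, b_hat = 2 -> I = 270 - 54 = 216
        box = make_shoebox(10, 2)
        I, var = integrate_sum(box, 2.0)
        assert I == pytest.approx(216.0)
        n_fg, n_bg = 27, (box.mask == MASK_BACKGROUND).sum()
        assert var == pytest.approx(270 + 54 * (1 + n_fg / n_bg))
        assert var > 0

    def test_linearity(self):
        box1 = make_shoebox(10, 2)
        box2 = make_shoebox(20, 4)
        I1, _ = integrate_sum(box1, 2.0)
        I2, _ = integrate_sum(box2, 4.0)
        assert I2 == pytest.approx(2 * I1)

    def test_zero_signal_unbiased(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(200):
            box = make_shoebox(0, 0, pad=2)
            box.data[:] = rng.poisson(3.0, box.data.shape)
            _, b, _ = estimate_background(box)
            I, _ = integrate_sum(box, b)
            vals.append(I)
        n_fg = 27
        sem = np.sqrt(200 * n_fg * 3.0) / 200 * 3  # generous 3 sigma
        assert abs(np.mean(vals)) < max(sem, 2.0)


@pytest.fixture(scope="module")
def noiseless_run():
    """Simulation with no background/noise and truth geometry, integrated."""
    cfg = SimConfig(space_group="P222", n_images=60, background=0.0,
                    scale_amplitude=0.0, wilson_scale=5000.0)
    truth = generate_ground_truth(cfg, seed=12)
    expt = build_experiment(cfg, U=truth.U_list[0])
    stack, _ = render_images(expt, truth, seed=12, noise=False)
    pm = ProfileModel(sigma_b=truth.sigma_b, sigma_m=truth.sigma_m)
    table, _ = integrate(expt, stack, profile_model=pm, d_min=cfg.d_min,
                         keep_shoeboxes=True)
    return cfg, truth, expt, pm, table


class TestProfileFitting:
    def test_prf_equals_sum_in_noiseless_limit(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        ok = (table.get_flags(INTEGRATED_SUM)
              & ~table.get_flags(PARTIAL)
              & (table["intensity_sum_value"] > 100))
        refs = build_reference_profiles(table, pm, expt)
        rel = []
        for i in np.flatnonzero(ok)[:40]:
            row = table.df.iloc[i]
            box = table.shoeboxes[i]
            ref = refs[_region_of(row, expt.detector)]
            # self-referenced fit: build the reference from this reflection
            from minidials.integrate import _scatter_to_grid, _angular_pixel_scale

            px_deg, _ = _angular_pixel_scale(expt)
            grid = _scatter_to_grid(box, row, pm.sigma_b / px_deg, pm.sigma_m,
                                    expt.scan, box.data)
            p_self = np.maximum(grid, 0)
            p_self /= p_self.sum()
            I_prf, _ = integrate_prf(box, 0.0, p_self, row, pm, expt)
            # compare against summation with the same (zero) background
            I_sum, _ = integrate_sum(box, 0.0)
            rel.append(abs(I_prf - I_sum) / I_sum)
        assert max(rel) < 1e-6

    def test_reference_profile_shape(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        refs = build_reference_profiles(table, pm, expt)
        for p in refs:
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
        # marginal standard deviations ~ 1 sigma in normalized units
        p = refs[4]  # central region
        cells = (np.arange(9) + 0.5) / 9 * 6 - 3  # cell centres, sigma units
        for ax in range(3):
            marg = p.sum(axis=tuple(i for i in range(3) if i != ax))
            mu = (cells * marg).sum()
            sd = np.sqrt(((cells - mu) ** 2 * marg).sum())
            assert 0.8 < sd < 1.25

    def test_low_overlap_raises_for_clipped_box(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        i = int(np.flatnonzero(table.get_flags(INTEGRATED_SUM))[0])
        box = table.shoeboxes[i]
        row = table.df.iloc[i]
        # keep only the low-x half of the shoebox; put all reference mass
        # in the uncovered high-x cells
        x0, x1, y0, y1, z0, z1 = box.bbox
        half = max(1, (x1 - x0) // 3)
        clipped = Shoebox(
            bbox=(x0, x0 + half, y0, y1, z0, z1),
            data=box.data[:, :, :half].copy(),
            mask=box.mask[:, :, :half].copy(),
        )
        ref = np.zeros((9, 9, 9))
        ref[:, :, 8] = 1.0 / 81.0
        with pytest.raises(ValueError, match="overlap"):
            integrate_prf(clipped, 0.0, ref, row, pm, expt)


class TestProfileModelEstimation:
    def test_recovery_within_15_percent(self, default_sim, strong_spots,
                                        crystal_free_experiment):
        from dataclasses import replace

        from minidials.index import IndexParams, index

        cfg, truth, _, _ = default_sim
        crystals, table, _ = index(crystal_free_experiment, strong_spots,
                                   IndexParams())
        expt = replace(crystal_free_experiment, crystal=crystals[0])
        pm = estimate_profile_params(expt, table)
        assert abs(pm.sigma_b - truth.sigma_b) / truth.sigma_b < 0.15
        assert abs(pm.sigma_m - truth.sigma_m) / truth.sigma_m < 0.15

    def test_sigma_m_scaling_law(self):
        from dataclasses import replace

        from minidials.index import IndexParams, index
        from minidials.model import Experiment
        from minidials.spotfind import filter_spots, find_spots

        ests = []
        for sm in (0.3, 0.6):
            cfg = SimConfig(space_group="P222", sigma_m=sm, n_images=60)
            truth, expt, stack, _ = simulate_with(cfg, seed=8)
            e0 = Experiment(beam=expt.beam, goniometer=expt.goniometer,
                            detector=expt.detector, scan=expt.scan)
            table = filter_spots(find_spots(e0, stack), min_spot_size=3)
            crystals, tab, _ = index(e0, table, IndexParams())
            e1 = replace(e0, crystal=crystals[0])
            ests.append(estimate_profile_params(e1, tab).sigma_m)
        assert abs(ests[1] / ests[0] - 2.0) < 0.3

    def test_too_few_spots(self, default_sim, strong_spots,
                           crystal_free_experiment):
        with pytest.raises(ValueError):
            estimate_profile_params(crystal_free_experiment,
                                    strong_spots.select(np.arange(3)))


def simulate_with(cfg, seed):
    from minidials.simulate import simulate_dataset

    return simulate_dataset(cfg, seed=seed)


class TestBoxes:
    def test_central_third_geometry(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        # box half extent is n_sigma * sigma: the +-1 sigma core spans one
        # third of the foreground box on each axis
        assert pm.n_sigma == 3.0
        row = table.df.iloc[0]
        span_x = row.fg_x1 - row.fg_x0
        from minidials.integrate import _angular_pixel_scale

        px_deg, _ = _angular_pixel_scale(expt)
        sig_px = pm.sigma_b / px_deg
        assert span_x == pytest.approx(2 * 3 * sig_px, abs=2.0)

    def test_edge_boxes_flagged_partial(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        part = table.get_flags(PARTIAL)
        z = table["z_cal_frame"]
        near_edge = (z < 1.0) | (z > cfg.n_images - 1.0)
        assert part[near_edge].mean() > 0.9

    def test_box_volume_grows_with_sigma_m(self, noiseless_run):
        cfg, truth, expt, pm, table = noiseless_run
        pm2 = ProfileModel(sigma_b=pm.sigma_b, sigma_m=2 * pm.sigma_m)
        t1 = predict_and_box(expt, pm, cfg.d_min)
        t2 = predict_and_box(expt, pm2, cfg.d_min)
        dz1 = (t1["fg_z1"] - t1["fg_z0"]).mean()
        dz2 = (t2["fg_z1"] - t2["fg_z0"]).mean()
        assert dz2 > 1.5 * dz1
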