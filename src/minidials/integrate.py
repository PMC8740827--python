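"""Integration: profile-model estimation, background, summation and 3D
profile fitting.

The reflection extent is described by two angular widths: ``sigma_b`` (the
spread of the diffracted beam on the detector face, deg) and ``sigma_m``
(the rocking-curve / mosaic width, deg).  Shoeboxes extend +-n_sigma of
each width (n_sigma = 3, so the +-1 sigma core occupies the central one
third of the box on every axis) plus a ring of background pixels.

Profile fitting maps background-subtracted counts of strong reflections
onto a 9x9x9 grid in the normalized local frame ((x, y) in units of
sigma_b about the predicted position, phi in units of sigma_m), averaged
over a 3x3 grid of detector regions, and then scales the normalized
reference onto each reflection by weighted least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import predict as _predict
from .reflections import (
    INDEXED,
    INTEGRATED_PRF,
    INTEGRATED_SUM,
    MASK_BACKGROUND,
    MASK_FOREGROUND,
    MASK_INVALID,
    MASK_OVERLOADED,
    NO_BACKGROUND,
    OVERLOADED,
    PARTIAL,
    PRF_FALLBACK,
    STRONG,
    ReflectionTable,
    Shoebox,
)

N_SIGMA = 3.0
GRID_N = 9
N_REGIONS = 3  # 3x3 detector regions for reference profiles


@dataclass
class ProfileModel:
    sigma_b: float  # deg
    sigma_m: float  # deg
    n_sigma: float = N_SIGMA

    def __post_init__(self):
        if not (self.sigma_b > 0 and self.sigma_m > 0 and self.n_sigma > 0):
            raise ValueError("profile model parameters must be positive")


def _binned_gaussian_var(sigma, width, n_phase=33):
    """Phase-averaged variance of a Gaussian of sd ``sigma`` observed as
    bin-centre masses with bin width ``width`` about the weighted centroid.

    For fine bins this approaches sigma^2 + width^2/12 (Sheppard); for
    coarse bins the centroid quantization makes the simple correction
    biased, so the estimator inverts this exact forward map instead.
    """
    from scipy.special import ndtr

    half = int(math.ceil((4 * sigma + 2 * width) / width))
    edges = (np.arange(-half, half + 1) - 0.5) * width
    centres = 0.5 * (edges[:-1] + edges[1:])
    out = 0.0
    for theta in np.linspace(-0.5, 0.5, n_phase, endpoint=False):
        c = theta * width
        m = np.diff(ndtr((edges - c) / sigma))
        m /= m.sum()
        mu = (m * centres).sum()
        out += (m * (centres - mu) ** 2).sum()
    return out / n_phase


def _invert_binned_var(v_obs, width):
    """sigma such that the phase-averaged binned variance equals v_obs."""
    from scipy.optimize import brentq

    lo, hi = 1e-4, max(4.0 * math.sqrt(max(v_obs, 1e-8)), 5 * width)
    f = lambda s: _binned_gaussian_var(s, width) - v_obs
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return math.sqrt(max(v_obs - width**2 / 12.0, lo**2))
    return brentq(f, lo, hi, xtol=1e-6)


def _angular_pixel_scale(experiment):
    """Degrees subtended per pixel at the panel distance."""
    det = experiment.detector
    dist = abs(float(np.asarray(det.origin) @ det.normal))
    return math.degrees(det.pixel_size[0] / dist), dist


def estimate_profile_params(experiment, strong_table, min_spots=20):
    """Estimate (sigma_b, sigma_m) from indexed strong-spot shoeboxes.

    sigma_b: intensity-weighted RMS angular deviation of foreground pixels
    about each spot's diffracted-beam direction, averaged over spots.
    sigma_m: RMS deviation of each spot's intensity-weighted phi profile
    about its centroid.  Both are corrected for the finite pixel/frame
    width (Sheppard's correction) and reported in degrees.
    """
    from .model import lab_coord_of_pixel

    table = strong_table
    sel = table.get_flags(INDEXED) & table.get_flags(STRONG)
    idx = np.flatnonzero(sel)
    if table.shoeboxes is None:
        raise ValueError("strong table has no shoeboxes")
    det = experiment.detector
    scan = experiment.scan
    px_deg, _ = _angular_pixel_scale(experiment)

    var_b, var_m, weights = [], [], []
    for i in idx:
        box = table.shoeboxes[i]
        if box is None:
            continue
        x0, x1, y0, y1, z0, z1 = box.bbox
        fg = box.mask == MASK_FOREGROUND
        if fg.sum() < 3:
            continue
        bg = box.data[box.mask == MASK_BACKGROUND]
        b_est = float(np.median(bg)) if bg.size else 0.0
        # use every valid pixel so the profile tails outside the thresholded
        # core still contribute to the second moments
        valid = box.mask != MASK_INVALID
        zz, yy, xx = np.nonzero(valid)
        counts = box.data[zz, yy, xx].astype(float)
        w = np.maximum(counts - b_est, 0.0)
        if w.sum() <= 0:
            continue
        # detector-face angular spread
        pos = lab_coord_of_pixel(det, xx + x0 + 0.5, yy + y0 + 0.5)
        unit = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        mean_dir = (unit * w[:, None]).sum(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        ang = np.degrees(np.arccos(np.clip(unit @ mean_dir, -1, 1)))
        # RMS about the mean direction; 2D isotropic -> per-axis sd is rms/sqrt(2)
        rms2 = float((w * ang**2).sum() / w.sum()) / 2.0
        # phi profile (raw binned variance; pixel/frame width removed below)
        phi = scan.phi_of_frame(zz + z0 + 0.5)
        mphi = float((w * phi).sum() / w.sum())
        vphi = float((w * (phi - mphi) ** 2).sum() / w.sum())
        var_b.append(max(rms2, 1e-8))
        var_m.append(max(vphi, 1e-8))
        weights.append(w.sum())

    if len(var_b) < min_spots:
        raise ValueError(
            f"too few usable strong spots for profile estimation ({len(var_b)})"
        )
    wt = np.asarray(weights)
    # invert the exact binned-Gaussian variance map: unbiased even when the
    # pixel or image width exceeds the underlying sigma
    sigma_b = _invert_binned_var(float(np.average(var_b, weights=wt)), px_deg)
    sigma_m = _invert_binned_var(float(np.average(var_m, weights=wt)), scan.dphi)
    floor = 1e-3
    return ProfileModel(sigma_b=max(sigma_b, floor), sigma_m=max(sigma_m, floor))


def predict_and_box(experiment, profile_model, d_min, bg_pad_xy=2, bg_pad_z=1):
    """Predict reflections and attach integration bounding boxes.

    The foreground box spans +-n_sigma * sigma on each axis about the
    predicted position; the full shoebox adds a background ring.  Boxes
    are clipped to the panel and scan; clipped reflections are flagged
    partial.
    """
    det = experiment.detector
    scan = experiment.scan
    px_deg, _ = _angular_pixel_scale(experiment)
    sig_b_px = profile_model.sigma_b / px_deg
    hx = profile_model.n_sigma * sig_b_px
    hz = profile_model.n_sigma * profile_model.sigma_m / scan.dphi

    res = _predict.predict(experiment, d_min=d_min)
    n = len(res["hkl"])
    rows = []
    for i in range(n):
        xc, yc, zc = res["x_px"][i], res["y_px"][i], res["z_frame"][i]
        fx0, fx1 = math.floor(xc - hx), math.ceil(xc + hx)
        fy0, fy1 = math.floor(yc - hx), math.ceil(yc + hx)
        fz0, fz1 = math.floor(zc - hz), math.ceil(zc + hz)
        x0, x1 = fx0 - bg_pad_xy, fx1 + bg_pad_xy
        y0, y1 = fy0 - bg_pad_xy, fy1 + bg_pad_xy
        z0, z1 = fz0 - bg_pad_z, fz1 + bg_pad_z
        partial = (
            x0 < 0 or y0 < 0 or z0 < 0
            or x1 > det.n_fast or y1 > det.n_slow or z1 > scan.n_images
        )
        x0, x1 = max(0, x0), min(det.n_fast, x1)
        y0, y1 = max(0, y0), min(det.n_slow, y1)
        z0, z1 = max(0, z0), min(scan.n_images, z1)
        rows.append(
            {
                "h": res["hkl"][i, 0], "k": res["hkl"][i, 1], "l": res["hkl"][i, 2],
                "x_cal_px": xc, "y_cal_px": yc, "z_cal_frame": zc,
                "phi_cal_deg": res["phi_deg"][i], "d": res["d"][i],
                "bbox_x0": x0, "bbox_x1": x1, "bbox_y0": y0, "bbox_y1": y1,
                "bbox_z0": z0, "bbox_z1": z1,
                "fg_x0": fx0, "fg_x1": fx1, "fg_y0": fy0, "fg_y1": fy1,
                "fg_z0": fz0, "fg_z1": fz1,
                "flags": PARTIAL if partial else 0,
            }
        )
    table = ReflectionTable(pd.DataFrame(rows))
    table.set_flags(np.ones(len(table), dtype=bool), INDEXED)
    return table


def extract_shoeboxes(table, experiment, images):
    """Fill shoeboxes with pixel data; mark foreground/background and
    overloaded pixels."""
    det = experiment.detector
    base_mask = det.pixel_mask()
    trusted_lo, trusted_hi = det.trusted_range
    images = np.asarray(images)
    boxes = []
    overloaded = np.zeros(len(table), dtype=bool)
    for i in range(len(table)):
        r = table.df.iloc[i]
        x0, x1 = int(r.bbox_x0), int(r.bbox_x1)
        y0, y1 = int(r.bbox_y0), int(r.bbox_y1)
        z0, z1 = int(r.bbox_z0), int(r.bbox_z1)
        if x1 <= x0 or y1 <= y0 or z1 <= z0:
            boxes.append(None)
            continue
        data = images[z0:z1, y0:y1, x0:x1].astype(float)
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        fg = (
            (xx >= r.fg_x0) & (xx < r.fg_x1)
            & (yy >= r.fg_y0) & (yy < r.fg_y1)
            & (zz >= r.fg_z0) & (zz < r.fg_z1)
        )
        mask = np.where(fg, MASK_FOREGROUND, MASK_BACKGROUND).astype(np.int8)
        bad = ~base_mask[y0:y1, x0:x1][None, :, :] | (data < trusted_lo)
        mask[bad] = MASK_INVALID
        over = data >= trusted_hi
        mask[over] = MASK_OVERLOADED
        overloaded[i] = bool((over & fg).any())
        boxes.append(Shoebox(bbox=(x0, x1, y0, y1, z0, z1), data=data, mask=mask))
    table.shoeboxes = boxes
    table.set_flags(overloaded, OVERLOADED)
    return table


def estimate_background(shoebox, min_pixels=10, nsig=3.0, max_rounds=5):
    """Constant background per shoebox by iterated mean with Poisson
    outlier rejection.  Returns (per-pixel background, mean, variance of
    the mean) or raises ValueError when too few background pixels."""
    sel = shoebox.mask == MASK_BACKGROUND
    vals = shoebox.data[sel]
    if vals.size < min_pixels:
        raise ValueError("too few background pixels")
    use = np.ones(vals.shape, dtype=bool)
    for round_ in range(max_rounds):
        # median start: a single extreme pixel must not poison the first
        # rejection pass
        m = float(np.median(vals)) if round_ == 0 else vals[use].mean()
        sigma = math.sqrt(max(m, 1e-6))
        new = np.abs(vals - m) <= nsig * sigma
        if new.sum() < min_pixels or np.array_equal(new, use):
            use = new if new.sum() >= min_pixels else use
            break
        use = new
    b_hat = float(vals[use].mean())
    var = b_hat / max(use.sum(), 1)
    background = np.full(shoebox.data.shape, b_hat)
    return background, b_hat, var


def integrate_sum(shoebox, b_hat):
    """Summation integration over the foreground mask.

    I = sum_fg(c) - n_fg * b; var = sum_fg(c) + n_fg*b*(1 + n_fg/n_bg).
    """
    fg = shoebox.mask == MASK_FOREGROUND
    n_fg = int(fg.sum())
    n_bg = int((shoebox.mask == MASK_BACKGROUND).sum())
    total = float(shoebox.data[fg].sum())
    I = total - n_fg * b_hat
    var = total + n_fg * b_hat * (1.0 + (n_fg / n_bg if n_bg else 1.0))
    return I, max(var, 1e-12)


def _axis_overlap_weights(lo, hi, n_sigma=N_SIGMA, grid_n=GRID_N):
    """Distribution of a pixel interval [lo, hi] (sigma units) over the
    grid cells along one axis.

    Within-pixel mass is apportioned by the standard normal measure, so a
    pixel or image much wider than sigma still deposits its counts with
    the expected profile shape rather than uniformly — this keeps the grid
    image of a reflection independent of its sub-pixel / frame phase.
    Rows are normalized to unit sum (counts are conserved; mass beyond the
    grid edge folds into the edge cells).
    """
    from scipy.special import ndtr

    edges = np.linspace(-n_sigma, n_sigma, grid_n + 1)
    lo = np.asarray(lo, dtype=float)[:, None]
    hi = np.asarray(hi, dtype=float)[:, None]
    left = np.clip(edges[None, :-1], lo, hi)
    right = np.clip(edges[None, 1:], lo, hi)
    w = np.maximum(ndtr(right) - ndtr(left), 0.0)
    # fold any out-of-range mass into the nearest edge cell
    w[:, 0] += np.maximum(ndtr(np.minimum(edges[0], hi[:, 0])) - ndtr(lo[:, 0]), 0.0)
    w[:, -1] += np.maximum(ndtr(hi[:, 0]) - ndtr(np.maximum(edges[-1], lo[:, 0])), 0.0)
    s = w.sum(axis=1, keepdims=True)
    s[s <= 0] = 1.0
    return w / s


def _scatter_to_grid(shoebox, row, sig_b_px, sigma_m, scan, values,
                     squared=False):
    """Scatter per-pixel ``values`` of the foreground region onto the
    9x9x9 local grid using separable box-overlap weights (the transform to
    the normalized profile frame)."""
    x0, x1, y0, y1, z0, z1 = shoebox.bbox
    fg = (shoebox.mask == MASK_FOREGROUND) | (shoebox.mask == MASK_OVERLOADED)
    zz, yy, xx = np.nonzero(fg)
    if len(zz) == 0:
        return np.zeros((GRID_N, GRID_N, GRID_N))
    vals = values[zz, yy, xx]
    ux_lo = (xx + x0 - row.x_cal_px) / sig_b_px
    ux_hi = (xx + x0 + 1 - row.x_cal_px) / sig_b_px
    vy_lo = (yy + y0 - row.y_cal_px) / sig_b_px
    vy_hi = (yy + y0 + 1 - row.y_cal_px) / sig_b_px
    wz_lo = (scan.phi_of_frame(zz + z0) - row.phi_cal_deg) / sigma_m
    wz_hi = (scan.phi_of_frame(zz + z0 + 1) - row.phi_cal_deg) / sigma_m
    Wx = _axis_overlap_weights(ux_lo, ux_hi)
    Wy = _axis_overlap_weights(vy_lo, vy_hi)
    Wz = _axis_overlap_weights(wz_lo, wz_hi)
    if squared:
        Wx, Wy, Wz = Wx**2, Wy**2, Wz**2
    return np.einsum("p,pi,pj,pk->ijk", vals, Wz, Wy, Wx, optimize=True)


def _region_of(row, detector):
    rx = min(N_REGIONS - 1, int(N_REGIONS * row.x_cal_px / detector.n_fast))
    ry = min(N_REGIONS - 1, int(N_REGIONS * row.y_cal_px / detector.n_slow))
    return ry * N_REGIONS + rx


def build_reference_profiles(table, profile_model, experiment,
                             min_strong=50, i_over_sig_min=10.0):
    """Accumulate per-region reference profiles from strong reflections.

    Returns a list of GRID_N^3 arrays (one per detector region, row-major
    3x3), each non-negative and normalized to unit sum.  Regions with no
    contributors inherit the global average profile.
    """
    det = experiment.detector
    scan = experiment.scan
    px_deg, _ = _angular_pixel_scale(experiment)
    sig_b_px = profile_model.sigma_b / px_deg

    ok = table.get_flags(INTEGRATED_SUM) & ~table.get_flags(OVERLOADED)
    I = table["intensity_sum_value"]
    V = np.maximum(table["intensity_sum_variance"], 1e-12)
    strong = ok & (I / np.sqrt(V) >= i_over_sig_min)
    idx = np.flatnonzero(strong)
    if len(idx) < min_strong:
        # relax the strength cut rather than fail outright
        order = np.argsort(-(I / np.sqrt(V)) * ok)
        idx = order[: max(min_strong, int(ok.sum()))]
        idx = idx[ok[idx]]
    if len(idx) == 0:
        raise ValueError("no reflections available for reference profiles")

    grids = np.zeros((N_REGIONS * N_REGIONS, GRID_N, GRID_N, GRID_N))
    counts = np.zeros(N_REGIONS * N_REGIONS, dtype=int)
    for i in idx:
        box = table.shoeboxes[i]
        if box is None:
            continue
        row = table.df.iloc[i]
        bsub = box.data - box.background
        grid = _scatter_to_grid(box, row, sig_b_px, profile_model.sigma_m,
                                scan, bsub)
        tot = grid.sum()
        if tot <= 0:
            continue
        reg = _region_of(row, det)
        grids[reg] += grid / tot
        counts[reg] += 1

    global_grid = grids.sum(axis=0)
    out = []
    for reg in range(N_REGIONS * N_REGIONS):
        g = grids[reg] if counts[reg] > 0 else global_grid
        g = np.maximum(g, 0.0)
        s = g.sum()
        if s <= 0:
            g = np.ones_like(g)
            s = g.sum()
        out.append(g / s)
    return out


def integrate_prf(shoebox, b_hat, reference, row, profile_model, experiment,
                  min_overlap=0.5):
    """Profile-fitted intensity by least-squares scaling of the reference.

    I = sum(p (c - b)/v) / sum(p^2/v) with v = max(c, 1) + b.  Raises
    ValueError when less than ``min_overlap`` of the profile mass overlaps
    the (possibly clipped) shoebox, in which case the caller should fall
    back to summation.
    """
    scan = experiment.scan
    px_deg, _ = _angular_pixel_scale(experiment)
    sig_b_px = profile_model.sigma_b / px_deg
    fg = (shoebox.mask == MASK_FOREGROUND) | (shoebox.mask == MASK_OVERLOADED)
    if not fg.any():
        raise ValueError("no profile overlap")
    # transform data, background and per-pixel variances to the grid frame
    args = (shoebox, row, sig_b_px, profile_model.sigma_m, scan)
    c_grid = _scatter_to_grid(*args, shoebox.data)
    b_grid = _scatter_to_grid(*args, np.broadcast_to(b_hat, shoebox.data.shape))
    # linear (not squared) weight scatter: keeps the per-cell information
    # content bounded for cells covered by slivers of a pixel
    v_pix = np.maximum(shoebox.data, 1.0) + b_hat
    v_grid = _scatter_to_grid(*args, v_pix)
    covered = v_grid > 0
    p = reference
    overlap = float(p[covered].sum())
    if overlap < min_overlap:
        raise ValueError(f"profile overlap {overlap:.2f} < {min_overlap}")
    pc = p[covered]
    num = float((pc * (c_grid - b_grid)[covered] / v_grid[covered]).sum())
    den = float((pc * pc / v_grid[covered]).sum())
    if den <= 0:
        raise ValueError("degenerate profile fit")
    return num / den, 1.0 / den


def integrate(experiment, images, strong_table=None, profile_model=None,
              d_min=None, profile_fitting=True, keep_shoeboxes=False):
    """Full integration pass -> (ReflectionTable, ProfileModel).

    Estimates the profile model from indexed strong spots (unless given),
    predicts and boxes all reflections to ``d_min``, estimates backgrounds,
    integrates by summation and (by default) profile fitting.
    """
    if profile_model is None:
        if strong_table is None:
            raise ValueError("need either a strong table or a profile model")
        profile_model = estimate_profile_params(experiment, strong_table)
    if d_min is None:
        if strong_table is not None and len(strong_table):
            d_min = float(np.percentile(strong_table["d"], 0.5))
        else:
            raise ValueError("d_min required without a strong table")

    table = predict_and_box(experiment, profile_model, d_min)
    table = extract_shoeboxes(table, experiment, images)

    n = len(table)
    I_sum = np.full(n, np.nan)
    V_sum = np.full(n, np.nan)
    bg = np.full(n, np.nan)
    x_obs = table["x_cal_px"].copy()
    y_obs = table["y_cal_px"].copy()
    z_obs = table["z_cal_frame"].copy()
    ok_sum = np.zeros(n, dtype=bool)
    for i in range(n):
        box = table.shoeboxes[i]
        if box is None:
            continue
        try:
            background, b_hat, _ = estimate_background(box)
        except ValueError:
            table.set_flags(np.arange(n) == i, NO_BACKGROUND)
            continue
        box.background = background
        bg[i] = b_hat
        I_sum[i], V_sum[i] = integrate_sum(box, b_hat)
        ok_sum[i] = True
        # observed centroid of the background-subtracted foreground
        fg = box.mask == MASK_FOREGROUND
        w = np.maximum(box.data - b_hat, 0.0) * fg
        tot = w.sum()
        if tot > 0:
            zz, yy, xx = np.nonzero(fg)
            wv = w[zz, yy, xx]
            x0, _, y0, _, z0, _ = box.bbox
            x_obs[i] = float(((xx + x0 + 0.5) * wv).sum() / tot)
            y_obs[i] = float(((yy + y0 + 0.5) * wv).sum() / tot)
            z_obs[i] = float(((zz + z0 + 0.5) * wv).sum() / tot)
    table["intensity_sum_value"] = I_sum
    table["intensity_sum_variance"] = V_sum
    table["background_mean"] = bg
    table["x_px"] = x_obs
    table["y_px"] = y_obs
    table["z_frame"] = z_obs
    table.set_flags(ok_sum, INTEGRATED_SUM)

    if profile_fitting:
        refs = build_reference_profiles(table, profile_model, experiment)
        I_prf = np.full(n, np.nan)
        V_prf = np.full(n, np.nan)
        ok_prf = np.zeros(n, dtype=bool)
        fallback = np.zeros(n, dtype=bool)
        det = experiment.detector
        for i in range(n):
            box = table.shoeboxes[i]
            if box is None or not ok_sum[i]:
                continue
            row = table.df.iloc[i]
            try:
                I_prf[i], V_prf[i] = integrate_prf(
                    box, bg[i], refs[_region_of(row, det)], row,
                    profile_model, experiment,
                )
                ok_prf[i] = True
            except ValueError:
                I_prf[i], V_prf[i] = I_sum[i], V_sum[i]
                fallback[i] = True
        table["intensity_prf_value"] = I_prf
        table["intensity_prf_variance"] = V_prf
        table.set_flags(ok_prf, INTEGRATED_PRF)
        table.set_flags(fallback, PRF_FALLBACK)

    if not keep_shoeboxes:
        table.shoeboxes = None
    return table, profile_model
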