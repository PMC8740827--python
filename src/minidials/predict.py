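"""Reflection prediction for the rotation method.

A reflection h diffracts at rotation angle phi* when its rotated reciprocal
lattice point lies on the Ewald sphere:

    | R(e, phi*) . A . h + s0 | = 1/lambda

Roots are located by scanning the squared Ewald offset

    f(phi) = |R(e, phi) r0 + s0|^2 - 1/lambda^2

over the scan range in coarse steps and refining each bracketing interval
by bisection.  Because |R r0| is constant, f is a pure sinusoid in phi,
f = a + b cos(phi) + c sin(phi), which the vectorized scan exploits.
"""

from __future__ import annotations

import numpy as np

from .model import lab_coord_of_pixel

SCAN_STEP_DEG = 0.1
BISECT_TOL_DEG = 1e-9  # interval width at which bisection stops


def _sinusoid_coeffs(axis, s0, r0):
    """Coefficients (a, b, c) of f(phi) = a + b cos + c sin per reflection.

    r0: (n, 3) reciprocal lattice points at phi = 0.
    """
    e = np.asarray(axis, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    r0 = np.atleast_2d(np.asarray(r0, dtype=float))
    par = (r0 @ e)[:, None] * e  # component along the rotation axis
    perp = r0 - par
    cross = np.cross(np.broadcast_to(e, r0.shape), r0)
    a = (r0 * r0).sum(axis=1) + 2.0 * (par @ s0)
    b = 2.0 * (perp @ s0)
    c = 2.0 * (cross @ s0)
    return a, b, c


def ewald_roots(axis, s0, r0, phi_start, phi_end, step=SCAN_STEP_DEG,
                windows=None):
    """Find all phi in [phi_start, phi_end] solving the diffraction condition.

    Returns (idx, phi): reflection row indices (into r0) and root angles in
    degrees.  ``windows``, if given, is an (n, 2) array restricting the
    search per reflection (used by refinement, where an observed phi makes
    the bracket known).
    """
    a, b, c = _sinusoid_coeffs(axis, s0, r0)
    n = a.shape[0]

    def f(phi_deg, rows=slice(None)):
        t = np.radians(phi_deg)
        return a[rows] + b[rows] * np.cos(t) + c[rows] * np.sin(t)

    idx_list, lo_list, hi_list = [], [], []
    if windows is None:
        grid = np.arange(phi_start, phi_end + 0.5 * step, step)
        grid[-1] = phi_end
        # chunk over reflections to bound memory
        block = max(1, int(4e6 // max(len(grid), 1)))
        for start in range(0, n, block):
            rows = slice(start, min(start + block, n))
            vals = (
                a[rows, None]
                + b[rows, None] * np.cos(np.radians(grid))[None, :]
                + c[rows, None] * np.sin(np.radians(grid))[None, :]
            )
            sign_change = vals[:, :-1] * vals[:, 1:] <= 0
            # drop double-counting where a value is exactly zero at a knot
            sign_change &= ~((vals[:, :-1] == 0) & (vals[:, 1:] == 0))
            ii, jj = np.nonzero(sign_change)
            idx_list.append(ii + start)
            lo_list.append(grid[jj])
            hi_list.append(grid[jj + 1])
    else:
        windows = np.asarray(windows, dtype=float)
        lo_w = np.maximum(windows[:, 0], phi_start)
        hi_w = np.maximum(np.minimum(windows[:, 1], phi_end), lo_w)
        nsteps = int(np.ceil((hi_w - lo_w).max() / step)) if n else 0
        if nsteps < 1:
            nsteps = 1
        frac = np.linspace(0.0, 1.0, nsteps + 1)
        grid = lo_w[:, None] + (hi_w - lo_w)[:, None] * frac[None, :]
        t = np.radians(grid)
        vals = a[:, None] + b[:, None] * np.cos(t) + c[:, None] * np.sin(t)
        sign_change = vals[:, :-1] * vals[:, 1:] <= 0
        sign_change &= ~((vals[:, :-1] == 0) & (vals[:, 1:] == 0))
        ii, jj = np.nonzero(sign_change)
        idx_list.append(ii)
        lo_list.append(grid[ii, jj])
        hi_list.append(grid[ii, jj + 1])

    if not idx_list or sum(len(x) for x in idx_list) == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    idx = np.concatenate(idx_list)
    lo = np.concatenate(lo_list)
    hi = np.concatenate(hi_list)

    flo = f(lo, idx)
    while np.any(hi - lo > BISECT_TOL_DEG):
        mid = 0.5 * (lo + hi)
        fmid = f(mid, idx)
        left = flo * fmid <= 0
        hi = np.where(left, mid, hi)
        lo = np.where(left, lo, mid)
        flo = np.where(left, flo, fmid)
    phi = 0.5 * (lo + hi)
    order = np.lexsort((phi, idx))
    return idx[order], phi[order]


def rotate_about(axis, phi_deg, vecs):
    """Rotate (n, 3) vectors about ``axis`` by per-row angles (deg)."""
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    v = np.atleast_2d(vecs)
    t = np.radians(np.asarray(phi_deg, dtype=float)).reshape(-1)
    cos, sin = np.cos(t)[:, None], np.sin(t)[:, None]
    par = (v @ e)[:, None] * e
    perp = v - par
    cross = np.cross(np.broadcast_to(e, v.shape), v)
    return par + cos * perp + sin * cross


def detector_intersection(experiment, s1):
    """Intersect diffracted rays with the panel.

    s1: (n, 3) diffracted wavevectors.  Returns (x_px, y_px, hits) where
    ``hits`` marks rays striking the panel from the crystal side.
    """
    det = experiment.detector
    s1 = np.atleast_2d(s1)
    n = det.normal
    o = np.asarray(det.origin)
    denom = s1 @ n
    on = float(o @ n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = on / denom
    hit = t[:, None] * s1  # lab coordinate of intersection (per row)
    rel = hit - o
    x = rel @ np.asarray(det.fast_axis) / det.pixel_size[0]
    y = rel @ np.asarray(det.slow_axis) / det.pixel_size[1]
    ok = np.isfinite(t) & (t > 0)
    ok &= (x >= 0) & (x <= det.n_fast) & (y >= 0) & (y <= det.n_slow)
    return x, y, ok


def predict(experiment, d_min=None, hkl=None, phi_windows=None,
            require_on_detector=True):
    """Predict reflection positions for an experiment with a crystal.

    Either enumerate all Miller indices to ``d_min`` or predict the supplied
    ``hkl`` list (optionally with per-reflection phi search windows).

    Returns a dict of numpy arrays: hkl, x_px, y_px, phi_deg, z_frame, d,
    two_theta_deg, s1 (n, 3).  With a scan-varying crystal, roots are found
    with the static A then re-solved once with the per-image A at the root.
    """
    crystal = experiment.crystal
    if crystal is None:
        raise ValueError("experiment has no crystal model")
    beam, scan, gonio = experiment.beam, experiment.scan, experiment.goniometer
    A = crystal.A_matrix
    if hkl is None:
        if d_min is None:
            raise ValueError("either d_min or hkl must be given")
        hkl = enumerate_hkl(A, d_min)
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    r0 = hkl @ A.T
    s0 = beam.s0

    idx, phi = ewald_roots(gonio.axis, s0, r0, scan.phi0, scan.phi_end,
                           windows=phi_windows)
    if crystal.scan_varying_A is not None and len(idx):
        # re-solve each root with the A model of its frame
        frames = np.clip(scan.frame_of_phi(phi).astype(int), 0,
                         scan.n_images - 1)
        r0_sv = np.empty((len(idx), 3))
        for fr in np.unique(frames):
            sel = frames == fr
            Af = crystal.A_at_frame(fr)
            r0_sv[sel] = hkl[idx[sel]] @ Af.T
        win = np.column_stack([phi - 2 * SCAN_STEP_DEG, phi + 2 * SCAN_STEP_DEG])
        sub, phi2 = ewald_roots(gonio.axis, s0, r0_sv, scan.phi0 - 1.0,
                                scan.phi_end + 1.0, windows=win)
        idx = idx[sub]
        phi = phi2
        r0 = r0_sv
        rot = rotate_about(gonio.axis, phi, r0[sub])
    else:
        rot = rotate_about(gonio.axis, phi, r0[idx]) if len(idx) else np.zeros((0, 3))

    s1 = rot + s0
    x, y, ok = detector_intersection(experiment, s1)
    if require_on_detector:
        idx, phi, s1, x, y = idx[ok], phi[ok], s1[ok], x[ok], y[ok]
    h_out = hkl[idx]
    rlen = np.linalg.norm(s1 - s0, axis=1)
    with np.errstate(divide="ignore"):
        d = np.where(rlen > 0, 1.0 / rlen, np.inf)
    stl = rlen / 2.0  # sin(theta)/lambda
    two_theta = 2.0 * np.degrees(np.arcsin(np.clip(stl * beam.wavelength, -1, 1)))
    return {
        "hkl": h_out,
        "x_px": x,
        "y_px": y,
        "phi_deg": phi,
        "z_frame": scan.frame_of_phi(phi),
        "d": d,
        "two_theta_deg": two_theta,
        "s1": s1,
    }


def enumerate_hkl(A, d_min, include_origin=False):
    """All Miller indices with d-spacing >= d_min for the given UB matrix."""
    G_star = A.T @ A
    G = np.linalg.inv(G_star)
    abc = np.sqrt(np.diag(G))  # direct cell lengths
    hmax = np.ceil(abc / d_min).astype(int) + 1
    ranges = [np.arange(-m, m + 1) for m in hmax]
    H, K, L = np.meshgrid(*ranges, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    r = hkl @ A.T
    r2 = (r * r).sum(axis=1)
    keep = r2 <= (1.0 / d_min) ** 2
    if not include_origin:
        keep &= r2 > 0
    return hkl[keep]
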