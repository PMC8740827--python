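"""Detector diagnostics for pixel-array data.

* ``overload_histogram``: histogram of all shoebox pixel values, to spot a
  truncated count distribution (saturation);
* ``find_bad_pixels``: accumulate, frame by frame, which pixels the spot
  threshold marks as signal; a pixel carrying signal on half or more of
  the frames is unlikely to be a real reflection and is flagged;
* ``flux_ratio``: ratio of the maximum to the mean instantaneous photon
  flux seen by a pixel during one exposure, for a Gaussian rocking curve
  of width sigma_m sliced into frames of width dphi — the pile-up hazard
  metric for photon-counting detectors;
* ``screen``: quick-look analysis of a small wedge: profile model, flux
  ratio, adjusted maximum trusted value, Wilson fit of the integrated
  intensities and exposure recommendations at standard resolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .reflections import INDEXED, STRONG
from .spotfind import SpotFindParams, dispersion_threshold, find_spots

STANDARD_RESOLUTIONS = (3.0, 2.5, 2.0, 1.5, 1.2, 1.0, 0.84)


def overload_histogram(table, n_slots=5000, data_min=0.0, data_max=5000.0):
    """Histogram of shoebox pixel values over all strong spots.

    Values are binned on [data_min, data_max) into ``n_slots`` equal slots
    accumulated over every shoebox; returns (slot_centres, counts).
    """
    edges = np.linspace(data_min, data_max, n_slots + 1)
    counts = np.zeros(n_slots, dtype=np.int64)
    if table is not None and table.shoeboxes is not None:
        for box in table.shoeboxes:
            if box is None:
                continue
            h, _ = np.histogram(box.data.ravel(), bins=edges)
            counts += h
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, counts


def find_bad_pixels(images, detector, params=None, min_frames=100,
                    frame_fraction=0.5):
    """Flag unreliable pixels from routinely collected rotation data.

    Per frame: apply the known mask, mark out-of-trusted-range pixels,
    run the spot threshold (min_spot_size=1 semantics — every signal pixel
    counts), and accumulate per-pixel signal counts.  Pixels with signal
    on ``frame_fraction`` or more of the frames are flagged, as are pixels
    outside the trusted range on at least that many frames.
    Returns a boolean (n_slow, n_fast) mask of flagged pixels.
    """
    import warnings

    params = params or SpotFindParams(min_spot_size=1)
    images = np.asarray(images)
    n_frames = images.shape[0]
    if n_frames < min_frames:
        warnings.warn(
            f"find_bad_pixels: only {n_frames} frames (< {min_frames}); "
            "proceeding with the available count"
        )
    base_mask = detector.pixel_mask()
    lo, hi = detector.trusted_range
    total = np.zeros(images.shape[1:], dtype=np.int64)
    out_of_range = np.zeros(images.shape[1:], dtype=np.int64)
    for z in range(n_frames):
        frame = images[z].astype(float)
        bad = (frame < lo) | (frame > hi)
        out_of_range += bad & base_mask
        mask = base_mask & ~bad
        peak = dispersion_threshold(
            frame, mask, params.gain, params.nsig_b, params.nsig_s,
            params.global_threshold,
        )
        total += peak.astype(np.int64)
    threshold = frame_fraction * n_frames
    return (total >= threshold) | (out_of_range >= threshold)


def flux_ratio(sigma_m, dphi):
    """Maximum-to-mean instantaneous flux for a frame centred on the peak
    of a Gaussian rocking curve.

    ratio = dphi / (sigma_m sqrt(2 pi) erf(dphi / (2 sqrt(2) sigma_m)));
    tends to 1 for fine slicing and to dphi/(sigma_m sqrt(2 pi)) for
    coarse slicing.
    """
    if not (sigma_m > 0 and dphi > 0):
        raise ValueError("sigma_m and dphi must be positive")
    z = dphi / (2.0 * math.sqrt(2.0) * sigma_m)
    return dphi / (sigma_m * math.sqrt(2.0 * math.pi) * erf(z))


@dataclass
class ScreenResult:
    flux_ratio: float
    adjusted_max_trusted: float
    wilson_K: float
    wilson_B: float
    sigma_b: float
    sigma_m: float
    n_spots: int
    recommendations: dict = field(default_factory=dict)  # d -> scale factor

    def recommended_scale_to(self, d, i_over_sigma=1.0):
        """Exposure multiplier for <I/sigma> ~ i_over_sigma at resolution d
        under Poisson statistics (sigma ~ sqrt(I))."""
        s2 = 1.0 / (4.0 * d * d)
        I_at_d = self.wilson_K * math.exp(-2.0 * self.wilson_B * s2)
        if I_at_d <= 0:
            return float("inf")
        return i_over_sigma**2 / I_at_d


def screen(experiment, images, d_min=None, params=None):
    """Quick wedge analysis -> ScreenResult.

    Runs spot finding and profile-model estimation on the wedge, computes
    the pile-up flux ratio from (sigma_m, dphi), adjusts the maximum
    trusted value, integrates by summation and fits the Wilson plot
    ln<I>_bin = ln K - 2 B (sin theta/lambda)^2 by weighted least squares.
    """
    from . import index as _index
    from .integrate import integrate
    from .spotfind import filter_spots

    images = np.asarray(images)
    if images.shape[0] < 5:
        raise ValueError("screen needs a wedge of at least 5 images")
    table = filter_spots(find_spots(experiment, images, params), min_spot_size=3)
    if len(table) < 20:
        raise ValueError("insufficient diffraction: too few spots found")

    if experiment.crystal is None:
        crystals, table, _ = _index.index(experiment, table)
        from dataclasses import replace

        experiment = replace(experiment, crystal=crystals[0])
    else:
        hkl, ok, _ = _index.assign_indices(
            experiment.crystal.A_matrix,
            _index.map_to_reciprocal(experiment, table),
        )
        table = table.copy()
        table.set_hkl(hkl)
        table.set_flags(ok, INDEXED)

    from .integrate import estimate_profile_params

    pm = estimate_profile_params(experiment, table)
    ratio = flux_ratio(pm.sigma_m, experiment.scan.dphi)
    adjusted = experiment.detector.trusted_range[1] / ratio

    itab, _ = integrate(experiment, images, strong_table=table,
                        profile_model=pm, d_min=d_min, profile_fitting=False)
    from .reflections import INTEGRATED_SUM

    ok = itab.get_flags(INTEGRATED_SUM)
    I = itab["intensity_sum_value"][ok]
    d = itab["d"][ok]
    s2 = 1.0 / (4.0 * d * d)
    edges = np.linspace(s2.min() - 1e-12, s2.max() + 1e-12, 9)
    K, B = _wilson_fit(I, s2, edges)

    result = ScreenResult(
        flux_ratio=float(ratio),
        adjusted_max_trusted=float(adjusted),
        wilson_K=float(K),
        wilson_B=float(B),
        sigma_b=pm.sigma_b,
        sigma_m=pm.sigma_m,
        n_spots=len(table),
    )
    for d_target in STANDARD_RESOLUTIONS:
        result.recommendations[d_target] = result.recommended_scale_to(d_target)
    return result


def _wilson_fit(I, s2, edges):
    """Weighted LS fit of ln<I> = ln K - 2 B s2 over s2 bins."""
    bins = np.clip(np.digitize(s2, edges) - 1, 0, len(edges) - 2)
    xs, ys, ws = [], [], []
    for b in range(len(edges) - 1):
        sel = bins == b
        if sel.sum() < 5:
            continue
        mean_I = I[sel].mean()
        if mean_I <= 0:
            continue
        xs.append(s2[sel].mean())
        ys.append(math.log(mean_I))
        ws.append(sel.sum())
    if len(xs) < 2:
        raise ValueError("too few populated bins for a Wilson fit")
    xs, ys, ws = np.asarray(xs), np.asarray(ys), np.asarray(ws, dtype=float)
    W = np.diag(ws)
    X = np.column_stack([np.ones_like(xs), -2.0 * xs])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
    return math.exp(beta[0]), beta[1]
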