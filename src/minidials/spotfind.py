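"""Strong-spot finding by local dispersion thresholding.

A pixel is *strong* when, over the valid pixels of a 7x7 window centred on
it (index of dispersion test, signal test, and a global floor):

  (i)   sigma^2/mu > gain * (1 + nsig_b * sqrt(2/(n-1)))
  (ii)  c - mu     > nsig_s * sqrt(gain * mu)
  (iii) c          > global_threshold

Strong pixels from all images are grouped into 6-connected components in
(x, y, frame), each component becoming one candidate reflection with a
shoebox (bounding box padded by one pixel of background) and an
intensity-weighted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import model as _model
from .reflections import (
    MASK_BACKGROUND,
    MASK_FOREGROUND,
    MASK_INVALID,
    MASK_OVERLOADED,
    OVERLOADED,
    STRONG,
    ReflectionTable,
    Shoebox,
)

KERNEL = 7  # dispersion window size (pixels, odd)


@dataclass
class SpotFindParams:
    gain: float = 1.0
    nsig_b: float = 6.0
    nsig_s: float = 3.0
    global_threshold: float = 0.0
    min_spot_size: int = 3
    max_spot_size: int = 1000
    d_min: float | None = None
    d_max: float | None = None
    maximum_trusted_value: float | None = None  # raise to keep overloads


def _window_sums(arr, size):
    """Sum of ``arr`` over a size x size window, zero-padded at borders."""
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * (size * size)


def dispersion_threshold(image, mask=None, gain=1.0, nsig_b=6.0, nsig_s=3.0,
                         global_threshold=0.0, kernel=KERNEL):
    """Boolean image of strong pixels (see module docstring for the tests)."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    valid = mask.astype(float)
    img = np.where(mask, image, 0.0)
    n = _window_sums(valid, kernel)
    s1 = _window_sums(img, kernel)
    s2 = _window_sums(img * img, kernel)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = s1 / n
        var_n1 = (s2 - s1 * s1 / n) / (n - 1)  # sample variance
        dispersion = var_n1 / mu
    enough = n >= 2
    with np.errstate(invalid="ignore"):
        t_disp = dispersion > gain * (1.0 + nsig_b * np.sqrt(2.0 / (n - 1)))
        t_sig = (image - mu) > nsig_s * np.sqrt(gain * np.maximum(mu, 0))
        t_glob = image > global_threshold
    strong = enough & mask & np.nan_to_num(t_disp) & np.nan_to_num(t_sig) & t_glob
    return strong


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def label_connected(strong):
    """Label strong voxels (n_frames, n_slow, n_fast) into maximal
    6-connected components; returns (labels array, n, slices ordered by
    (z0, y0, x0))."""
    labels, n = ndimage.label(strong, structure=_STRUCT6)
    slices = ndimage.find_objects(labels)
    order = sorted(
        range(n),
        key=lambda i: (slices[i][0].start, slices[i][1].start, slices[i][2].start),
    )
    return labels, n, [slices[i] for i in order], order


def find_spots(experiment, images, params=None):
    """Find strong spots on an image stack -> ReflectionTable with shoeboxes.

    ``images``: (n_frames, n_slow, n_fast) array matching the experiment
    scan.  Pixels above the detector's trusted maximum are excluded from
    thresholding unless ``params.maximum_trusted_value`` raises the limit,
    in which case retained overloaded pixels flag their reflection.
    """
    params = params or SpotFindParams()
    det = experiment.detector
    scan = experiment.scan
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    n_frames = images.shape[0]
    if n_frames == 0:
        return ReflectionTable()

    trusted_max = det.trusted_range[1]
    if params.maximum_trusted_value is not None:
        trusted_max = params.maximum_trusted_value
    base_mask = det.pixel_mask()

    strong = np.zeros(images.shape, dtype=bool)
    for z in range(n_frames):
        frame = images[z].astype(float)
        mask = base_mask & (frame >= det.trusted_range[0]) & (frame <= trusted_max)
        strong[z] = dispersion_threshold(
            frame, mask, params.gain, params.nsig_b, params.nsig_s,
            params.global_threshold,
        )

    labels, n, slices, order = label_connected(strong)
    if n == 0:
        return ReflectionTable()

    rows = []
    shoeboxes = []
    overload_level = det.trusted_range[1]
    for rank, sl in enumerate(slices):
        lab = order[rank] + 1
        zsl, ysl, xsl = sl
        z0, z1 = zsl.start, zsl.stop
        y0, y1 = max(0, ysl.start - 1), min(det.n_slow, ysl.stop + 1)
        x0, x1 = max(0, xsl.start - 1), min(det.n_fast, xsl.stop + 1)
        data = images[z0:z1, y0:y1, x0:x1].astype(float)
        inbox = labels[z0:z1, y0:y1, x0:x1] == lab
        mask = np.where(inbox, MASK_FOREGROUND, MASK_BACKGROUND).astype(np.int8)
        mask[~base_mask[None, y0:y1, x0:x1] & ~inbox] = MASK_INVALID
        over = data > overload_level
        mask[over & inbox] = MASK_OVERLOADED
        n_vox = int(inbox.sum())
        w = np.where(inbox, data, 0.0)
        tot = w.sum()
        if tot <= 0:
            w = inbox.astype(float)
            tot = w.sum()
        zz, yy, xx = np.nonzero(inbox)
        wv = w[zz, yy, xx]
        xcen = float(((xx + x0 + 0.5) * wv).sum() / tot)
        ycen = float(((yy + y0 + 0.5) * wv).sum() / tot)
        zcen = float(((zz + z0 + 0.5) * wv).sum() / tot)
        flags = STRONG
        if over.any():
            flags |= OVERLOADED
        rows.append(
            {
                "x_px": xcen, "y_px": ycen, "z_frame": zcen,
                "x_mm": xcen * det.pixel_size[0],
                "y_mm": ycen * det.pixel_size[1],
                "phi_deg": scan.phi_of_frame(zcen),
                "intensity_sum_value": float(tot),
                "n_voxels": n_vox,
                "flags": flags,
            }
        )
        shoeboxes.append(Shoebox(bbox=(x0, x1, y0, y1, z0, z1), data=data, mask=mask))

    df = pd.DataFrame(rows)
    # resolution of each centroid from the experiment geometry
    s1 = _model.s1_of_pixel(experiment, df["x_px"].to_numpy(), df["y_px"].to_numpy())
    r = s1 - experiment.beam.s0
    rlen = np.linalg.norm(r, axis=1)
    with np.errstate(divide="ignore"):
        df["d"] = np.where(rlen > 0, 1.0 / rlen, np.inf)
    table = ReflectionTable(df)
    table.shoeboxes = shoeboxes
    return table


def filter_spots(table, d_min=None, d_max=None, min_spot_size=3,
                 max_spot_size=1000):
    """Drop spots by voxel count and (optionally) resolution range."""
    if d_min is not None and d_max is not None and d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    if len(table) == 0:
        return table
    keep = np.ones(len(table), dtype=bool)
    if "n_voxels" in table:
        nv = table["n_voxels"]
        keep &= (nv >= min_spot_size) & (nv <= max_spot_size)
    if d_min is not None:
        keep &= table["d"] >= d_min
    if d_max is not None:
        keep &= table["d"] <= d_max
    return table.select(keep)
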