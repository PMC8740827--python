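"""Synthetic rotation-experiment generator.

Forward-models a rotation diffraction experiment so that every downstream
stage of the package can be tested by parameter recovery, with no external
data.  The physical model:

* true intensities drawn per acentric Wilson law — exponential with mean
  ``Sigma * exp(-2 * B * (sin(theta)/lambda)^2)`` — from one draw per
  symmetry orbit, so symmetry-equivalent reflections share a true value;
* each reflection crosses the Ewald sphere at phi*, with a Gaussian rocking
  curve of width ``sigma_m`` (deg) partitioning its intensity between
  adjacent frames by normal-CDF differences;
* on the detector face the spot is an isotropic 2D Gaussian of standard
  deviation ``sigma_b * distance * pi/180`` mm centred on the predicted
  position;
* smooth per-image inverse scale ``g(phi) = k(phi) * exp(-2 B(phi) s^2)``
  multiplies the deposited signal (what scaling later has to undo);
* pixel counts are Poisson over a flat background, clipped at saturation;
* optional planted defects: dead / hot / twinkling pixels, a scrambled
  outlier dataset, and per-dataset indexing-ambiguity operators.

All stochastic steps take explicit seeds; identical seeds give identical
output bit for bit.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.special import ndtr  # standard normal CDF

from . import predict as _predict
from .model import (
    A_from_cell_orientation,
    Beam,
    Crystal,
    Detector,
    Experiment,
    Goniometer,
    Scan,
    beam_centre_px,
)
from .reflections import ReflectionTable
from .smv import write_smv

SUPPORTED_SPACE_GROUPS = ("P1", "P2", "P222", "P4", "P422", "P3", "P23", "P432")

_GEMMI_NAMES = {
    "P1": "P 1",
    "P2": "P 1 2 1",
    "P222": "P 2 2 2",
    "P4": "P 4",
    "P422": "P 4 2 2",
    "P3": "P 3",
    "P23": "P 2 3",
    "P432": "P 4 3 2",
}

_DEFAULT_CELLS = {
    "P1": (38.0, 44.0, 52.0, 83.0, 97.0, 105.0),
    "P2": (38.0, 44.0, 52.0, 90.0, 103.0, 90.0),
    "P222": (40.0, 50.0, 60.0, 90.0, 90.0, 90.0),
    "P4": (45.0, 45.0, 55.0, 90.0, 90.0, 90.0),
    "P422": (45.0, 45.0, 55.0, 90.0, 90.0, 90.0),
    "P3": (45.0, 45.0, 55.0, 90.0, 90.0, 120.0),
    "P23": (48.0, 48.0, 48.0, 90.0, 90.0, 90.0),
    "P432": (48.0, 48.0, 48.0, 90.0, 90.0, 90.0),
}


def point_group_ops(space_group):
    """Integer rotation matrices of the point group acting on Miller indices."""
    if space_group not in _GEMMI_NAMES:
        raise ValueError(
            f"unsupported space group '{space_group}'; supported: "
            + ", ".join(SUPPORTED_SPACE_GROUPS)
        )
    sg = gemmi.SpaceGroup(_GEMMI_NAMES[space_group])
    ops = []
    seen = set()
    for op in sg.operations():
        rot = (np.array(op.rot, dtype=np.int64) // 24)
        # action on Miller indices is by the transpose of the fractional rot
        m = rot.T.copy()
        key = m.tobytes()
        if key not in seen:
            seen.add(key)
            ops.append(m)
    return ops


def laue_ops(space_group):
    """Point-group rotations closed under Friedel inversion (on hkl)."""
    ops = point_group_ops(space_group)
    out, seen = [], set()
    for m in ops:
        for s in (1, -1):
            g = s * m
            key = g.tobytes()
            if key not in seen:
                seen.add(key)
                out.append(g)
    return out


def canonical_hkl(hkl, ops):
    """Per-row canonical (lexicographically largest) orbit representative."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    best = None
    for op in ops:
        cand = hkl @ op.T
        if best is None:
            best = cand.copy()
        else:
            # lexicographic max over (h, k, l)
            better = (
                (cand[:, 0] > best[:, 0])
                | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
                | (
                    (cand[:, 0] == best[:, 0])
                    & (cand[:, 1] == best[:, 1])
                    & (cand[:, 2] > best[:, 2])
                )
            )
            best[better] = cand[better]
    return best


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment (desk scale).

    The defaults describe a small, minutes-scale rotation experiment:
    a 256x256 pixel detector of 0.2 mm pixels at 150 mm, 1 A beam,
    180 images of 1 deg, moderate counts on a flat background of
    2 counts/pixel.
    """

    space_group: str = "P222"
    cell: tuple | None = None  # default per space group
    d_min: float = 2.5
    n_fast: int = 256
    n_slow: int = 256
    pixel_size: float = 0.2  # mm
    distance: float = 150.0  # mm
    wavelength: float = 1.0  # A
    phi0: float = 0.0
    dphi: float = 1.0  # deg/image
    n_images: int = 180
    background: float = 2.0  # counts/pixel
    wilson_scale: float = 2000.0  # Sigma, counts
    wilson_B: float = 15.0  # A^2
    sigma_m: float = 0.3  # deg, rocking-curve width
    sigma_b: float = 0.05  # deg, beam divergence / spot footprint
    saturation: float = 65535.0
    scale_amplitude: float = 0.3  # planted k(phi) sinusoid amplitude
    scale_period: float = 180.0  # deg
    decay_slope: float = 0.0  # A^2 per full scan of planted B(phi) ramp
    n_dead: int = 0
    n_hot: int = 0
    n_twinkle: int = 0
    cell_drift: float = 0.0  # fractional linear drift of cell over the scan


@dataclass
class GroundTruth:
    """Manifest of everything the generator decided."""

    config: SimConfig
    cell: tuple
    space_group: str
    U_list: list  # per-dataset 3x3 orientation matrices
    sigma_m: float
    sigma_b: float
    background: float
    wilson_B: float
    wilson_scale: float
    intensities: dict  # canonical hkl tuple -> true mean intensity
    scale_phase: list  # per-dataset phase of the k(phi) sinusoid
    ambiguity_ops: list  # per-dataset 3x3 integer matrices on hkl
    planted_bad_pixels: list  # (x, y, kind)
    outlier_dataset: int | None = None
    saturation: float = 65535.0
    seed: int = 0

    def k_of_phi(self, phi, dataset=0):
        cfg = self.config
        return 1.0 + cfg.scale_amplitude * np.sin(
            2 * np.pi * (np.asarray(phi, float)) / cfg.scale_period
            + self.scale_phase[dataset]
        )

    def B_of_phi(self, phi, dataset=0):
        cfg = self.config
        span = max(cfg.n_images * cfg.dphi, 1e-9)
        return cfg.decay_slope * (np.asarray(phi, float) - cfg.phi0) / span

    def inverse_scale(self, phi, s2, dataset=0):
        """g(phi) = k(phi) exp(-2 B(phi) (sin theta/lambda)^2)."""
        return self.k_of_phi(phi, dataset) * np.exp(
            -2.0 * self.B_of_phi(phi, dataset) * np.asarray(s2, float)
        )

    def true_intensity(self, hkl):
        ops = laue_ops(self.space_group)
        canon = canonical_hkl(hkl, ops)
        return np.array(
            [self.intensities.get(tuple(h), 0.0) for h in canon], dtype=float
        )

    def to_json(self, path):
        d = {
            "cell": list(self.cell),
            "space_group": self.space_group,
            "U_list": [np.asarray(U).tolist() for U in self.U_list],
            "sigma_m": self.sigma_m,
            "sigma_b": self.sigma_b,
            "background": self.background,
            "wilson_B": self.wilson_B,
            "wilson_scale": self.wilson_scale,
            "intensities": {",".join(map(str, k)): v for k, v in self.intensities.items()},
            "scale_phase": list(self.scale_phase),
            "ambiguity_ops": [np.asarray(m).tolist() for m in self.ambiguity_ops],
            "planted_bad_pixels": [list(b) for b in self.planted_bad_pixels],
            "outlier_dataset": self.outlier_dataset,
            "saturation": self.saturation,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def build_experiment(config, U=None, exp_id="0", scan_varying_A=None):
    """Experiment model matching the simulation geometry."""
    cfg = config
    cell = cfg.cell or _DEFAULT_CELLS[cfg.space_group]
    det = Detector(
        origin=(
            -0.5 * cfg.n_fast * cfg.pixel_size,
            -0.5 * cfg.n_slow * cfg.pixel_size,
            cfg.distance,
        ),
        pixel_size=(cfg.pixel_size, cfg.pixel_size),
        n_fast=cfg.n_fast,
        n_slow=cfg.n_slow,
        trusted_range=(0.0, cfg.saturation),
    )
    crystal = None
    if U is not None:
        crystal = Crystal(
            A=A_from_cell_orientation(cell, U),
            space_group=cfg.space_group,
            scan_varying_A=scan_varying_A,
        )
    return Experiment(
        beam=Beam(wavelength=cfg.wavelength),
        goniometer=Goniometer(),
        detector=det,
        scan=Scan(cfg.phi0, cfg.dphi, cfg.n_images),
        crystal=crystal,
        id=exp_id,
    )


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q


def generate_ground_truth(config, seed=0, n_datasets=1, ambiguity=False,
                          outlier=False):
    """Draw all random ingredients of a simulated experiment.

    With ``ambiguity=True`` each dataset after the first is assigned, with
    probability 1/2, a planted reindexing operator drawn from the coset of
    the lattice group over the space-group point group.  With
    ``outlier=True`` the last dataset's intensities are scrambled when
    rendered or tabulated.
    """
    cfg = config
    if cfg.space_group not in SUPPORTED_SPACE_GROUPS:
        raise ValueError(
            f"unsupported space group '{cfg.space_group}'; supported: "
            + ", ".join(SUPPORTED_SPACE_GROUPS)
        )
    cell = cfg.cell or _DEFAULT_CELLS[cfg.space_group]
    rng = np.random.default_rng(seed)
    U_list = [random_rotation(rng) for _ in range(n_datasets)]

    # enumerate the asymmetric unit of intensities to d_min
    B = A_from_cell_orientation(cell, np.eye(3))
    hkl = _predict.enumerate_hkl(B, cfg.d_min)
    ops = laue_ops(cfg.space_group)
    canon = canonical_hkl(hkl, ops)
    uniq, inv = np.unique(canon, axis=0, return_inverse=True)
    r = uniq @ B.T
    d = 1.0 / np.linalg.norm(r, axis=1)
    s2 = 1.0 / (4.0 * d * d)
    mean = cfg.wilson_scale * np.exp(-2.0 * cfg.wilson_B * s2)
    draws = rng.exponential(1.0, size=len(uniq)) * mean
    intensities = {tuple(h): float(v) for h, v in zip(uniq, draws)}

    scale_phase = [0.0] + [float(rng.uniform(0, 2 * np.pi)) for _ in range(n_datasets - 1)]

    amb_ops = [np.eye(3, dtype=np.int64)]
    if ambiguity and n_datasets > 1:
        coset = ambiguity_coset_ops(cfg.space_group, cell)
        for _ in range(n_datasets - 1):
            if coset and rng.random() < 0.5:
                amb_ops.append(coset[rng.integers(len(coset))])
            else:
                amb_ops.append(np.eye(3, dtype=np.int64))
    else:
        amb_ops += [np.eye(3, dtype=np.int64) for _ in range(n_datasets - 1)]

    bad = []
    margin = 8  # keep planted defects away from the panel edge
    for kind, n in (("dead", cfg.n_dead), ("hot", cfg.n_hot), ("twinkle", cfg.n_twinkle)):
        for _ in range(n):
            x = int(rng.integers(margin, cfg.n_fast - margin))
            y = int(rng.integers(margin, cfg.n_slow - margin))
            bad.append((x, y, kind))

    return GroundTruth(
        config=cfg,
        cell=tuple(cell),
        space_group=cfg.space_group,
        U_list=U_list,
        sigma_m=cfg.sigma_m,
        sigma_b=cfg.sigma_b,
        background=cfg.background,
        wilson_B=cfg.wilson_B,
        wilson_scale=cfg.wilson_scale,
        intensities=intensities,
        scale_phase=scale_phase,
        ambiguity_ops=amb_ops,
        planted_bad_pixels=bad,
        outlier_dataset=(n_datasets - 1) if (outlier and n_datasets > 1) else None,
        saturation=cfg.saturation,
        seed=seed,
    )


def lattice_ops_for_cell(space_group):
    """Proper rotations of the holohedry of the lattice implied by the
    space group's crystal system, acting on hkl."""
    holohedry = {
        "P1": "P1", "P2": "P2", "P222": "P222",
        "P4": "P422", "P422": "P422",
        "P3": "P3",  # metric holohedry is 622; handled via index module for cells
        "P23": "P432", "P432": "P432",
    }[space_group]
    return point_group_ops(holohedry)


def ambiguity_coset_ops(space_group, cell=None):
    """Lattice-group operators not in the space-group point group (on hkl)."""
    latt = lattice_ops_for_cell(space_group)
    if space_group == "P3":
        # hexagonal metric: add the twofold about c to the lattice group
        twofold = np.diag([-1, -1, 1]).astype(np.int64)
        extra = []
        for m in list(latt):
            g = m @ twofold
            if not any(np.array_equal(g, e) for e in latt + extra):
                extra.append(g)
        latt = latt + extra
    pg = point_group_ops(space_group)

    def in_group(m, group):
        return any(np.array_equal(m, g) for g in group)

    return [m for m in latt if not in_group(m, pg)]


def predict_reflections(experiment, d_min):
    """Predict all reflections in the scan to d_min -> ReflectionTable.

    Every root of the Ewald-sphere crossing inside the scan with a
    detector intersection inside the panel yields one row.
    """
    res = _predict.predict(experiment, d_min=d_min)
    import pandas as pd

    df = pd.DataFrame(
        {
            "h": res["hkl"][:, 0],
            "k": res["hkl"][:, 1],
            "l": res["hkl"][:, 2],
            "x_cal_px": res["x_px"],
            "y_cal_px": res["y_px"],
            "phi_cal_deg": res["phi_deg"],
            "z_cal_frame": res["z_frame"],
            "d": res["d"],
            "two_theta_deg": res["two_theta_deg"],
        }
    )
    return ReflectionTable(df)


def frame_fractions(phi_star, scan, sigma_m, z_lo, z_hi):
    """Fractions of a reflection's intensity landing on frames z_lo..z_hi-1.

    Gaussian rocking curve: frame j receives
    Phi((phi_{j+1}-phi*)/sigma) - Phi((phi_j-phi*)/sigma).
    """
    edges = scan.phi_of_frame(np.arange(z_lo, z_hi + 1))
    cdf = ndtr((edges - phi_star) / sigma_m)
    return np.diff(cdf)


def render_images(experiment, truth, out_dir=None, seed=0, dataset=0,
                  noise=True, return_stack=True, scramble=False):
    """Render the SMV image stack for one dataset.

    Returns (stack, paths): the (n_images, n_slow, n_fast) float array of
    stored counts and the list of written SMV files (empty if ``out_dir``
    is None).  ``scramble=True`` randomly permutes true intensities among
    reflections (the planted outlier-dataset behaviour).
    """
    cfg = truth.config
    scan = experiment.scan
    det = experiment.detector
    rng = np.random.default_rng(np.random.SeedSequence([seed, dataset, 0xD1A15]))

    pred = _predict.predict(experiment, d_min=cfg.d_min)
    hkl = pred["hkl"]
    n = len(hkl)
    I_true = truth.true_intensity(hkl) if n else np.zeros(0)
    if scramble and n:
        I_true = I_true[rng.permutation(n)]
    s2 = 1.0 / (4.0 * pred["d"] ** 2) if n else np.zeros(0)
    g = truth.inverse_scale(pred["phi_deg"], s2, dataset) if n else np.zeros(0)
    I_dep = I_true * g

    sd_mm = truth.sigma_b * cfg.distance * math.pi / 180.0
    sd_px = sd_mm / cfg.pixel_size
    half = max(2, int(math.ceil(4.0 * sd_px)) + 1)

    signal = np.zeros((scan.n_images, det.n_slow, det.n_fast), dtype=float)
    for i in range(n):
        phi_star = pred["phi_deg"][i]
        zc = scan.frame_of_phi(phi_star)
        z_lo = max(0, int(math.floor(zc - 5.0 * truth.sigma_m / scan.dphi)) - 1)
        z_hi = min(scan.n_images, int(math.ceil(zc + 5.0 * truth.sigma_m / scan.dphi)) + 1)
        if z_hi <= z_lo:
            continue
        fr = frame_fractions(phi_star, scan, truth.sigma_m, z_lo, z_hi)
        xc, yc = pred["x_px"][i], pred["y_px"][i]
        x0 = max(0, int(math.floor(xc)) - half)
        x1 = min(det.n_fast, int(math.floor(xc)) + half + 1)
        y0 = max(0, int(math.floor(yc)) - half)
        y1 = min(det.n_slow, int(math.floor(yc)) + half + 1)
        if x1 <= x0 or y1 <= y0:
            continue
        ex = np.diff(ndtr((np.arange(x0, x1 + 1) - xc) / sd_px))
        ey = np.diff(ndtr((np.arange(y0, y1 + 1) - yc) / sd_px))
        patch = np.outer(ey, ex)
        for j, f in enumerate(fr):
            if f <= 0:
                continue
            signal[z_lo + j, y0:y1, x0:x1] += I_dep[i] * f * patch

    signal += truth.background
    if noise:
        stack = rng.poisson(signal).astype(float)
    else:
        stack = signal.copy()
    np.clip(stack, 0, truth.saturation, out=stack)

    for x, y, kind in truth.planted_bad_pixels:
        if kind == "dead":
            stack[:, y, x] = 0
        elif kind == "hot":
            stack[:, y, x] = truth.saturation
        elif kind == "twinkle":
            stack[0::2, y, x] = 0
            stack[1::2, y, x] = truth.saturation

    paths = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        bx, by = beam_centre_px(experiment)
        for z in range(scan.n_images):
            path = os.path.join(out_dir, f"sim_{dataset}_{z + 1:04d}.img")
            write_smv(
                path,
                stack[z],
                {
                    "PIXEL_SIZE": cfg.pixel_size,
                    "DISTANCE": cfg.distance,
                    "WAVELENGTH": cfg.wavelength,
                    "OSC_START": scan.phi_of_frame(z),
                    "OSC_RANGE": scan.dphi,
                    "BEAM_CENTER_X": bx * cfg.pixel_size,
                    "BEAM_CENTER_Y": by * cfg.pixel_size,
                },
            )
            paths.append(path)
    return (stack if return_stack else None), paths


def two_lattice_config():
    """Reduced study conditions for the two-lattice scenario: a 64x64 px
    panel and a small triclinic cell, so both lattices resolve cleanly at
    desk scale."""
    return SimConfig(
        space_group="P1",
        cell=(24.0, 28.0, 32.0, 85.0, 95.0, 100.0),
        n_fast=64, n_slow=64, pixel_size=0.8, distance=100.0,
        n_images=90, d_min=2.8, wilson_scale=3000.0,
    )


def simulate_two_lattice(config, seed=0, noise=True):
    """Two crystals in the beam: both lattices' reflections land on one
    image stack (shared background and Poisson noise).

    Returns (stack, [experiment per lattice], truth); the experiments
    carry the two planted crystal orientations.
    """
    truth = generate_ground_truth(config, seed=seed, n_datasets=2,
                                  ambiguity=False)
    expts = [build_experiment(config, U=U, exp_id=str(i))
             for i, U in enumerate(truth.U_list)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x271a77]))
    # render each lattice's signal without noise or background, then add
    truth_nobg = replace(truth, background=0.0, planted_bad_pixels=[])
    signal = None
    for i, e in enumerate(expts):
        s, _ = render_images(e, truth_nobg, seed=seed, dataset=i, noise=False)
        signal = s if signal is None else signal + s
    signal += truth.background
    stack = rng.poisson(signal).astype(float) if noise else signal
    np.clip(stack, 0, truth.saturation, out=stack)
    return stack, expts, truth


def simulate_dataset(config, seed=0, out_dir=None, noise=True):
    """Convenience: ground truth + experiment + rendered stack for 1 dataset.

    With ``config.cell_drift`` non-zero the crystal's cell lengths grow
    linearly by that fraction over the scan (a per-image A model), which
    the scan-varying refinement should recover.
    """
    truth = generate_ground_truth(config, seed=seed, n_datasets=1)
    sv = None
    if config.cell_drift:
        n = config.n_images
        sv = []
        for i in range(n):
            f = 1.0 + config.cell_drift * (i + 0.5) / n
            cell_i = tuple(np.array(truth.cell) * [f, f, f, 1, 1, 1])
            sv.append(A_from_cell_orientation(cell_i, truth.U_list[0]))
    expt = build_experiment(config, U=truth.U_list[0], exp_id="0",
                            scan_varying_A=sv)
    stack, paths = render_images(expt, truth, out_dir=out_dir, seed=seed, noise=noise)
    return truth, expt, stack, paths


def simulate_multi(config, n_datasets, seed=0, out_dir=None, ambiguity=True,
                   outlier=False, render=True, noise=True):
    """Simulate several datasets sharing one set of true intensities.

    Each dataset has its own random orientation, its own scale-curve phase
    and optionally a planted indexing-ambiguity operator; the last dataset
    can be a planted outlier with scrambled intensities.  Returns
    (list of (stack, experiment, paths), truth).
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    truth = generate_ground_truth(config, seed=seed, n_datasets=n_datasets,
                                  ambiguity=ambiguity, outlier=outlier)
    out = []
    for m in range(n_datasets):
        expt = build_experiment(config, U=truth.U_list[m], exp_id=str(m))
        stack, paths = (None, [])
        if render:
            stack, paths = render_images(
                expt, truth, out_dir=out_dir, seed=seed, dataset=m, noise=noise,
                scramble=(truth.outlier_dataset == m),
            )
        out.append((stack, expt, paths))
    return out, truth


def simulate_intensity_tables(config, n_datasets=1, seed=0, ambiguity=False,
                              outlier=False, obs_per_dataset=None):
    """Table-level simulation: integrated-intensity observations, no images.

    For each dataset, reflections predicted in its scan acquire observed
    intensities ``I_obs ~ Normal(g * I_true, g * I_true + v_bg)`` — the
    Gaussian limit of Poisson counting over the spot plus a flat-background
    term — with the planted inverse scale g(phi) and, where configured, an
    ambiguity operator applied to the indices.  Returns (tables, truth).
    """
    truth = generate_ground_truth(config, seed=seed, n_datasets=n_datasets,
                                  ambiguity=ambiguity, outlier=outlier)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AB7E]))
    v_bg = 25.0 * config.background  # ~foreground-pixel count x background
    tables = []
    import pandas as pd

    for m in range(n_datasets):
        expt = build_experiment(config, U=truth.U_list[m], exp_id=str(m))
        pred = _predict.predict(expt, d_min=config.d_min)
        hkl = pred["hkl"]
        if obs_per_dataset is not None and len(hkl) > obs_per_dataset:
            sel = rng.choice(len(hkl), size=obs_per_dataset, replace=False)
            hkl = hkl[sel]
            for key in ("x_px", "y_px", "phi_deg", "z_frame", "d"):
                pred[key] = pred[key][sel]
        I_true = truth.true_intensity(hkl)
        if truth.outlier_dataset == m:
            I_true = I_true[rng.permutation(len(I_true))]
        s2 = 1.0 / (4.0 * pred["d"] ** 2)
        g = truth.inverse_scale(pred["phi_deg"], s2, m)
        var = np.maximum(g * I_true + v_bg, 1e-6)
        I_obs = g * I_true + rng.standard_normal(len(hkl)) * np.sqrt(var)
        hkl_out = hkl @ truth.ambiguity_ops[m].T
        df = pd.DataFrame(
            {
                "h": hkl_out[:, 0],
                "k": hkl_out[:, 1],
                "l": hkl_out[:, 2],
                "id": m,
                "x_px": pred["x_px"],
                "y_px": pred["y_px"],
                "z_frame": pred["z_frame"],
                "phi_deg": pred["phi_deg"],
                "d": pred["d"],
                "intensity_sum_value": I_obs,
                "intensity_sum_variance": var,
            }
        )
        t = ReflectionTable(df)
        from .reflections import INDEXED, INTEGRATED_SUM

        t.set_flags(np.ones(len(t), dtype=bool), INDEXED | INTEGRATED_SUM)
        tables.append(t)
    return tables, truth
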