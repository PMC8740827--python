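"""Centroid refinement: minimize observed-minus-predicted residuals.

Static refinement adjusts three crystal orientation angles, the
symmetry-constrained unit-cell parameters, the detector origin and the
detector in-plane rotation by (damped) least squares on weighted centroid
residuals (dx mm, dy mm, dphi deg).  Scan-varying refinement then attaches
orientation and cell parameters to knots spaced every ``interval_deg``
along the scan, interpolated with a Gaussian smoother over the three
nearest knots (sd = interval/2), which absorbs slow drifts of the crystal
model over the rotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import model as _model
from . import predict as _predict
from .model import axis_angle_matrix
from .reflections import INDEXED

SYSTEM_OF_SG = {
    "P1": "triclinic",
    "P2": "monoclinic",
    "P222": "orthorhombic",
    "P4": "tetragonal",
    "P422": "tetragonal",
    "P3": "hexagonal",
    "P23": "cubic",
    "P432": "cubic",
}

_CELL_PARAMS = {
    "triclinic": ((0, 1, 2, 3, 4, 5), None),
    "monoclinic": ((0, 1, 2, 4), None),
    "orthorhombic": ((0, 1, 2), None),
    "tetragonal": ((0, 2), None),
    "hexagonal": ((0, 2), None),
    "cubic": ((0,), None),
}


def cell_free_params(cell, system):
    idx, _ = _CELL_PARAMS[system]
    return [cell[i] for i in idx]


def cell_from_free(free, system):
    f = list(free)
    if system == "triclinic":
        return tuple(f)
    if system == "monoclinic":
        a, b, c, be = f
        return (a, b, c, 90.0, be, 90.0)
    if system == "orthorhombic":
        a, b, c = f
        return (a, b, c, 90.0, 90.0, 90.0)
    if system == "tetragonal":
        a, c = f
        return (a, a, c, 90.0, 90.0, 90.0)
    if system == "hexagonal":
        a, c = f
        return (a, a, c, 90.0, 90.0, 120.0)
    if system == "cubic":
        return (f[0],) * 3 + (90.0, 90.0, 90.0)
    raise ValueError(system)


@dataclass
class RefineParams:
    refine_beam: bool = False  # reserved; beam fixed at desk scale
    refine_detector: bool = True
    outlier_mads: float = 4.5
    max_iterations: int = 50
    phi_window_deg: float = 2.0
    centroid_floor_px: float = 0.25
    centroid_floor_frames: float = 0.25


@dataclass
class RefineResult:
    rmsd_x_before: float
    rmsd_y_before: float
    rmsd_phi_before: float
    rmsd_x_after: float
    rmsd_y_after: float
    rmsd_phi_after: float
    parameters: np.ndarray
    n_outliers: int = 0
    n_used: int = 0
    knots_phi: np.ndarray | None = None
    knot_cells: list | None = None
    knot_U: list | None = None


def _misset_matrix(rx, ry, rz):
    return (
        axis_angle_matrix((0, 0, 1), rz)
        @ axis_angle_matrix((0, 1, 0), ry)
        @ axis_angle_matrix((1, 0, 0), rx)
    )


def _apply_detector_params(detector, dx, dy, dz, tau_deg):
    f = np.asarray(detector.fast_axis)
    s = np.asarray(detector.slow_axis)
    n = detector.normal
    origin = np.asarray(detector.origin) + dx * f + dy * s + dz * n
    R = axis_angle_matrix(n, tau_deg)
    return replace(
        detector,
        origin=tuple(origin),
        fast_axis=tuple(R @ f),
        slow_axis=tuple(R @ s),
    )


class _Target:
    """Shared state for the least-squares target: the observation list,
    search windows, weights, and the parameter layout."""

    def __init__(self, experiment, table, params, cell_system):
        self.expt = experiment
        self.params = params
        self.system = cell_system
        sel = table.get_flags(INDEXED) if "flags" in table else np.ones(len(table), bool)
        sub = table.select(sel)
        self.hkl = sub.hkl
        self.x_obs = sub["x_px"]
        self.y_obs = sub["y_px"]
        self.phi_obs = sub["phi_deg"]
        det = experiment.detector
        self.px = det.pixel_size
        n = len(self.hkl)
        # centroid variance estimate: counting statistics with a floor
        counts = (
            np.maximum(sub["intensity_sum_value"], 1.0)
            if "intensity_sum_value" in sub
            else np.ones(n)
        )
        floor_x = (params.centroid_floor_px * det.pixel_size[0]) ** 2
        floor_phi = (params.centroid_floor_frames * experiment.scan.dphi) ** 2
        spot_var_mm = (1.0 * det.pixel_size[0]) ** 2
        spot_var_phi = experiment.scan.dphi ** 2
        self.sig_x = np.sqrt(spot_var_mm / counts + floor_x)
        self.sig_y = np.sqrt(spot_var_mm / counts + floor_x)
        self.sig_phi = np.sqrt(spot_var_phi / counts + floor_phi)
        w = params.phi_window_deg
        self.windows = np.column_stack([self.phi_obs - w, self.phi_obs + w])
        self.U0 = experiment.crystal.U
        self.cell0 = experiment.crystal.cell
        self.det0 = experiment.detector

    def n_obs(self):
        return len(self.hkl)

    def predictions(self, A_rows, detector):
        """Predicted (x_mm, y_mm, phi_deg, found) with per-row A matrices."""
        scan = self.expt.scan
        gon = self.expt.goniometer
        beam = self.expt.beam
        r0 = np.einsum("nij,nj->ni", A_rows, self.hkl.astype(float))
        idx, phi = _predict.ewald_roots(
            gon.axis, beam.s0, r0,
            scan.phi0 - self.params.phi_window_deg,
            scan.phi_end + self.params.phi_window_deg,
            windows=self.windows,
        )
        n = len(self.hkl)
        found = np.zeros(n, dtype=bool)
        phi_out = np.zeros(n)
        # keep the root closest to the observation if several fall in-window
        for i, p in zip(idx, phi):
            if not found[i] or abs(p - self.phi_obs[i]) < abs(phi_out[i] - self.phi_obs[i]):
                phi_out[i] = p
            found[i] = True
        expt2 = _model.Experiment(
            beam=beam, goniometer=gon, detector=detector, scan=scan,
            crystal=self.expt.crystal, id=self.expt.id,
        )
        rot = _predict.rotate_about(gon.axis, phi_out, r0)
        s1 = rot + beam.s0
        x, y, ok = _predict.detector_intersection(expt2, s1)
        found &= ok
        return x, y, phi_out, found

    def residuals(self, x, y, phi, found):
        rx = (x - self.x_obs) * self.px[0]
        ry = (y - self.y_obs) * self.px[1]
        rphi = phi - self.phi_obs
        big = 5.0
        out = np.concatenate(
            [
                np.where(found, rx / self.sig_x, big),
                np.where(found, ry / self.sig_y, big),
                np.where(found, rphi / self.sig_phi, big),
            ]
        )
        return out

    def rmsds(self, x, y, phi, found):
        if found.sum() == 0:
            return (np.nan, np.nan, np.nan)
        rx = ((x - self.x_obs) * self.px[0])[found]
        ry = ((y - self.y_obs) * self.px[1])[found]
        rphi = (phi - self.phi_obs)[found]
        return (
            float(np.sqrt(np.mean(rx**2))),
            float(np.sqrt(np.mean(ry**2))),
            float(np.sqrt(np.mean(rphi**2))),
        )


def _reject_outliers(target, A, detector, mads):
    x, y, phi, found = target.predictions(
        np.broadcast_to(A, (target.n_obs(), 3, 3)), detector
    )
    keep = found.copy()
    for res in (
        (x - target.x_obs),
        (y - target.y_obs),
        (phi - target.phi_obs) / target.expt.scan.dphi,
    ):
        r = res[found]
        med = np.median(r)
        mad = np.median(np.abs(r - med)) + 1e-12
        ok = np.abs(res - med) <= mads * 1.4826 * mad
        keep &= ok
    return keep


def static_refine(experiment, table, params=None, cell_system=None):
    """Static refinement -> (refined Experiment, RefineResult)."""
    params = params or RefineParams()
    if experiment.crystal is None:
        raise ValueError("experiment has no crystal to refine")
    system = cell_system or SYSTEM_OF_SG.get(
        experiment.crystal.space_group, "triclinic"
    )
    target = _Target(experiment, table, params, system)
    n = target.n_obs()
    if n < 20:
        raise ValueError(f"too few indexed reflections to refine ({n})")

    keep = _reject_outliers(
        target, experiment.crystal.A_matrix, experiment.detector, params.outlier_mads
    )
    n_out = int((~keep).sum())
    target.hkl = target.hkl[keep]
    target.x_obs = target.x_obs[keep]
    target.y_obs = target.y_obs[keep]
    target.phi_obs = target.phi_obs[keep]
    target.sig_x = target.sig_x[keep]
    target.sig_y = target.sig_y[keep]
    target.sig_phi = target.sig_phi[keep]
    target.windows = target.windows[keep]
    n = target.n_obs()

    cell_free0 = cell_free_params(target.cell0, system)
    n_cell = len(cell_free0)
    refine_dz = params.refine_detector and n > 100
    det_pars = (["dx", "dy"] + (["dz"] if refine_dz else []) + ["tau"]) if params.refine_detector else []

    def build(x):
        rx, ry, rz = x[0:3]
        cell = cell_from_free(x[3 : 3 + n_cell], system)
        U = _misset_matrix(rx, ry, rz) @ target.U0
        A = _model.A_from_cell_orientation(cell, U)
        i = 3 + n_cell
        dx = dy = dz = tau = 0.0
        if params.refine_detector:
            dx = x[i]; dy = x[i + 1]; i += 2
            if refine_dz:
                dz = x[i]; i += 1
            tau = x[i]
        det = _apply_detector_params(target.det0, dx, dy, dz, tau)
        return A, det

    x0 = np.concatenate([[0.0, 0.0, 0.0], cell_free0, np.zeros(len(det_pars))])
    scales = np.concatenate(
        [[0.01] * 3, [1e-3 * max(c, 1.0) for c in cell_free0], [0.01] * len(det_pars)]
    )

    def fun(x):
        A, det = build(x)
        A_rows = np.broadcast_to(A, (n, 3, 3))
        return target.residuals(*target.predictions(A_rows, det))

    A0, det0 = build(x0)
    before = target.rmsds(
        *target.predictions(np.broadcast_to(A0, (n, 3, 3)), det0)
    )
    res = least_squares(
        fun, x0, x_scale=scales, ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=params.max_iterations * (len(x0) + 1), method="trf",
    )
    A1, det1 = build(res.x)
    after = target.rmsds(
        *target.predictions(np.broadcast_to(A1, (n, 3, 3)), det1)
    )

    crystal = _model.Crystal(A=A1, space_group=experiment.crystal.space_group)
    new_expt = _model.Experiment(
        beam=experiment.beam, goniometer=experiment.goniometer, detector=det1,
        scan=experiment.scan, crystal=crystal, id=experiment.id,
    )
    result = RefineResult(
        rmsd_x_before=before[0], rmsd_y_before=before[1], rmsd_phi_before=before[2],
        rmsd_x_after=after[0], rmsd_y_after=after[1], rmsd_phi_after=after[2],
        parameters=res.x, n_outliers=n_out, n_used=n,
    )
    return new_expt, result


def predict_centroids(experiment, hkl, phi_hint=None, window_deg=2.0):
    """Predicted (x_px, y_px, phi_deg) for the given indices.

    Reflections never crossing the Ewald sphere in scan are omitted; with
    ``phi_hint`` the root search is restricted to a window per reflection.
    """
    windows = None
    if phi_hint is not None:
        phi_hint = np.asarray(phi_hint, dtype=float)
        windows = np.column_stack([phi_hint - window_deg, phi_hint + window_deg])
    res = _predict.predict(experiment, hkl=hkl, phi_windows=windows)
    return res


def scan_varying_refine(experiment, table, interval_deg=36.0, params=None):
    """Scan-varying crystal refinement -> (Experiment with per-image A,
    RefineResult).  The detector is held at its statically-refined values.
    """
    params = params or RefineParams()
    scan = experiment.scan
    span = scan.n_images * scan.dphi
    if span < interval_deg:
        warnings.warn("scan shorter than one interval; falling back to static")
        e2, r = static_refine(experiment, table, params)
        return e2, r
    system = SYSTEM_OF_SG.get(experiment.crystal.space_group, "triclinic")
    target = _Target(experiment, table, params, system)
    n = target.n_obs()
    if n < 20:
        raise ValueError("too few indexed reflections to refine")

    keep = _reject_outliers(
        target, experiment.crystal.A_matrix, experiment.detector, params.outlier_mads
    )
    for attr in ("hkl", "x_obs", "y_obs", "phi_obs", "sig_x", "sig_y", "sig_phi", "windows"):
        setattr(target, attr, getattr(target, attr)[keep])
    n = target.n_obs()

    n_knots = int(math.floor(span / interval_deg)) + 1
    knots = scan.phi0 + np.linspace(0.0, span, n_knots)
    sd = interval_deg / 2.0

    def smoother_weights(phi):
        phi = np.asarray(phi, dtype=float)
        d2 = (phi[:, None] - knots[None, :]) ** 2
        w = np.exp(-d2 / (2 * sd * sd))
        # keep the 3 nearest knots only
        if n_knots > 3:
            order = np.argsort(d2, axis=1)
            mask = np.zeros_like(w, dtype=bool)
            np.put_along_axis(mask, order[:, :3], True, axis=1)
            w = np.where(mask, w, 0.0)
        return w / w.sum(axis=1, keepdims=True)

    W_obs = smoother_weights(target.phi_obs)
    cell_free0 = cell_free_params(target.cell0, system)
    n_cell = len(cell_free0)
    per_knot = 3 + n_cell

    def knot_A(xk):
        rx, ry, rz = xk[:3]
        cell = cell_from_free(xk[3:], system)
        U = _misset_matrix(rx, ry, rz) @ target.U0
        return _model.A_from_cell_orientation(cell, U)

    def A_rows_of(x):
        A_knots = np.array([knot_A(x[i * per_knot : (i + 1) * per_knot])
                            for i in range(n_knots)])
        return np.einsum("nk,kij->nij", W_obs, A_knots), A_knots

    x0 = np.tile(np.concatenate([[0.0, 0.0, 0.0], cell_free0]), n_knots)
    scales = np.tile(
        np.concatenate([[0.01] * 3, [1e-3 * max(c, 1.0) for c in cell_free0]]),
        n_knots,
    )

    def fun(x):
        A_rows, _ = A_rows_of(x)
        return target.residuals(*target.predictions(A_rows, target.det0))

    A_rows0, _ = A_rows_of(x0)
    before = target.rmsds(*target.predictions(A_rows0, target.det0))
    res = least_squares(
        fun, x0, x_scale=scales, ftol=1e-8, xtol=1e-8, gtol=1e-8,
        max_nfev=params.max_iterations * (len(x0) + 1), method="trf",
    )
    A_rows1, A_knots = A_rows_of(res.x)
    after = target.rmsds(*target.predictions(A_rows1, target.det0))

    # per-image A at frame centres
    phi_centres = scan.phi_of_frame(np.arange(scan.n_images) + 0.5)
    W_img = smoother_weights(phi_centres)
    A_per_image = np.einsum("nk,kij->nij", W_img, A_knots)
    crystal = _model.Crystal(
        A=A_per_image.mean(axis=0),
        space_group=experiment.crystal.space_group,
        scan_varying_A=tuple(tuple(map(tuple, Am)) for Am in A_per_image),
    )
    new_expt = _model.Experiment(
        beam=experiment.beam, goniometer=experiment.goniometer,
        detector=experiment.detector, scan=scan, crystal=crystal,
        id=experiment.id,
    )
    knot_cells = [
        _model.cell_from_A(Ak) for Ak in A_knots
    ]
    result = RefineResult(
        rmsd_x_before=before[0], rmsd_y_before=before[1], rmsd_phi_before=before[2],
        rmsd_x_after=after[0], rmsd_y_after=after[1], rmsd_phi_after=after[2],
        parameters=res.x, n_outliers=int((~keep).sum()), n_used=n,
        knots_phi=knots, knot_cells=knot_cells,
        knot_U=[None] * n_knots,
    )
    return new_expt, result
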