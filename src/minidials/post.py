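"""Post-scaling products.

* two-theta cell refinement: the unit cell (with symmetry constraints)
  against observed scattering angles only, so the result is independent of
  the crystal orientation model, with uncertainties from the inverse
  normal matrix;
* French & Wilson conversion of merged intensities (possibly negative) to
  positive structure-factor amplitudes under a Wilson prior;
* merged output and fixed-format exporters (SHELX HKLF4, column text);
* an incremental JSON processing report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model as _model
from .reflections import OUTLIER, SCALED, ReflectionTable
from .refine import SYSTEM_OF_SG, cell_free_params, cell_from_free
from .scale import _corrected, _group_keys
from .simulate import laue_ops, point_group_ops


@dataclass
class TwoThetaResult:
    cell: tuple
    esd: tuple  # per cell parameter (0 for constrained ones)
    system: str
    n_obs: int
    rmsd_two_theta_deg: float


def two_theta_refine(tables, experiments, system=None):
    """Refine symmetry-constrained cell parameters against 2-theta values.

    2theta_obs comes from each observed centroid's direction relative to
    the beam; 2theta_calc = 2 asin(lambda / (2 d(cell, h))).  Returns a
    TwoThetaResult with esds scaled by the reduced chi-square.
    """
    if isinstance(tables, ReflectionTable):
        tables = [tables]
    if not isinstance(experiments, (list, tuple)):
        experiments = [experiments]
    tts, hkls = [], []
    lam = experiments[0].beam.wavelength
    for t, e in zip(tables, experiments):
        sel = np.ones(len(t), dtype=bool)
        if "flags" in t:
            sel &= ~t.get_flags(OUTLIER)
        x = (t["x_px"] if "x_px" in t else t["x_cal_px"])[sel]
        y = (t["y_px"] if "y_px" in t else t["y_cal_px"])[sel]
        p = _model.lab_coord_of_pixel(e.detector, x, y)
        b = np.asarray(e.beam.direction)
        ct = (p @ b) / np.linalg.norm(p, axis=1)
        tts.append(np.degrees(np.arccos(np.clip(ct, -1, 1))))
        hkls.append(t.hkl[sel])
    tt_obs = np.concatenate(tts)
    hkl = np.vstack(hkls)
    n = len(tt_obs)
    if n < 10:
        raise ValueError(f"too few observations for two-theta refinement ({n})")

    if system is None:
        sg = experiments[0].crystal.space_group if experiments[0].crystal else "P1"
        system = SYSTEM_OF_SG.get(sg, "triclinic")
    cell0 = experiments[0].crystal.cell
    x0 = np.array(cell_free_params(cell0, system), dtype=float)

    h = hkl.astype(float)

    def tt_calc(x):
        cell = cell_from_free(x, system)
        B = _model.B_from_cell(cell)
        r = h @ B.T
        stl = 0.5 * np.linalg.norm(r, axis=1)  # sin(theta)/lambda
        return 2.0 * np.degrees(np.arcsin(np.clip(stl * lam, -1, 1)))

    fit = least_squares(lambda x: tt_calc(x) - tt_obs, x0, method="lm")
    resid = fit.fun
    dof = max(n - len(x0), 1)
    chi2_red = float(resid @ resid) / dof
    J = fit.jac
    try:
        cov = np.linalg.inv(J.T @ J) * chi2_red
        esd_free = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        esd_free = np.full(len(x0), np.nan)

    cell = cell_from_free(fit.x, system)
    # expand free-parameter esds to the 6 cell slots (shared params share esd)
    esd = [0.0] * 6
    idx_map = {
        "triclinic": [0, 1, 2, 3, 4, 5],
        "monoclinic": [0, 1, 2, 4],
        "orthorhombic": [0, 1, 2],
        "tetragonal": [0, 2],
        "hexagonal": [0, 2],
        "cubic": [0],
    }[system]
    for free_i, slot in enumerate(idx_map):
        esd[slot] = float(esd_free[free_i])
    if system in ("tetragonal", "hexagonal"):
        esd[1] = esd[0]
    if system == "cubic":
        esd[1] = esd[2] = esd[0]
    return TwoThetaResult(
        cell=tuple(float(c) for c in cell),
        esd=tuple(esd),
        system=system,
        n_obs=n,
        rmsd_two_theta_deg=float(np.sqrt(np.mean(resid**2))),
    )


def format_cell_esd(value, esd):
    """'57.75947(4)'-style rendering: esd rounded to 1 significant digit."""
    if esd <= 0 or not np.isfinite(esd):
        return f"{value:.5f}"
    exp = int(math.floor(math.log10(esd)))
    # two significant esd digits when the leading digit is 1
    sig = 2 if int(esd / 10**exp) == 1 else 1
    exp -= sig - 1
    digits = max(0, -exp)
    scaled = int(round(esd / 10**exp))
    if scaled == 10**sig:
        scaled //= 10
        digits -= 1
    return f"{value:.{digits}f}({scaled})"


# ---------------------------------------------------------------------------
# French & Wilson


def french_wilson(I, sigma, Sigma, centric=False, n_points=2000):
    """Posterior mean and sd of the amplitude F given I ~ N(F^2, sigma^2)
    and a Wilson prior (acentric p(F) ~ F exp(-F^2/Sigma); centric
    p(F) ~ exp(-F^2/(2 Sigma))).

    Computed by trapezoidal integration over F in [0, sqrt(max(I,0) +
    10 sigma)].  Vectorized over reflections.
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), I.shape).copy()
    Sigma = np.broadcast_to(np.asarray(Sigma, dtype=float), I.shape).copy()
    centric = np.broadcast_to(np.asarray(centric, dtype=bool), I.shape)
    if np.any(sigma <= 0):
        raise ValueError("sigma(I) must be positive")
    if np.any(Sigma <= 0):
        raise ValueError("Sigma must be positive")

    upper = np.sqrt(np.maximum(I, 0.0) + 10.0 * sigma)
    # for strong reflections the posterior is a narrow peak near sqrt(I);
    # sample only its support so the fixed point count resolves the width
    lower = np.zeros_like(upper)
    strong = I / sigma > 30.0
    lower[strong] = np.sqrt(np.maximum(I[strong] - 10.0 * sigma[strong], 0.0))
    grid = np.linspace(0.0, 1.0, n_points)[None, :]
    F = lower[:, None] + (upper - lower)[:, None] * grid
    # log posterior (unnormalized), stabilized per reflection
    log_like = -0.5 * ((I[:, None] - F**2) / sigma[:, None]) ** 2
    with np.errstate(divide="ignore"):
        log_prior_ac = np.where(F > 0, np.log(np.maximum(F, 1e-300)), -np.inf) - F**2 / Sigma[:, None]
    log_prior_c = -(F**2) / (2.0 * Sigma[:, None])
    log_p = log_like + np.where(centric[:, None], log_prior_c, log_prior_ac)
    log_p -= log_p.max(axis=1, keepdims=True)
    p = np.exp(log_p)
    z0 = np.trapezoid(p, F, axis=1)
    z1 = np.trapezoid(p * F, F, axis=1)
    z2 = np.trapezoid(p * F**2, F, axis=1)
    mean = z1 / z0
    var = np.maximum(z2 / z0 - mean**2, 0.0)
    return mean, np.sqrt(var)


def centric_flags(hkl, space_group):
    """A reflection is centric when some rotation of the point group maps
    h to -h."""
    hkl = np.asarray(hkl, dtype=np.int64)
    flags = np.zeros(len(hkl), dtype=bool)
    for op in point_group_ops(space_group):
        flags |= np.all(hkl @ op.T == -hkl, axis=1)
    return flags


@dataclass
class MergedDataset:
    df: pd.DataFrame  # h k l I sigI F sigF multiplicity centric d
    space_group: str
    anomalous: bool


def merge(table, space_group="P1", anomalous=False, n_bins=10):
    """Inverse-variance-weighted merge per unique index, then French &
    Wilson amplitudes with per-bin Sigma = bin mean of max(I, 0)."""
    if isinstance(table, (list, tuple)):
        table = ReflectionTable.concat(table)
    I, sig, ok = _corrected(table)
    keys = _group_keys(table.hkl, space_group, anomalous)
    df = pd.DataFrame(
        {
            "key": [k for k, s in zip(keys, ok) if s],
            "I": I[ok],
            "w": 1.0 / np.maximum(sig[ok] ** 2, 1e-12),
            "d": table["d"][ok],
        }
    )
    grp = df.groupby("key")
    merged = grp.apply(
        lambda g_: pd.Series(
            {
                "I": float((g_["I"] * g_["w"]).sum() / g_["w"].sum()),
                "sigI": float(1.0 / math.sqrt(g_["w"].sum())),
                "multiplicity": len(g_),
                "d": float(g_["d"].mean()),
            }
        ),
        include_groups=False,
    ).reset_index()
    hkl = np.array([list(k) for k in merged["key"]], dtype=np.int64)
    merged["h"], merged["k"], merged["l"] = hkl[:, 0], hkl[:, 1], hkl[:, 2]

    s3 = 1.0 / merged["d"] ** 3
    edges = np.linspace(s3.min() - 1e-12, s3.max() + 1e-12, n_bins + 1)
    bins = np.clip(np.digitize(s3, edges) - 1, 0, n_bins - 1)
    Sigma_bin = np.array(
        [
            max(np.maximum(merged["I"][bins == b], 0.0).mean(), 1e-6)
            if (bins == b).any()
            else 1.0
            for b in range(n_bins)
        ]
    )
    Sigma = Sigma_bin[bins]
    centric = centric_flags(hkl, space_group)
    F, sigF = french_wilson(merged["I"].to_numpy(), merged["sigI"].to_numpy(),
                            Sigma, centric)
    merged["F"] = F
    merged["sigF"] = sigF
    merged["centric"] = centric
    out = merged[["h", "k", "l", "I", "sigI", "F", "sigF", "multiplicity",
                  "centric", "d"]].copy()
    out["multiplicity"] = out["multiplicity"].astype(int)
    return MergedDataset(df=out, space_group=space_group, anomalous=anomalous)


# ---------------------------------------------------------------------------
# exporters


def export_hklf4(data, path):
    """SHELX HKLF4: 3 integer fields of width 4 (h k l) and two fixed-point
    fields of width 8 with 2 decimals (I, sigma), closed by the all-zero
    record."""
    if isinstance(data, MergedDataset):
        rows = data.df[["h", "k", "l", "I", "sigI"]].itertuples(index=False)
    else:
        I, sig, ok = _corrected(data)
        rows = (
            (h, k, l, i, s)
            for (h, k, l), i, s, o in zip(data.hkl, I, sig, ok)
            if o
        )
    with open(path, "w") as fh:
        for h, k, l, i, s in rows:
            if max(abs(int(h)), abs(int(k)), abs(int(l))) > 999:
                raise ValueError("HKLF4 overflow: index magnitude > 999")
            fh.write(f"{int(h):4d}{int(k):4d}{int(l):4d}{i:8.2f}{s:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hklf4(path):
    """Parse an HKLF4 file back -> DataFrame (h, k, l, I, sigI)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if len(line.rstrip("\n")) < 28:
                continue
            h = int(line[0:4]); k = int(line[4:8]); l = int(line[8:12])
            i = float(line[12:20]); s = float(line[20:28])
            if h == 0 and k == 0 and l == 0 and i == 0 and s == 0:
                break
            rows.append((h, k, l, i, s))
    return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigI"])


def export_unmerged_text(table, experiment, path, cell=None, symmetry=None):
    """Column-headed text export of scaled, unmerged observations.

    Columns: h k l batch I sigI scale phi d; the header records the cell,
    symmetry and wavelength.
    """
    I, sig, ok = _corrected(table)
    g = table["inverse_scale"] if "inverse_scale" in table else np.ones(len(table))
    z = table["z_frame"] if "z_frame" in table else table["z_cal_frame"]
    phi = table["phi_deg"] if "phi_deg" in table else table["phi_cal_deg"]
    batch = np.floor(z).astype(int) + experiment.scan.first_image_number
    if cell is None and experiment.crystal is not None:
        cell = experiment.crystal.cell
    if symmetry is None and experiment.crystal is not None:
        symmetry = experiment.crystal.space_group
    with open(path, "w") as fh:
        fh.write("# unmerged reflection data\n")
        if cell is not None:
            fh.write("# cell " + " ".join(f"{c:.6f}" for c in cell) + "\n")
        fh.write(f"# symmetry {symmetry or 'P1'}\n")
        fh.write(f"# wavelength {experiment.beam.wavelength:.6f}\n")
        fh.write("h\tk\tl\tbatch\tI\tsigI\tscale\tphi\td\n")
        hkl = table.hkl
        for i in np.flatnonzero(ok):
            fh.write(
                f"{hkl[i,0]}\t{hkl[i,1]}\t{hkl[i,2]}\t{batch[i]}\t"
                f"{I[i]:.6f}\t{sig[i]:.6f}\t{g[i]:.6f}\t{phi[i]:.4f}\t"
                f"{table['d'][i]:.6f}\n"
            )


def read_unmerged_text(path):
    """Read the column text export -> (DataFrame, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] in ("cell", "symmetry", "wavelength"):
                header[parts[0]] = parts[1:] if parts[0] == "cell" else parts[1]
        else:
            body_start = i
            break
    import io

    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
    return df, header


# ---------------------------------------------------------------------------
# report

REPORT_SCHEMA = {
    "spotfinding": {"n_spots": int, "per_image_spot_count": list},
    "indexing": {"fraction_indexed": float, "per_image_indexed_fraction": list,
                 "cells": list},
    "refinement": {"rmsd_x_mm": float, "rmsd_y_mm": float, "rmsd_phi_deg": float},
    "integration": {"n_integrated": int, "sigma_b_deg": float, "sigma_m_deg": float},
    "symmetry": {"elements": list, "chosen": dict},
    "scaling": {"overall": dict, "bins": list, "error_model": dict},
    "delta_cc_half": {"groups": list},
}


def build_report(**sections):
    """Assemble the incremental JSON report from whichever stage outputs
    exist.  Unknown section names raise; sections may be partial."""
    report = {"format": "minidials-report", "version": 1}
    for name, payload in sections.items():
        if payload is None:
            continue
        if name not in REPORT_SCHEMA:
            raise ValueError(f"unknown report section '{name}'")
        report[name] = payload
    return report


def validate_report(report):
    """Check the report structure against the section schema; returns a
    list of problems (empty when valid)."""
    problems = []
    if report.get("format") != "minidials-report":
        problems.append("missing or wrong 'format' marker")
    for name, payload in report.items():
        if name in ("format", "version"):
            continue
        spec = REPORT_SCHEMA.get(name)
        if spec is None:
            problems.append(f"unknown section '{name}'")
            continue
        for key, typ in spec.items():
            if key in payload and not isinstance(payload[key], typ):
                problems.append(f"{name}.{key} should be {typ.__name__}")
    return problems


def write_report(report, path):
    problems = validate_report(report)
    if problems:
        raise ValueError("invalid report: " + "; ".join(problems))
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
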