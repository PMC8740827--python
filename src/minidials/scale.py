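"""Scaling and merging statistics.

The "physical" scaling model assigns every observation i an inverse scale

    g_i = k(phi_i) * exp(-2 B(phi_i) (sin theta_i / lambda)^2)

with k and B smoothed from knots spaced every 15 degrees along the scan
(Gaussian smoother over the three nearest knots, sd = interval/2; k is
smoothed in the log so it stays positive).  Fitting alternates
inverse-variance merging of symmetry-equivalent observations with a
Gauss-Newton update of the knots, under the gauge <k> = 1 and <B> = 0
(a constant B is absorbed by the merged intensities exactly).

The error model inflates counting sigmas as sigma'^2 = a^2 (sigma^2 +
(b I)^2), with (a, b) chosen so normalized deviations about the merge
means have unit variance overall and in the top intensity decile.

Merging statistics use the standard definitions (R_merge, R_meas, R_pim,
CC1/2 from seeded random half-splits) in equal-volume resolution bins;
the usable resolution limit is where a smooth tanh fit of CC1/2 against
1/d crosses 0.3.  Delta-CC1/2 measures each group's contribution to the
overall CC1/2 and drives iterative scale-and-filter cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .reflections import OUTLIER, SCALED, ReflectionTable
from .simulate import canonical_hkl, laue_ops, point_group_ops

KNOT_INTERVAL_DEG = 15.0
DELTA_CC_HALF_THRESHOLD = 0.008


class ScalingError(RuntimeError):
    pass


@dataclass
class ScalingModel:
    knots_phi: np.ndarray
    log_k_knots: np.ndarray
    B_knots: np.ndarray
    smoother_sd: float
    a: float = 1.0
    b: float = 0.0

    def smoother(self, phi):
        phi = np.asarray(phi, dtype=float)
        d2 = (phi[:, None] - self.knots_phi[None, :]) ** 2
        w = np.exp(-d2 / (2 * self.smoother_sd**2))
        if len(self.knots_phi) > 3:
            order = np.argsort(d2, axis=1)
            mask = np.zeros_like(w, dtype=bool)
            np.put_along_axis(mask, order[:, :3], True, axis=1)
            w = np.where(mask, w, 0.0)
        return w / w.sum(axis=1, keepdims=True)

    def k_of_phi(self, phi):
        return np.exp(self.smoother(phi) @ self.log_k_knots)

    def B_of_phi(self, phi):
        return self.smoother(phi) @ self.B_knots

    def inverse_scale(self, phi, s2):
        return self.k_of_phi(phi) * np.exp(-2.0 * self.B_of_phi(phi) * np.asarray(s2))


def _intensity_and_sigma(table):
    if "intensity_prf_value" in table and np.isfinite(table["intensity_prf_value"]).all():
        I = table["intensity_prf_value"]
        V = table["intensity_prf_variance"]
    else:
        I = table["intensity_sum_value"]
        V = table["intensity_sum_variance"]
    return I, np.sqrt(np.maximum(V, 1e-12))


def _group_keys(hkl, space_group, anomalous):
    ops = point_group_ops(space_group) if anomalous else laue_ops(space_group)
    canon = canonical_hkl(hkl, ops)
    return [tuple(h) for h in canon]


@dataclass
class ScaleParams:
    space_group: str = "P1"
    anomalous: bool = False
    knot_interval: float = KNOT_INTERVAL_DEG
    max_rounds: int = 50
    tol: float = 1e-6
    refine_error_model: bool = True
    # restraints: at typical desk-scale resolution the s^2 lever arm is
    # short, so B(phi) is pulled toward zero (like the decay restraint in
    # production scaling programs) and log k is kept smooth via its second
    # differences
    restraint_sigma_logk: float = 0.1
    restraint_sigma_B: float = 0.3  # A^2


def _prepare(table):
    I, sig = _intensity_and_sigma(table)
    ok = np.isfinite(I) & np.isfinite(sig) & (sig > 0)
    if "flags" in table:
        ok &= ~table.get_flags(OUTLIER)
    return I, sig, ok


def scale_datasets(tables, params=None, experiments=None):
    """Fit one scaling model per dataset -> (tables with inverse_scale,
    list of ScalingModel).

    ``tables`` is a list of reflection tables (one per dataset) carrying
    hkl, phi_deg, d, and integrated intensities.  Merge groups are the
    symmetry-unique reflections of ``params.space_group`` (I+ and I- kept
    separate when anomalous).
    """
    params = params or ScaleParams()
    tables = [t for t in tables]
    n_ds = len(tables)

    I_all, sig_all, ok_all, phi_all, s2_all, key_all, ds_all = [], [], [], [], [], [], []
    for m, t in enumerate(tables):
        I, sig, ok = _prepare(t)
        if ok.sum() == 0:
            raise ScalingError("no observations to scale")
        phi = t["phi_deg"] if "phi_deg" in t else t["phi_cal_deg"]
        s2 = 1.0 / (4.0 * np.maximum(t["d"], 1e-6) ** 2)
        keys = _group_keys(t.hkl, params.space_group, params.anomalous)
        I_all.append(I); sig_all.append(sig); ok_all.append(ok)
        phi_all.append(phi); s2_all.append(s2); key_all.append(keys)
        ds_all.append(np.full(len(t), m))

    I = np.concatenate(I_all)
    sig = np.concatenate(sig_all)
    ok = np.concatenate(ok_all)
    phi = np.concatenate(phi_all)
    s2 = np.concatenate(s2_all)
    ds = np.concatenate(ds_all)
    keys = [k for ks in key_all for k in ks]
    uniq_index = pd.factorize(pd.Series(keys))[0]

    models = []
    for m, t in enumerate(tables):
        pm = phi[ds == m]
        lo, hi = float(pm.min()), float(pm.max())
        n_knots = max(2, int(np.floor((hi - lo) / params.knot_interval)) + 2)
        knots = np.linspace(lo, hi, n_knots)
        models.append(
            ScalingModel(
                knots_phi=knots,
                log_k_knots=np.zeros(n_knots),
                B_knots=np.zeros(n_knots),
                smoother_sd=params.knot_interval / 2.0,
            )
        )
        mult = np.bincount(uniq_index[(ds == m) & ok])
        if (mult[mult > 0].mean() if (mult > 0).any() else 0) < 2:
            warnings.warn(
                f"dataset {m}: fewer than 2 observations per unique on "
                "average; decay term held at 0"
            )
            models[m]._fix_B = True

    W = [models[m].smoother(phi[ds == m]) for m in range(n_ds)]

    def g_of(m):
        sel = ds == m
        k = np.exp(W[m] @ models[m].log_k_knots)
        B = W[m] @ models[m].B_knots
        return k * np.exp(-2.0 * B * s2[sel])

    g = np.ones(len(I))
    for m in range(n_ds):
        g[ds == m] = g_of(m)

    sig_adj = sig.copy()
    prev_obj = np.inf
    for round_ in range(params.max_rounds):
        w = np.where(ok, 1.0 / sig_adj**2, 0.0)
        num = np.bincount(uniq_index, weights=w * g * I)
        den = np.bincount(uniq_index, weights=w * g * g)
        mean_I = num / np.maximum(den, 1e-30)
        target = mean_I[uniq_index]

        for m in range(n_ds):
            sel = (ds == m) & ok
            Wm = W[m][ok[ds == m]]
            fix_B = getattr(models[m], "_fix_B", False)
            nk = len(models[m].knots_phi)

            # restraint weight: comparable to the statistical information a
            # knot's share of the observations carries
            w_rest = np.sqrt(max(sel.sum(), 1)) / nk

            def resid(x):
                logk = x[:nk]
                Bk = models[m].B_knots if fix_B else x[nk:]
                gm = np.exp(Wm @ logk) * np.exp(-2.0 * (Wm @ Bk) * s2[sel])
                data_res = np.sqrt(w[sel]) * (I[sel] - gm * target[sel])
                parts = [data_res]
                if nk > 2:
                    parts.append(w_rest * np.diff(logk, 2) / params.restraint_sigma_logk)
                if not fix_B:
                    parts.append(w_rest * Bk / params.restraint_sigma_B)
                return np.concatenate(parts)

            x0 = (
                models[m].log_k_knots
                if fix_B
                else np.concatenate([models[m].log_k_knots, models[m].B_knots])
            )
            fit = least_squares(resid, x0, method="lm", max_nfev=3 * (len(x0) + 1))
            models[m].log_k_knots = fit.x[:nk]
            if not fix_B:
                models[m].B_knots = fit.x[nk:]

        for m in range(n_ds):
            g[ds == m] = g_of(m)
        # gauge: <k> = 1 over observations, <B> = 0 per dataset
        for m in range(n_ds):
            sel = (ds == m) & ok
            k_mean = np.exp(W[m][ok[ds == m]] @ models[m].log_k_knots).mean()
            models[m].log_k_knots -= np.log(max(k_mean, 1e-12))
            if not getattr(models[m], "_fix_B", False):
                B_mean = (W[m][ok[ds == m]] @ models[m].B_knots).mean()
                models[m].B_knots -= B_mean
            g[ds == m] = g_of(m)

        obj = float(np.sum(w * (I - g * target) ** 2))
        # the merge target refreshes each round, so the objective is not
        # strictly monotone; require a stable value over a few rounds
        if round_ >= 5 and abs(prev_obj - obj) <= params.tol * max(obj, 1e-12):
            break
        prev_obj = obj

    # error model on the pooled scaled observations
    a, b = 1.0, 0.0
    if params.refine_error_model:
        a, b = refine_error_model_arrays(
            I[ok] / g[ok], sig[ok] / g[ok], uniq_index[ok]
        )
    for m in range(n_ds):
        models[m].a, models[m].b = a, b

    out_tables = []
    pos = 0
    for m, t in enumerate(tables):
        nt = len(t)
        t = t.copy()
        gm = g[pos : pos + nt]
        t["inverse_scale"] = gm
        t.set_flags(ok[pos : pos + nt], SCALED)
        out_tables.append(t)
        pos += nt
    return out_tables, models


def refine_error_model(table, space_group="P1", anomalous=False):
    """Fit (a, b) with sigma'^2 = a^2 (sigma^2 + (b I)^2) on a scaled table."""
    I, sig, ok = _prepare(table)
    g = table["inverse_scale"] if "inverse_scale" in table else np.ones(len(table))
    keys = _group_keys(table.hkl, space_group, anomalous)
    uniq = pd.factorize(pd.Series(keys))[0]
    return refine_error_model_arrays(I[ok] / g[ok], sig[ok] / g[ok], uniq[ok])


def refine_error_model_arrays(I, sig, uniq_index):
    """(a, b) from corrected intensities grouped by ``uniq_index``."""
    uniq, inv = np.unique(uniq_index, return_inverse=True)
    counts = np.bincount(inv)
    multi = counts[inv] >= 2
    if multi.sum() < 10:
        warnings.warn("error model degenerate (all singletons); returning (1, 0)")
        return 1.0, 0.0
    I = I[multi]
    sig = sig[multi]
    inv = pd.factorize(inv[multi])[0]
    n = np.bincount(inv)

    mean_I = np.bincount(inv, weights=I) / n
    dev = I - mean_I[inv]
    corr = np.sqrt(n[inv] / np.maximum(n[inv] - 1.0, 1.0))
    top = I >= np.quantile(I, 0.9)

    def norm_var(params):
        a, b = params
        s2 = a * a * (sig**2 + (b * I) ** 2)
        z = dev * corr / np.sqrt(np.maximum(s2, 1e-12))
        return float(np.var(z)), float(np.var(z[top])) if top.sum() > 5 else float(np.var(z))

    def loss(params):
        if params[0] <= 0 or params[1] < 0:
            return 1e6
        v_all, v_top = norm_var(params)
        return (v_all - 1.0) ** 2 + (v_top - 1.0) ** 2

    res = minimize(loss, x0=[1.0, 0.02], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500})
    a, b = float(abs(res.x[0])), float(abs(res.x[1]))
    return a, b


# ---------------------------------------------------------------------------
# merging statistics


@dataclass
class MergeStats:
    overall: dict
    bins: pd.DataFrame
    anomalous: bool = False
    seed: int = 0


def _corrected(table):
    I, sig, ok = _prepare(table)
    g = table["inverse_scale"] if "inverse_scale" in table else np.ones(len(table))
    return I / g, sig / g, ok


def merge_stats(table, n_bins=10, anomalous=False, seed=0, space_group="P1",
                cell=None, d_min=None, half_labels=None):
    """Standard merging statistics, overall and in equal-volume bins.

    R_merge = sum_h sum_i |I_i - <I>| / sum I; R_meas multiplies each term
    by sqrt(n/(n-1)); R_pim by sqrt(1/(n-1)).  CC1/2 is the correlation
    between merged means of two random half-splits (per-observation labels,
    seeded).  Completeness is reported when ``cell`` is given.
    """
    if isinstance(table, (list, tuple)):
        table = ReflectionTable.concat(table)
    I, sig, ok = _corrected(table)
    d = table["d"]
    keys = _group_keys(table.hkl, space_group, anomalous)
    uniq = pd.factorize(pd.Series(keys))[0]

    if half_labels is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCC12]))
        half_labels = rng.integers(0, 2, size=len(table))

    sel = ok
    df = pd.DataFrame(
        {
            "uniq": uniq[sel],
            "I": I[sel],
            "w": 1.0 / np.maximum(sig[sel] ** 2, 1e-12),
            "d": d[sel],
            "half": half_labels[sel],
        }
    )
    if len(df) == 0:
        raise ScalingError("no observations to merge")

    s3 = 1.0 / df["d"] ** 3
    edges = np.linspace(s3.min() - 1e-12, s3.max() + 1e-12, n_bins + 1)
    df["bin"] = np.clip(np.digitize(s3, edges) - 1, 0, n_bins - 1)

    def stats_of(sub):
        grp = sub.groupby("uniq")
        n = grp["I"].transform("size")
        mean_I = grp["I"].transform("mean")
        multi = n >= 2
        sumI = sub.loc[multi, "I"].abs().sum()
        if multi.sum() and sumI > 0:
            dev = (sub["I"] - mean_I).abs()[multi]
            nn = n[multi]
            r_merge = dev.sum() / sumI
            r_meas = (dev * np.sqrt(nn / (nn - 1))).sum() / sumI
            r_pim = (dev * np.sqrt(1.0 / (nn - 1))).sum() / sumI
        else:
            r_merge = r_meas = r_pim = np.nan
        # CC1/2 over half-split means
        h = sub.groupby(["uniq", "half"])["I"].mean().unstack("half")
        if h.shape[1] == 2:
            both = h.dropna()
            cc = (
                float(np.corrcoef(both[0], both[1])[0, 1])
                if len(both) >= 3 and both[0].std() > 0 and both[1].std() > 0
                else np.nan
            )
            n_cc = len(both)
        else:
            cc, n_cc = np.nan, 0
        w = sub["w"]
        mean_i_sig = float((sub["I"] * np.sqrt(w)).mean())
        return {
            "n_obs": len(sub),
            "n_unique": sub["uniq"].nunique(),
            "multiplicity": len(sub) / max(sub["uniq"].nunique(), 1),
            "mean_i_over_sigma": mean_i_sig,
            "r_merge": float(r_merge),
            "r_meas": float(r_meas),
            "r_pim": float(r_pim),
            "cc_half": cc,
            "n_cc_pairs": n_cc,
        }

    rows = []
    for b in range(n_bins):
        sub = df[df["bin"] == b]
        if len(sub) == 0:
            continue
        row = stats_of(sub)
        row["bin"] = b
        row["d_max"] = float(1.0 / max(edges[b], 1e-9) ** (1 / 3)) if edges[b] > 0 else float("inf")
        row["d_min"] = float(1.0 / edges[b + 1] ** (1 / 3))
        rows.append(row)
    bins = pd.DataFrame(rows)

    overall = stats_of(df)
    overall["d_min"] = float(df["d"].min())
    overall["d_max"] = float(df["d"].max())

    if cell is not None:
        from .model import A_from_cell_orientation
        from .predict import enumerate_hkl

        A = A_from_cell_orientation(cell, np.eye(3))
        all_hkl = enumerate_hkl(A, d_min or overall["d_min"])
        all_keys = set(_group_keys(all_hkl, space_group, anomalous))
        obs_keys = {k for k, s in zip(keys, sel) if s}
        overall["completeness"] = len(obs_keys & all_keys) / max(len(all_keys), 1)
    return MergeStats(overall=overall, bins=bins, anomalous=anomalous, seed=seed)


def resolution_limit(stats, cc_limit=0.3):
    """Resolution at which the fitted CC1/2 curve crosses ``cc_limit``.

    Fits c(s) = c0/2 (1 - tanh((s - s0)/r)) over s = 1/d at bin centres.
    Returns (d_limit, flag) where flag is '' or 'no crossing' / 'fallback'.
    """
    bins = stats.bins.dropna(subset=["cc_half"])
    if len(bins) < 5:
        raise ScalingError("too few bins with defined CC1/2")
    s = 0.5 * (1.0 / bins["d_min"] + 1.0 / bins["d_max"]).to_numpy()
    cc = bins["cc_half"].to_numpy()

    def model(p, s):
        c0, s0, r = p
        return c0 / 2.0 * (1.0 - np.tanh((s - s0) / r))

    try:
        fit = least_squares(
            lambda p: model(p, s) - cc,
            x0=[max(cc.max(), 0.5), float(np.median(s)), 0.1 * (s.max() - s.min() + 1e-6)],
            bounds=([0, 0, 1e-6], [1.2, 10 * s.max(), 10 * s.max()]),
        )
        c0, s0, r = fit.x
        d_edge = float(bins["d_min"].min())  # strongest bin edge
        if model([c0, s0, r], np.array([s.max()]))[0] > cc_limit:
            return d_edge, "no crossing"
        if c0 <= cc_limit:
            return d_edge, "no crossing"
        s_cross = s0 + r * np.arctanh(1.0 - 2.0 * cc_limit / c0)
        if not np.isfinite(s_cross) or s_cross <= 0:
            raise RuntimeError
        return float(1.0 / s_cross), ""
    except Exception:
        below = np.nonzero(cc < cc_limit)[0]
        if len(below) == 0:
            return float(bins["d_min"].min()), "no crossing"
        return float(1.0 / s[below[0]]), "fallback"


# ---------------------------------------------------------------------------
# delta CC1/2 and iterative filtering


def delta_cc_half(tables, grouping="dataset", block_size=10, seed=0,
                  space_group="P1", anomalous=False):
    """Delta CC1/2 per group: CC1/2(all) - CC1/2(all minus group).

    ``tables`` is a list (grouped by dataset) or a single table (grouped by
    image blocks of ``block_size``).  The same per-observation half-split
    labels are used throughout.  Returns (list of (group, delta), overall
    CC1/2).
    """
    if isinstance(tables, ReflectionTable):
        tables = [tables]
    table = ReflectionTable.concat(tables)
    n = len(table)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCC12]))
    half = rng.integers(0, 2, size=n)

    if grouping == "dataset" and len(set(table["id"])) >= 2:
        group_ids = table["id"]
    else:
        z = table["z_frame"] if "z_frame" in table else table["z_cal_frame"]
        group_ids = table["id"] * 10_000 + (np.floor(z).astype(int) // block_size)

    def cc_of(mask):
        sub = table.select(mask)
        st = merge_stats(sub, n_bins=1, anomalous=anomalous, seed=seed,
                         space_group=space_group, half_labels=half[mask])
        return st.overall["cc_half"]

    all_mask = np.ones(n, dtype=bool)
    cc_all = cc_of(all_mask)
    out = []
    for gid in np.unique(group_ids):
        mask = group_ids != gid
        if mask.sum() < 2:
            continue
        try:
            cc_wo = cc_of(mask)
        except ScalingError:
            continue
        out.append((int(gid), float(cc_all - cc_wo)))
    return out, float(cc_all)


@dataclass
class FilterCycle:
    cycle: int
    cc_half: float
    deltas: list
    removed: int | None
    frac_removed: float


def scale_and_filter(tables, params=None, threshold=DELTA_CC_HALF_THRESHOLD,
                     max_cycles=5, max_removed_frac=0.3, seed=0):
    """Iterate scaling and delta-CC1/2 removal until convergence.

    Each cycle scales the surviving datasets, computes per-dataset
    delta CC1/2 and removes the worst group if its delta is below
    ``-threshold``.  Stops when nothing is removed, after ``max_cycles``,
    or when more than ``max_removed_frac`` of the data would be gone.
    Returns (kept tables, kept ids, history).
    """
    params = params or ScaleParams()
    tables = list(tables)
    ids = [int(t["id"][0]) if len(t) else i for i, t in enumerate(tables)]
    n_total = sum(len(t) for t in tables)
    history = []
    for cycle in range(max_cycles):
        scaled, _ = scale_datasets(tables, params)
        deltas, cc_all = delta_cc_half(
            scaled, grouping="dataset", seed=seed,
            space_group=params.space_group, anomalous=params.anomalous,
        )
        removed = None
        if deltas:
            worst_gid, worst = min(deltas, key=lambda t: t[1])
            n_after = sum(
                len(t) for t, i in zip(tables, ids) if i != worst_gid
            )
            frac_gone = 1.0 - n_after / n_total
            if worst < -threshold and frac_gone <= max_removed_frac and len(tables) > 2:
                keep = [i for i, gid in enumerate(ids) if gid != worst_gid]
                tables = [tables[i] for i in keep]
                ids = [ids[i] for i in keep]
                removed = int(worst_gid)
        history.append(
            FilterCycle(
                cycle=cycle, cc_half=cc_all, deltas=deltas, removed=removed,
                frac_removed=1.0 - sum(len(t) for t in tables) / n_total,
            )
        )
        if removed is None:
            break
    return tables, ids, history


def exclude_images(table, dataset, start, end):
    """Flag observations of ``dataset`` whose centroid frame falls in the
    1-based inclusive image range [start, end] as outliers."""
    z = table["z_frame"] if "z_frame" in table else table["z_cal_frame"]
    img = np.floor(z).astype(int) + 1  # 1-based image number
    sel = (table["id"] == dataset) & (img >= start) & (img <= end)
    if not sel.any():
        warnings.warn(f"exclude_images {start}:{end}: no observations in range")
        return table
    t = table.copy()
    t.set_flags(sel, OUTLIER)
    return t
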