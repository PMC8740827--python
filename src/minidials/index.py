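"""Autoindexing: from strong-spot centroids to a crystal model.

The protocol follows the classic rotation-method recipe: map centroids to
reciprocal space with the current geometry, locate lattice periodicity with
a 3D FFT, pick three basis vectors spanning a maximal set of points, assign
Miller indices, and refine — iterating from low to high resolution.

Lattice-symmetry assessment enumerates potential twofold axes as integer
direct/reciprocal vector pairs (u, g) with u.g = 2 and measures the
Le Page delta — the angle between the direct-space axis D.u and the
reciprocal-space axis A.g — which is zero for an exact symmetry axis of
the metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from .model import cell_from_A
from .reflections import INDEXED, ReflectionTable


class IndexingError(RuntimeError):
    pass


def map_to_reciprocal(experiment, table):
    """Reciprocal-space positions of strong centroids (crystal frame, phi=0).

    r = R(e, -phi_obs) . (s1(x, y) - s0)
    """
    from .predict import rotate_about

    x = table["x_px"]
    y = table["y_px"]
    phi = table["phi_deg"]
    s1 = _model.s1_of_pixel(experiment, x, y)
    dr = s1 - experiment.beam.s0
    return rotate_about(experiment.goniometer.axis, -phi, dr)


def fft_candidate_basis(points, grid_n=64, d_min=None, rel_peak_min=0.25):
    """Candidate direct-space basis vectors from the FFT of the reciprocal
    point density.

    Points are binned onto a grid_n^3 grid covering |r| <= 1/d_min; local
    maxima of the FFT amplitude above ``rel_peak_min`` of the largest
    non-origin peak are converted to direct-space vectors (A), ranked by
    peak height.  Vectors shorter than 3 A or beyond the grid's Nyquist
    length are excluded; of each +/- pair only one representative returns.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 20:
        raise IndexingError("too few spots for FFT basis search")
    rnorm = np.linalg.norm(points, axis=1)
    if d_min is None:
        d_min = 1.0 / rnorm.max()
    rmax = 1.0 / d_min
    keep = rnorm <= rmax
    pts = points[keep]

    idx = np.floor((pts + rmax) / (2 * rmax) * grid_n).astype(int)
    idx = np.clip(idx, 0, grid_n - 1)
    density = np.zeros((grid_n, grid_n, grid_n))
    np.add.at(density, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)

    amp = np.abs(np.fft.fftn(density))
    from scipy import ndimage

    local_max = amp == ndimage.maximum_filter(amp, size=3, mode="wrap")
    amp0 = amp.copy()
    amp0[0, 0, 0] = 0.0
    peak_floor = rel_peak_min * amp0.max()
    cand = np.argwhere(local_max & (amp0 >= peak_floor))

    freqs = np.fft.fftfreq(grid_n) * grid_n  # integer frequencies
    out = []
    for m in cand:
        mi = freqs[m].astype(float)
        if not np.any(mi):
            continue
        # parabolic sub-grid interpolation along each axis
        off = np.zeros(3)
        for ax in range(3):
            lo = list(m)
            hi = list(m)
            lo[ax] = (m[ax] - 1) % grid_n
            hi[ax] = (m[ax] + 1) % grid_n
            f0, f1, f2 = amp[tuple(lo)], amp[tuple(m)], amp[tuple(hi)]
            denom = f0 - 2 * f1 + f2
            if denom < 0:
                off[ax] = 0.5 * (f0 - f2) / denom
        vec = (mi + off) * (d_min / 2.0)
        length = np.linalg.norm(vec)
        if length < 3.0 or length > grid_n * d_min / 4.0:
            continue
        # canonical sign: first nonzero component positive
        for c in vec:
            if abs(c) > 1e-9:
                if c < 0:
                    vec = -vec
                break
        out.append((float(amp[tuple(m)]), vec))

    out.sort(key=lambda t: -t[0])
    # dedupe nearly-identical vectors
    vecs = []
    for height, v in out:
        if any(np.linalg.norm(v - w) < 0.5 * d_min for w in vecs):
            continue
        vecs.append(v)
    return vecs


def assign_indices(A, points, tolerance=0.3, adaptive=False):
    """Assign Miller indices: h = round(A^-1 r) where all three fractional
    residuals are below tolerance.  Returns (hkl (n,3) with unindexed rows
    zero, indexed mask, fraction_indexed).

    With ``adaptive=True`` the cut tightens to a robust multiple of the
    observed residual spread (capped at ``tolerance``), which separates
    genuinely lattice-consistent spots from accidental near-matches, e.g.
    spots belonging to a second lattice."""
    A = np.asarray(A, dtype=float)
    points = np.atleast_2d(points)
    h_frac = points @ np.linalg.inv(A).T
    h_round = np.rint(h_frac)
    resid = np.max(np.abs(h_frac - h_round), axis=1)
    ok = (resid < tolerance) & np.any(h_round != 0, axis=1)
    if adaptive and ok.sum() >= 20:
        r = resid[ok]
        sigma = 1.4826 * np.median(np.abs(r - np.median(r))) + 1e-6
        tol_eff = min(tolerance, max(10.0 * sigma, 0.02))
        ok = (resid < tol_eff) & np.any(h_round != 0, axis=1)
    hkl = np.where(ok[:, None], h_round, 0).astype(np.int64)
    frac = float(ok.mean()) if len(ok) else 0.0
    return hkl, ok, frac


def _reduce_direct(D):
    """Shortest-vector (Buerger-style) pass on a direct basis.

    Repeatedly replaces a basis vector by a shorter sum/difference with
    another until no replacement shortens it; restores right-handedness.
    """
    V = [D[:, i].astype(float).copy() for i in range(3)]
    changed = True
    it = 0
    while changed and it < 100:
        changed = False
        it += 1
        order = np.argsort([np.linalg.norm(v) for v in V])
        V = [V[i] for i in order]
        for j in range(2, -1, -1):
            for i in range(3):
                if i == j:
                    continue
                for s in (1.0, -1.0):
                    w = V[j] + s * V[i]
                    if np.linalg.norm(w) < np.linalg.norm(V[j]) - 1e-9:
                        V[j] = w
                        changed = True
    D2 = np.column_stack(V)
    if np.linalg.det(D2) < 0:
        D2[:, 2] *= -1
    return D2


def _reduce_A(A):
    D = np.linalg.inv(A).T
    D2 = _reduce_direct(D)
    return np.linalg.inv(D2).T


def _predict_positions(experiment, table, window_deg=2.0):
    """Predicted pixel positions and angles for the table's indexed rows,
    searching phi near each observation.
    Returns (x_px, y_px, phi_deg, found) per row."""
    from . import predict as _predict

    hkl = table.hkl
    phi_obs = table["phi_deg"]
    windows = np.column_stack([phi_obs - window_deg, phi_obs + window_deg])
    A = experiment.crystal.A_matrix
    r0 = hkl.astype(float) @ A.T
    idx, phi = _predict.ewald_roots(
        experiment.goniometer.axis, experiment.beam.s0, r0,
        experiment.scan.phi0 - window_deg, experiment.scan.phi_end + window_deg,
        windows=windows,
    )
    n = len(hkl)
    x_out = np.zeros(n)
    y_out = np.zeros(n)
    phi_out = np.zeros(n)
    found = np.zeros(n, dtype=bool)
    if len(idx):
        rot = _predict.rotate_about(experiment.goniometer.axis, phi, r0[idx])
        s1 = rot + experiment.beam.s0
        x, y, ok = _predict.detector_intersection(experiment, s1)
        best = {}
        for i_root, (i_row, p) in enumerate(zip(idx, phi)):
            err = abs(p - phi_obs[i_row])
            if ok[i_root] and (i_row not in best or err < best[i_row][0]):
                best[i_row] = (err, x[i_root], y[i_root], p)
        for i_row, (_, xx, yy, pp) in best.items():
            x_out[i_row] = xx
            y_out[i_row] = yy
            phi_out[i_row] = pp
            found[i_row] = True
    return x_out, y_out, phi_out, found


def _A_from_direct(v1, v2, v3):
    D = np.column_stack([v1, v2, v3])
    if np.linalg.det(D) < 0:
        D = np.column_stack([v1, v2, -v3])
    return np.linalg.inv(D).T


def _linear_refit(points, hkl, ok, A_prev=None):
    """Least-squares A minimizing |A h - r| over indexed points.

    Falls back to ``A_prev`` when the indexed set does not constrain all
    three basis vectors (rank-deficient, e.g. on a thin wedge)."""
    H = hkl[ok].astype(float)
    R = points[ok]
    if np.linalg.matrix_rank(H) < 3:
        if A_prev is None:
            raise IndexingError("indexed reflections span fewer than 3 dimensions")
        return A_prev
    At, *_ = np.linalg.lstsq(H, R, rcond=None)
    A_new = At.T
    if A_prev is not None and abs(np.linalg.det(A_new)) < 1e-3 * abs(np.linalg.det(A_prev)):
        return A_prev
    return A_new


def candidate_triple(vecs, points, tolerance=0.3, n_top=12,
                     min_volume=100.0):
    """Pick a basis-vector triple by indexed fraction, subject to
    independence constraints (volume, pairwise angles).

    Among triples within 5% of the best fraction the smallest cell wins:
    a doubled cell's reciprocal lattice is denser and can index everything
    a true cell does (plus stray points), so raw fraction alone favours
    supercells."""
    candidates = []
    pool = vecs[:n_top]
    for i, j, k in itertools.combinations(range(len(pool)), 3):
        v1, v2, v3 = pool[i], pool[j], pool[k]
        vol = abs(np.linalg.det(np.column_stack([v1, v2, v3])))
        if vol < min_volume:
            continue
        angles_ok = True
        for a, b in ((v1, v2), (v1, v3), (v2, v3)):
            cosang = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if not 20.0 < ang < 160.0:
                angles_ok = False
                break
        if not angles_ok:
            continue
        A = _reduce_A(_A_from_direct(v1, v2, v3))
        if min(cell_from_A(A)[:3]) < 3.0:
            continue  # near-dependent triple collapsed under reduction
        hkl, ok, frac = assign_indices(A, points, tolerance)
        if ok.sum() == 0:
            continue
        # every axis must actually discriminate: a basis direction along
        # which all indices collapse to 0 indexes nothing real
        h_ok = hkl[ok]
        if min((h_ok[:, i] != 0).mean() for i in range(3)) < 0.1:
            continue
        candidates.append((frac, vol, A))
    if not candidates:
        raise IndexingError("no independent basis triple found")
    f_max = max(c[0] for c in candidates)
    viable = [c for c in candidates if c[0] >= f_max - 0.05]
    viable.sort(key=lambda c: (c[1], -c[0]))
    return viable[0][2]


@dataclass
class IndexParams:
    tolerance: float = 0.3
    grid_n: int = 64
    max_lattices: int = 1
    d_min: float | None = None
    min_fraction: float = 0.1
    refine_geometry: bool = True
    space_group: str = "P1"
    max_cell: float | None = None  # longest direct axis; None = estimate


def index(experiments, tables, params=None):
    """Index one or more sweeps.

    Returns (crystals, updated tables, info).  With several sweeps the
    reciprocal points are pooled for a single UB determination, then each
    sweep keeps its own refined copy.  ``params.max_lattices > 1`` repeats
    the basis search on the unindexed remainder of the first sweep.
    """
    from . import refine as _refine

    params = params or IndexParams()
    single = not isinstance(experiments, (list, tuple))
    expts = [experiments] if single else list(experiments)
    tabs = [tables] if single else list(tables)

    point_sets = [map_to_reciprocal(e, t) for e, t in zip(expts, tabs)]
    points = np.vstack(point_sets)
    d_obs = 1.0 / np.maximum(np.linalg.norm(points, axis=1), 1e-12)
    d_min_data = params.d_min or float(np.percentile(d_obs, 1.0))

    crystals = []
    info = {"fraction_indexed": [], "per_lattice_fraction": []}
    remaining = np.ones(len(points), dtype=bool)

    for lattice in range(max(1, params.max_lattices)):
        pts = points[remaining]
        if len(pts) < 20:
            break
        max_cell = params.max_cell
        if max_cell is None:
            # estimate the longest plausible axis from the typical spacing
            # between neighbouring reciprocal points
            from scipy.spatial import cKDTree

            nn, _ = cKDTree(pts).query(pts, k=2)
            max_cell = float(np.clip(1.3 / np.median(nn[:, 1]), 20.0, 200.0))
        try:
            # the FFT grid's Nyquist direct length is grid_n * d / 4, so bin
            # only spots at or below the resolution that resolves max_cell
            d_fft = max(d_min_data, 4.0 * max_cell / params.grid_n)
            vecs = fft_candidate_basis(pts, grid_n=params.grid_n, d_min=d_fft)
            A = _reduce_A(candidate_triple(vecs, pts, min(params.tolerance, 0.15)))
        except IndexingError:
            if lattice == 0:
                raise
            break
        # iterate from low resolution inwards
        first_frac = None
        for d_cur in (2.0 * d_min_data, 1.4 * d_min_data, d_min_data):
            sel = np.linalg.norm(pts, axis=1) <= 1.0 / d_cur
            hkl, ok, frac = assign_indices(A, pts[sel], params.tolerance)
            if first_frac is None:
                first_frac = frac
            if ok.sum() >= 5:
                A = _linear_refit(pts[sel], hkl, ok, A_prev=A)
        A = _reduce_A(A)
        hkl, ok, frac = assign_indices(A, pts, params.tolerance, adaptive=True)
        if frac < params.min_fraction:
            if lattice == 0:
                raise IndexingError(
                    f"indexing failed: fraction indexed {frac:.2f} < "
                    f"{params.min_fraction}"
                )
            break
        crystal = _model.Crystal(A=A, space_group=params.space_group)
        crystals.append(crystal)
        info["per_lattice_fraction"].append(frac)
        # mark these points as claimed
        rem_idx = np.flatnonzero(remaining)
        remaining[rem_idx[ok]] = False

    if not crystals:
        raise IndexingError("indexing failed: no lattice found")

    # assign per-sweep tables against all lattices (first match wins)
    offsets = np.cumsum([0] + [len(p) for p in point_sets])
    new_tables = []
    for si, (e, t) in enumerate(zip(expts, tabs)):
        pts = point_sets[si]
        hkl_all = np.zeros((len(pts), 3), dtype=np.int64)
        lat_id = np.full(len(pts), -1, dtype=np.int64)
        for li, cr in enumerate(crystals):
            hkl, ok, _ = assign_indices(cr.A_matrix, pts, params.tolerance,
                                        adaptive=True)
            newly = ok & (lat_id < 0)
            hkl_all[newly] = hkl[newly]
            lat_id[newly] = li
        t = t.copy()
        t.set_hkl(hkl_all)
        t["lattice"] = lat_id
        t["flags"] = t["flags"] & ~INDEXED
        t.set_flags(lat_id >= 0, INDEXED)
        new_tables.append(t)

    # per-sweep refinement of each lattice model
    refined = []
    for li in range(len(crystals)):
        per_sweep = []
        for si, (e, t) in enumerate(zip(expts, new_tables)):
            sub = t.select((t["lattice"] == li) & t.get_flags(INDEXED))
            if len(sub) < 20:
                per_sweep.append(crystals[li])
                continue
            e_l = _model.Experiment(
                beam=e.beam, goniometer=e.goniometer, detector=e.detector,
                scan=e.scan, crystal=crystals[li], id=e.id,
            )
            if params.refine_geometry:
                try:
                    e_ref, _ = _refine.static_refine(e_l, sub)
                    per_sweep.append(e_ref.crystal)
                except Exception:
                    per_sweep.append(crystals[li])
            else:
                per_sweep.append(crystals[li])
        refined.append(per_sweep)

    # final indexed decision by positional residuals against the refined
    # models: accidental near-integer matches (e.g. spots of another
    # lattice) predict to the wrong place on the detector and are dropped
    for si, (e, t) in enumerate(zip(expts, new_tables)):
        keep = np.zeros(len(t), dtype=bool)
        for li in range(len(crystals)):
            sel = (t["lattice"] == li) & t.get_flags(INDEXED)
            if sel.sum() < 10:
                keep |= sel
                continue
            sub = t.select(sel)
            e_l = _model.Experiment(
                beam=e.beam, goniometer=e.goniometer, detector=e.detector,
                scan=e.scan, crystal=refined[li][si], id=e.id,
            )
            x_p, y_p, phi_p, ok_p = _predict_positions(e_l, sub)
            good = np.zeros(len(sub), dtype=bool)
            if ok_p.sum() >= 10:
                rx = (x_p - sub["x_px"])[ok_p]
                ry = (y_p - sub["y_px"])[ok_p]
                rphi = ((phi_p - sub["phi_deg"]) / e.scan.dphi)[ok_p]
                cut = np.ones(ok_p.sum(), dtype=bool)
                for r in (rx, ry, rphi):
                    med = np.median(r)
                    mad = 1.4826 * np.median(np.abs(r - med)) + 1e-3
                    cut &= np.abs(r - med) <= 4.5 * mad
                good[np.flatnonzero(ok_p)[cut]] = True
            else:
                good[:] = ok_p
            idxs = np.flatnonzero(sel)
            keep[idxs[good]] = True
        t["flags"] = t["flags"] & ~INDEXED
        t.set_flags(keep, INDEXED)
        t["lattice"] = np.where(keep, t["lattice"], -1)

    info["fraction_indexed"] = float(
        np.mean(np.concatenate([tt.get_flags(INDEXED) for tt in new_tables]))
    )

    if single:
        crys = [refined[li][0] for li in range(len(crystals))]
        return crys, new_tables[0], info
    # several sweeps: list (per sweep) of lists (per lattice)
    crys = [[refined[li][si] for li in range(len(crystals))] for si in range(len(expts))]
    return crys, new_tables, info


# ---------------------------------------------------------------------------
# Le Page lattice-symmetry assessment


def _coprime_vectors(limit=2):
    out = []
    rng = range(-limit, limit + 1)
    for u in itertools.product(rng, rng, rng):
        if u == (0, 0, 0):
            continue
        g = np.gcd.reduce([abs(c) for c in u if c] or [1])
        if g != 1:
            continue
        # canonical sign: first nonzero positive
        for c in u:
            if c:
                if c < 0:
                    u = tuple(-x for x in u)
                break
        out.append(u)
    return sorted(set(out))


_UG_CANDIDATES = _coprime_vectors(2)


def lepage_twofolds(A, max_delta):
    """Potential twofold axes of the lattice metric.

    Returns a list of dicts with keys u (direct integer axis), g
    (reciprocal integer axis), delta (deg), and R_hkl — the twofold as an
    integer matrix acting on Miller indices.
    """
    A = np.asarray(A, dtype=float)
    D = np.linalg.inv(A).T  # direct basis, columns a, b, c
    found = []
    for u in _UG_CANDIDATES:
        tu = D @ np.asarray(u, dtype=float)
        for g in _UG_CANDIDATES:
            dot = int(np.dot(u, g))
            for gs in ((g, dot), (tuple(-x for x in g), -dot)):
                gg, dd = gs
                if dd not in (1, 2):
                    continue
                qg = A @ np.asarray(gg, dtype=float)
                cosang = (tu @ qg) / (np.linalg.norm(tu) * np.linalg.norm(qg))
                delta = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if delta <= max_delta:
                    uu = np.asarray(u, dtype=np.int64)
                    ggv = np.asarray(gg, dtype=np.int64)
                    # twofold about u: R = (2/(u.g)) u g^T - I (integer for u.g in {1,2})
                    R_direct = (2 // dd) * np.outer(uu, ggv) - np.eye(3, dtype=np.int64)
                    found.append(
                        {
                            "u": uu,
                            "g": ggv,
                            "delta": delta,
                            "R_hkl": R_direct.T.copy(),
                        }
                    )
    # dedupe identical rotation matrices, keep smallest delta
    best = {}
    for f in found:
        key = f["R_hkl"].tobytes()
        if key not in best or f["delta"] < best[key]["delta"]:
            best[key] = f
    return sorted(best.values(), key=lambda f: f["delta"])


def close_group(mats):
    """Closure of a set of integer matrices under multiplication."""
    elems = {np.eye(3, dtype=np.int64).tobytes(): np.eye(3, dtype=np.int64)}
    for m in mats:
        elems[np.asarray(m, dtype=np.int64).tobytes()] = np.asarray(m, dtype=np.int64)
    changed = True
    while changed:
        changed = False
        current = list(elems.values())
        for a in current:
            for b in current:
                c = a @ b
                key = c.tobytes()
                if key not in elems:
                    if len(elems) > 48:
                        raise IndexingError("group closure exceeded order 48")
                    elems[key] = c
                    changed = True
    return list(elems.values())


_BRAVAIS_BY_ORDER = {1: "aP", 2: "mP", 4: "oP", 8: "tP", 12: "hP", 24: "cP"}

_SIGNED_PERMS = []
for perm in itertools.permutations(range(3)):
    for signs in itertools.product((1, -1), repeat=3):
        M = np.zeros((3, 3), dtype=np.int64)
        for col, (row, s) in enumerate(zip(perm, signs)):
            M[row, col] = s
        if round(np.linalg.det(M)) == 1:
            _SIGNED_PERMS.append(M)


@dataclass
class BravaisCandidate:
    bravais_symbol: str
    transform: np.ndarray  # acts on hkl
    cell: tuple
    max_delta: float
    rmsd_after_fit: float | None = None
    n_twofolds: int = 0


_SYSTEM_OF_BRAVAIS = {
    "aP": "triclinic", "mP": "monoclinic", "oP": "orthorhombic",
    "tP": "tetragonal", "hP": "hexagonal", "cP": "cubic",
}


def constrain_cell(cell, system):
    a, b, c, al, be, ga = cell
    if system == "triclinic":
        return cell
    if system == "monoclinic":
        return (a, b, c, 90.0, be, 90.0)
    if system == "orthorhombic":
        return (a, b, c, 90.0, 90.0, 90.0)
    if system == "tetragonal":
        ab = 0.5 * (a + b)
        return (ab, ab, c, 90.0, 90.0, 90.0)
    if system == "hexagonal":
        ab = 0.5 * (a + b)
        return (ab, ab, c, 90.0, 90.0, 120.0)
    if system == "cubic":
        abc = (a + b + c) / 3.0
        return (abc, abc, abc, 90.0, 90.0, 90.0)
    raise ValueError(system)


def _cell_misfit(cell, system):
    a, b, c, al, be, ga = cell
    if system == "triclinic":
        return 0.0
    if system == "monoclinic":
        return abs(al - 90) + abs(ga - 90)
    if system == "orthorhombic":
        return abs(al - 90) + abs(be - 90) + abs(ga - 90)
    if system == "tetragonal":
        return abs(al - 90) + abs(be - 90) + abs(ga - 90) + 100 * abs(a - b) / max(a, b)
    if system == "hexagonal":
        return abs(al - 90) + abs(be - 90) + abs(ga - 120) + 100 * abs(a - b) / max(a, b)
    if system == "cubic":
        return (
            abs(al - 90) + abs(be - 90) + abs(ga - 90)
            + 100 * (abs(a - b) + abs(b - c)) / max(a, b, c)
        )
    raise ValueError(system)


def bravais_candidates(crystal, table=None, experiment=None, max_delta=2.0):
    """Rank possible Bravais settings of an indexed (triclinic) solution.

    Enumerates Le Page twofolds at ``max_delta``, infers the lattice class
    from the closed group they generate, and proposes one candidate per
    supported class up to that symmetry.  Transforms are chosen among
    signed permutations minimizing the constrained-cell misfit.  Triclinic
    aP is always listed.  When ``table`` and ``experiment`` are given, each
    candidate's constrained model is scored by a short refinement and its
    positional rmsd reported.
    """
    A = crystal.A_matrix
    twofolds = lepage_twofolds(A, max_delta)
    try:
        group = close_group([f["R_hkl"] for f in twofolds])
        order = len(group)
    except IndexingError:
        order = 1
    symbol_max = _BRAVAIS_BY_ORDER.get(order, "aP")
    ladder = ["aP", "mP", "oP", "tP", "hP", "cP"]
    # classes to propose: every supported class not above the found order
    reachable = {"aP"}
    if order >= 2:
        reachable.add("mP")
    if order >= 4:
        reachable.add("oP")
    if order >= 8:
        reachable.add("tP")
    if order == 12:
        reachable.add("hP")
        reachable.discard("oP")  # hexagonal metric has no orthorhombic P cell
        reachable.discard("tP")
    if order == 24:
        reachable.add("cP")

    out = []
    for symbol in ladder:
        if symbol not in reachable:
            continue
        system = _SYSTEM_OF_BRAVAIS[symbol]
        best = None
        for M in _SIGNED_PERMS:
            # transform acts on hkl; new A = A M^-1
            A_new = A @ np.linalg.inv(M)
            cell_new = cell_from_A(A_new)
            mis = _cell_misfit(cell_new, system)
            if system == "monoclinic" and cell_new[4] < 90.0:
                mis += 1.0  # prefer beta >= 90 conventions
            if best is None or mis < best[0]:
                best = (mis, M, cell_new)
        mis, M, cell_new = best
        # a class is only credible if a signed-permutation setting brings the
        # cell within ~the Le Page tolerance of its constraints
        if symbol != "aP" and mis > 3.0 * max_delta:
            continue
        delta_here = max(
            (f["delta"] for f in twofolds), default=0.0
        ) if symbol != "aP" else 0.0
        cand = BravaisCandidate(
            bravais_symbol=symbol,
            transform=M,
            cell=constrain_cell(cell_new, system),
            max_delta=delta_here,
            n_twofolds=len(twofolds),
        )
        out.append(cand)

    # optional short refinement for rmsd reporting
    if table is not None and experiment is not None:
        from . import refine as _refine

        for cand in out:
            try:
                t2, cr2 = reindex(table, crystal, cand.transform)
                system = _SYSTEM_OF_BRAVAIS[cand.bravais_symbol]
                cell_c = constrain_cell(cr2.cell, system)
                U = _polar_orientation(cr2.A_matrix, cell_c)
                cr_c = _model.Crystal(
                    A=_model.A_from_cell_orientation(cell_c, U),
                    space_group=crystal.space_group,
                )
                e2 = _model.Experiment(
                    beam=experiment.beam, goniometer=experiment.goniometer,
                    detector=experiment.detector, scan=experiment.scan,
                    crystal=cr_c, id=experiment.id,
                )
                sub = t2.select(t2.get_flags(INDEXED))
                if len(sub) > 300:
                    sub = sub.select(np.linspace(0, len(sub) - 1, 300).astype(int))
                _, result = _refine.static_refine(e2, sub, cell_system=system)
                cand.rmsd_after_fit = float(
                    np.hypot(result.rmsd_x_after, result.rmsd_y_after)
                )
            except Exception:
                cand.rmsd_after_fit = None

    out.sort(key=lambda c: -ladder.index(c.bravais_symbol))
    return out


def _polar_orientation(A, cell):
    """Orientation U closest to A B(cell)^-1 (polar decomposition)."""
    from .model import B_from_cell

    M = A @ np.linalg.inv(B_from_cell(cell))
    Uu, _, Vt = np.linalg.svd(M)
    U = Uu @ Vt
    if np.linalg.det(U) < 0:
        U = Uu @ np.diag([1, 1, -1]) @ Vt
    return U


def reindex(table, crystal, transform):
    """Apply hkl' = M hkl, A' = A M^-1; predictions are unchanged."""
    M = np.asarray(transform)
    det = np.linalg.det(M)
    if abs(det) < 1e-9:
        raise ValueError("reindex transform is not invertible")
    Minv = np.linalg.inv(M)
    new_table = table.copy()
    if "h" in table:
        hkl = table.hkl @ M.T
        hkl_round = np.rint(hkl)
        if not np.allclose(hkl, hkl_round, atol=1e-6):
            raise ValueError("transform does not map indices to integers")
        new_table.set_hkl(hkl_round.astype(np.int64))
    new_crystal = _model.Crystal(
        A=crystal.A_matrix @ Minv,
        space_group=crystal.space_group,
        scan_varying_A=None
        if crystal.scan_varying_A is None
        else tuple(np.asarray(Am) @ Minv for Am in crystal.scan_varying_A),
    )
    return new_table, new_crystal
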