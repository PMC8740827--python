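"""Symmetry determination from intensity statistics.

Each rotation of the lattice point group (the highest symmetry compatible
with the unit-cell metric) is scored by the Pearson correlation between
intensities related by that operator.  The identity's correlation —
measured between random half-splits of repeated observations — estimates
the correlation an operator truly present should reach (CC_true); each
operator then gets a likelihood from a two-component normal model, and
closed subgroups are ranked by the joint log-likelihood of their included
and excluded elements.  The best subgroup fixes both the Laue ("true")
group of the intensities and the acentric rotation-only group assigned to
the output.

For multiple datasets, ``cosym_align`` resolves indexing ambiguity by
assigning one lattice-group operator per dataset to maximize the summed
pairwise intensity correlations — symmetry and consistent indexing are
decided together, with the first dataset fixing the gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import index as _index
from . import model as _model
from .reflections import INDEXED, OUTLIER, ReflectionTable

SIGMA_CC_DEFAULT = 0.1


@dataclass
class SymmetryElement:
    matrix: np.ndarray  # action on hkl
    order: int
    axis: tuple  # integer axis direction (direct space), (0,0,0) for identity

    @property
    def label(self):
        if self.order == 1:
            return "1 (0, 0, 0)"
        return f"{self.order} ({self.axis[0]}, {self.axis[1]}, {self.axis[2]})"


@dataclass
class SymmetryElementScore:
    element: SymmetryElement
    cc: float
    n: int
    z_cc: float
    likelihood: float
    stars: int
    insufficient: bool = False


@dataclass
class SubgroupScore:
    symbol: str  # acentric point-group symbol
    laue_symbol: str
    elements: list  # indices into the scored element list
    score: float
    order: int
    transform: np.ndarray  # reindex operator to the conventional setting


def _element_order(M):
    P = np.eye(3, dtype=np.int64)
    for k in range(1, 7):
        P = P @ M
        if np.array_equal(P, np.eye(3, dtype=np.int64)):
            return k
    raise ValueError("element order > 6")


def _rotation_axis(M_hkl):
    """Integer direct-space axis of a rotation given in its hkl action."""
    # direct-space matrix is the inverse transpose of the hkl action
    Md = np.linalg.inv(M_hkl).T
    w, v = np.linalg.eig(Md)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    # scale to small integers
    nz = np.abs(axis) > 1e-6
    if not nz.any():
        return (0, 0, 0)
    axis = axis / np.min(np.abs(axis[nz]))
    ints = np.rint(axis).astype(int)
    if np.max(np.abs(ints)) > 6 or not np.allclose(axis, ints, atol=1e-3):
        ints = np.rint(axis * 2).astype(int)
    g = np.gcd.reduce(np.abs(ints[ints != 0])) or 1
    ints = ints // g
    for c in ints:
        if c:
            if c < 0:
                ints = -ints
            break
    return tuple(int(x) for x in ints)


def lattice_group_elements(cell, max_delta=2.0):
    """Rotation elements of the lattice point group for a unit cell.

    Derived from the Le Page twofold enumeration closed under
    multiplication; the identity is always included.
    """
    A = _model.A_from_cell_orientation(cell, np.eye(3))
    twofolds = _index.lepage_twofolds(A, max_delta)
    mats = _index.close_group([f["R_hkl"] for f in twofolds])
    elements = []
    for M in mats:
        order = _element_order(M)
        axis = (0, 0, 0) if order == 1 else _rotation_axis(M)
        elements.append(SymmetryElement(matrix=M, order=order, axis=axis))
    elements.sort(key=lambda e: (e.order != 1, e.order, e.axis))
    return elements


def _friedel_canonical(hkl):
    """Canonical representative of {h, -h} (lexicographically larger)."""
    hkl = np.asarray(hkl, dtype=np.int64)
    neg = -hkl
    pick_neg = (
        (neg[:, 0] > hkl[:, 0])
        | ((neg[:, 0] == hkl[:, 0]) & (neg[:, 1] > hkl[:, 1]))
        | ((neg[:, 0] == hkl[:, 0]) & (neg[:, 1] == hkl[:, 1]) & (neg[:, 2] > hkl[:, 2]))
    )
    return np.where(pick_neg[:, None], neg, hkl)


def _intensity_column(table):
    for col in ("intensity_scaled_value", "intensity_prf_value", "intensity_sum_value"):
        if col in table and np.isfinite(table[col]).any():
            return col
    raise ValueError("no intensity column in table")


def _merged_map(table):
    """dict: Friedel-canonical hkl tuple -> (mean I, n obs, list of I)."""
    col = _intensity_column(table)
    sel = np.isfinite(table[col])
    if "flags" in table:
        sel &= ~table.get_flags(OUTLIER)
    hkl = _friedel_canonical(table.hkl[sel])
    I = table[col][sel]
    out = {}
    for h, i in zip(map(tuple, hkl), I):
        out.setdefault(h, []).append(float(i))
    return out


def score_element(table, element, sigma_cc=SIGMA_CC_DEFAULT, cc_true=None,
                  seed=0, merged=None):
    """Score one symmetry element by intensity correlation.

    For the identity, CC is measured between random half-splits of each
    multiply-observed unique reflection.  For other elements, pairs are
    (I(h), I(g.h)) over unique reflections whose partner is also observed.
    ``cc_true`` (the identity CC) calibrates the likelihood; when None it
    is computed first.
    """
    merged = merged if merged is not None else _merged_map(table)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C0]))
    M = np.asarray(element.matrix if isinstance(element, SymmetryElement) else element)

    if np.array_equal(M, np.eye(3, dtype=M.dtype)):
        a, b = [], []
        for h, obs in merged.items():
            if len(obs) >= 2:
                perm = rng.permutation(len(obs))
                half = len(obs) // 2
                a.append(np.mean([obs[i] for i in perm[:half]]))
                b.append(np.mean([obs[i] for i in perm[half:]]))
        pairs = np.array([a, b]).T if a else np.zeros((0, 2))
    else:
        keys = list(merged.keys())
        karr = np.array(keys, dtype=np.int64)
        partners = _friedel_canonical(karr @ M.T)
        seen = set()
        pairs = []
        for h, p in zip(keys, map(tuple, partners)):
            if p == h or p not in merged:
                continue
            key = (h, p) if h < p else (p, h)
            if key in seen:
                continue
            seen.add(key)
            pairs.append((np.mean(merged[h]), np.mean(merged[p])))
        pairs = np.asarray(pairs) if pairs else np.zeros((0, 2))

    n = len(pairs)
    insufficient = n < 10
    if insufficient:
        cc = 0.0
        likelihood = 0.5
    else:
        cc = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
        if cc_true is None:
            cc_true = 0.95
        likelihood = _likelihood(cc, cc_true, sigma_cc)
    z = cc / sigma_cc
    stars = 3 if likelihood > 0.9 else 2 if likelihood > 0.7 else 1 if likelihood > 0.5 else 0
    el = element if isinstance(element, SymmetryElement) else SymmetryElement(
        matrix=M, order=_element_order(M.astype(np.int64)),
        axis=_rotation_axis(M.astype(np.int64)),
    )
    return SymmetryElementScore(
        element=el, cc=cc, n=n, z_cc=z, likelihood=likelihood, stars=stars,
        insufficient=insufficient,
    )


def _likelihood(cc, cc_true, sigma_cc):
    """P(present): two-component normal model, N(cc_true, sigma) vs
    N(0, 2 sigma)."""

    def G(x, mu, s):
        return np.exp(-0.5 * ((x - mu) / s) ** 2) / s

    g1 = G(cc, cc_true, sigma_cc)
    g0 = G(cc, 0.0, 2.0 * sigma_cc)
    return float(g1 / (g1 + g0)) if (g1 + g0) > 0 else 0.5


def score_all_elements(table, elements=None, cell=None, sigma_cc=SIGMA_CC_DEFAULT,
                       max_delta=2.0, seed=0):
    """Score every lattice-group element; identity first (calibrating
    CC_true for the rest)."""
    if elements is None:
        if cell is None:
            raise ValueError("need elements or a cell")
        elements = lattice_group_elements(cell, max_delta)
    merged = _merged_map(table)
    ident = [e for e in elements if e.order == 1][0]
    s_id = score_element(table, ident, sigma_cc, cc_true=None, seed=seed, merged=merged)
    cc_true = max(s_id.cc, 3.0 * sigma_cc)
    s_id.likelihood = _likelihood(s_id.cc, cc_true, sigma_cc)
    s_id.stars = 3 if s_id.likelihood > 0.9 else 2 if s_id.likelihood > 0.7 else 1 if s_id.likelihood > 0.5 else 0
    scores = [s_id]
    for e in elements:
        if e.order == 1:
            continue
        scores.append(
            score_element(table, e, sigma_cc, cc_true=cc_true, seed=seed, merged=merged)
        )
    return scores


# ---------------------------------------------------------------------------
# subgroups

_POINT_GROUP_SYMBOLS = {
    # keyed by sorted tuple of element orders
    (1,): "1",
    (1, 2): "2",
    (1, 2, 2, 2): "222",
    (1, 2, 4, 4): "4",
    (1, 2, 2, 2, 2, 2, 4, 4): "422",
    (1, 3, 3): "3",
    (1, 2, 2, 2, 3, 3): "32",
    (1, 2, 3, 3, 6, 6): "6",
    (1, 2, 2, 2, 2, 2, 2, 2, 3, 3, 6, 6): "622",
    (1, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3): "23",
    (1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4): "432",
}

LAUE_OF_ACENTRIC = {
    "1": "-1", "2": "2/m", "222": "mmm", "4": "4/m", "422": "4/mmm",
    "3": "-3", "32": "-3m", "6": "6/m", "622": "6/mmm", "23": "m-3",
    "432": "m-3m",
}


def point_group_symbol(matrices):
    orders = tuple(sorted(_element_order(np.asarray(M, dtype=np.int64)) for M in matrices))
    return _POINT_GROUP_SYMBOLS.get(orders, f"order{len(matrices)}")


def enumerate_subgroups(elements):
    """All closed subgroups of the element list (as frozensets of element
    indices)."""
    mats = [np.asarray(e.matrix, dtype=np.int64) for e in elements]
    key_of = {m.tobytes(): i for i, m in enumerate(mats)}
    ident = [i for i, e in enumerate(elements) if e.order == 1][0]

    def closure(idx_set):
        group = {ident} | set(idx_set)
        changed = True
        while changed:
            changed = False
            for a in list(group):
                for b in list(group):
                    c = mats[a] @ mats[b]
                    i = key_of.get(c.tobytes())
                    if i is None:
                        return None  # not closed within the lattice group
                    if i not in group:
                        group.add(i)
                        changed = True
        return frozenset(group)

    subgroups = {frozenset([ident])}
    frontier = {frozenset([ident])}
    while frontier:
        new = set()
        for sg in frontier:
            for i in range(len(elements)):
                if i in sg:
                    continue
                cl = closure(sg | {i})
                if cl is not None and cl not in subgroups:
                    subgroups.add(cl)
                    new.add(cl)
        frontier = new
    return sorted(subgroups, key=len)


def choose_subgroup(scores, elements=None, clip=1e-6):
    """Best closed subgroup by summed log-likelihood of included elements
    plus log(1 - likelihood) of excluded ones; ties break to higher order."""
    elements = elements or [s.element for s in scores]
    subs = enumerate_subgroups(elements)
    L = np.clip([s.likelihood for s in scores], clip, 1 - clip)
    best = None
    for sg in subs:
        val = sum(np.log(L[i]) for i in sg) + sum(
            np.log(1 - L[i]) for i in range(len(scores)) if i not in sg
        )
        key = (val, len(sg))
        if best is None or key > best[0]:
            best = (key, sg)
    sg = best[1]
    mats = [np.asarray(elements[i].matrix, dtype=np.int64) for i in sorted(sg)]
    symbol = point_group_symbol(mats)
    transform = conventional_setting_transform(mats, symbol)
    return SubgroupScore(
        symbol=symbol,
        laue_symbol=LAUE_OF_ACENTRIC.get(symbol, symbol),
        elements=sorted(sg),
        score=float(best[0][0]),
        order=len(sg),
        transform=transform,
    )


def conventional_setting_transform(matrices, symbol):
    """Signed-permutation reindex operator mapping the subgroup onto the
    conventional generators of its point group (identity if none found)."""
    from .simulate import point_group_ops, _GEMMI_NAMES

    name = {"1": "P1", "2": "P2", "222": "P222", "4": "P4", "422": "P422",
            "3": "P3", "23": "P23", "432": "P432"}.get(symbol)
    if name is None:
        return np.eye(3, dtype=np.int64)
    target = {np.asarray(m, dtype=np.int64).tobytes() for m in point_group_ops(name)}
    ours = [np.asarray(m, dtype=np.int64) for m in matrices]
    for P in _index._SIGNED_PERMS:
        Pinv = np.rint(np.linalg.inv(P)).astype(np.int64)
        ok = all((P @ M @ Pinv).tobytes() in target for M in ours)
        if ok:
            return P
    return np.eye(3, dtype=np.int64)


def apply_symmetry(table, crystal, subgroup):
    """Reindex to the conventional setting of the chosen subgroup.

    Returns (table, crystal, laue_symbol, acentric_symbol); the crystal's
    space group is set to the acentric ("macromolecular") symbol.
    """
    M = np.asarray(subgroup.transform, dtype=np.int64)
    if abs(round(float(np.linalg.det(M)))) != 1:
        raise ValueError("conventional-setting transform is not unimodular")
    new_table, new_crystal = _index.reindex(table, crystal, M)
    new_crystal = _model.Crystal(
        A=new_crystal.A_matrix,
        space_group={"1": "P1", "2": "P2", "222": "P222", "4": "P4",
                     "422": "P422", "3": "P3", "23": "P23", "432": "P432"}.get(
            subgroup.symbol, "P1"
        ),
        scan_varying_A=new_crystal.scan_varying_A,
    )
    return new_table, new_crystal, subgroup.laue_symbol, subgroup.symbol


# ---------------------------------------------------------------------------
# cosym: multi-dataset operator alignment


def _dataset_vectors(tables, ops):
    """Per dataset and candidate op: merged intensities keyed by canonical
    unique index."""
    vecs = []
    for t in tables:
        merged = _merged_map(t)
        keys = np.array(list(merged.keys()), dtype=np.int64)
        vals = np.array([np.mean(v) for v in merged.values()])
        per_op = []
        for M in ops:
            canon = _friedel_canonical(keys @ np.asarray(M).T)
            d = {}
            for h, v in zip(map(tuple, canon), vals):
                d.setdefault(h, []).append(v)
            per_op.append({h: float(np.mean(v)) for h, v in d.items()})
        vecs.append(per_op)
    return vecs


def _pair_cc(da, db):
    shared = [h for h in da if h in db]
    if len(shared) < 5:
        return 0.0, len(shared)
    a = np.array([da[h] for h in shared])
    b = np.array([db[h] for h in shared])
    if a.std() == 0 or b.std() == 0:
        return 0.0, len(shared)
    return float(np.corrcoef(a, b)[0, 1]), len(shared)


def cosym_align(tables, elements=None, cell=None, max_delta=2.0, seed=0,
                n_restarts=5, min_shared=50):
    """Assign one lattice-group operator per dataset so all datasets index
    consistently.

    Coordinate descent over assignments (dataset 0 fixed to the identity),
    restarted from ``n_restarts`` random starts; the assignment with the
    best summed pairwise CC wins.  Returns (ops, objective).
    """
    if len(tables) < 2:
        raise ValueError("cosym needs at least two datasets")
    if elements is None:
        if cell is None:
            raise ValueError("need elements or a cell")
        elements = lattice_group_elements(cell, max_delta)
    ops = [np.asarray(e.matrix, dtype=np.int64) for e in elements]
    M_data = len(tables)
    vecs = _dataset_vectors(tables, ops)

    n_shared = 0
    for h in vecs[0][0]:
        if all(h in vecs[m][0] or any(h in vecs[m][o] for o in range(len(ops)))
               for m in range(M_data)):
            n_shared += 1
    if n_shared < min_shared:
        raise ValueError(
            f"too few shared unique reflections across datasets ({n_shared})"
        )

    cc_cache = {}

    def pair_term(m1, o1, m2, o2):
        key = (m1, o1, m2, o2)
        if key not in cc_cache:
            cc, _ = _pair_cc(vecs[m1][o1], vecs[m2][o2])
            cc_cache[key] = cc
        return cc_cache[key]

    def objective(assign):
        return sum(
            pair_term(i, assign[i], j, assign[j])
            for i in range(M_data) for j in range(i + 1, M_data)
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC05]))
    best_assign, best_val = None, -np.inf
    for restart in range(n_restarts):
        if restart == 0:
            assign = [0] * M_data
        else:
            assign = [0] + list(rng.integers(0, len(ops), M_data - 1))
        val = objective(assign)
        improved = True
        while improved:
            improved = False
            for m in range(1, M_data):
                cur = assign[m]
                terms = []
                for o in range(len(ops)):
                    assign[m] = o
                    terms.append(objective(assign))
                # operators inside the true point group are equivalent up
                # to noise; prefer the earliest (identity-first) within a
                # small tolerance of the best
                t_best = max(terms)
                o_best = next(o for o, t in enumerate(terms)
                              if t >= t_best - 0.02)
                assign[m] = o_best
                if terms[o_best] > val + 1e-12:
                    val = terms[o_best]
                    improved = improved or (o_best != cur)
        if val > best_val:
            best_val, best_assign = val, list(assign)

    return [ops[o] for o in best_assign], float(best_val)
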