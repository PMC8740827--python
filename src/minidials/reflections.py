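"""Columnar reflection store and the shoebox container.

A :class:`ReflectionTable` is a thin wrapper around a pandas DataFrame with
a fixed column vocabulary, a flags bitmask, and an optional parallel list of
:class:`Shoebox` objects (the cuboid of pixels around each reflection).  It
serializes to a typed TSV file plus a JSON sidecar for shoeboxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# flag bits
STRONG = 1 << 0
INDEXED = 1 << 1
INTEGRATED_SUM = 1 << 2
INTEGRATED_PRF = 1 << 3
SCALED = 1 << 4
OUTLIER = 1 << 5
OVERLOADED = 1 << 6
PARTIAL = 1 << 7  # clipped at a scan or detector edge
NO_BACKGROUND = 1 << 8
PRF_FALLBACK = 1 << 9  # profile fit fell back to summation

FLAG_NAMES = {
    "strong": STRONG,
    "indexed": INDEXED,
    "integrated_sum": INTEGRATED_SUM,
    "integrated_prf": INTEGRATED_PRF,
    "scaled": SCALED,
    "outlier": OUTLIER,
    "overloaded": OVERLOADED,
    "partial": PARTIAL,
    "nobackground": NO_BACKGROUND,
    "prf_fallback": PRF_FALLBACK,
}

# shoebox mask codes
MASK_INVALID = 0
MASK_BACKGROUND = 1
MASK_FOREGROUND = 2
MASK_OVERLOADED = 3


@dataclass
class Shoebox:
    """Cuboid of pixels around one reflection.

    ``bbox`` is (x0, x1, y0, y1, z0, z1), half-open, pixels/frames.
    ``data`` is counts with shape (z1-z0, y1-y0, x1-x0); ``background`` the
    per-pixel background model and ``mask`` per-pixel codes.
    """

    bbox: tuple
    data: np.ndarray
    background: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        x0, x1, y0, y1, z0, z1 = self.bbox
        if not (x1 > x0 and y1 > y0 and z1 > z0):
            raise ValueError("shoebox bbox must be non-empty")
        expect = (z1 - z0, y1 - y0, x1 - x0)
        if tuple(self.data.shape) != expect:
            raise ValueError(f"shoebox data shape {self.data.shape} != bbox {expect}")
        if self.mask is None:
            self.mask = np.full(expect, MASK_BACKGROUND, dtype=np.int8)
        if self.background is None:
            self.background = np.zeros(expect, dtype=float)

    def to_dict(self):
        return {
            "bbox": list(int(v) for v in self.bbox),
            "data": np.asarray(self.data).ravel().tolist(),
            "background": np.asarray(self.background).ravel().tolist(),
            "mask": np.asarray(self.mask).ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        x0, x1, y0, y1, z0, z1 = d["bbox"]
        shape = (z1 - z0, y1 - y0, x1 - x0)
        return cls(
            bbox=tuple(d["bbox"]),
            data=np.asarray(d["data"], dtype=float).reshape(shape),
            background=np.asarray(d["background"], dtype=float).reshape(shape),
            mask=np.asarray(d["mask"], dtype=np.int8).reshape(shape),
        )


_INT_COLS = ("h", "k", "l", "id", "flags", "n_voxels")
_COLUMN_ORDER = [
    "h", "k", "l", "id",
    "x_px", "y_px", "z_frame",
    "x_mm", "y_mm", "phi_deg",
    "x_cal_px", "y_cal_px", "z_cal_frame",
    "x_cal_mm", "y_cal_mm", "phi_cal_deg",
    "intensity_sum_value", "intensity_sum_variance",
    "intensity_prf_value", "intensity_prf_variance",
    "background_mean", "d", "flags", "n_voxels", "inverse_scale", "partiality",
]


class ReflectionTable:
    """Reflection data for one or more datasets."""

    def __init__(self, df=None, shoeboxes=None):
        self.df = pd.DataFrame() if df is None else df.reset_index(drop=True)
        if "flags" not in self.df.columns:
            self.df["flags"] = np.zeros(len(self.df), dtype=np.int64)
        if "id" not in self.df.columns:
            self.df["id"] = np.zeros(len(self.df), dtype=np.int64)
        self.shoeboxes = shoeboxes  # list[Shoebox | None] parallel to df, or None

    def __len__(self):
        return len(self.df)

    def __getitem__(self, col):
        return self.df[col].to_numpy()

    def __setitem__(self, col, values):
        self.df[col] = values

    def __contains__(self, col):
        return col in self.df.columns

    @property
    def hkl(self):
        return self.df[["h", "k", "l"]].to_numpy(dtype=np.int64)

    def set_hkl(self, hkl):
        hkl = np.asarray(hkl, dtype=np.int64)
        self.df["h"], self.df["k"], self.df["l"] = hkl[:, 0], hkl[:, 1], hkl[:, 2]

    def get_flags(self, flag):
        return (self.df["flags"].to_numpy(dtype=np.int64) & flag) != 0

    def set_flags(self, selection, flag):
        f = self.df["flags"].to_numpy(dtype=np.int64).copy()
        f[np.asarray(selection)] |= flag
        self.df["flags"] = f

    def unset_flags(self, selection, flag):
        f = self.df["flags"].to_numpy(dtype=np.int64).copy()
        f[np.asarray(selection)] &= ~flag
        self.df["flags"] = f

    def select(self, selection):
        """Row subset (boolean mask or index array) as a new table."""
        sel = np.asarray(selection)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        else:
            idx = sel
        sub = ReflectionTable(self.df.iloc[idx].reset_index(drop=True))
        if self.shoeboxes is not None:
            sub.shoeboxes = [self.shoeboxes[i] for i in idx]
        return sub

    def copy(self):
        t = ReflectionTable(self.df.copy())
        t.shoeboxes = None if self.shoeboxes is None else list(self.shoeboxes)
        return t

    @staticmethod
    def concat(tables):
        dfs = [t.df for t in tables if len(t)]
        if not dfs:
            return ReflectionTable()
        out = ReflectionTable(pd.concat(dfs, ignore_index=True))
        if any(t.shoeboxes is not None for t in tables):
            boxes = []
            for t in tables:
                boxes.extend(t.shoeboxes if t.shoeboxes is not None else [None] * len(t))
            out.shoeboxes = boxes
        return out

    # -- serialization ------------------------------------------------------

    def write(self, path, with_shoeboxes=False):
        """Write as TSV with a typed header; shoeboxes to a JSON sidecar."""
        cols = [c for c in _COLUMN_ORDER if c in self.df.columns]
        cols += [c for c in self.df.columns if c not in cols]
        path = str(path)
        with open(path, "w") as fh:
            types = "\t".join("int" if c in _INT_COLS else "float" for c in cols)
            fh.write("#types\t" + types + "\n")
            self.df[cols].to_csv(fh, sep="\t", index=False, lineterminator="\n")
        if with_shoeboxes and self.shoeboxes is not None:
            side = [None if b is None else b.to_dict() for b in self.shoeboxes]
            with open(path + ".shoeboxes.json", "w") as fh:
                json.dump(side, fh)

    @classmethod
    def read(cls, path):
        path = str(path)
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#types"):
                raise ValueError("reflection file missing #types header line")
            df = pd.read_csv(fh, sep="\t")
        for c in df.columns:
            if c in _INT_COLS:
                df[c] = df[c].astype(np.int64)
        table = cls(df)
        try:
            with open(path + ".shoeboxes.json") as fh:
                side = json.load(fh)
            table.shoeboxes = [None if d is None else Shoebox.from_dict(d) for d in side]
        except FileNotFoundError:
            pass
        return table
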