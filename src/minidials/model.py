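"""Experiment geometry models and the pixel <-> laboratory-frame mappings.

The experiment model bundles everything the downstream stages need to know
about the measurement: the beam (direction and wavelength), the goniometer
(single rotation axis), a single flat detector panel, the rotation scan,
and optionally the crystal (orientation + unit cell encoded in the UB
matrix A, whose columns are the reciprocal basis vectors a*, b*, c* in the
laboratory frame, units 1/A).

Conventions (fixed, documented, and used throughout the package):

* laboratory frame is right-handed, units mm; the default beam travels
  along +z, the default goniometer axis is +x;
* pixel coordinates are 0-based with integer values at pixel corners, so
  the centre of pixel ``i`` is at ``i + 0.5``; bounding boxes are half-open;
* angles are degrees at every interface and in every file; radians appear
  only inside computations;
* image numbers at user interfaces are 1-based inclusive; internally frames
  are 0-based, frame ``z`` spanning rotation angles
  ``[phi0 + z*dphi, phi0 + (z+1)*dphi)``.

The wavevector convention: ``s0 = beam.direction / wavelength`` points from
source towards the crystal, ``|s0| = 1/lambda``.  A pixel at laboratory
position p scatters along ``s1 = p / (|p| * lambda)`` and the scattering
vector is ``r = s1 - s0`` with ``|r| = 2 sin(theta)/lambda``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

FORMAT_VERSION = 1

__all__ = [
    "Beam",
    "Goniometer",
    "Detector",
    "Scan",
    "Crystal",
    "Experiment",
    "lab_coord_of_pixel",
    "s1_of_pixel",
    "read_experiment",
    "write_experiment",
    "apply_overrides",
    "axis_angle_matrix",
    "cell_from_A",
    "B_from_cell",
    "A_from_cell_orientation",
]


class ModelError(ValueError):
    """Raised for invalid or inconsistent experiment models."""


def _unit(v, tol=1e-9, name="vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ModelError(f"{name} must be a unit vector (|v| = {n})")
    return v


def axis_angle_matrix(axis, angle_deg):
    """Rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    K = np.array([[0, -e[2], e[1]], [e[2], 0, -e[0]], [-e[1], e[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def axis_angle_matrices(axis, angles_deg):
    """Stack of rotation matrices for an array of angles (degrees)."""
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    t = np.radians(np.asarray(angles_deg, dtype=float))
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -e[2], e[1]], [e[2], 0, -e[0]], [-e[1], e[0], 0]])
    K2 = K @ K
    return np.eye(3) + s[..., None, None] * K + (1 - c)[..., None, None] * K2


@dataclass(frozen=True)
class Beam:
    direction: tuple = (0.0, 0.0, 1.0)
    wavelength: float = 1.0

    def __post_init__(self):
        _unit(self.direction, name="beam.direction")
        if not self.wavelength > 0:
            raise ModelError("beam.wavelength must be > 0")
        object.__setattr__(self, "direction", tuple(float(x) for x in self.direction))

    @property
    def s0(self):
        """Incident wavevector, |s0| = 1/lambda, pointing source -> crystal."""
        return np.asarray(self.direction) / self.wavelength


@dataclass(frozen=True)
class Goniometer:
    axis: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        _unit(self.axis, name="goniometer.axis")
        object.__setattr__(self, "axis", tuple(float(x) for x in self.axis))


@dataclass(frozen=True)
class Detector:
    origin: tuple = (-25.6, -25.6, 150.0)  # mm, lab position of pixel (0,0) corner
    fast_axis: tuple = (1.0, 0.0, 0.0)
    slow_axis: tuple = (0.0, 1.0, 0.0)
    pixel_size: tuple = (0.2, 0.2)  # mm (fast, slow)
    n_fast: int = 256
    n_slow: int = 256
    trusted_range: tuple = (0.0, 65535.0)
    masked_regions: tuple = ()  # half-open pixel rectangles (x0, x1, y0, y1)

    def __post_init__(self):
        f = _unit(self.fast_axis, name="detector.fast_axis")
        s = _unit(self.slow_axis, name="detector.slow_axis")
        if abs(float(f @ s)) > 1e-6:
            raise ModelError("detector fast and slow axes must be orthogonal")
        if not (self.pixel_size[0] > 0 and self.pixel_size[1] > 0):
            raise ModelError("pixel_size must be positive")
        if not self.trusted_range[0] < self.trusted_range[1]:
            raise ModelError("trusted_range must be (min, max) with min < max")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "fast_axis", tuple(float(x) for x in f))
        object.__setattr__(self, "slow_axis", tuple(float(x) for x in s))
        object.__setattr__(self, "pixel_size", tuple(float(x) for x in self.pixel_size))
        object.__setattr__(self, "trusted_range", tuple(float(x) for x in self.trusted_range))
        object.__setattr__(
            self, "masked_regions", tuple(tuple(int(v) for v in r) for r in self.masked_regions)
        )

    @property
    def normal(self):
        return np.cross(self.fast_axis, self.slow_axis)

    def pixel_mask(self):
        """Boolean (n_slow, n_fast) array, True where the pixel is usable."""
        mask = np.ones((self.n_slow, self.n_fast), dtype=bool)
        for x0, x1, y0, y1 in self.masked_regions:
            mask[y0:y1, x0:x1] = False
        return mask


@dataclass(frozen=True)
class Scan:
    phi0: float = 0.0  # deg, start angle of the first image
    dphi: float = 1.0  # deg / image
    n_images: int = 180
    first_image_number: int = 1  # 1-based index of the first image

    def __post_init__(self):
        if not self.dphi > 0:
            raise ModelError("scan.dphi must be > 0")
        if not self.n_images >= 1:
            raise ModelError("scan.n_images must be >= 1")

    def phi_of_frame(self, z):
        """Rotation angle (deg) at continuous frame coordinate z (0-based)."""
        return self.phi0 + np.asarray(z, dtype=float) * self.dphi

    def frame_of_phi(self, phi):
        return (np.asarray(phi, dtype=float) - self.phi0) / self.dphi

    @property
    def phi_end(self):
        return self.phi0 + self.n_images * self.dphi


@dataclass(frozen=True)
class Crystal:
    A: tuple  # 3x3, columns a*, b*, c* lab frame, 1/A
    space_group: str = "P1"
    scan_varying_A: tuple | None = None  # optional per-image A matrices

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ModelError("crystal.A must be non-singular")
        cell = cell_from_A(A)
        if not all(p > 0 for p in cell[:3]):
            raise ModelError("derived cell lengths must be positive")
        if not all(0.0 < ang < 180.0 for ang in cell[3:]):
            raise ModelError("derived cell angles must lie in (0, 180) deg")
        object.__setattr__(self, "A", tuple(tuple(float(v) for v in row) for row in A))
        if self.scan_varying_A is not None:
            sv = tuple(
                tuple(tuple(float(v) for v in row) for row in np.asarray(m, float).reshape(3, 3))
                for m in self.scan_varying_A
            )
            object.__setattr__(self, "scan_varying_A", sv)

    @property
    def A_matrix(self):
        return np.asarray(self.A, dtype=float)

    def A_at_frame(self, z):
        """A matrix at (continuous) frame z: per-image if scan-varying."""
        if self.scan_varying_A is None:
            return self.A_matrix
        i = int(np.clip(np.floor(z), 0, len(self.scan_varying_A) - 1))
        return np.asarray(self.scan_varying_A[i], dtype=float)

    @property
    def cell(self):
        """(a, b, c, alpha, beta, gamma) in A / deg derived from A^T A."""
        return cell_from_A(self.A_matrix)

    @property
    def U(self):
        """Orientation part of A = U B (B from the derived cell)."""
        B = B_from_cell(self.cell)
        return self.A_matrix @ np.linalg.inv(B)


@dataclass(frozen=True)
class Experiment:
    beam: Beam = field(default_factory=Beam)
    goniometer: Goniometer = field(default_factory=Goniometer)
    detector: Detector = field(default_factory=Detector)
    scan: Scan = field(default_factory=Scan)
    crystal: Crystal | None = None
    id: str = "0"


def cell_from_A(A):
    """Unit cell (a, b, c, alpha, beta, gamma) from the UB matrix.

    Uses the direct metric G = (A^T A)^-1 only, so the result is invariant
    under any pure rotation applied to A.
    """
    A = np.asarray(A, dtype=float)
    G = np.linalg.inv(A.T @ A)  # direct metric tensor
    a, b, c = np.sqrt(np.diag(G))
    al = math.degrees(math.acos(np.clip(G[1, 2] / (b * c), -1, 1)))
    be = math.degrees(math.acos(np.clip(G[0, 2] / (a * c), -1, 1)))
    ga = math.degrees(math.acos(np.clip(G[0, 1] / (a * b), -1, 1)))
    return (float(a), float(b), float(c), al, be, ga)


def B_from_cell(cell):
    """Reciprocal-basis matrix B for a cell in the standard PDB setting.

    Columns are a*, b*, c* of the unrotated crystal; A = U B.
    """
    uc = gemmi.UnitCell(*cell)
    F = np.array(uc.frac.mat.tolist())  # fractionalization matrix
    # direct basis O = F^-1 (columns a, b, c); reciprocal basis = O^-T = F^T
    return F.T.copy()


def A_from_cell_orientation(cell, U):
    return np.asarray(U, dtype=float) @ B_from_cell(cell)


# ---------------------------------------------------------------------------
# pixel <-> lab mappings


def lab_coord_of_pixel(detector, x, y):
    """Laboratory coordinate (mm) of fractional pixel position (x fast, y slow)."""
    o = np.asarray(detector.origin)
    f = np.asarray(detector.fast_axis)
    s = np.asarray(detector.slow_axis)
    x = np.asarray(x, dtype=float)[..., None]
    y = np.asarray(y, dtype=float)[..., None]
    return o + x * detector.pixel_size[0] * f + y * detector.pixel_size[1] * s


def s1_of_pixel(experiment, x, y):
    """Diffracted wavevector s1 (1/A) for a pixel; |s1| = 1/lambda."""
    p = lab_coord_of_pixel(experiment.detector, x, y)
    norm = np.linalg.norm(p, axis=-1)
    if np.any(norm == 0):
        raise ModelError("pixel at crystal position")
    return p / (norm[..., None] if np.ndim(norm) else norm) / experiment.beam.wavelength


# ---------------------------------------------------------------------------
# serialization

_REQUIRED = ("beam", "goniometer", "detector", "scan")


class SchemaError(ValueError):
    pass


def experiment_to_dict(e):
    d = {
        "format_version": FORMAT_VERSION,
        "id": e.id,
        "beam": {"direction": list(e.beam.direction), "wavelength": e.beam.wavelength},
        "goniometer": {"axis": list(e.goniometer.axis)},
        "detector": {
            "origin": list(e.detector.origin),
            "fast_axis": list(e.detector.fast_axis),
            "slow_axis": list(e.detector.slow_axis),
            "pixel_size": list(e.detector.pixel_size),
            "n_fast": e.detector.n_fast,
            "n_slow": e.detector.n_slow,
            "trusted_range": list(e.detector.trusted_range),
            "masked_regions": [list(r) for r in e.detector.masked_regions],
        },
        "scan": {
            "phi0": e.scan.phi0,
            "dphi": e.scan.dphi,
            "n_images": e.scan.n_images,
            "first_image_number": e.scan.first_image_number,
        },
    }
    if e.crystal is not None:
        d["crystal"] = {
            "A": [list(r) for r in e.crystal.A],
            "space_group": e.crystal.space_group,
        }
        if e.crystal.scan_varying_A is not None:
            d["crystal"]["scan_varying_A"] = [
                [list(r) for r in m] for m in e.crystal.scan_varying_A
            ]
    return d


def experiment_from_dict(d):
    for key in _REQUIRED:
        if key not in d:
            raise SchemaError(f"experiment file missing required field '{key}'")
    beam = Beam(tuple(d["beam"]["direction"]), float(d["beam"]["wavelength"]))
    gonio = Goniometer(tuple(d["goniometer"]["axis"]))
    det = d["detector"]
    detector = Detector(
        origin=tuple(det["origin"]),
        fast_axis=tuple(det["fast_axis"]),
        slow_axis=tuple(det["slow_axis"]),
        pixel_size=tuple(det["pixel_size"]),
        n_fast=int(det["n_fast"]),
        n_slow=int(det["n_slow"]),
        trusted_range=tuple(det["trusted_range"]),
        masked_regions=tuple(tuple(r) for r in det.get("masked_regions", ())),
    )
    sc = d["scan"]
    scan = Scan(float(sc["phi0"]), float(sc["dphi"]), int(sc["n_images"]),
                int(sc.get("first_image_number", 1)))
    crystal = None
    if "crystal" in d and d["crystal"] is not None:
        cd = d["crystal"]
        crystal = Crystal(
            A=tuple(tuple(r) for r in cd["A"]),
            space_group=cd.get("space_group", "P1"),
            scan_varying_A=(
                tuple(tuple(tuple(r) for r in m) for m in cd["scan_varying_A"])
                if cd.get("scan_varying_A") is not None
                else None
            ),
        )
    return Experiment(beam=beam, goniometer=gonio, detector=detector, scan=scan,
                      crystal=crystal, id=str(d.get("id", "0")))


def write_experiment(experiment, path):
    with open(path, "w") as fh:
        json.dump(experiment_to_dict(experiment), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_experiment(path):
    with open(path) as fh:
        return experiment_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# import-time overrides


def apply_overrides(experiment, fast_slow_beam_centre=None, distance=None):
    """Return a copy of the experiment with the detector translated so the
    direct beam intersects the stated pixel and/or lies at the stated normal
    distance.  All other fields are unchanged."""
    det = experiment.detector
    if fast_slow_beam_centre is None and distance is None:
        return experiment
    o = np.asarray(det.origin, dtype=float)
    n = det.normal
    b = np.asarray(experiment.beam.direction)
    bn = float(b @ n)
    if abs(bn) < 1e-9:
        raise ModelError("beam is parallel to the detector plane")
    if distance is not None:
        d_now = float(o @ n) / 1.0
        o = o + (math.copysign(float(distance), d_now) - d_now) * np.asarray(n)
    if fast_slow_beam_centre is not None:
        fx, sy = (float(v) for v in fast_slow_beam_centre)
        # where the beam currently pierces the plane through o
        t = float(o @ n) / bn
        hit = t * b
        want = (
            o
            + fx * det.pixel_size[0] * np.asarray(det.fast_axis)
            + sy * det.pixel_size[1] * np.asarray(det.slow_axis)
        )
        o = o + (hit - want)
    new_det = replace(det, origin=tuple(o))
    return replace(experiment, detector=new_det)


def beam_centre_px(experiment):
    """Pixel coordinate (fast, slow) where the direct beam hits the panel."""
    det = experiment.detector
    b = np.asarray(experiment.beam.direction)
    n = det.normal
    o = np.asarray(det.origin)
    bn = float(b @ n)
    if abs(bn) < 1e-9:
        raise ModelError("beam is parallel to the detector plane")
    hit = (float(o @ n) / bn) * b - o
    fx = float(hit @ det.fast_axis) / det.pixel_size[0]
    sy = float(hit @ det.slow_axis) / det.pixel_size[1]
    return fx, sy
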