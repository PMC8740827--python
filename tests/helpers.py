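"""Shared helpers for the test-suite: truth-comparison utilities."""

from __future__ import annotations

import numpy as np

from minidials.model import B_from_cell


def polar_rotation(M):
    """Nearest pure rotation to M (polar decomposition)."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def rotation_angle_deg(R):
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1, 1))))


def lattice_match(A_found, cell_true, U_true, atol=0.02):
    """Check A_found describes the same lattice as (cell_true, U_true).

    Returns (matched, misorientation_deg): the change-of-basis N =
    (U B)^-1 A_found must be integer with |det| = 1; the misorientation is
    the polar angle of the residual after removing N.
    """
    A_true = np.asarray(U_true) @ B_from_cell(cell_true)
    N = np.linalg.inv(A_true) @ np.asarray(A_found)
    Nr = np.rint(N)
    if abs(abs(np.linalg.det(Nr)) - 1.0) > 1e-6 or np.abs(N - Nr).max() > atol:
        return False, np.nan
    R = polar_rotation(np.asarray(A_found) @ np.linalg.inv(Nr) @ np.linalg.inv(A_true))
    return True, rotation_angle_deg(R)


def cell_length_errors_pct(cell_found, cell_true):
    """Relative errors (%) of sorted cell lengths (setting-independent)."""
    a = np.sort(np.asarray(cell_found)[:3])
    b = np.sort(np.asarray(cell_true)[:3])
    return 100.0 * np.abs(a - b) / b
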