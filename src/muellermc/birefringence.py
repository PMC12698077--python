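"""Uniaxial linear birefringence along photon flight segments.

White matter behaves as a negative uniaxial medium (form birefringence of
packed myelinated fibers): ordinary index ``n_o``, extraordinary index
``n_e`` with ``delta_n = n_e - n_o < 0`` and the optic axis in the
laboratory x-y plane at azimuth ``eta``.  Light propagating at angle
``alpha`` to the optic axis sees the effective extraordinary index

    n(alpha) = n_o n_e / sqrt(n_e^2 cos^2 alpha + n_o^2 sin^2 alpha)

and accumulates, over a straight flight of length ``d``, the phase
retardation ``delta = 2 pi d (n(alpha) - n_o) / lambda``.  The retarder is
applied in the photon's transverse frame with its axis along the
projection of the optic axis; the frame angle ``beta`` is measured from
the local y-axis to ``f = k x e`` counter-clockwise about the propagation
direction, equivalently the axis projection sits at ``beta`` from local x.

All angle-valued helpers are scalar ``numba`` kernels so the transport
loop can inline them; the public wrappers accept arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "OpticAxis",
    "axis_angle_alpha",
    "effective_index",
    "phase_retardation",
    "local_beta",
    "apply_birefringence",
]

NM_TO_CM = 1e-7
_PARALLEL_TOL = 1e-9


class OpticAxis:
    """In-plane optic axis at azimuth ``eta_deg`` (degrees, lab x-y plane)."""

    def __init__(self, eta_deg: float):
        self.eta_deg = float(eta_deg)
        e = np.radians(self.eta_deg)
        self.unit_vector = np.array([np.cos(e), np.sin(e), 0.0])


@njit(cache=True)
def _alpha(ux: float, uy: float, uz: float, ex: float, ey: float) -> float:
    dot = ux * ex + uy * ey  # axis has no z component
    if dot > 1.0:
        dot = 1.0
    elif dot < -1.0:
        dot = -1.0
    return np.arccos(dot)


@njit(cache=True)
def _n_eff(alpha: float, n_o: float, n_e: float) -> float:
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    return n_o * n_e / np.sqrt(n_e * n_e * ca * ca + n_o * n_o * sa * sa)


@njit(cache=True)
def _delta(path_cm: float, alpha: float, n_o: float, n_e: float, wavelength_nm: float) -> float:
    dn = _n_eff(alpha, n_o, n_e) - n_o
    return 2.0 * np.pi * path_cm * dn / (wavelength_nm * NM_TO_CM)


@njit(cache=True)
def _beta(
    kx: float, ky: float, kz: float,
    ex: float, ey: float,
    lxx: float, lxy: float, lxz: float,
    lyx: float, lyy: float, lyz: float,
) -> float:
    """Signed angle (counter-clockwise about k) from local y to f = k x e.

    Returns NaN when the propagation direction is parallel to the optic
    axis (degenerate; the retardation vanishes there anyway)."""
    fx = ky * 0.0 - kz * ey
    fy = kz * ex - kx * 0.0
    fz = kx * ey - ky * ex
    norm = np.sqrt(fx * fx + fy * fy + fz * fz)
    if norm < _PARALLEL_TOL:
        return np.nan
    fx /= norm
    fy /= norm
    fz /= norm
    cosb = fx * lyx + fy * lyy + fz * lyz
    sinb = -(fx * lxx + fy * lxy + fz * lxz)
    return np.arctan2(sinb, cosb)


@njit(cache=True)
def _retard_stokes(
    sq: float, su: float, sv: float, delta: float, beta: float
) -> tuple[float, float, float]:
    """Apply R(-beta) MR(delta) R(beta) to the (Q, U, V) components."""
    c2 = np.cos(2.0 * beta)
    s2 = np.sin(2.0 * beta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    q1 = c2 * sq + s2 * su
    u1 = -s2 * sq + c2 * su
    u2 = cd * u1 + sd * sv
    v2 = -sd * u1 + cd * sv
    return c2 * q1 - s2 * u2, s2 * q1 + c2 * u2, v2


def axis_angle_alpha(direction: np.ndarray, eta_deg: float) -> float:
    """Angle (radians, in [0, pi]) between a unit propagation direction and
    the in-plane optic axis at azimuth ``eta_deg``."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < _PARALLEL_TOL:
        raise ValueError("zero-norm direction")
    if abs(n - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    e = np.radians(eta_deg)
    return float(_alpha(d[0], d[1], d[2], np.cos(e), np.sin(e)))


def effective_index(alpha: float, n_o: float, n_e: float) -> float:
    """Effective index n(alpha); n_o along the axis, n_e across it."""
    return float(_n_eff(float(alpha), n_o, n_e))


def phase_retardation(
    path_cm: float, alpha: float, n_o: float, n_e: float, wavelength_nm: float
) -> float:
    """Phase retardation (radians) over a flight of ``path_cm``.

    Negative for a negative uniaxial medium (n_e < n_o); zero along the
    axis or for zero path."""
    if path_cm < 0:
        raise ValueError("path length must be non-negative")
    return float(_delta(path_cm, float(alpha), n_o, n_e, wavelength_nm))


def local_beta(direction: np.ndarray, eta_deg: float, local_y: np.ndarray) -> float:
    """Frame angle beta (radians in [0, 2 pi)) of the local optic axis.

    ``local_y`` must be orthonormal to ``direction``; the matching local x
    completing the right-handed frame is ``local_y x direction``.

    Raises ``ValueError`` when the direction is parallel to the optic axis
    (beta undefined)."""
    k = np.asarray(direction, dtype=float)
    ly = np.asarray(local_y, dtype=float)
    lx = np.cross(ly, k)
    e = np.radians(eta_deg)
    b = _beta(k[0], k[1], k[2], np.cos(e), np.sin(e),
              lx[0], lx[1], lx[2], ly[0], ly[1], ly[2])
    if np.isnan(b):
        raise ValueError("propagation direction parallel to the optic axis")
    return float(b % (2.0 * np.pi))


def apply_birefringence(
    stokes: np.ndarray,
    direction: np.ndarray,
    local_y: np.ndarray,
    eta_deg: float,
    n_o: float,
    n_e: float,
    path_cm: float,
    wavelength_nm: float,
) -> np.ndarray:
    """Stokes vector after a straight flight through a birefringent region.

    The intensity component is untouched (a retarder neither depolarizes
    nor diattenuates); an isotropic region (n_e == n_o) or propagation
    along the axis returns the input unchanged."""
    s = np.array(stokes, dtype=float)
    if n_e == n_o or path_cm == 0.0:
        return s
    k = np.asarray(direction, dtype=float)
    alpha = axis_angle_alpha(k, eta_deg)
    delta = phase_retardation(path_cm, alpha, n_o, n_e, wavelength_nm)
    if delta == 0.0:
        return s
    try:
        beta = local_beta(k, eta_deg, local_y)
    except ValueError:
        return s  # alpha == 0: no retardation accumulates
    # the retarder acts with the ordinary-minus-extraordinary phase (-delta):
    # the handedness convention under which the decomposed azimuth of a
    # negative uniaxial medium reads the optic-axis azimuth directly
    s[1], s[2], s[3] = _retard_stokes(s[1], s[2], s[3], -delta, beta)
    return s
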