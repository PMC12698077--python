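"""Stokes/Mueller algebra and the Lu-Chipman polar decomposition.

Conventions
-----------
Stokes vectors are length-4 ``numpy`` arrays ``(I, Q, U, V)``; Mueller
matrices are real 4x4 arrays with the intensity element at ``[0, 0]``.
Angles at the public surface are radians unless a name says degrees.

A Mueller matrix of a depolarizing sample factorizes as

    M = M_delta @ M_R @ M_D

(depolarizer, retarder, diattenuator).  Three scalar observables are read
off the factors: the total depolarization ``Delta = 1 - (|a|+|b|+|c|)/3``
over the diagonal of the depolarizer's 3x3 sub-block, the scalar linear
retardance ``R = arccos(r - 1)`` with
``r = sqrt((mR22+mR33)^2 + (mR32-mR23)^2)``, and the optic-axis azimuth
``theta = 1/2 * atan2`` on the ``(2,4)/(4,3)`` retarder elements.

The azimuth branch is fixed so that the round trip
``azimuth(rotated_retarder(delta, beta)) == beta`` holds for
``delta in (0, pi)`` and ``beta in [0, pi)``: a rotated linear retarder is
built as ``R(-beta) @ MR(delta) @ R(beta)`` and the azimuth is evaluated as
``0.5 * atan2(m[3,1], m[2,3])`` (0-based), which equals the printed element
ratio with the quadrant resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "retarder_mueller",
    "stokes_rotation",
    "rotated_retarder",
    "total_depolarization",
    "linear_retardance",
    "optic_axis_azimuth",
    "cloude_filter",
    "lu_chipman",
    "DecompositionResult",
]

#: azimuth below this retardance (degrees) is numerically unstable
LOW_RETARDANCE_DEG = 1.0

_AZIMUTH_EPS = 1e-12


def retarder_mueller(delta: float) -> np.ndarray:
    """Mueller matrix of a linear retarder with its fast axis along x.

    Parameters
    ----------
    delta : float
        Phase retardation in radians (any sign; a negative uniaxial
        medium produces negative ``delta``).
    """
    c, s = np.cos(delta), np.sin(delta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, c, s],
            [0.0, 0.0, -s, c],
        ]
    )


def stokes_rotation(beta: float) -> np.ndarray:
    """Rotation of the Stokes reference frame by ``beta`` radians about the
    propagation direction (acts on (Q, U) through the double angle)."""
    c2, s2 = np.cos(2.0 * beta), np.sin(2.0 * beta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c2, s2, 0.0],
            [0.0, -s2, c2, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def rotated_retarder(delta: float, beta: float) -> np.ndarray:
    """Linear retarder of retardation ``delta`` with fast axis at azimuth
    ``beta`` (radians, counter-clockwise from x)."""
    return stokes_rotation(-beta) @ retarder_mueller(delta) @ stokes_rotation(beta)


def total_depolarization(m_delta: np.ndarray) -> float:
    """Total depolarization of a depolarizer factor.

    ``Delta = 1 - (|a| + |b| + |c|) / 3`` over the diagonal of the lower
    3x3 sub-block; 0 for a non-depolarizing element, 1 for the ideal
    depolarizer diag(1, 0, 0, 0).
    """
    m = np.asarray(m_delta, dtype=float)
    d = np.abs(np.diagonal(m)[1:]).sum() / 3.0
    # clamp rounding noise at the non-depolarizing limit
    return float(min(1.0, max(0.0, 1.0 - d)))


def linear_retardance(m_r: np.ndarray) -> float:
    """Scalar linear retardance of a retarder factor, in degrees in [0, 180].

    The arccos argument is clamped to [-1, 1] against floating-point noise.
    """
    m = np.asarray(m_r, dtype=float)
    r = np.hypot(m[1, 1] + m[2, 2], m[2, 1] - m[1, 2])
    return float(np.degrees(np.arccos(np.clip(r - 1.0, -1.0, 1.0))))


def optic_axis_azimuth(m_r: np.ndarray) -> float:
    """Optic-axis azimuth of a linear-retarder factor, degrees in [0, 180).

    Returns NaN when both defining elements vanish (no linear retardance:
    the azimuth is undefined).
    """
    m = np.asarray(m_r, dtype=float)
    a, b = m[3, 1], m[2, 3]
    if abs(a) < _AZIMUTH_EPS and abs(b) < _AZIMUTH_EPS:
        return float("nan")
    theta = 0.5 * np.degrees(np.arctan2(a, b)) % 180.0
    # the modulo can round back up to the excluded end point
    return float(theta if theta < 180.0 else 0.0)


# Pauli basis used for the coherency construction.
_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)


def coherency_matrix(m: np.ndarray) -> np.ndarray:
    """Hermitian 4x4 coherency matrix T = 1/4 sum_ij m_ij (s_i (x) s_j*)."""
    m = np.asarray(m, dtype=float)
    kron = np.einsum("iab,jcd->ijacbd", _PAULI, np.conj(_PAULI)).reshape(4, 4, 4, 4)
    t = 0.25 * np.einsum("ij,ijab->ab", m, kron)
    return 0.5 * (t + t.conj().T)


def cloude_filter(m: np.ndarray, tol: float = 1e-6) -> tuple[bool, np.ndarray]:
    """Physical-realizability test via the coherency-matrix eigenvalues.

    Returns ``(is_physical, eigenvalues)`` with the eigenvalues sorted
    descending and normalized to unit sum; the matrix is physical when no
    eigenvalue is below ``-tol`` times the largest one.
    """
    t = coherency_matrix(m)
    ev = np.linalg.eigvalsh(t)[::-1]
    lmax = ev[0]
    is_physical = bool(lmax > 0 and np.all(ev >= -tol * lmax))
    s = ev.sum()
    if s != 0.0:
        ev = ev / s
    return is_physical, ev


@dataclass
class DecompositionResult:
    """Outcome of the Lu-Chipman polar decomposition of a Mueller matrix."""

    depolarizer: np.ndarray
    retarder: np.ndarray
    diattenuator: np.ndarray
    total_depolarization: float
    linear_retardance: float  # degrees in [0, 180]
    azimuth: float  # degrees in [0, 180); NaN when undefined
    valid: bool  # Cloude realizability of the input
    degenerate: bool = False  # |diattenuation| ~ 1 short-circuit taken

    def reconstruct(self) -> np.ndarray:
        return self.depolarizer @ self.retarder @ self.diattenuator


def _diattenuator(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Diattenuator factor from the first row of a normalized matrix."""
    dvec = m[0, 1:]
    d = float(np.linalg.norm(dvec))
    md = np.eye(4)
    md[0, 1:] = dvec
    md[1:, 0] = dvec
    if d > 0.0:
        dhat = dvec / d
        a = np.sqrt(max(0.0, 1.0 - d * d))
        md[1:, 1:] = a * np.eye(3) + (1.0 - a) * np.outer(dhat, dhat)
    return md, d


def lu_chipman(m: np.ndarray) -> DecompositionResult:
    """Polar decomposition ``M = M_delta @ M_R @ M_D`` with scalar read-outs.

    The input is normalized by its ``[0, 0]`` element first.  The
    diattenuator is built from the first row; the depolarizer sub-block is
    the signed symmetric square root of ``m' m'^T`` (sign from
    ``det m'``); the retarder is ``M_delta^{-1} M'``.  A diattenuation
    magnitude within 1e-9 of unity is treated as degenerate (bulk
    backscattering tissue diattenuates very weakly, so this branch flags
    pathological pixels rather than a physical regime): the diattenuator
    and retarder are set to identity.

    Raises
    ------
    ValueError
        If the input has non-finite entries or a non-positive ``m[0, 0]``.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("Mueller matrix has non-finite entries")
    if m[0, 0] <= 0.0:
        raise ValueError("Mueller matrix must have m[0,0] > 0")
    m = m / m[0, 0]

    valid, _ = cloude_filter(m)

    md, d = _diattenuator(m)
    degenerate = d >= 1.0 - 1e-9
    if degenerate:
        md = np.eye(4)
        mprime = m.copy()
    else:
        mprime = m @ np.linalg.inv(md)

    p = mprime[1:, 0]
    msub = mprime[1:, 1:]
    mmt = msub @ msub.T
    ev, vec = np.linalg.eigh(mmt)
    ev = np.clip(ev, 0.0, None)
    sq = np.sqrt(ev)
    # signed symmetric square root of m' m'^T
    root = (vec * sq) @ vec.T
    if np.linalg.det(msub) < 0.0:
        root = -root

    mdelta = np.eye(4)
    mdelta[1:, 0] = p
    mdelta[1:, 1:] = root

    if degenerate:
        mr = np.eye(4)
    else:
        # pseudo-inverse guards strongly depolarizing pixels (singular root)
        cond_ok = np.linalg.cond(root) < 1e12 if np.all(np.isfinite(root)) else False
        if cond_ok:
            mr_sub = np.linalg.solve(root, msub)
        else:
            mr_sub = np.linalg.pinv(root) @ msub
        mr = np.eye(4)
        mr[1:, 1:] = mr_sub

    delta_tot = total_depolarization(mdelta)
    ret = linear_retardance(mr)
    azi = optic_axis_azimuth(mr)
    return DecompositionResult(
        depolarizer=mdelta,
        retarder=mr,
        diattenuator=md,
        total_depolarization=delta_tot,
        linear_retardance=ret,
        azimuth=azi,
        valid=valid,
        degenerate=degenerate,
    )
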