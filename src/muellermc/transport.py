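"""Polarized Monte Carlo photon transport through slab phantoms.

Photons are launched at normal incidence, uniformly over a square source
footprint, each carrying a pure polarization state drawn uniformly from
the Poincare sphere, ``S_in = (1, cos t, sin t cos p, sin t sin p)`` with
``t ~ U[0, pi]``, ``p ~ U[0, 2 pi)``.  The walk alternates exponential
free flights (``ds = -ln(zeta) / mu_e``) with scattering events sampled
from the tabulated ``s11 sin(theta)`` density; the azimuth is uniform, so
trajectories are polarization-independent and the per-pixel estimator
``M = G D^-1`` is built from weighted ``(S_out, S_in)`` records (a
polarization-dependent rejection sampler is available behind
``polarized_sampling`` for sensitivity checks).  The default detector
("distant") models the physical geometry - a small circular detector far
above the surface registering near-vertical exits - by polarized local
(next-event) estimation: every scattering event tallies the expected
contribution of a virtual scattering straight up, including the
retardation and attenuation of the vertical exit path.  The "ideal"
detector instead bins physically escaping photons by exit position,
accepting every upward direction.

The Stokes vector rides in the photon's co-moving transverse frame
``(local_x, local_y)`` with ``local_x x local_y = k`` and ``Q > 0`` along
``local_x``; frame rotations replace the classical meridian-plane
back-rotations and are algebraically identical to them.  Per straight
flight segment the uniaxial retardation of the current region is applied
in this frame; internal inclusion boundaries are index-matched (only
``mu_s`` and the optic axis change) and the free path is re-sampled
memorylessly after a crossing.  External boundaries use polarization-
resolved Fresnel reflection/transmission; photons leaving the top surface
are handed to the detector, all other escapes terminate the walk.  A
safety cap on the event count (default 2.5e5) discards runaways into an
explicit loss tally instead of Russian roulette, keeping the estimator
unbiased up to the reported truncation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mie import PhaseTable
from .phantoms import PhantomModel

__all__ = [
    "TransportConfig",
    "TransportResult",
    "sample_free_path",
    "launch_stokes",
    "fresnel_reflectances",
    "run_transport",
]

NM_TO_CM = 1e-7
NPIX = 100
DET_HALF_CM = 0.5
PIXEL_CM = 0.01
_EPS_NUDGE = 1e-9  # cm, push-through at internal boundaries
_FRAME_REFRESH = 1000  # events between frame re-orthonormalizations

#: Detector basis convention: Stokes of exiting photons are referenced to
#: the laboratory (x, y) axes as seen looking down onto the sample
#: (mirror of the right-handed frame about y).  Fixed once by requiring
#: that a host with optic axis at azimuth eta maps to azimuth eta.
DET_FLIP_Y = True

# diagnostics indices
DIAG_LAUNCHED, DIAG_DETECTED, DIAG_TOP_OUT, DIAG_BOTTOM, DIAG_SIDE, DIAG_CAP = range(6)


@dataclass
class TransportConfig:
    """Run-level knobs for one simulated Mueller-matrix image."""

    photons: int = 2_000_000
    batches: int = 10
    seed: int = 0
    #: uniform illumination extends 2 mm beyond the imaged field, far past
    #: the lateral range that influences detected contributions; launching
    #: over the whole slab surface would only waste photons
    source_half_cm: float = DET_HALF_CM + 0.2
    event_cap: int = 250_000  # truncation loss stays below 1e-3 of photons
    polarized_sampling: bool = False  # rejection on the polarized phase law
    #: "distant": the physical geometry (circular detector far above the
    #: surface registering near-vertical exits), scored by polarized local
    #: estimation - every scattering event tallies its expected straight-up
    #: escape; "ideal": bin physically escaping photons by exit position,
    #: accepting every upward direction
    detector: str = "distant"

    def batch_seeds(self) -> np.ndarray:
        ss = np.random.SeedSequence(self.seed)
        return (ss.generate_state(self.batches) % np.uint32(2**31)).astype(np.int64)


@dataclass
class TransportResult:
    """Per-batch detector accumulators plus walk diagnostics."""

    g_sum: np.ndarray  # (batches, NPIX, NPIX, 4, 4) sum S_out S_in^T
    d_sum: np.ndarray  # (batches, NPIX, NPIX, 4, 4) sum S_in S_in^T
    counts: np.ndarray  # (batches, NPIX, NPIX)
    diagnostics: np.ndarray  # (batches, 6) int64 tallies
    config: TransportConfig
    phantom: PhantomModel

    @property
    def cap_loss_fraction(self) -> float:
        d = self.diagnostics.sum(axis=0)
        return float(d[DIAG_CAP] / max(1, d[DIAG_LAUNCHED]))

    def manifest(self) -> dict:
        d = self.diagnostics.sum(axis=0)
        return {
            "photons": int(d[DIAG_LAUNCHED]),
            "detected": int(d[DIAG_DETECTED]),
            "escaped_top_outside_grid": int(d[DIAG_TOP_OUT]),
            "escaped_bottom": int(d[DIAG_BOTTOM]),
            "escaped_side": int(d[DIAG_SIDE]),
            "cap_discarded": int(d[DIAG_CAP]),
            "seed": self.config.seed,
            "batches": self.config.batches,
            "phantom": self.phantom.to_config(),
        }


def sample_free_path(zeta: float, mu_e: float) -> float:
    """Exponential free path ``-ln(zeta)/mu_e`` (cm), ``zeta in (0, 1]``."""
    if mu_e <= 0:
        raise ValueError("extinction coefficient must be positive")
    return -np.log(zeta) / mu_e


def launch_stokes(theta: float, psi: float) -> np.ndarray:
    """Pure input state at Poincare-sphere angles (theta, psi)."""
    return np.array(
        [1.0, np.cos(theta), np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi)]
    )


@njit(cache=True)
def _fresnel(n1: float, n2: float, ci: float) -> tuple[float, float, float]:
    """(Rs, Rp, cos theta_t); total internal reflection gives (1, 1, 0)."""
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0, 1.0, 0.0
    ct = np.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n2 * ci - n1 * ct) / (n2 * ci + n1 * ct)
    return rs * rs, rp * rp, ct


def fresnel_reflectances(n1: float, n2: float, cos_incidence: float) -> tuple[float, float]:
    """Intensity reflectances (Rs, Rp) at a dielectric interface."""
    rs, rp, _ = _fresnel(n1, n2, float(cos_incidence))
    return float(rs), float(rp)


# ---------------------------------------------------------------------------
# pseudo-random stream: xorshift128+ seeded through splitmix64; the walk
# draws from one continuous stream per batch


@njit(cache=True, inline="always")
def _rand(st: np.ndarray) -> float:
    """Next double in [0, 1) from a 2-word xorshift128+ state."""
    t = st[0]
    s = st[1]
    st[0] = s
    t ^= t << np.uint64(23)
    t ^= t >> np.uint64(18)
    t ^= s ^ (s >> np.uint64(5))
    st[1] = t
    return float((t + s) >> np.uint64(11)) * (2.0**-53)


@njit(cache=True)
def _seed_state(seed: int) -> np.ndarray:
    st = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        st[i] = w ^ (w >> np.uint64(31))
    return st


# ---------------------------------------------------------------------------
# kernel

# params vector layout
(
    P_THICK, P_LATHALF, P_H_MUS, P_H_NO, P_H_NE, P_H_EX, P_H_EY, P_H_DN,
    P_I_FLAG, P_I_HALF, P_I_Z0, P_I_Z1, P_I_MUS, P_I_NO, P_I_NE, P_I_EX,
    P_I_EY, P_I_DN, P_N_MED, P_N_AMB, P_WAVE, P_SRC_HALF, P_CAP, P_POLSAMP,
    P_DETMODE, P_NPARAM,
) = range(26)

#: optical-depth cutoff for local-estimation contributions (exp(-12) ~ 6e-6)
TAU_CUTOFF = 12.0


def _pack_params(phantom: PhantomModel, config: TransportConfig) -> np.ndarray:
    p = np.zeros(P_NPARAM)
    p[P_THICK] = phantom.thickness_cm
    p[P_LATHALF] = phantom.lateral_half_cm
    host = phantom.host
    p[P_H_MUS] = host.mus
    p[P_H_NO] = host.n_o
    p[P_H_NE] = host.n_e
    e = np.radians(host.eta_deg)
    p[P_H_EX], p[P_H_EY] = np.cos(e), np.sin(e)
    p[P_H_DN] = host.delta_n
    if phantom.inclusion is not None:
        inc = phantom.inclusion
        p[P_I_FLAG] = 1.0
        p[P_I_HALF] = phantom.inclusion_half_cm
        p[P_I_Z0] = phantom.inclusion_depth_cm
        p[P_I_Z1] = phantom.inclusion_depth_cm + phantom.inclusion_thickness_cm
        p[P_I_MUS] = inc.mus
        p[P_I_NO], p[P_I_NE] = inc.n_o, inc.n_e
        ei = np.radians(inc.eta_deg)
        p[P_I_EX], p[P_I_EY] = np.cos(ei), np.sin(ei)
        p[P_I_DN] = inc.delta_n
    p[P_N_MED] = phantom.n_medium
    p[P_N_AMB] = phantom.n_ambient
    p[P_WAVE] = phantom.wavelength_nm
    p[P_SRC_HALF] = config.source_half_cm
    p[P_CAP] = float(config.event_cap)
    p[P_POLSAMP] = 1.0 if config.polarized_sampling else 0.0
    p[P_DETMODE] = 1.0 if config.detector == "distant" else 0.0
    return p


@njit(cache=True, fastmath=True)
def _walk_kernel(
    n_photons: int,
    seed: int,
    params: np.ndarray,
    inv_cdf_theta: np.ndarray,
    r12: np.ndarray,
    r33: np.ndarray,
    r34: np.ndarray,
    s11n: np.ndarray,
    g_sum: np.ndarray,
    d_sum: np.ndarray,
    counts: np.ndarray,
    diag: np.ndarray,
):
    rst = _seed_state(seed)
    thick = params[P_THICK]
    lat = params[P_LATHALF]
    incl = params[P_I_FLAG] > 0.5
    ih = params[P_I_HALF]
    iz0 = params[P_I_Z0]
    iz1 = params[P_I_Z1]
    n_med = params[P_N_MED]
    n_amb = params[P_N_AMB]
    lam_cm = params[P_WAVE] * NM_TO_CM
    src_half = params[P_SRC_HALF]
    cap = int(params[P_CAP])
    polsamp = params[P_POLSAMP] > 0.5

    local_est = params[P_DETMODE] > 0.5

    n_inv = inv_cdf_theta.shape[0]
    n_tab = r12.shape[0]
    dtheta = np.pi / (n_tab - 1)

    for _ in range(n_photons):
        diag[DIAG_LAUNCHED] += 1
        # launch
        x = src_half * (2.0 * _rand(rst) - 1.0)
        y = src_half * (2.0 * _rand(rst) - 1.0)
        z = 0.0
        kx, ky, kz = 0.0, 0.0, 1.0
        lxx, lxy, lxz = 1.0, 0.0, 0.0
        lyx, lyy, lyz = 0.0, 1.0, 0.0
        tp = np.pi * _rand(rst)
        pp = 2.0 * np.pi * _rand(rst)
        si0 = 1.0
        sq0 = np.cos(tp)
        su0 = np.sin(tp) * np.cos(pp)
        sv0 = np.sin(tp) * np.sin(pp)
        sq, su, sv = sq0, su0, sv0  # I kept at 1

        events = 0
        alive = True
        while alive:
            # current region
            in_box = incl and (iz0 <= z < iz1) and (-ih <= x < ih) and (-ih <= y < ih)
            if in_box:
                mus = params[P_I_MUS]
                n_o, n_e = params[P_I_NO], params[P_I_NE]
                ex, ey = params[P_I_EX], params[P_I_EY]
                dn = params[P_I_DN]
            else:
                mus = params[P_H_MUS]
                n_o, n_e = params[P_H_NO], params[P_H_NE]
                ex, ey = params[P_H_EX], params[P_H_EY]
                dn = params[P_H_DN]

            # free path in the current region
            if mus > 0.0:
                ds = -np.log(1.0 - _rand(rst)) / mus
            else:
                ds = np.inf

            # distance to the domain boundary along k
            t_dom = np.inf
            bound = -1  # 0 top, 1 bottom, 2 side, 3 internal
            if kz < 0.0:
                t_dom, bound = -z / kz, 0
            elif kz > 0.0:
                t_dom, bound = (thick - z) / kz, 1
            cand = ds if ds < t_dom else t_dom

            # lateral faces: |t| >= lat - max(|x|, |y|), usually >> cand
            ax = x if x >= 0.0 else -x
            ay = y if y >= 0.0 else -y
            if cand > lat - (ax if ax > ay else ay):
                if kx > 0.0:
                    t = (lat - x) / kx
                    if t < t_dom:
                        t_dom, bound = t, 2
                elif kx < 0.0:
                    t = (-lat - x) / kx
                    if t < t_dom:
                        t_dom, bound = t, 2
                if ky > 0.0:
                    t = (lat - y) / ky
                    if t < t_dom:
                        t_dom, bound = t, 2
                elif ky < 0.0:
                    t = (-lat - y) / ky
                    if t < t_dom:
                        t_dom, bound = t, 2
                cand = ds if ds < t_dom else t_dom

            # internal box boundary (cheap per-axis bound gates the ray cast)
            if incl:
                if in_box:
                    b1 = ih - ax if ih - ax < ih - ay else ih - ay
                    b2 = z - iz0 if z - iz0 < iz1 - z else iz1 - z
                    bnd = b1 if b1 < b2 else b2
                else:
                    gx = ax - ih if ax > ih else 0.0
                    gy = ay - ih if ay > ih else 0.0
                    gz = iz0 - z if z < iz0 else (z - iz1 if z > iz1 else 0.0)
                    bnd = gx
                    if gy > bnd:
                        bnd = gy
                    if gz > bnd:
                        bnd = gz
                if cand >= bnd:
                    tx0 = (-ih - x) / kx if kx != 0.0 else -np.inf
                    tx1 = (ih - x) / kx if kx != 0.0 else np.inf
                    if tx0 > tx1:
                        tx0, tx1 = tx1, tx0
                    if kx == 0.0 and not (-ih <= x < ih):
                        tx0, tx1 = np.inf, -np.inf
                    ty0 = (-ih - y) / ky if ky != 0.0 else -np.inf
                    ty1 = (ih - y) / ky if ky != 0.0 else np.inf
                    if ty0 > ty1:
                        ty0, ty1 = ty1, ty0
                    if ky == 0.0 and not (-ih <= y < ih):
                        ty0, ty1 = np.inf, -np.inf
                    tz0 = (iz0 - z) / kz if kz != 0.0 else -np.inf
                    tz1 = (iz1 - z) / kz if kz != 0.0 else np.inf
                    if tz0 > tz1:
                        tz0, tz1 = tz1, tz0
                    if kz == 0.0 and not (iz0 <= z < iz1):
                        tz0, tz1 = np.inf, -np.inf
                    t_enter = max(tx0, ty0, tz0)
                    t_exit = min(tx1, ty1, tz1)
                    if in_box:
                        if t_exit > 0.0 and t_exit < t_dom:
                            t_dom, bound = t_exit, 3
                    else:
                        if t_enter > _EPS_NUDGE and t_enter < t_exit and t_enter < t_dom:
                            t_dom, bound = t_enter, 3

            step = ds if ds < t_dom else t_dom
            scattering = ds < t_dom

            # uniaxial retardation over this straight segment
            if dn != 0.0 and step > 0.0:
                ca = kx * ex + ky * ey  # cos(alpha), axis in-plane
                neff = n_o * n_e / np.sqrt(n_e * n_e * ca * ca + n_o * n_o * (1.0 - ca * ca))
                # ordinary-minus-extraordinary phase: with this package's
                # Stokes handedness the decomposed azimuth of a negative
                # uniaxial host then reads the optic-axis azimuth eta
                delta = 2.0 * np.pi * step * (n_o - neff) / lam_cm
                if delta != 0.0:
                    # f = k x e; beta from local_y, counter-clockwise about k
                    fx = -kz * ey
                    fy = kz * ex
                    fz = kx * ey - ky * ex
                    fn = np.sqrt(fx * fx + fy * fy + fz * fz)
                    if fn > 1e-9:
                        fx /= fn
                        fy /= fn
                        fz /= fn
                        cb = fx * lyx + fy * lyy + fz * lyz
                        sb = -(fx * lxx + fy * lxy + fz * lxz)
                        c2 = cb * cb - sb * sb
                        s2 = 2.0 * cb * sb
                        cd = np.cos(delta)
                        sd = np.sin(delta)
                        q1 = c2 * sq + s2 * su
                        u1 = -s2 * sq + c2 * su
                        u2 = cd * u1 + sd * sv
                        v2 = -sd * u1 + cd * sv
                        sq = c2 * q1 - s2 * u2
                        su = s2 * q1 + c2 * u2
                        sv = v2

            x += kx * step
            y += ky * step
            z += kz * step

            if scattering:
                events += 1
                if events > cap:
                    diag[DIAG_CAP] += 1
                    alive = False
                    break

                if local_est and -DET_HALF_CM <= x < DET_HALF_CM and -DET_HALF_CM <= y < DET_HALF_CM:
                    # expected contribution of a virtual scattering straight
                    # up to the distant detector, attenuated by the vertical
                    # optical depth; every event scores, which replaces the
                    # ~1% geometric acceptance of the physical cone
                    if incl and (-ih <= x < ih) and (-ih <= y < ih) and z > iz0:
                        ovl = (z if z < iz1 else iz1) - iz0
                        tau = params[P_H_MUS] * (z - ovl) + params[P_I_MUS] * ovl
                    else:
                        tau = params[P_H_MUS] * z
                    if tau <= TAU_CUTOFF:
                        cth = -kz  # cos of the virtual scattering angle
                        if cth > 1.0:
                            cth = 1.0
                        elif cth < -1.0:
                            cth = -1.0
                        th_d = np.arccos(cth)
                        gidx = th_d / dtheta
                        j0 = int(gidx)
                        if j0 >= n_tab - 1:
                            j0 = n_tab - 2
                        wj = gidx - j0
                        p11 = s11n[j0] * (1.0 - wj) + s11n[j0 + 1] * wj
                        d12 = r12[j0] * (1.0 - wj) + r12[j0 + 1] * wj
                        d33 = r33[j0] * (1.0 - wj) + r33[j0 + 1] * wj
                        d34 = r34[j0] * (1.0 - wj) + r34[j0 + 1] * wj
                        # rotate the frame so local_x lies in the (k, -z) plane
                        epx = kz * kx
                        epy = kz * ky
                        epz = kz * kz - 1.0
                        en = np.sqrt(epx * epx + epy * epy + epz * epz)
                        if en > 1e-9:
                            epx /= en
                            epy /= en
                            epz /= en
                            cphi = epx * lxx + epy * lxy + epz * lxz
                            sphi = epx * lyx + epy * lyy + epz * lyz
                        else:
                            cphi, sphi = 1.0, 0.0
                        c2p_ = cphi * cphi - sphi * sphi
                        s2p_ = 2.0 * cphi * sphi
                        q1 = c2p_ * sq + s2p_ * su
                        u1 = -s2p_ * sq + c2p_ * su
                        # scattering matrix toward -z (not renormalized)
                        i2 = 1.0 + d12 * q1
                        q2 = d12 + q1
                        u2 = d33 * u1 + d34 * sv
                        v2 = -d34 * u1 + d33 * sv
                        # transverse frame after the virtual deflection
                        sth = np.sqrt(max(0.0, 1.0 - cth * cth))
                        lxvx = cth * (cphi * lxx + sphi * lyx) - sth * kx
                        lxvy = cth * (cphi * lxy + sphi * lyy) - sth * ky
                        lxvz = cth * (cphi * lxz + sphi * lyz) - sth * kz
                        lyvx = -sphi * lxx + cphi * lyx
                        lyvy = -sphi * lxy + cphi * lyy
                        lyvz = -sphi * lxz + cphi * lyz
                        # uniaxial retardation along the vertical exit path:
                        # propagation is exactly across the in-plane axes
                        # (alpha = 90 deg), so each region contributes the
                        # full |delta_n| over its crossed length; segments
                        # ordered from the event up to the surface
                        if incl and (-ih <= x < ih) and (-ih <= y < ih) and z > iz0:
                            ovl2 = (z if z < iz1 else iz1) - iz0
                            lh_below = z - iz1 if z > iz1 else 0.0
                            lh_above = iz0
                        else:
                            ovl2 = 0.0
                            lh_below = 0.0
                            lh_above = z
                        for seg in range(3):
                            if seg == 0:
                                seg_len = lh_below
                                ex_r, ey_r = params[P_H_EX], params[P_H_EY]
                                dn_r = params[P_H_DN]
                            elif seg == 1:
                                seg_len = ovl2
                                ex_r, ey_r = params[P_I_EX], params[P_I_EY]
                                dn_r = params[P_I_DN]
                            else:
                                seg_len = lh_above
                                ex_r, ey_r = params[P_H_EX], params[P_H_EY]
                                dn_r = params[P_H_DN]
                            if dn_r != 0.0 and seg_len > 0.0:
                                dlt = 2.0 * np.pi * seg_len * (-dn_r) / lam_cm
                                # f = (-z) x e = (ey, -ex, 0)
                                cb = ey_r * lyvx - ex_r * lyvy
                                sb = -(ey_r * lxvx - ex_r * lxvy)
                                c2b = cb * cb - sb * sb
                                s2b = 2.0 * cb * sb
                                cdl = np.cos(dlt)
                                sdl = np.sin(dlt)
                                qq = c2b * q2 + s2b * u2
                                uu = -s2b * q2 + c2b * u2
                                u3 = cdl * uu + sdl * v2
                                v3 = -sdl * uu + cdl * v2
                                q2 = c2b * qq - s2b * u3
                                u2 = s2b * qq + c2b * u3
                                v2 = v3
                        # rotate into the detector basis (x_d = lab x)
                        c_d = lxvx
                        s_d = lyvx
                        nn = c_d * c_d + s_d * s_d
                        if nn > 1e-12:
                            c2d = (c_d * c_d - s_d * s_d) / nn
                            s2d = 2.0 * c_d * s_d / nn
                        else:
                            c2d, s2d = 1.0, 0.0
                        qd = c2d * q2 + s2d * u2
                        ud = -s2d * q2 + c2d * u2
                        vd = v2
                        if DET_FLIP_Y:
                            ud = -ud
                            vd = -vd
                        w = p11 * np.exp(-tau)
                        ipix = int((x + DET_HALF_CM) / PIXEL_CM)
                        jpix = int((y + DET_HALF_CM) / PIXEL_CM)
                        if 0 <= ipix < NPIX and 0 <= jpix < NPIX:
                            g_sum[jpix, ipix, 0, 0] += w * i2
                            g_sum[jpix, ipix, 0, 1] += w * i2 * sq0
                            g_sum[jpix, ipix, 0, 2] += w * i2 * su0
                            g_sum[jpix, ipix, 0, 3] += w * i2 * sv0
                            g_sum[jpix, ipix, 1, 0] += w * qd
                            g_sum[jpix, ipix, 1, 1] += w * qd * sq0
                            g_sum[jpix, ipix, 1, 2] += w * qd * su0
                            g_sum[jpix, ipix, 1, 3] += w * qd * sv0
                            g_sum[jpix, ipix, 2, 0] += w * ud
                            g_sum[jpix, ipix, 2, 1] += w * ud * sq0
                            g_sum[jpix, ipix, 2, 2] += w * ud * su0
                            g_sum[jpix, ipix, 2, 3] += w * ud * sv0
                            g_sum[jpix, ipix, 3, 0] += w * vd
                            g_sum[jpix, ipix, 3, 1] += w * vd * sq0
                            g_sum[jpix, ipix, 3, 2] += w * vd * su0
                            g_sum[jpix, ipix, 3, 3] += w * vd * sv0
                            d_sum[jpix, ipix, 0, 0] += w
                            d_sum[jpix, ipix, 0, 1] += w * sq0
                            d_sum[jpix, ipix, 0, 2] += w * su0
                            d_sum[jpix, ipix, 0, 3] += w * sv0
                            d_sum[jpix, ipix, 1, 0] += w * sq0
                            d_sum[jpix, ipix, 1, 1] += w * sq0 * sq0
                            d_sum[jpix, ipix, 1, 2] += w * sq0 * su0
                            d_sum[jpix, ipix, 1, 3] += w * sq0 * sv0
                            d_sum[jpix, ipix, 2, 0] += w * su0
                            d_sum[jpix, ipix, 2, 1] += w * su0 * sq0
                            d_sum[jpix, ipix, 2, 2] += w * su0 * su0
                            d_sum[jpix, ipix, 2, 3] += w * su0 * sv0
                            d_sum[jpix, ipix, 3, 0] += w * sv0
                            d_sum[jpix, ipix, 3, 1] += w * sv0 * sq0
                            d_sum[jpix, ipix, 3, 2] += w * sv0 * su0
                            d_sum[jpix, ipix, 3, 3] += w * sv0 * sv0
                            counts[jpix, ipix] += 1

                # sample scattering angle and azimuth
                accepted = False
                ct = 1.0
                st = 0.0
                c2p = 1.0
                s2p = 0.0
                f12 = 0.0
                f33 = 1.0
                f34 = 0.0
                while not accepted:
                    u = _rand(rst)
                    fidx = u * (n_inv - 1)
                    i0 = int(fidx)
                    if i0 >= n_inv - 1:
                        i0 = n_inv - 2
                    w = fidx - i0
                    theta_s = inv_cdf_theta[i0] * (1.0 - w) + inv_cdf_theta[i0 + 1] * w
                    gidx = theta_s / dtheta
                    j0 = int(gidx)
                    if j0 >= n_tab - 1:
                        j0 = n_tab - 2
                    wj = gidx - j0
                    f12 = r12[j0] * (1.0 - wj) + r12[j0 + 1] * wj
                    f33 = r33[j0] * (1.0 - wj) + r33[j0 + 1] * wj
                    f34 = r34[j0] * (1.0 - wj) + r34[j0 + 1] * wj
                    phi = 2.0 * np.pi * _rand(rst)
                    cp = np.cos(phi)
                    sp = np.sin(phi)
                    c2p = cp * cp - sp * sp
                    s2p = 2.0 * cp * sp
                    if polsamp:
                        q_rot = sq * c2p + su * s2p
                        w_acc = 0.5 * (1.0 + f12 * q_rot)
                        accepted = _rand(rst) < w_acc
                    else:
                        accepted = True
                    if accepted:
                        ct = np.cos(theta_s)
                        st = np.sqrt(max(0.0, 1.0 - ct * ct))
                        # rotate Stokes into the scattering plane
                        q1 = c2p * sq + s2p * su
                        u1 = -s2p * sq + c2p * su
                        # rotate frame about k by phi
                        nlxx = cp * lxx + sp * lyx
                        nlxy = cp * lxy + sp * lyy
                        nlxz = cp * lxz + sp * lyz
                        lyx = -sp * lxx + cp * lyx
                        lyy = -sp * lxy + cp * lyy
                        lyz = -sp * lxz + cp * lyz
                        lxx, lxy, lxz = nlxx, nlxy, nlxz
                        # scattering matrix (ratios to s11), then renormalize
                        si1 = 1.0 + f12 * q1
                        q2 = f12 + q1
                        u2 = f33 * u1 + f34 * sv
                        v2 = -f34 * u1 + f33 * sv
                        sq = q2 / si1
                        su = u2 / si1
                        sv = v2 / si1
                        # rotate direction by theta in the (k, local_x) plane
                        nkx = ct * kx + st * lxx
                        nky = ct * ky + st * lxy
                        nkz = ct * kz + st * lxz
                        lxx = ct * lxx - st * kx
                        lxy = ct * lxy - st * ky
                        lxz = ct * lxz - st * kz
                        kx, ky, kz = nkx, nky, nkz
                if events % _FRAME_REFRESH == 0:
                    # re-orthonormalize the frame against rounding drift
                    kn = np.sqrt(kx * kx + ky * ky + kz * kz)
                    kx /= kn
                    ky /= kn
                    kz /= kn
                    dot = lxx * kx + lxy * ky + lxz * kz
                    lxx -= dot * kx
                    lxy -= dot * ky
                    lxz -= dot * kz
                    ln = np.sqrt(lxx * lxx + lxy * lxy + lxz * lxz)
                    lxx /= ln
                    lxy /= ln
                    lxz /= ln
                    lyx = ky * lxz - kz * lxy
                    lyy = kz * lxx - kx * lxz
                    lyz = kx * lxy - ky * lxx
                continue

            if bound == 3:
                # index-matched internal boundary: push through, resample
                x += kx * _EPS_NUDGE
                y += ky * _EPS_NUDGE
                z += kz * _EPS_NUDGE
                continue

            if bound == 2:
                diag[DIAG_SIDE] += 1
                alive = False
                break

            # external z boundary: Fresnel
            top = bound == 0
            ci = -kz if top else kz
            if ci > 1.0:
                ci = 1.0
            sin_i = np.sqrt(max(0.0, 1.0 - ci * ci))
            rs_, rp_, ctr = _fresnel(n_med, n_amb, ci)
            if sin_i < 1e-9:
                # normal incidence: polarization-independent
                r_phot = rs_
                if _rand(rst) < r_phot:
                    kz = -kz
                    continue
                # transmit straight out
                if top:
                    if local_est:
                        diag[DIAG_TOP_OUT] += 1
                        alive = False
                        break
                    diag[DIAG_TOP_OUT] += 1
                    # detector frame: x_d = lab x
                    c_d = lxx  # x_d . local_x
                    s_d = lyx  # x_d . local_y
                    nn = np.sqrt(c_d * c_d + s_d * s_d)
                    if nn > 1e-12:
                        c2d = (c_d * c_d - s_d * s_d) / (nn * nn)
                        s2d = 2.0 * c_d * s_d / (nn * nn)
                    else:
                        c2d, s2d = 1.0, 0.0
                    qd = c2d * sq + s2d * su
                    ud = -s2d * sq + c2d * su
                    vd = sv
                    if DET_FLIP_Y:
                        ud = -ud
                        vd = -vd
                    ipix = int((x + DET_HALF_CM) / PIXEL_CM)
                    jpix = int((y + DET_HALF_CM) / PIXEL_CM)
                    if 0 <= ipix < NPIX and 0 <= jpix < NPIX and x >= -DET_HALF_CM and y >= -DET_HALF_CM:
                        diag[DIAG_TOP_OUT] -= 1
                        diag[DIAG_DETECTED] += 1
                        so0 = 1.0
                        so1, so2, so3 = qd, ud, vd
                        g_sum[jpix, ipix, 0, 0] += so0
                        g_sum[jpix, ipix, 0, 1] += so0 * sq0
                        g_sum[jpix, ipix, 0, 2] += so0 * su0
                        g_sum[jpix, ipix, 0, 3] += so0 * sv0
                        g_sum[jpix, ipix, 1, 0] += so1
                        g_sum[jpix, ipix, 1, 1] += so1 * sq0
                        g_sum[jpix, ipix, 1, 2] += so1 * su0
                        g_sum[jpix, ipix, 1, 3] += so1 * sv0
                        g_sum[jpix, ipix, 2, 0] += so2
                        g_sum[jpix, ipix, 2, 1] += so2 * sq0
                        g_sum[jpix, ipix, 2, 2] += so2 * su0
                        g_sum[jpix, ipix, 2, 3] += so2 * sv0
                        g_sum[jpix, ipix, 3, 0] += so3
                        g_sum[jpix, ipix, 3, 1] += so3 * sq0
                        g_sum[jpix, ipix, 3, 2] += so3 * su0
                        g_sum[jpix, ipix, 3, 3] += so3 * sv0
                        d_sum[jpix, ipix, 0, 0] += 1.0
                        d_sum[jpix, ipix, 0, 1] += sq0
                        d_sum[jpix, ipix, 0, 2] += su0
                        d_sum[jpix, ipix, 0, 3] += sv0
                        d_sum[jpix, ipix, 1, 0] += sq0
                        d_sum[jpix, ipix, 1, 1] += sq0 * sq0
                        d_sum[jpix, ipix, 1, 2] += sq0 * su0
                        d_sum[jpix, ipix, 1, 3] += sq0 * sv0
                        d_sum[jpix, ipix, 2, 0] += su0
                        d_sum[jpix, ipix, 2, 1] += su0 * sq0
                        d_sum[jpix, ipix, 2, 2] += su0 * su0
                        d_sum[jpix, ipix, 2, 3] += su0 * sv0
                        d_sum[jpix, ipix, 3, 0] += sv0
                        d_sum[jpix, ipix, 3, 1] += sv0 * sq0
                        d_sum[jpix, ipix, 3, 2] += sv0 * su0
                        d_sum[jpix, ipix, 3, 3] += sv0 * sv0
                        counts[jpix, ipix] += 1
                else:
                    diag[DIAG_BOTTOM] += 1
                alive = False
                break

            # oblique incidence: s-p decomposition
            # surface normal (outward): top (0,0,-1), bottom (0,0,1)
            nzs = -1.0 if top else 1.0
            # s axis: k x n / |k x n|
            sx = ky * nzs
            sy = -kx * nzs
            sz = 0.0
            sn = np.sqrt(sx * sx + sy * sy)
            sx /= sn
            sy /= sn
            # p_i = s x k
            px = sy * kz - sz * ky
            py = sz * kx - sx * kz
            pz = sx * ky - sy * kx
            # rotate Stokes so local_x -> p_i
            cr = px * lxx + py * lxy + pz * lxz
            srot = px * lyx + py * lyy + pz * lyz
            c2r = cr * cr - srot * srot
            s2r = 2.0 * cr * srot
            q1 = c2r * sq + s2r * su
            u1 = -s2r * sq + c2r * su
            sq, su = q1, u1
            r_phot = 0.5 * (rp_ * (1.0 + sq) + rs_ * (1.0 - sq))
            if _rand(rst) < r_phot:
                # reflect
                rp_a = np.sqrt(rp_)
                rs_a = np.sqrt(rs_)
                i1 = 0.5 * ((rp_ + rs_) + (rp_ - rs_) * sq)
                q2 = 0.5 * ((rp_ - rs_) + (rp_ + rs_) * sq)
                u2 = rp_a * rs_a * su
                v2 = rp_a * rs_a * sv
                sq, su, sv = q2 / i1, u2 / i1, v2 / i1
                kz = -kz
                # new frame: local_y = s, local_x = s x k'
                lyx, lyy, lyz = sx, sy, sz
                lxx = sy * kz - sz * ky
                lxy = sz * kx - sx * kz
                lxz = sx * ky - sy * kx
                continue
            # transmit
            tp_ = 1.0 - rp_
            ts_ = 1.0 - rs_
            i1 = 0.5 * ((tp_ + ts_) + (tp_ - ts_) * sq)
            q2 = 0.5 * ((tp_ - ts_) + (tp_ + ts_) * sq)
            a_cross = np.sqrt(tp_ * ts_)
            u2 = a_cross * su
            v2 = a_cross * sv
            sq, su, sv = q2 / i1, u2 / i1, v2 / i1
            # refracted direction
            scale = n_med / n_amb
            kx = scale * kx
            ky = scale * ky
            kz = nzs * ctr
            if top and local_est:
                diag[DIAG_TOP_OUT] += 1
                alive = False
                break
            if top:
                # frame after refraction: local_y = s, local_x = s x k'
                lyx, lyy, lyz = sx, sy, sz
                lxx = sy * kz - sz * ky
                lxy = sz * kx - sx * kz
                lxz = sx * ky - sy * kx
                # rotate into the detector basis: x_d = projection of lab x
                xdx = 1.0 - kx * kx
                xdy = -kx * ky
                xdz = -kx * kz
                nn = np.sqrt(xdx * xdx + xdy * xdy + xdz * xdz)
                if nn > 1e-12:
                    xdx /= nn
                    xdy /= nn
                    xdz /= nn
                    c_d = xdx * lxx + xdy * lxy + xdz * lxz
                    s_d = xdx * lyx + xdy * lyy + xdz * lyz
                    c2d = c_d * c_d - s_d * s_d
                    s2d = 2.0 * c_d * s_d
                    qd = c2d * sq + s2d * su
                    ud = -s2d * sq + c2d * su
                    vd = sv
                else:
                    qd, ud, vd = sq, su, sv
                if DET_FLIP_Y:
                    ud = -ud
                    vd = -vd
                ipix = int((x + DET_HALF_CM) / PIXEL_CM)
                jpix = int((y + DET_HALF_CM) / PIXEL_CM)
                if 0 <= ipix < NPIX and 0 <= jpix < NPIX and x >= -DET_HALF_CM and y >= -DET_HALF_CM:
                    diag[DIAG_DETECTED] += 1
                    so1, so2, so3 = qd, ud, vd
                    g_sum[jpix, ipix, 0, 0] += 1.0
                    g_sum[jpix, ipix, 0, 1] += sq0
                    g_sum[jpix, ipix, 0, 2] += su0
                    g_sum[jpix, ipix, 0, 3] += sv0
                    g_sum[jpix, ipix, 1, 0] += so1
                    g_sum[jpix, ipix, 1, 1] += so1 * sq0
                    g_sum[jpix, ipix, 1, 2] += so1 * su0
                    g_sum[jpix, ipix, 1, 3] += so1 * sv0
                    g_sum[jpix, ipix, 2, 0] += so2
                    g_sum[jpix, ipix, 2, 1] += so2 * sq0
                    g_sum[jpix, ipix, 2, 2] += so2 * su0
                    g_sum[jpix, ipix, 2, 3] += so2 * sv0
                    g_sum[jpix, ipix, 3, 0] += so3
                    g_sum[jpix, ipix, 3, 1] += so3 * sq0
                    g_sum[jpix, ipix, 3, 2] += so3 * su0
                    g_sum[jpix, ipix, 3, 3] += so3 * sv0
                    d_sum[jpix, ipix, 0, 0] += 1.0
                    d_sum[jpix, ipix, 0, 1] += sq0
                    d_sum[jpix, ipix, 0, 2] += su0
                    d_sum[jpix, ipix, 0, 3] += sv0
                    d_sum[jpix, ipix, 1, 0] += sq0
                    d_sum[jpix, ipix, 1, 1] += sq0 * sq0
                    d_sum[jpix, ipix, 1, 2] += sq0 * su0
                    d_sum[jpix, ipix, 1, 3] += sq0 * sv0
                    d_sum[jpix, ipix, 2, 0] += su0
                    d_sum[jpix, ipix, 2, 1] += su0 * sq0
                    d_sum[jpix, ipix, 2, 2] += su0 * su0
                    d_sum[jpix, ipix, 2, 3] += su0 * sv0
                    d_sum[jpix, ipix, 3, 0] += sv0
                    d_sum[jpix, ipix, 3, 1] += sv0 * sq0
                    d_sum[jpix, ipix, 3, 2] += sv0 * su0
                    d_sum[jpix, ipix, 3, 3] += sv0 * sv0
                    counts[jpix, ipix] += 1
                else:
                    diag[DIAG_TOP_OUT] += 1
            else:
                diag[DIAG_BOTTOM] += 1
            alive = False
            break


def run_transport(
    phantom: PhantomModel,
    table: PhaseTable,
    config: TransportConfig,
) -> TransportResult:
    """Simulate one Mueller-matrix image; returns per-batch accumulators.

    The same seed, phantom and configuration produce bit-identical
    accumulators."""
    if phantom.host.mua != 0.0 or (phantom.inclusion is not None and phantom.inclusion.mua != 0.0):
        raise NotImplementedError("absorbing regions are not supported (mu_a = 0 in all studies)")
    params = _pack_params(phantom, config)
    r12 = (table.s12 / table.s11).astype(np.float64)
    r33 = (table.s33 / table.s11).astype(np.float64)
    r34 = (table.s34 / table.s11).astype(np.float64)
    s11n = (table.s11 / table.s11.mean()).astype(np.float64)  # relative phase law
    inv_cdf = table.inv_cdf_theta.astype(np.float64)

    nb = config.batches
    g_sum = np.zeros((nb, NPIX, NPIX, 4, 4))
    d_sum = np.zeros((nb, NPIX, NPIX, 4, 4))
    counts = np.zeros((nb, NPIX, NPIX), dtype=np.int64)
    diag = np.zeros((nb, 6), dtype=np.int64)

    per_batch = config.photons // nb
    extra = config.photons - per_batch * nb
    seeds = config.batch_seeds()
    for b in range(nb):
        n = per_batch + (1 if b < extra else 0)
        _walk_kernel(
            n, int(seeds[b]), params, inv_cdf, r12, r33, r34, s11n,
            g_sum[b], d_sum[b], counts[b], diag[b],
        )
    return TransportResult(g_sum, d_sum, counts, diag, config, phantom)
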