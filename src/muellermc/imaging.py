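"""Per-pixel Mueller-matrix estimation and polarimetric map generation.

The detector is an ideal imaging detector: photons leaving the top
surface are binned by exit position into a 100 x 100 grid of 0.1 mm
pixels covering the central 1 cm x 1 cm of the phantom; only pixels
entirely inside the inscribed 1 cm diameter circle enter the analysis.

For every pixel the Mueller matrix is the correlation-matrix estimate

    M = G D^-1,   G = sum S_out S_in^T,   D = sum S_in S_in^T,

exact whenever each record satisfies ``S_out = M S_in`` (the empirical
``D-hat`` cancels the input-state sampling).  When ``D-hat`` is too
ill-conditioned the analytic second-moment matrix of the uniform
Poincare-sphere input law, ``diag(1, 1/2, 1/4, 1/4) * count``, is used
instead.  Estimates are normalized pixel-wise by ``m00``, screened by the
Cloude realizability test and decomposed (Lu-Chipman) into maps of total
depolarization, scalar linear retardance and optic-axis azimuth.

Monte Carlo uncertainty comes from batch statistics: the photon budget is
split into equal batches and the spread of per-batch ROI means (or
normalized elements, for the convergence criterion) across batches gives
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polarization import LOW_RETARDANCE_DEG, cloude_filter, lu_chipman
from .transport import DET_HALF_CM, NPIX, PIXEL_CM, TransportResult

__all__ = [
    "PolarimetricMaps",
    "active_mask",
    "pixel_centers",
    "estimate_mueller",
    "estimate_mueller_field",
    "normalize_m11",
    "convergence_check",
    "make_maps",
    "roi_masks",
    "roi_statistics",
    "roi_contrast",
    "circular_mean_azimuth",
]

#: analytic D of the uniform Poincare input law per record
D_ANALYTIC = np.diag([1.0, 0.5, 0.25, 0.25])
MIN_PIXEL_COUNT = 100
_COND_LIMIT = 1e6


def pixel_centers() -> np.ndarray:
    """Pixel-center coordinates (cm) along one axis of the imaged field."""
    return -DET_HALF_CM + PIXEL_CM * (np.arange(NPIX) + 0.5)


def active_mask(radius_cm: float = DET_HALF_CM) -> np.ndarray:
    """Pixels entirely inside the inscribed circle of the imaged field."""
    c = pixel_centers()
    xx, yy = np.meshgrid(c, c)
    half = PIXEL_CM / 2.0
    corner = np.sqrt((np.abs(xx) + half) ** 2 + (np.abs(yy) + half) ** 2)
    return corner <= radius_cm


def estimate_mueller(
    g_sum: np.ndarray, d_sum: np.ndarray, count: int, min_count: int = MIN_PIXEL_COUNT
) -> np.ndarray | None:
    """Mueller estimate of one pixel, or None below the count threshold."""
    if count < min_count:
        return None
    if np.linalg.cond(d_sum) > _COND_LIMIT:
        d_sum = D_ANALYTIC * count
    return g_sum @ np.linalg.inv(d_sum)


def estimate_mueller_field(
    g_sum: np.ndarray,
    d_sum: np.ndarray,
    counts: np.ndarray,
    min_count: int = MIN_PIXEL_COUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel ``G D^-1`` over the full grid.

    Returns ``(M, estimated)`` where ``M`` is (NPIX, NPIX, 4, 4) and
    ``estimated`` flags pixels with enough photons."""
    estimated = counts >= min_count
    m = np.zeros((NPIX, NPIX, 4, 4))
    if not estimated.any():
        return m, estimated
    d = d_sum[estimated]
    cond = np.linalg.cond(d)
    bad = ~np.isfinite(cond) | (cond > _COND_LIMIT)
    if bad.any():
        d = d.copy()
        d[bad] = D_ANALYTIC[None] * counts[estimated][bad, None, None]
    m[estimated] = np.linalg.solve(
        np.swapaxes(d, -1, -2), np.swapaxes(g_sum[estimated], -1, -2)
    ).swapaxes(-1, -2)
    return m, estimated


def normalize_m11(m: np.ndarray) -> np.ndarray:
    """Normalize a Mueller matrix by its intensity element ``m[0, 0]``.

    Raises ``ValueError`` for non-positive ``m[0, 0]``."""
    if m[0, 0] <= 0:
        raise ValueError("m[0,0] must be positive")
    return m / m[0, 0]


def convergence_check(
    result: TransportResult,
    active: np.ndarray | None = None,
    min_count: int = 20,
    threshold: float = 0.015,
) -> tuple[bool, float]:
    """Batch-to-batch convergence of the normalized Mueller elements.

    Computes, per active pixel and element, the standard error of the
    m11-normalized coefficients across batches; converged when the
    maximum over pixels estimated in every batch is below ``threshold``
    (1.5%)."""
    if active is None:
        active = active_mask()
    nb = result.g_sum.shape[0]
    if nb < 2:
        raise ValueError("need at least 2 batches")
    per_batch = []
    ok_all = np.ones((NPIX, NPIX), dtype=bool)
    for b in range(nb):
        m, est = estimate_mueller_field(
            result.g_sum[b], result.d_sum[b], result.counts[b], min_count
        )
        m00 = m[..., 0, 0]
        ok = est & (m00 > 0)
        mn = np.zeros_like(m)
        mn[ok] = m[ok] / m00[ok][:, None, None]
        per_batch.append(mn)
        ok_all &= ok
    stack = np.stack(per_batch)  # (nb, NPIX, NPIX, 4, 4)
    se = stack.std(axis=0, ddof=1) / np.sqrt(nb)
    sel = ok_all & active
    if not sel.any():
        return False, float("inf")
    max_se = float(se[sel].max())
    return max_se < threshold, max_se


@dataclass
class PolarimetricMaps:
    """Maps of the three scalar polarimetric observables plus masks."""

    depolarization: np.ndarray  # dimensionless, NaN outside valid pixels
    retardance: np.ndarray  # degrees
    azimuth: np.ndarray  # degrees in [0, 180)
    active: np.ndarray  # detector-geometry mask
    valid: np.ndarray  # active & estimated & Cloude-physical
    estimated: np.ndarray  # enough photons for the pixel estimate
    low_retardance: np.ndarray  # azimuth numerically unstable there
    mueller: np.ndarray  # (NPIX, NPIX, 4, 4) normalized estimates

    def as_pages(self) -> np.ndarray:
        """Stack (depolarization, retardance, azimuth) for TIFF export."""
        return np.stack(
            [self.depolarization, self.retardance, self.azimuth]
        ).astype(np.float32)


def make_maps(
    result_or_g,
    d_sum: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    min_count: int = MIN_PIXEL_COUNT,
) -> PolarimetricMaps:
    """Pixel-wise Cloude screening + Lu-Chipman decomposition.

    Accepts either a :class:`TransportResult` (batches are summed) or raw
    ``(g_sum, d_sum, counts)`` grids."""
    if isinstance(result_or_g, TransportResult):
        g = result_or_g.g_sum.sum(axis=0)
        d = result_or_g.d_sum.sum(axis=0)
        c = result_or_g.counts.sum(axis=0)
    else:
        g, d, c = result_or_g, d_sum, counts
    m_field, estimated = estimate_mueller_field(g, d, c, min_count)
    active = active_mask()
    depol = np.full((NPIX, NPIX), np.nan)
    ret = np.full((NPIX, NPIX), np.nan)
    azi = np.full((NPIX, NPIX), np.nan)
    valid = np.zeros((NPIX, NPIX), dtype=bool)
    lowret = np.zeros((NPIX, NPIX), dtype=bool)
    norm = np.zeros_like(m_field)
    for j, i in zip(*np.nonzero(estimated & active)):
        m = m_field[j, i]
        if m[0, 0] <= 0:
            continue
        mn = normalize_m11(m)
        norm[j, i] = mn
        physical, _ = cloude_filter(mn)
        if not physical:
            continue
        dec = lu_chipman(mn)
        valid[j, i] = True
        depol[j, i] = dec.total_depolarization
        ret[j, i] = dec.linear_retardance
        azi[j, i] = dec.azimuth
        lowret[j, i] = dec.linear_retardance < LOW_RETARDANCE_DEG
    return PolarimetricMaps(depol, ret, azi, active, valid, estimated, lowret, norm)


# ---------------------------------------------------------------------------
# regions of interest


def roi_masks(phantom, margin_cm: float = 0.1, core_fraction: float = 0.6):
    """(inclusion ROI, host ROI) pixel masks for a phantom with inclusion.

    The inclusion ROI is the central ``core_fraction`` of the footprint
    projection; the host ROI is everything at least ``margin_cm`` outside
    the footprint (within the active circle)."""
    if phantom.inclusion is None:
        raise ValueError("phantom has no inclusion")
    c = pixel_centers()
    xx, yy = np.meshgrid(c, c)
    act = active_mask()
    h = phantom.inclusion_half_cm
    core = core_fraction * h
    incl = act & (np.abs(xx) <= core) & (np.abs(yy) <= core)
    host = act & (np.maximum(np.abs(xx), np.abs(yy)) >= h + margin_cm)
    if not incl.any() or not host.any():
        raise ValueError("empty ROI")
    return incl, host


def circular_mean_azimuth(azimuth_deg: np.ndarray) -> float:
    """Circular mean of an axial (180-degree periodic) angle map."""
    a = np.radians(2.0 * azimuth_deg[np.isfinite(azimuth_deg)])
    if a.size == 0:
        return float("nan")
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) / 2.0 % 180.0)


def _batch_roi_means(result: TransportResult, roi: np.ndarray, min_count: int = 20):
    """Per-batch ROI summaries of the three observables (for standard
    errors): pixel-wise map means and the decomposition of the
    ROI-averaged normalized Mueller matrix."""
    out = {
        "depolarization": [], "retardance": [], "azimuth": [],
        "depolarization_avg": [], "retardance_avg": [], "azimuth_avg": [],
    }
    for b in range(result.g_sum.shape[0]):
        m_field, est = estimate_mueller_field(
            result.g_sum[b], result.d_sum[b], result.counts[b], min_count
        )
        dep, ret, azi, mats = [], [], [], []
        for j, i in zip(*np.nonzero(est & roi)):
            m = m_field[j, i]
            if m[0, 0] <= 0:
                continue
            mn = normalize_m11(m)
            # same realizability screen as the map pipeline; keeps noisy
            # per-batch pixels from blowing up the standard errors
            if not cloude_filter(mn)[0]:
                continue
            mats.append(mn)
            dec = lu_chipman(mn)
            dep.append(dec.total_depolarization)
            ret.append(dec.linear_retardance)
            azi.append(dec.azimuth)
        out["depolarization"].append(np.mean(dep) if dep else np.nan)
        out["retardance"].append(np.mean(ret) if ret else np.nan)
        out["azimuth"].append(
            circular_mean_azimuth(np.asarray(azi)) if azi else np.nan
        )
        if mats:
            dec = lu_chipman(np.mean(mats, axis=0))
            out["depolarization_avg"].append(dec.total_depolarization)
            out["retardance_avg"].append(dec.linear_retardance)
            out["azimuth_avg"].append(dec.azimuth)
        else:
            for k in ("depolarization_avg", "retardance_avg", "azimuth_avg"):
                out[k].append(np.nan)
    return {k: np.asarray(v) for k, v in out.items()}


def roi_statistics(
    maps: PolarimetricMaps, roi: np.ndarray, result: TransportResult | None = None
) -> dict:
    """ROI summaries of the three observables.

    Two estimates are reported for each observable: the pixel-wise map
    mean (``depolarization`` etc., matching pixel-wise decomposition
    followed by zone averaging) and the decomposition of the ROI-averaged
    normalized Mueller matrix (``*_avg``), which is far less sensitive to
    per-pixel estimator noise at moderate photon budgets.  Azimuth
    statistics are circular on the doubled angle (axial data).  Batch-based
    standard errors are added when the per-batch accumulators are given.
    """
    sel = roi & maps.valid
    stats = {
        "n_pixels": int(sel.sum()),
        "depolarization": float(np.nanmean(maps.depolarization[sel])),
        "retardance": float(np.nanmean(maps.retardance[sel])),
        "azimuth": circular_mean_azimuth(maps.azimuth[sel]),
    }
    if sel.any():
        dec = lu_chipman(maps.mueller[sel].mean(axis=0))
        stats["depolarization_avg"] = dec.total_depolarization
        stats["retardance_avg"] = dec.linear_retardance
        stats["azimuth_avg"] = dec.azimuth
    else:
        stats["depolarization_avg"] = float("nan")
        stats["retardance_avg"] = float("nan")
        stats["azimuth_avg"] = float("nan")
    if result is not None:
        per_batch = _batch_roi_means(result, roi)
        for key in ("depolarization", "retardance", "depolarization_avg", "retardance_avg"):
            v = per_batch[key]
            v = v[np.isfinite(v)]
            stats[f"{key}_se"] = (
                float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
            )
        for key in ("azimuth", "azimuth_avg"):
            a = per_batch[key]
            a = a[np.isfinite(a)]
            if len(a) > 1:
                # circular spread on the doubled angle
                z = np.exp(1j * np.radians(2.0 * a))
                rbar = np.abs(z.mean())
                circ_sd = np.degrees(np.sqrt(max(0.0, -2.0 * np.log(max(rbar, 1e-12))))) / 2.0
                stats[f"{key}_se"] = float(circ_sd / np.sqrt(len(a)))
            else:
                stats[f"{key}_se"] = float("nan")
    return stats


def roi_contrast(
    maps: PolarimetricMaps,
    incl_roi: np.ndarray,
    host_roi: np.ndarray,
    result: TransportResult | None = None,
) -> dict:
    """Depolarization contrast host-minus-inclusion in percentage points."""
    s_in = roi_statistics(maps, incl_roi, result)
    s_host = roi_statistics(maps, host_roi, result)
    out = {
        "mean_inclusion": s_in["depolarization"],
        "mean_host": s_host["depolarization"],
        "contrast_pp": 100.0 * (s_host["depolarization"] - s_in["depolarization"]),
    }
    if result is not None:
        se = np.hypot(s_in.get("depolarization_se", np.nan), s_host.get("depolarization_se", np.nan))
        out["contrast_pp_se"] = 100.0 * float(se)
    return out
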