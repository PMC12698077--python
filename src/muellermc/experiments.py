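"""Config-driven experiment runners for the phantom studies.

Three studies are reproduced end-to-end:

* depth sweep - both phantoms simulated with the inclusion top face at a
  grid of depths (in scattering mean-free-path units, ls = 25 um at
  mu_s = 400 cm^-1); inclusion-zone ROI means of depolarization, linear
  retardance and optic-axis azimuth trace the depth trends, including the
  crossing-fiber retardance minimum / azimuth flip and the depth at which
  the two phantoms become indistinguishable;
* birefringence sweep - the host ``delta_n`` varied with an isotropic
  tumor inclusion at depth 1 ls, measuring the host-minus-tumor
  depolarization contrast;
* scattering sweep - tumor scattering coefficient varied at nearly
  isotropic host birefringence (delta_n = -1e-5), same contrast measure.

Trend tables are classified into the symbols {C1, C2, up, down, 0, T, B}:
constant (within 2 SE of the previous depth, numbered by level), a
significant increase/decrease toward the surface, retardance compatible
with zero, and azimuth reading the top-layer (inclusion) or bottom-layer
(host) axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging
from .mie import PhaseTable, build_phase_table, density_for_target_mus, gaussian_size_groups
from .phantoms import PhantomModel, build_crossing_fiber_phantom, build_tumor_phantom
from .transport import TransportConfig, TransportResult, run_transport

__all__ = [
    "ExperimentConfig",
    "ConditionResult",
    "default_phase_table",
    "simulate_condition",
    "run_depth_sweep",
    "run_dn_sweep",
    "run_mus_sweep",
    "classify_trends",
    "retardance_minimum_depth",
    "azimuth_flip_depth",
    "depol_separation_onset",
    "retardance_equality_depth",
    "save_outputs",
]

UP, DOWN, CONST = "↑", "↓", "C"

#: default depth grid (ls units): dense near the shallow transitions,
#: coarse beyond
DEPTHS_DEFAULT = (0.5, 1, 2, 4, 6, 8, 10, 12, 16, 20, 24, 28, 32, 36, 40)
DN_SWEEP_DEFAULT = (-1e-4, -5e-4, -1e-3)
MUS_SWEEP_DEFAULT = (120.0, 171.0, 240.0, 280.0)


@dataclass
class ExperimentConfig:
    """Photon budget and bookkeeping shared by all conditions of a study."""

    photons: int = 2_000_000
    batches: int = 10
    seed: int = 0
    min_pixel_count: int = 100
    output_dir: str | None = None

    def transport(self, condition_index: int = 0) -> TransportConfig:
        # distinct, reproducible sub-seed per condition
        sub = int(np.random.SeedSequence([self.seed, condition_index]).generate_state(1)[0] % (2**31))
        return TransportConfig(photons=self.photons, batches=self.batches, seed=sub)


@dataclass
class ConditionResult:
    """One simulated condition: maps plus ROI summaries."""

    phantom: PhantomModel
    maps: imaging.PolarimetricMaps
    result: TransportResult
    inclusion_stats: dict
    host_stats: dict
    contrast: dict
    converged: bool
    max_batch_se: float

    def manifest(self) -> dict:
        man = self.result.manifest()
        man["converged"] = self.converged
        man["max_batch_se"] = self.max_batch_se
        return man


def default_phase_table(phantom: PhantomModel, cache_dir=None) -> PhaseTable:
    """Ensemble phase table of the five-group Gaussian sphere mixture.

    One table serves every region: the tumor's lower scattering
    coefficient only rescales the particle number density, which leaves
    the angular law unchanged."""
    groups = gaussian_size_groups(n_particle=phantom.n_particle)
    groups = density_for_target_mus(
        groups, phantom.wavelength_nm, phantom.n_medium, phantom.host.mus
    )
    return build_phase_table(groups, phantom.wavelength_nm, phantom.n_medium, cache_dir=cache_dir)


def simulate_condition(
    phantom: PhantomModel,
    config: ExperimentConfig,
    condition_index: int = 0,
    table: PhaseTable | None = None,
) -> ConditionResult:
    """Transport + decomposition + ROI statistics for one phantom."""
    if table is None:
        table = default_phase_table(phantom)
    result = run_transport(phantom, table, config.transport(condition_index))
    maps = imaging.make_maps(result, min_count=config.min_pixel_count)
    converged, max_se = imaging.convergence_check(result)
    if phantom.inclusion is not None:
        incl_roi, host_roi = imaging.roi_masks(phantom)
        s_in = imaging.roi_statistics(maps, incl_roi, result)
        s_host = imaging.roi_statistics(maps, host_roi, result)
        contrast = imaging.roi_contrast(maps, incl_roi, host_roi, result)
    else:
        act = imaging.active_mask()
        s_in = s_host = imaging.roi_statistics(maps, act, result)
        contrast = {"contrast_pp": 0.0}
    return ConditionResult(phantom, maps, result, s_in, s_host, contrast, converged, max_se)


def _sweep_row(kind: str, depth: float, cond: ConditionResult) -> dict:
    row = {"phantom": kind, "depth_ls": depth}
    for prefix, stats in (("incl", cond.inclusion_stats), ("host", cond.host_stats)):
        for key in (
            "depolarization", "retardance", "azimuth",
            "depolarization_avg", "retardance_avg", "azimuth_avg",
        ):
            row[f"{prefix}_{key}"] = stats.get(key)
            row[f"{prefix}_{key}_se"] = stats.get(f"{key}_se")
    row["contrast_pp"] = cond.contrast.get("contrast_pp")
    row["contrast_pp_se"] = cond.contrast.get("contrast_pp_se")
    row["converged"] = cond.converged
    row["max_batch_se"] = cond.max_batch_se
    return row


def run_depth_sweep(
    config: ExperimentConfig,
    depths_ls=DEPTHS_DEFAULT,
    kinds=("crossing_fiber", "tumor"),
    table: PhaseTable | None = None,
    on_condition=None,
) -> pd.DataFrame:
    """Simulate both phantoms over a grid of inclusion depths."""
    rows = []
    idx = 0
    for kind in kinds:
        for depth in depths_ls:
            phantom = (
                build_crossing_fiber_phantom(depth)
                if kind == "crossing_fiber"
                else build_tumor_phantom(depth)
            )
            if table is None:
                table = default_phase_table(phantom)
            cond = simulate_condition(phantom, config, idx, table)
            rows.append(_sweep_row(kind, depth, cond))
            if on_condition is not None:
                on_condition(kind, depth, cond)
            idx += 1
    return pd.DataFrame(rows)


def run_dn_sweep(
    config: ExperimentConfig,
    dn_values=DN_SWEEP_DEFAULT,
    depth_ls: float = 1.0,
    table: PhaseTable | None = None,
) -> pd.DataFrame:
    """Host birefringence sweep: isotropic tumor, equal scattering."""
    rows = []
    for i, dn in enumerate(dn_values):
        phantom = build_tumor_phantom(depth_ls, host={"delta_n": dn})
        if table is None:
            table = default_phase_table(phantom)
        cond = simulate_condition(phantom, config, i, table)
        row = _sweep_row("tumor", depth_ls, cond)
        row["delta_n"] = dn
        rows.append(row)
    return pd.DataFrame(rows)


def run_mus_sweep(
    config: ExperimentConfig,
    mus_values=MUS_SWEEP_DEFAULT,
    depth_ls: float = 1.0,
    dn_host: float = -1e-5,
    table: PhaseTable | None = None,
) -> pd.DataFrame:
    """Tumor scattering-coefficient sweep at weak host birefringence."""
    rows = []
    for i, mus_t in enumerate(mus_values):
        phantom = build_tumor_phantom(depth_ls, mus_tumor=mus_t, host={"delta_n": dn_host})
        if table is None:
            table = default_phase_table(phantom)
        cond = simulate_condition(phantom, config, i, table)
        row = _sweep_row("tumor", depth_ls, cond)
        row["mus_tumor"] = mus_t
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived depth-trend metrics


def retardance_minimum_depth(df: pd.DataFrame, kind: str = "crossing_fiber") -> float:
    """Depth of the inclusion-ROI retardance minimum (parabolic refinement).

    The crossing-fiber phantom shows a retardance kink: the host top
    layer's retardation is compensated by the orthogonal hidden bundle,
    with the minimum near the transition depth."""
    sub = df[df.phantom == kind].sort_values("depth_ls")
    d = sub.depth_ls.to_numpy(dtype=float)
    r = sub.incl_retardance_avg.to_numpy(dtype=float)
    i = int(np.nanargmin(r))
    if 0 < i < len(d) - 1:
        x0, x1, x2 = d[i - 1], d[i], d[i + 1]
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a > 0:
            return float(np.clip(-b / (2 * a), x0, x2))
    return float(d[i])


def _axial_distance(a: float, b: float) -> float:
    """Distance between two axial angles (180-degree period), degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def azimuth_flip_depth(
    df: pd.DataFrame,
    kind: str = "crossing_fiber",
    axis_top_deg: float = 0.0,
    axis_bottom_deg: float = 90.0,
) -> float:
    """Depth at which the inclusion-ROI azimuth flips from the inclusion
    axis to the host axis (balance point of the axial distances,
    linearly interpolated between grid points)."""
    sub = df[df.phantom == kind].sort_values("depth_ls")
    d = sub.depth_ls.to_numpy(dtype=float)
    az = sub.incl_azimuth_avg.to_numpy(dtype=float)
    # signed score: negative while reading the top (inclusion) axis
    score = np.array(
        [_axial_distance(a, axis_top_deg) - _axial_distance(a, axis_bottom_deg) for a in az]
    )
    sign = score < 0
    for i in range(len(d) - 1):
        if sign[i] and not sign[i + 1]:
            # linear root of the score between the bracketing depths
            s0, s1 = score[i], score[i + 1]
            return float(d[i] + (d[i + 1] - d[i]) * (-s0) / (s1 - s0))
    return float(d[0]) if not sign.any() else float(d[-1])


def depol_separation_onset(df: pd.DataFrame) -> float:
    """Largest depth at which the two phantoms' depolarization ROI means
    differ by more than twice the pooled standard error."""
    cf = df[df.phantom == "crossing_fiber"].sort_values("depth_ls")
    tu = df[df.phantom == "tumor"].sort_values("depth_ls")
    depths = np.intersect1d(cf.depth_ls.to_numpy(), tu.depth_ls.to_numpy())
    onset = float("nan")
    for depth in depths:
        a = cf[cf.depth_ls == depth].iloc[0]
        b = tu[tu.depth_ls == depth].iloc[0]
        se = np.hypot(a.incl_depolarization_se, b.incl_depolarization_se)
        if abs(a.incl_depolarization - b.incl_depolarization) > 2.0 * se:
            onset = float(depth)
    return onset


def retardance_equality_depth(df: pd.DataFrame) -> float:
    """First depth beyond which the two phantoms' inclusion-ROI
    retardances stay within twice the pooled standard error."""
    cf = df[df.phantom == "crossing_fiber"].sort_values("depth_ls")
    tu = df[df.phantom == "tumor"].sort_values("depth_ls")
    depths = np.intersect1d(cf.depth_ls.to_numpy(), tu.depth_ls.to_numpy())
    equal = []
    for depth in depths:
        a = cf[cf.depth_ls == depth].iloc[0]
        b = tu[tu.depth_ls == depth].iloc[0]
        se = np.hypot(a.incl_retardance_avg_se, b.incl_retardance_avg_se)
        equal.append(abs(a.incl_retardance_avg - b.incl_retardance_avg) < 2.0 * se)
    for i in range(len(depths)):
        if all(equal[i:]):
            return float(depths[i])
    return float("nan")


def classify_trends(
    df: pd.DataFrame,
    depths=(32.0, 20.0, 6.0, 1.0),
    axis_top_deg: float = 0.0,
    axis_bottom_deg: float = 90.0,
    zero_retardance_deg: float = 2.0,
    azimuth_window_deg: float = 15.0,
) -> pd.DataFrame:
    """Symbolic depth-trend table (columns ordered deep to shallow).

    Depolarization and retardance cells compare each depth with the next
    deeper grid point (the deepest available acts as baseline): constant
    within 2 SE gives C1/C2 (numbered by distinct constant level),
    otherwise an arrow for the direction of change toward the surface.
    Retardance compatible with zero (below ``zero_retardance_deg`` or
    2 SE) reads "0".  Azimuth reads "T" or "B" when the ROI circular mean
    falls within ``azimuth_window_deg`` of the inclusion or host axis.
    """
    out = []
    for kind in df.phantom.unique():
        sub = df[df.phantom == kind].sort_values("depth_ls", ascending=False)
        grid = sub.depth_ls.to_numpy(dtype=float)
        for param, col in (
            ("depolarization", "incl_depolarization"),
            ("retardance", "incl_retardance_avg"),
            ("azimuth", "incl_azimuth_avg"),
        ):
            row = {"phantom": kind, "parameter": param}
            if param == "azimuth":
                for depth in depths:
                    a = float(sub[sub.depth_ls == depth].iloc[0][col])
                    if _axial_distance(a, axis_top_deg) <= azimuth_window_deg:
                        sym = "T"
                    elif _axial_distance(a, axis_bottom_deg) <= azimuth_window_deg:
                        sym = "B"
                    else:
                        sym = "?"
                    row[f"{depth:g}ls"] = sym
                out.append(row)
                continue
            # scalar parameters: compare with the nearest deeper grid point
            level = 1  # constant-level id for C1/C2
            anchor = None  # mean anchoring the current constant level
            for depth in depths:
                here = sub[sub.depth_ls == depth].iloc[0]
                deeper = sub[sub.depth_ls > depth]
                mean, se = float(here[col]), float(here[f"{col}_se"])
                if param == "retardance" and mean < max(zero_retardance_deg, 2.0 * se):
                    row[f"{depth:g}ls"] = "0"
                    continue
                if deeper.empty:
                    ref_mean, ref_se = mean, se
                else:
                    ref = deeper.iloc[-1]  # nearest deeper depth
                    ref_mean, ref_se = float(ref[col]), float(ref[f"{col}_se"])
                if anchor is None:
                    anchor = ref_mean
                diff = mean - ref_mean
                pooled = max(np.hypot(se, ref_se), 1e-12)
                if abs(diff) < 2.0 * pooled:
                    if param == "depolarization":
                        if abs(mean - anchor) > 2.0 * pooled:
                            level += 1
                            anchor = mean
                        row[f"{depth:g}ls"] = f"{CONST}{level}"
                    else:
                        row[f"{depth:g}ls"] = CONST
                else:
                    row[f"{depth:g}ls"] = UP if diff > 0 else DOWN
                    level += 1
                    anchor = mean
            out.append(row)
    cols = ["phantom", "parameter"] + [f"{d:g}ls" for d in depths]
    return pd.DataFrame(out)[cols]


def save_outputs(outdir, name: str, cond: ConditionResult, extra: dict | None = None):
    """Write maps (float32 TIFF), ROI stats (CSV) and the run manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{name}_maps.tif", cond.maps.as_pages())
    stats = pd.DataFrame(
        [dict(cond.inclusion_stats, roi="inclusion"), dict(cond.host_stats, roi="host")]
    )
    stats.to_csv(outdir / f"{name}_roi.csv", index=False)
    man = cond.manifest()
    if extra:
        man.update(extra)
    (outdir / f"{name}_manifest.json").write_text(json.dumps(man, indent=2))
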