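"""Slab-with-inclusion optical phantoms mimicking brain white matter.

Two phantom families share one geometry: a 1 cm thick scattering,
birefringent host slab (optic axis in-plane at azimuth 90 degrees)
containing a subsurface box inclusion centered under the imaged field.

* ``crossing_fiber``: the inclusion shares every optical property of the
  host except the optic-axis azimuth, rotated to 0 degrees - hidden
  crossing fiber bundles.
* ``tumor``: the inclusion keeps the host scattering (or a lower,
  tumor-like scattering coefficient) but is optically isotropic - linear
  birefringence removed.

Coordinates: z grows downward from the illuminated surface, the slab is
``z in [0, thickness)``; all boxes are half-open ``[low, high)`` in every
axis.  Depths are specified in units of the host scattering mean free
path ``ls = 1 / mu_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "PhantomModel",
    "build_crossing_fiber_phantom",
    "build_tumor_phantom",
    "region_at",
]

# study conditions for the healthy-white-matter host
HOST_MUS = 400.0  # cm^-1
HOST_DELTA_N = -1e-4  # n_e - n_o
N_E = 1.33
N_PARTICLE = 1.59
HOST_ETA_DEG = 90.0
INCLUSION_ETA_DEG = 0.0
WAVELENGTH_NM = 633.0

SLAB_THICKNESS_CM = 1.0
LATERAL_HALF_CM = 1.0  # 2 cm x 2 cm slab, twice the imaged field
INCLUSION_HALF_CM = 0.2  # 4 mm x 4 mm footprint
INCLUSION_THICKNESS_CM = 0.2  # 2 mm


@dataclass
class Region:
    """Optical properties of one homogeneous region."""

    mus: float  # scattering coefficient, cm^-1
    mua: float = 0.0  # absorption coefficient, cm^-1 (0 in all studies)
    n_e: float = N_E
    delta_n: float = HOST_DELTA_N  # n_e - n_o; 0 => isotropic
    eta_deg: float = HOST_ETA_DEG  # optic-axis azimuth, degrees

    @property
    def n_o(self) -> float:
        return self.n_e - self.delta_n

    @property
    def birefringent(self) -> bool:
        return self.delta_n != 0.0

    def __post_init__(self) -> None:
        if self.mus <= 0:
            raise ValueError("scattering coefficient must be positive")
        if self.mua < 0:
            raise ValueError("absorption coefficient must be non-negative")


@dataclass
class PhantomModel:
    """Host slab plus an optional box inclusion."""

    host: Region
    inclusion: Region | None = None
    inclusion_kind: str = "none"  # crossing_fiber | tumor | none
    inclusion_depth_cm: float = 0.0  # top face depth
    inclusion_thickness_cm: float = INCLUSION_THICKNESS_CM
    inclusion_half_cm: float = INCLUSION_HALF_CM
    thickness_cm: float = SLAB_THICKNESS_CM
    lateral_half_cm: float = LATERAL_HALF_CM
    wavelength_nm: float = WAVELENGTH_NM
    n_ambient: float = 1.0
    n_particle: float = N_PARTICLE

    def __post_init__(self) -> None:
        if self.inclusion is not None:
            if self.inclusion_depth_cm < 0:
                raise ValueError("inclusion depth must be non-negative")
            if self.inclusion_depth_cm + self.inclusion_thickness_cm > self.thickness_cm:
                raise ValueError("inclusion protrudes below the slab")
            if self.inclusion_half_cm > self.lateral_half_cm:
                raise ValueError("inclusion footprint exceeds the lateral extent")

    @property
    def ls_cm(self) -> float:
        """Host scattering mean free path, cm."""
        return 1.0 / self.host.mus

    @property
    def n_medium(self) -> float:
        """Index used for Fresnel boundaries (anisotropy of order 1e-3 or
        less is ignored there)."""
        return self.host.n_e

    def to_config(self) -> dict:
        cfg = {
            "kind": self.inclusion_kind,
            "thickness_cm": self.thickness_cm,
            "lateral_half_cm": self.lateral_half_cm,
            "wavelength_nm": self.wavelength_nm,
            "host": vars(self.host).copy(),
        }
        if self.inclusion is not None:
            cfg["inclusion"] = vars(self.inclusion).copy()
            cfg["inclusion_depth_cm"] = self.inclusion_depth_cm
            cfg["inclusion_thickness_cm"] = self.inclusion_thickness_cm
            cfg["inclusion_half_cm"] = self.inclusion_half_cm
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "PhantomModel":
        host = Region(**cfg["host"])
        incl = Region(**cfg["inclusion"]) if "inclusion" in cfg else None
        kwargs = {
            k: cfg[k]
            for k in (
                "inclusion_depth_cm",
                "inclusion_thickness_cm",
                "inclusion_half_cm",
                "thickness_cm",
                "lateral_half_cm",
                "wavelength_nm",
            )
            if k in cfg
        }
        return cls(host=host, inclusion=incl, inclusion_kind=cfg.get("kind", "none"), **kwargs)


def _depth_cm(depth_ls: float, host_mus: float) -> float:
    return depth_ls / host_mus


def build_crossing_fiber_phantom(depth_ls: float, **overrides) -> PhantomModel:
    """Crossing-fiber phantom: inclusion optic axis orthogonal to the host.

    ``depth_ls`` is the depth of the inclusion's top face in mean free
    paths of the host (25 um at the default 400 cm^-1)."""
    host_kw = dict(mus=HOST_MUS, eta_deg=HOST_ETA_DEG)
    host_kw.update(overrides.pop("host", {}))
    incl_kw = overrides.pop("inclusion", {})
    host = Region(**host_kw)
    incl_defaults = dict(
        mus=host.mus, mua=host.mua, n_e=host.n_e,
        delta_n=host.delta_n, eta_deg=INCLUSION_ETA_DEG,
    )
    incl_defaults.update(incl_kw)
    incl = Region(**incl_defaults)
    return PhantomModel(
        host=host,
        inclusion=incl,
        inclusion_kind="crossing_fiber",
        inclusion_depth_cm=_depth_cm(depth_ls, host.mus),
        **overrides,
    )


def build_tumor_phantom(
    depth_ls: float, mus_tumor: float = HOST_MUS, **overrides
) -> PhantomModel:
    """Tumor phantom: isotropic inclusion (linear birefringence removed).

    By default the inclusion keeps the host scattering coefficient; lower
    tumor-like values (e.g. 120-280 cm^-1) may be passed."""
    host_kw = dict(mus=HOST_MUS, eta_deg=HOST_ETA_DEG)
    host_kw.update(overrides.pop("host", {}))
    incl_kw = overrides.pop("inclusion", {})
    host = Region(**host_kw)
    incl_defaults = dict(
        mus=mus_tumor, mua=host.mua, n_e=host.n_e,
        delta_n=0.0, eta_deg=0.0,
    )
    incl_defaults.update(incl_kw)
    incl = Region(**incl_defaults)
    return PhantomModel(
        host=host,
        inclusion=incl,
        inclusion_kind="tumor",
        inclusion_depth_cm=_depth_cm(depth_ls, host.mus),
        **overrides,
    )


def region_at(position, phantom: PhantomModel) -> str:
    """Region id ('host' or 'inclusion') at a point inside the slab."""
    x, y, z = (float(v) for v in position)
    if not (0.0 <= z < phantom.thickness_cm):
        raise ValueError("position outside the slab")
    if abs(x) >= phantom.lateral_half_cm or abs(y) >= phantom.lateral_half_cm:
        raise ValueError("position outside the slab")
    if phantom.inclusion is None:
        return "host"
    d0 = phantom.inclusion_depth_cm
    d1 = d0 + phantom.inclusion_thickness_cm
    h = phantom.inclusion_half_cm
    if d0 <= z < d1 and -h <= x < h and -h <= y < h:
        return "inclusion"
    return "host"
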