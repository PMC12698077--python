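"""Mie single-scattering matrices for polydisperse spherical scatterers.

The scattering medium is modeled as groups of dielectric spheres (no
absorption) suspended in an isotropic host.  For each group the exact Mie
series gives the amplitude functions ``S1`` and ``S2``; the four
independent elements of the single-sphere scattering matrix follow as

    s11 = (|S2|^2 + |S1|^2) / 2      s12 = (|S2|^2 - |S1|^2) / 2
    s33 = Re(S2 S1*)                 s34 = Im(S2 S1*)

in differential-cross-section units (cm^2/sr per particle).  Ensemble
tables average the groups with number-density weights, are tabulated on a
0..180 degree grid with a 0.02 degree step, and carry the cumulative
distribution of ``s11(theta) sin(theta)`` for inverse-transform sampling
of the scattering angle.

The series coefficients a_n, b_n use the logarithmic-derivative downward
recurrence with Riccati-Bessel functions built by upward recurrence, the
standard numerically stable scheme for size parameters far below the
series-truncation bound.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "ScattererGroup",
    "PhaseTable",
    "mie_ab",
    "mie_amplitudes",
    "mie_scattering_matrix",
    "mie_cross_sections",
    "gaussian_size_groups",
    "build_phase_table",
    "density_for_target_mus",
    "sample_scattering_angle",
]

NM_TO_CM = 1e-7
#: angular step of the tabulated phase matrices, degrees
TABLE_STEP_DEG = 0.02
N_TABLE = 9001  # 0..180 deg inclusive

_MAX_SIZE_PARAMETER = 1e4  # series-truncation sanity bound


@dataclass(frozen=True)
class ScattererGroup:
    """One monodisperse population of spherical scatterers."""

    diameter_nm: float
    n_particle: float
    number_density: float = 0.0  # cm^-3
    weight: float = 1.0  # dimensionless fraction of the ensemble

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        if self.number_density < 0:
            raise ValueError("number density must be non-negative")


def _n_max(x: float) -> int:
    return int(np.round(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_ab(size_parameter: float, relative_index: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie series coefficients ``a_n, b_n`` for a non-absorbing sphere.

    ``size_parameter`` is ``pi * d * n_medium / lambda``; ``relative_index``
    is ``n_particle / n_medium`` (real: no absorption).
    """
    x = float(size_parameter)
    m = float(relative_index)
    if not (0 < x < _MAX_SIZE_PARAMETER):
        raise ValueError(f"size parameter {x!r} outside convergent range")
    if m <= 0:
        raise ValueError("relative index must be positive")
    nmax = _n_max(x)
    mx = m * x

    # logarithmic derivative D_n(mx), downward recurrence
    nstart = nmax + 16
    d = np.zeros(nstart + 1)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    n = np.arange(1, nmax + 1)
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    psi_m1, psi0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi0 = -np.sin(x), np.cos(x)
    for k in range(1, nmax + 1):
        psi[k] = (2 * k - 1) / x * psi0 - psi_m1
        chi[k] = (2 * k - 1) / x * chi0 - chi_m1
        psi_m1, psi0 = psi0, psi[k]
        chi_m1, chi0 = chi0, chi[k]
    psi[0], chi[0] = np.sin(x), np.cos(x)
    xi = psi - 1j * chi
    # shifted arrays psi_{n-1}, xi_{n-1} for n = 1..nmax
    psi_prev = np.empty(nmax)
    chi_prev = np.empty(nmax)
    psi_prev[0], chi_prev[0] = np.sin(x), np.cos(x)
    if nmax > 1:
        psi_prev[1:] = psi[1:nmax]
        chi_prev[1:] = chi[1:nmax]
    xi_prev = psi_prev - 1j * chi_prev

    dn = d[1 : nmax + 1]
    psin = psi[1:]
    xin = xi[1:]
    da = dn / m + n / x
    db = dn * m + n / x
    a = (da * psin - psi_prev) / (da * xin - xi_prev)
    b = (db * psin - psi_prev) / (db * xin - xi_prev)
    return a, b


def mie_amplitudes(
    size_parameter: float, relative_index: float, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude functions ``S1(theta), S2(theta)`` (theta in radians)."""
    a, b = mie_ab(size_parameter, relative_index)
    nmax = a.size
    mu = np.cos(np.atleast_1d(np.asarray(theta, dtype=float)))
    s1 = np.zeros_like(mu, dtype=complex)
    s2 = np.zeros_like(mu, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        fac = (2 * n + 1) / (n * (n + 1))
        s1 += fac * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += fac * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_next = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_next
    return s1, s2


def mie_scattering_matrix(
    size_parameter: float,
    relative_index: float,
    theta: np.ndarray,
    wavenumber: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Elements ``(s11, s12, s33, s34)`` of the single-sphere matrix.

    Dimensionless (|S|^2 scale) unless ``wavenumber`` (cm^-1) is given, in
    which case the elements are divided by k^2 to carry cm^2/sr units.
    """
    s1, s2 = mie_amplitudes(size_parameter, relative_index, theta)
    a1, a2 = np.abs(s1) ** 2, np.abs(s2) ** 2
    cross = s2 * np.conj(s1)
    s11 = 0.5 * (a2 + a1)
    s12 = 0.5 * (a2 - a1)
    s33 = np.real(cross)
    s34 = np.imag(cross)
    if wavenumber is not None:
        scale = 1.0 / wavenumber**2
        s11, s12, s33, s34 = (e * scale for e in (s11, s12, s33, s34))
    return s11, s12, s33, s34


def mie_cross_sections(size_parameter: float, relative_index: float, wavelength_nm: float, n_medium: float) -> tuple[float, float]:
    """Scattering and extinction cross-sections in cm^2."""
    a, b = mie_ab(size_parameter, relative_index)
    n = np.arange(1, a.size + 1)
    k = 2.0 * np.pi * n_medium / (wavelength_nm * NM_TO_CM)  # cm^-1
    csca = (2.0 * np.pi / k**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    cext = (2.0 * np.pi / k**2) * np.sum((2 * n + 1) * np.real(a + b))
    return float(csca), float(cext)


def gaussian_size_groups(
    mean_diameter_nm: float = 50.0,
    sigma_fraction: float = 0.10,
    n_groups: int = 5,
    n_particle: float = 1.59,
) -> list[ScattererGroup]:
    """Equal-weight quantile discretization of a truncated Gaussian size law.

    The diameter distribution is Gaussian with standard deviation
    ``sigma_fraction * mean`` truncated at +-2 sigma; the groups sit at the
    midpoint quantiles of ``n_groups`` equal probability-mass bins.
    """
    sigma = sigma_fraction * mean_diameter_nm
    tn = truncnorm(-2.0, 2.0, loc=mean_diameter_nm, scale=sigma)
    q = (2.0 * np.arange(1, n_groups + 1) - 1.0) / (2.0 * n_groups)
    diameters = tn.ppf(q)
    w = 1.0 / n_groups
    return [ScattererGroup(float(d), n_particle, weight=w) for d in diameters]


@dataclass
class PhaseTable:
    """Tabulated ensemble scattering matrix and sampling tables.

    ``s11 .. s34`` are number-density-weighted averages over the groups in
    cm^2/sr per mean particle; ``cdf`` is the cumulative distribution of
    ``s11(theta) sin(theta)`` on the same grid; ``sigma_s`` is the mean
    per-particle scattering cross-section (cm^2).
    """

    angles_deg: np.ndarray
    s11: np.ndarray
    s12: np.ndarray
    s33: np.ndarray
    s34: np.ndarray
    cdf: np.ndarray
    sigma_s: float
    wavelength_nm: float
    n_medium: float
    inv_cdf_theta: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inv_cdf_theta is None:
            u = np.linspace(0.0, 1.0, 1 << 15)
            theta = np.radians(self.angles_deg)
            self.inv_cdf_theta = np.interp(u, self.cdf, theta)

    @property
    def anisotropy(self) -> float:
        """Scattering anisotropy g = <cos theta>."""
        th = np.radians(self.angles_deg)
        w = self.s11 * np.sin(th)
        return float(np.trapezoid(w * np.cos(th), th) / np.trapezoid(w, th))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "angle_deg": self.angles_deg,
                "s11": self.s11,
                "s12": self.s12,
                "s33": self.s33,
                "s34": self.s34,
                "cdf": self.cdf,
            }
        ).to_csv(path, index=False)


def _group_hash(groups: list[ScattererGroup]) -> str:
    h = hashlib.sha256()
    for g in groups:
        h.update(f"{g.diameter_nm:.9e}|{g.n_particle:.9e}|{g.number_density:.9e}|{g.weight:.9e};".encode())
    return h.hexdigest()[:16]


def build_phase_table(
    groups: list[ScattererGroup],
    wavelength_nm: float,
    n_medium: float,
    cache_dir=None,
) -> PhaseTable:
    """Ensemble phase table over ``groups`` at one wavelength.

    Weights are the group number densities (falling back to the ``weight``
    fractions when no densities are set).  With ``cache_dir`` set, tables
    are memoized to ``.npz`` keyed by (wavelength, medium index, groups).
    """
    if not groups:
        raise ValueError("at least one scatterer group is required")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")

    cache_path = None
    if cache_dir is not None:
        from pathlib import Path

        key = f"{wavelength_nm:.6f}_{n_medium:.6f}_{_group_hash(groups)}"
        cache_path = Path(cache_dir) / f"phase_{key}.npz"
        if cache_path.exists():
            z = np.load(cache_path)
            return PhaseTable(
                z["angles_deg"], z["s11"], z["s12"], z["s33"], z["s34"],
                z["cdf"], float(z["sigma_s"]), wavelength_nm, n_medium,
            )

    angles_deg = np.linspace(0.0, 180.0, N_TABLE)
    theta = np.radians(angles_deg)
    k = 2.0 * np.pi * n_medium / (wavelength_nm * NM_TO_CM)  # cm^-1

    dens = np.array([g.number_density for g in groups])
    if dens.sum() <= 0:
        dens = np.array([g.weight for g in groups])
    w = dens / dens.sum()

    s11 = np.zeros(N_TABLE)
    s12 = np.zeros(N_TABLE)
    s33 = np.zeros(N_TABLE)
    s34 = np.zeros(N_TABLE)
    sigma_s = 0.0
    for g, wi in zip(groups, w):
        x = np.pi * g.diameter_nm * n_medium / wavelength_nm
        m = g.n_particle / n_medium
        e11, e12, e33, e34 = mie_scattering_matrix(x, m, theta, wavenumber=k)
        s11 += wi * e11
        s12 += wi * e12
        s33 += wi * e33
        s34 += wi * e34
        csca, _ = mie_cross_sections(x, m, wavelength_nm, n_medium)
        sigma_s += wi * csca

    pdf = s11 * np.sin(theta)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(theta))))
    cdf /= cdf[-1]
    table = PhaseTable(angles_deg, s11, s12, s33, s34, cdf, sigma_s, wavelength_nm, n_medium)

    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            cache_path,
            angles_deg=angles_deg, s11=s11, s12=s12, s33=s33, s34=s34,
            cdf=cdf, sigma_s=sigma_s,
        )
    return table


def density_for_target_mus(
    groups: list[ScattererGroup],
    wavelength_nm: float,
    n_medium: float,
    target_mus: float,
) -> list[ScattererGroup]:
    """Scale group number densities so ``sum_i N_i sigma_s,i = target_mus``.

    Relative weights are preserved: ``N_i = weight_i * C`` with a single
    constant ``C`` fixed by the target scattering coefficient (cm^-1).
    """
    if target_mus <= 0:
        raise ValueError("target scattering coefficient must be positive")
    sigmas = []
    for g in groups:
        x = np.pi * g.diameter_nm * n_medium / wavelength_nm
        csca, _ = mie_cross_sections(x, g.n_particle / n_medium, wavelength_nm, n_medium)
        sigmas.append(csca)
    sigmas = np.array(sigmas)
    w = np.array([g.weight for g in groups])
    denom = float(np.sum(w * sigmas))
    if denom <= 0:
        raise ValueError("total scattering cross-section is zero")
    c = target_mus / denom
    return [replace(g, number_density=float(gw * c)) for g, gw in zip(groups, w)]


def sample_scattering_angle(table: PhaseTable, u: float) -> float:
    """Inverse-transform sample of the scattering angle (radians) from the
    ``s11 sin(theta)`` density, linear interpolation between nodes."""
    return float(np.interp(u, table.cdf, np.radians(table.angles_deg)))
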