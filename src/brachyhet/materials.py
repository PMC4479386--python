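"""Photon interaction data and sampling for water and cortical bone.

Each :class:`Material` carries energy-indexed tables of the total mass
attenuation coefficient mu/rho, the mass energy-absorption coefficient
mu_en/rho, and the fraction of interactions that are photoelectric.  The
tables ship with the package as plain-text files transcribed from the
NIST / Hubbell-Seltzer compilations; see the file headers for provenance.

Coefficient lookups interpolate log-log, which is exact for power-law
segments and standard practice for photon cross sections.

The module also implements Klein-Nishina Compton scattering: the
differential and total free-electron cross sections in closed form, and a
rejection sampler for the scattered photon energy/angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Material",
    "ScatterSample",
    "load_material",
    "lookup_coefficient",
    "sample_compton",
    "select_interaction",
    "kn_total_cross_section",
    "kn_differential_energy",
    "kn_mean_scatter_fraction",
    "kerma_coefficient",
]

ELECTRON_REST_MEV = 0.51099895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23


class CoefficientRangeError(ValueError):
    """Requested energy lies outside a material's tabulated range."""


@dataclass(frozen=True)
class Material:
    """A homogeneous medium with energy-indexed interaction coefficients.

    Parameters
    ----------
    name
        Identifier, e.g. ``"water"``.
    density
        Mass density in g/cm^3.
    energy_grid
        Strictly increasing photon energies in MeV.
    mu_over_rho_total
        Total mass attenuation coefficient, cm^2/g, per grid point.
    mu_en_over_rho
        Mass energy-absorption coefficient, cm^2/g, per grid point.
    photoelectric_fraction
        Fraction of interactions that are photoelectric, per grid point.
    provenance
        Free-text description of where the numbers come from.
    """

    name: str
    density: float
    energy_grid: np.ndarray
    mu_over_rho_total: np.ndarray
    mu_en_over_rho: np.ndarray
    photoelectric_fraction: np.ndarray
    provenance: str = ""
    z_over_a: float = field(default=0.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, float)
        if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("energy_grid must be 1-D and strictly increasing")
        if not (e[0] <= 0.01 and e[-1] >= 0.7):
            raise ValueError("energy_grid must cover [0.01, 0.7] MeV")
        for label in ("mu_over_rho_total", "mu_en_over_rho"):
            v = np.asarray(getattr(self, label), float)
            if v.shape != e.shape or np.any(v <= 0):
                raise ValueError(f"{label} must be positive, same shape as grid")
        if np.any(self.mu_en_over_rho > self.mu_over_rho_total):
            raise ValueError("mu_en/rho must not exceed mu/rho at any node")
        f = np.asarray(self.photoelectric_fraction, float)
        if f.shape != e.shape or np.any((f < 0) | (f > 1)):
            raise ValueError("photoelectric_fraction must lie in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ScatterSample:
    """Outcome of one Compton scatter: scattered energy (MeV) and cos(theta)."""

    scattered_energy: float
    cos_theta: float


def load_material(name: str) -> Material:
    """Load one of the packaged materials (``water`` or ``cortical_bone``)."""
    ref = resources.files("brachyhet.data").joinpath(f"{name}.txt")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"no packaged material named {name!r}") from exc
    meta: dict[str, str] = {}
    rows = []
    prov_lines = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body and not body.startswith("provenance"):
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            else:
                prov_lines.append(body)
            continue
        rows.append([float(x) for x in line.split()])
    arr = np.array(rows)
    return Material(
        name=name,
        density=float(meta["density_g_cm3"]),
        energy_grid=arr[:, 0],
        mu_over_rho_total=arr[:, 1],
        mu_en_over_rho=arr[:, 2],
        photoelectric_fraction=arr[:, 3],
        provenance=" ".join(prov_lines),
        z_over_a=float(meta.get("Z_over_A", 0.0)),
    )


def lookup_coefficient(material: Material, energy, kind: str = "total"):
    """Log-log interpolated mass coefficient (cm^2/g) at ``energy`` (MeV).

    ``kind`` selects ``"total"`` (mu/rho) or ``"energy_absorption"``
    (mu_en/rho).  Exact at grid nodes; raises outside the tabulated range.
    """
    if kind == "total":
        table = material.mu_over_rho_total
    elif kind == "energy_absorption":
        table = material.mu_en_over_rho
    else:
        raise ValueError(f"unknown coefficient kind {kind!r}")
    e = np.asarray(energy, float)
    grid = material.energy_grid
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        bad = e[(e < grid[0]) | (e > grid[-1])]
        raise CoefficientRangeError(
            f"energy {np.atleast_1d(bad)[0]:g} MeV outside [{grid[0]:g}, "
            f"{grid[-1]:g}] MeV table range for material {material.name!r}"
        )
    out = np.exp(np.interp(np.log(e), np.log(grid), np.log(table)))
    return float(out) if np.isscalar(energy) else out


def _photoelectric_fraction_at(material: Material, energy) -> np.ndarray:
    e = np.asarray(energy, float)
    grid = material.energy_grid
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise CoefficientRangeError(
            f"energy outside table range for material {material.name!r}"
        )
    # interpolate the fraction linearly in log(E); it is not power-law-like
    return np.interp(np.log(e), np.log(grid), material.photoelectric_fraction)


# ---------------------------------------------------------------------------
# Klein-Nishina scattering
# ---------------------------------------------------------------------------

def kn_total_cross_section(energy) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2) at ``energy`` MeV."""
    a = np.asarray(energy, float) / ELECTRON_REST_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (t1 + t2 - t3)


def kn_differential_energy(incident_energy: float, eps) -> np.ndarray:
    """Unnormalised Klein-Nishina density d(sigma)/d(eps).

    ``eps`` is the scattered-to-incident energy ratio E'/E, valid on
    [1/(1+2a), 1] with a = E/m_e c^2.  Proportional to
    (1/eps + eps) * (1 - eps * sin^2(theta) / (1 + eps^2)).
    """
    a = incident_energy / ELECTRON_REST_MEV
    eps = np.asarray(eps, float)
    one_minus_cos = (1.0 - eps) / (a * eps)
    sin2 = one_minus_cos * (2.0 - one_minus_cos)
    return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps * eps))


def kn_mean_scatter_fraction(energy) -> np.ndarray:
    """Mean E'/E over the Klein-Nishina density, by adaptive quadrature."""
    from scipy.integrate import quad

    def one(e: float) -> float:
        a = e / ELECTRON_REST_MEV
        lo = 1.0 / (1.0 + 2.0 * a)
        num = quad(lambda x: x * kn_differential_energy(e, x), lo, 1.0)[0]
        den = quad(lambda x: kn_differential_energy(e, x), lo, 1.0)[0]
        return num / den

    e = np.asarray(energy, float)
    if e.ndim == 0:
        return one(float(e))
    return np.array([one(v) for v in e])


def sample_compton(incident_energy: float, rng: np.random.Generator,
                   size: int | None = None):
    """Draw Compton scatters from the Klein-Nishina cross section.

    Uses the standard two-branch rejection scheme on eps = E'/E (candidate
    densities proportional to 1/eps and eps).  Returns a single
    :class:`ScatterSample` when ``size`` is None, else arrays
    ``(scattered_energy, cos_theta)`` of length ``size``.
    """
    if incident_energy <= 0:
        raise ValueError("incident energy must be positive")
    n = 1 if size is None else int(size)
    a = incident_energy / ELECTRON_REST_MEV
    eps_min = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    out_eps = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        u1, u2, u3 = rng.random(m), rng.random(m), rng.random(m)
        eps = np.where(
            u1 < a1 / (a1 + a2),
            eps_min * np.exp(a1 * u2),
            np.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * u2),
        )
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        accept = u3 <= 1.0 - eps * sin2 / (1.0 + eps * eps)
        out_eps[pending[accept]] = eps[accept]
        pending = pending[~accept]
    cos_theta = 1.0 - (1.0 - out_eps) / (a * out_eps)
    energy = incident_energy * out_eps
    if size is None:
        return ScatterSample(float(energy[0]), float(cos_theta[0]))
    return energy, cos_theta


def select_interaction(material: Material, energy: float,
                       rng: np.random.Generator) -> str:
    """Choose ``"photoelectric"`` or ``"compton"`` at a collision."""
    f = float(_photoelectric_fraction_at(material, energy))
    return "photoelectric" if rng.random() < f else "compton"


# ---------------------------------------------------------------------------
# Model-consistent collision kerma coefficient
# ---------------------------------------------------------------------------

def kerma_coefficient(material: Material, energy) -> np.ndarray:
    """Collision-kerma coefficient of the transport model, cm^2/g.

    Expected energy transferred to electrons per unit photon path, per
    unit energy: mu/rho * [f_pe + (1 - f_pe) * (1 - <E'/E>_KN)].  This is
    the response the track-length and binned-fluence dose estimators fold
    with, and it is exactly consistent (in expectation) with the energy
    the analog estimator deposits at collisions, so the three estimators
    score the same physical quantity.
    """
    mu = lookup_coefficient(material, energy, "total")
    f = _photoelectric_fraction_at(material, energy)
    mean_eps = _mean_eps_interp(energy)
    out = mu * (f + (1.0 - f) * (1.0 - mean_eps))
    return out


_MEAN_EPS_GRID: tuple[np.ndarray, np.ndarray] | None = None


def _mean_eps_interp(energy) -> np.ndarray:
    """<E'/E>_KN on a cached dense log grid (0.005-1 MeV), log-interpolated."""
    global _MEAN_EPS_GRID
    if _MEAN_EPS_GRID is None:
        grid = np.geomspace(0.005, 1.0, 160)
        _MEAN_EPS_GRID = (np.log(grid), kn_mean_scatter_fraction(grid))
    loggrid, vals = _MEAN_EPS_GRID
    return np.interp(np.log(np.asarray(energy, float)), loggrid, vals)
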