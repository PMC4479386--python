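"""Monte Carlo dose simulation with three per-shell estimators.

:func:`run_simulation` transports photon histories through the phantom and
scores dose in every 0.1 cm tally shell three ways, mirroring the tally
types commonly used for brachytherapy dosimetry:

* track-length kerma ("F6-analog"): path length x E x kerma coefficient,
  evaluated continuously in energy;
* analog energy deposition ("*F8-analog"): energy handed to electrons at
  collisions, divided by shell mass;
* binned-fluence fold ("*F4-analog"): track-length fluence accumulated in
  energy bins (default 10 keV), folded with the kerma response at bin
  midpoints.  Its discrepancy against the other two is the binning
  discretisation error, growing where the local spectrum is soft.

All estimators fold the same model-consistent collision-kerma coefficient
(see :func:`brachyhet.materials.kerma_coefficient`), so they agree in
expectation and differ only through variance and binning.

Doses are MeV/g per source photon.  Histories are processed in a fixed
order from a single seeded generator, in ``n_batches`` consecutive batches
used for the uncertainty estimate; identical (config, n_histories, seed)
reproduce bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .materials import Material, kerma_coefficient, load_material, lookup_coefficient
from .phantom import PhantomConfig, build_shell_partition

__all__ = [
    "run_simulation",
    "average_energy",
    "estimate_uncertainty",
    "EnergySpectrum",
    "ShellDoseProfile",
    "ENERGY_CUTOFF_MEV",
]

ENERGY_CUTOFF_MEV = 0.01
DEFAULT_EBIN_WIDTH_MEV = 0.010
DEFAULT_N_BATCHES = 20
_DENSE_GRID_SIZE = 256


@dataclass(frozen=True)
class EnergySpectrum:
    """Track-length-weighted photon spectrum in one tally shell."""

    bin_edges: np.ndarray
    fractions: np.ndarray

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def average_energy(spectrum: EnergySpectrum) -> float:
    """Mean photon energy E_avg = sum_i f_i E_i over spectrum bins (MeV)."""
    f = np.asarray(spectrum.fractions, float)
    total = f.sum()
    if total <= 0:
        raise ValueError("spectrum is empty: no photons crossed this shell")
    if abs(total - 1.0) > 1e-9:
        raise ValueError("spectrum fractions are not normalised")
    return float(np.dot(f, spectrum.bin_midpoints))


def estimate_uncertainty(batch_doses) -> float:
    """Relative standard error of the mean from per-batch dose estimates."""
    x = np.asarray(batch_doses, float)
    if x.size < 2:
        raise ValueError("need at least 2 batches for an uncertainty estimate")
    m = x.mean()
    se = x.std(ddof=1) / np.sqrt(x.size)
    if se == 0.0:
        return 0.0
    if m == 0.0:
        return np.inf
    return float(se / abs(m))


@dataclass(frozen=True)
class ShellDoseProfile:
    """Per-tally-shell dose estimates from one simulation.

    ``shell_inner_radii`` are the inner radii of the tally shells (cm);
    dose arrays are MeV/g per source photon.  ``batch_*`` arrays have
    shape (n_batches, n_shells) and hold per-batch per-history estimates,
    from which the relative standard errors derive.
    """

    config: PhantomConfig
    n_histories: int
    seed: int
    shell_inner_radii: np.ndarray
    dose_tracklength: np.ndarray
    dose_deposition: np.ndarray
    dose_fluence_folded: np.ndarray
    rse_tracklength: np.ndarray
    rse_deposition: np.ndarray
    rse_fluence_folded: np.ndarray
    spectra: list[EnergySpectrum]
    energy_escaped: float
    energy_deposited: float
    batch_tracklength: np.ndarray = field(repr=False, default=None)
    batch_deposition: np.ndarray = field(repr=False, default=None)
    batch_fluence_folded: np.ndarray = field(repr=False, default=None)

    def shell_at(self, radius: float) -> int:
        """Index of the tally shell whose half-open extent contains radius."""
        h = self.config.tally_shell_thickness
        i = int(round((radius - self.shell_inner_radii[0]) / h - 0.5))
        i = min(max(i, 0), len(self.shell_inner_radii) - 1)
        return i

    def energy_balance_error(self) -> float:
        """Relative error of deposited + escaped vs emitted energy."""
        emitted = self.n_histories * self.config.source_energy
        return abs(self.energy_deposited + self.energy_escaped - emitted) / emitted


def _dense_tables(materials: list[Material]):
    """Physics lookups resampled on one dense log-energy grid for the kernel."""
    lo, hi = 0.01, 0.7
    grid = np.geomspace(lo, hi, _DENSE_GRID_SIZE)
    loge = np.log(grid)
    n_mat = len(materials)
    log_sigma = np.empty((n_mat, grid.size))
    fpe = np.empty((n_mat, grid.size))
    log_kresp = np.empty((n_mat, grid.size))
    for i, m in enumerate(materials):
        mu = lookup_coefficient(m, grid, "total")
        log_sigma[i] = np.log(mu * m.density)
        fpe[i] = np.interp(loge, np.log(m.energy_grid), m.photoelectric_fraction)
        log_kresp[i] = np.log(grid * kerma_coefficient(m, grid))
    return loge[0], loge[1] - loge[0], log_sigma, fpe, log_kresp, grid


def run_simulation(
    config: PhantomConfig,
    n_histories: int,
    seed: int,
    *,
    n_batches: int = DEFAULT_N_BATCHES,
    ebin_width: float = DEFAULT_EBIN_WIDTH_MEV,
) -> ShellDoseProfile:
    """Simulate ``n_histories`` photon histories and score shell doses.

    The source is an isotropic point emitter of monoenergetic photons
    (default 0.662 MeV) at the phantom center.  See the module docstring
    for the estimator definitions.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if not (0 <= seed < 2**31):
        raise ValueError("seed must be a non-negative 31-bit integer")
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    partition = build_shell_partition(config)
    mats = sorted({s.material for s in partition})
    mat_objs = [load_material(m) for m in mats]
    mat_index = {m: i for i, m in enumerate(mats)}
    mat_idx = np.array([mat_index[s.material] for s in partition], dtype=np.int64)
    bounds = np.array([s.inner_radius for s in partition]
                      + [partition[-1].outer_radius])
    vol = 4.0 / 3.0 * np.pi * (bounds[1:] ** 3 - bounds[:-1] ** 3)
    density = np.array([mat_objs[i].density for i in mat_idx])
    mass = vol * density

    loge0, dloge, log_sigma, fpe_tab, log_kresp, _ = _dense_tables(mat_objs)

    n_ebins = int(np.ceil((config.source_energy - ENERGY_CUTOFF_MEV)
                          / ebin_width))
    ebin_edges = ENERGY_CUTOFF_MEV + ebin_width * np.arange(n_ebins + 1)

    dose_tl_b, dep_e_b, flu_b, escaped, deposited = _kernel.run_histories(
        int(n_histories), int(seed), float(config.source_energy),
        ENERGY_CUTOFF_MEV, bounds, mat_idx, vol,
        loge0, dloge, log_sigma, fpe_tab, log_kresp,
        int(n_batches), ENERGY_CUTOFF_MEV, float(ebin_width), n_ebins,
    )

    # per-batch per-history estimates (equal batch sizes up to rounding)
    batch_sizes = np.bincount(
        np.arange(n_histories) * n_batches // n_histories,
        minlength=n_batches).astype(float)
    batch_tl = dose_tl_b / batch_sizes[:, None]
    batch_dep = dep_e_b / mass[None, :] / batch_sizes[:, None]

    # fold binned fluence with the kerma response at bin midpoints
    mids = 0.5 * (ebin_edges[:-1] + ebin_edges[1:])
    resp_mid = np.empty((len(mat_objs), n_ebins))
    for i, m in enumerate(mat_objs):
        resp_mid[i] = mids * kerma_coefficient(m, np.clip(mids, 0.01, 0.7))
    batch_f4 = np.einsum("bke,ke->bk", flu_b, resp_mid[mat_idx]) \
        / vol[None, :] / batch_sizes[:, None]

    lo_idx = int(round(config.tally_range[0] / config.tally_shell_thickness))
    hi_idx = int(round(config.tally_range[1] / config.tally_shell_thickness))
    sl = slice(lo_idx, hi_idx)

    def _finish(batch_vals):
        mean = batch_vals.mean(axis=0)
        se = batch_vals.std(axis=0, ddof=1) / np.sqrt(n_batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            rse = np.where(mean > 0, se / mean, 0.0)
        return mean, rse

    d_tl, r_tl = _finish(batch_tl[:, sl])
    d_dep, r_dep = _finish(batch_dep[:, sl])
    d_f4, r_f4 = _finish(batch_f4[:, sl])

    flu_total = flu_b.sum(axis=0)[sl]
    spectra = []
    for row in flu_total:
        tot = row.sum()
        fr = row / tot if tot > 0 else row
        spectra.append(EnergySpectrum(bin_edges=ebin_edges, fractions=fr))

    return ShellDoseProfile(
        config=config,
        n_histories=n_histories,
        seed=seed,
        shell_inner_radii=bounds[sl],
        dose_tracklength=d_tl,
        dose_deposition=d_dep,
        dose_fluence_folded=d_f4,
        rse_tracklength=r_tl,
        rse_deposition=r_dep,
        rse_fluence_folded=r_f4,
        spectra=spectra,
        energy_escaped=float(escaped),
        energy_deposited=float(deposited),
        batch_tracklength=batch_tl[:, sl],
        batch_deposition=batch_dep[:, sl],
        batch_fluence_folded=batch_f4[:, sl],
    )
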