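"""Compiled analog photon-transport kernel.

Single-threaded, seeded, history-ordered transport of monoenergetic photons
from an isotropic point source at the center of a concentric-shell phantom,
under the kerma approximation (energy transferred to electrons is deposited
at the collision site; no electron transport, no coherent scattering, no
variance reduction).

Spherical symmetry lets a photon state be just (radius r, radial direction
cosine mu, energy E).  Flights walk the shell lattice boundary by boundary,
inverting a sampled optical depth piecewise; every traversed segment is
scored into the track-length tallies of the shell it lies in.

All physics lookups use a dense common log-energy grid prepared by the
caller: sigma (total interaction coefficient, 1/cm), the photoelectric
fraction, and kerma_response = E * kerma_coefficient(E) (MeV cm^2/g).
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST_MEV = 0.51099895


@njit(cache=True, fastmath=False)
def _sample_compton_eps(alpha: float) -> float:
    """Rejection-sample eps = E'/E from the Klein-Nishina density."""
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = eps_min * np.exp(a1 * np.random.random())
        else:
            eps = np.sqrt(eps_min * eps_min
                          + (1.0 - eps_min * eps_min) * np.random.random())
        t = (1.0 - eps) / (alpha * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps


@njit(cache=True, fastmath=False)
def _interp_log(logE: float, loge0: float, dloge: float, table: np.ndarray,
                mat: int) -> float:
    """Linear interpolation of table[mat, :] on the dense log-energy grid."""
    x = (logE - loge0) / dloge
    if x <= 0.0:
        return table[mat, 0]
    n = table.shape[1]
    if x >= n - 1:
        return table[mat, n - 1]
    i = int(x)
    f = x - i
    return table[mat, i] * (1.0 - f) + table[mat, i + 1] * f


@njit(cache=True, fastmath=False)
def run_histories(
    n_histories: int,
    seed: int,
    source_energy: float,
    cutoff: float,
    boundaries: np.ndarray,      # (n_shells+1,) radii, boundaries[0] == 0
    mat_idx: np.ndarray,         # (n_shells,) material index per shell
    shell_volume: np.ndarray,    # (n_shells,) cm^3
    loge0: float,
    dloge: float,
    log_sigma: np.ndarray,       # (n_mat, n_grid) log of total Sigma, 1/cm
    fpe_tab: np.ndarray,         # (n_mat, n_grid) photoelectric fraction
    log_kresp: np.ndarray,       # (n_mat, n_grid) log of E*kappa, MeV cm^2/g
    n_batches: int,
    ebin_lo: float,
    ebin_width: float,
    n_ebins: int,
):
    """Transport ``n_histories`` photons; return batched shell tallies.

    Returns
    -------
    dose_tl : (n_batches, n_shells) track-length kerma, MeV/g summed per batch
    dep_e   : (n_batches, n_shells) energy deposited, MeV summed per batch
    fluence : (n_batches, n_shells, n_ebins) track length, cm summed per batch
    escaped : total energy escaping the phantom, MeV
    deposited : total energy deposited anywhere, MeV
    """
    np.random.seed(seed)
    n_shells = mat_idx.shape[0]
    n_mat = log_sigma.shape[0]
    dose_tl = np.zeros((n_batches, n_shells))
    dep_e = np.zeros((n_batches, n_shells))
    fluence = np.zeros((n_batches, n_shells, n_ebins))
    escaped = 0.0
    deposited = 0.0
    # physics at the current photon energy, refreshed when E changes
    sig_at_E = np.empty(n_mat)
    kresp_at_E = np.empty(n_mat)

    for h in range(n_histories):
        batch = h * n_batches // n_histories
        E = source_energy
        logE = np.log(E)
        for m in range(n_mat):
            sig_at_E[m] = np.exp(_interp_log(logE, loge0, dloge, log_sigma, m))
            kresp_at_E[m] = np.exp(_interp_log(logE, loge0, dloge, log_kresp, m))
        ib = int((E - ebin_lo) / ebin_width)
        if ib >= n_ebins:
            ib = n_ebins - 1
        r = 0.0
        mu = 1.0
        k = 0
        alive = True
        steps = 0
        while alive:
            tau = -np.log(np.random.random())
            # one flight: walk lattice boundaries until the optical depth
            # is used up or the photon leaves the phantom
            while True:
                steps += 1
                if steps > 1000000:
                    # pathological trajectory guard; deposit and stop
                    dep_e[batch, k] += E
                    deposited += E
                    alive = False
                    break
                rmu = r * mu
                p2 = r * r - rmu * rmu
                a = boundaries[k]
                b = boundaries[k + 1]
                inward = mu < 0.0 and a > 0.0 and p2 < a * a
                if inward:
                    s = -rmu - np.sqrt(a * a - p2)
                    rnext = a
                    knext = k - 1
                else:
                    d2 = b * b - p2
                    if d2 < 0.0:
                        d2 = 0.0
                    s = -rmu + np.sqrt(d2)
                    rnext = b
                    knext = k + 1
                if s < 0.0:
                    s = 0.0
                sigma = sig_at_E[mat_idx[k]]
                if sigma * s >= tau:
                    # collision inside this segment
                    sc = tau / sigma
                    dose_tl[batch, k] += sc * kresp_at_E[mat_idx[k]] \
                        / shell_volume[k]
                    fluence[batch, k, ib] += sc
                    rnew = np.sqrt(r * r + sc * sc + 2.0 * r * sc * mu)
                    if rnew > 0.0:
                        mu = (rmu + sc) / rnew
                        if mu > 1.0:
                            mu = 1.0
                        elif mu < -1.0:
                            mu = -1.0
                    r = rnew
                    fpe = _interp_log(logE, loge0, dloge, fpe_tab, mat_idx[k])
                    if np.random.random() < fpe:
                        dep_e[batch, k] += E
                        deposited += E
                        alive = False
                    else:
                        eps = _sample_compton_eps(E / ELECTRON_REST_MEV)
                        edep = E * (1.0 - eps)
                        dep_e[batch, k] += edep
                        deposited += edep
                        E = E * eps
                        if E <= cutoff:
                            dep_e[batch, k] += E
                            deposited += E
                            alive = False
                        else:
                            logE = np.log(E)
                            for m in range(n_mat):
                                sig_at_E[m] = np.exp(_interp_log(
                                    logE, loge0, dloge, log_sigma, m))
                                kresp_at_E[m] = np.exp(_interp_log(
                                    logE, loge0, dloge, log_kresp, m))
                            ib = int((E - ebin_lo) / ebin_width)
                            if ib < 0:
                                ib = 0
                            elif ib >= n_ebins:
                                ib = n_ebins - 1
                            # Compton kinematics: 1 - cos = m(1/E' - 1/E_in)
                            e_in = E / eps
                            cos_t = 1.0 + ELECTRON_REST_MEV / e_in \
                                - ELECTRON_REST_MEV / E
                            if cos_t > 1.0:
                                cos_t = 1.0
                            elif cos_t < -1.0:
                                cos_t = -1.0
                            sin_t = np.sqrt(1.0 - cos_t * cos_t)
                            phi = 2.0 * np.pi * np.random.random()
                            smu = np.sqrt(max(1.0 - mu * mu, 0.0))
                            mu = mu * cos_t + smu * sin_t * np.cos(phi)
                            if mu > 1.0:
                                mu = 1.0
                            elif mu < -1.0:
                                mu = -1.0
                    break
                # full segment traversed
                dose_tl[batch, k] += s * kresp_at_E[mat_idx[k]] \
                    / shell_volume[k]
                fluence[batch, k, ib] += s
                tau -= sigma * s
                if knext >= n_shells:
                    escaped += E
                    alive = False
                    break
                if rnext > 0.0:
                    mu = (rmu + s) / rnext
                    if mu > 1.0:
                        mu = 1.0
                    elif mu < -1.0:
                        mu = -1.0
                r = rnext
                k = knext
    return dose_tl, dep_e, fluence, escaped, deposited
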