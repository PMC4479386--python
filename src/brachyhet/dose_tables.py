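"""Percentage-dose-difference tables over a (distance, thickness) grid.

The central quantity is dD% = 100 (D_het - D_hom) / D_hom, evaluated
inside the bone layer: both doses are mass-averaged over the tally cells
spanning [d, d + t), with D_het from the heterogeneous phantom and D_hom
from the homogeneous water phantom at the same radii.  The track-length
kerma estimator supplies both doses.

Tables serialise to a single long-format CSV with ``# key=value`` metadata
header lines, columns ``d,t,delta_pct,sigma_pct``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import LATTICE_CM, PhantomConfig
from .transport import ShellDoseProfile, run_simulation

__all__ = [
    "DoseDifferenceTable",
    "percent_difference",
    "layer_average_dose",
    "build_table",
    "read_table",
    "write_table",
    "TableParseError",
    "DEFAULT_DISTANCES",
    "DEFAULT_THICKNESSES",
]

# the production grid: distances 0.1-10 cm step 0.5, thicknesses
# 0.2-1.8 cm step 0.1 (extensible to 2.0)
DEFAULT_DISTANCES = np.round(np.arange(0.1, 10.01, 0.5), 10)
DEFAULT_THICKNESSES = np.round(np.arange(0.2, 1.81, 0.1), 10)

REQUIRED_METADATA = ("source_energy_MeV", "n_histories", "seed", "bone_material")


class TableParseError(ValueError):
    """A dose-difference table file violates the documented format."""


def percent_difference(dose_het: float, dose_hom: float) -> float:
    """dD% = 100 (dose_het - dose_hom) / dose_hom."""
    if dose_hom <= 0:
        raise ValueError("homogeneous reference dose must be positive")
    return 100.0 * (dose_het - dose_hom) / dose_hom


@dataclass(frozen=True)
class DoseDifferenceTable:
    """dD%(d, t) on a rectangular grid, with 1-sigma uncertainties.

    ``distances`` (bone inner radius, cm) and ``thicknesses`` (cm) are
    strictly increasing axes; ``values`` and ``uncertainties`` are percent,
    indexed [distance, thickness].
    """

    distances: np.ndarray
    thicknesses: np.ndarray
    values: np.ndarray
    uncertainties: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, float)
        t = np.asarray(self.thicknesses, float)
        v = np.asarray(self.values, float)
        u = np.asarray(self.uncertainties, float)
        if d.ndim != 1 or t.ndim != 1:
            raise ValueError("axes must be 1-D")
        if np.any(np.diff(d) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if v.shape != (d.size, t.size) or u.shape != v.shape:
            raise ValueError("values/uncertainties shape must be (n_d, n_t)")
        if not np.all(np.isfinite(v)):
            raise ValueError("table values must be finite")
        if np.any(u < 0):
            raise ValueError("uncertainties must be non-negative")

    def at(self, d: float, t: float) -> tuple[float, float]:
        """Value and uncertainty at an exact grid node."""
        i = int(np.argmin(np.abs(self.distances - d)))
        j = int(np.argmin(np.abs(self.thicknesses - t)))
        if abs(self.distances[i] - d) > 1e-9 or abs(self.thicknesses[j] - t) > 1e-9:
            raise KeyError(f"({d}, {t}) is not a grid node")
        return float(self.values[i, j]), float(self.uncertainties[i, j])


def layer_average_dose(profile: ShellDoseProfile, d: float, t: float,
                       estimator: str = "tracklength") -> tuple[float, float]:
    """Mass-averaged dose over the tally cells spanning [d, d + t).

    Returns (dose, 1-sigma absolute uncertainty), the latter from the
    per-batch layer averages so inter-cell correlations are respected.
    The cells in [d, d+t) share one material, so mass weights reduce to
    volume weights.
    """
    batch = {"tracklength": profile.batch_tracklength,
             "deposition": profile.batch_deposition,
             "fluence_folded": profile.batch_fluence_folded}[estimator]
    r0 = profile.shell_inner_radii
    h = profile.config.tally_shell_thickness
    sel = (r0 >= d - 1e-9) & (r0 < d + t - 1e-9)
    if not np.any(sel):
        raise ValueError(f"layer [{d}, {d + t}) has no tally cells in range")
    r_in = r0[sel]
    w = (r_in + h) ** 3 - r_in**3
    w = w / w.sum()
    layer_per_batch = batch[:, sel] @ w
    mean = float(layer_per_batch.mean())
    sigma = float(layer_per_batch.std(ddof=1) / np.sqrt(layer_per_batch.size))
    return mean, sigma


def _pair_seed(base_seed: int, d: float, t: float) -> int:
    """Stable per-(d, t) stream seed derived from the base seed."""
    key = f"{base_seed}:{round(d * 10)}:{round(t * 10)}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def build_table(
    distances=DEFAULT_DISTANCES,
    thicknesses=DEFAULT_THICKNESSES,
    n_histories: int = 10**6,
    base_seed: int = 0,
    *,
    bone_material: str = "cortical_bone",
    source_energy: float = 0.662,
    outer_radius: float = 15.0,
    progress=None,
) -> DoseDifferenceTable:
    """Build dD%(d, t) from paired heterogeneous/homogeneous simulations.

    One homogeneous reference run (seed ``base_seed``) plus one
    heterogeneous run per grid point, each with its own seed derived from
    ``base_seed`` and (d, t).  Uncertainties combine both runs' layer
    averages in quadrature.  Every (d, t) must be lattice-aligned with
    d + t inside the phantom.
    """
    distances = np.asarray(distances, float)
    thicknesses = np.asarray(thicknesses, float)
    tally_hi = float(min(np.ceil((distances[-1] + thicknesses[-1]) * 10) / 10,
                         outer_radius))
    hom_cfg = PhantomConfig(outer_radius=outer_radius,
                            source_energy=source_energy,
                            tally_range=(LATTICE_CM, tally_hi))
    hom = run_simulation(hom_cfg, n_histories, base_seed % 2**31)
    values = np.empty((distances.size, thicknesses.size))
    sigmas = np.empty_like(values)
    for i, d in enumerate(distances):
        for j, t in enumerate(thicknesses):
            cfg = replace(hom_cfg, bone_distance=float(d),
                          bone_thickness=float(t),
                          bone_material=bone_material)
            seed = _pair_seed(base_seed, d, t)
            het = run_simulation(cfg, n_histories, seed)
            dh, sh = layer_average_dose(het, d, t)
            dw, sw = layer_average_dose(hom, d, t)
            values[i, j] = percent_difference(dh, dw)
            # first-order propagation of the ratio's two independent terms
            sigmas[i, j] = 100.0 * (dh / dw) * np.hypot(sh / dh, sw / dw)
            if progress is not None:
                progress(d, t, values[i, j], sigmas[i, j])
    meta = {
        "source_energy_MeV": source_energy,
        "n_histories": n_histories,
        "seed": base_seed,
        "bone_material": bone_material,
        "outer_radius_cm": outer_radius,
        "distance_convention": "bone inner radius, cm",
        "estimator": "tracklength",
    }
    return DoseDifferenceTable(distances, thicknesses, values, sigmas, meta)


def write_table(table: DoseDifferenceTable, path) -> None:
    """Serialise a table to long-format CSV with a metadata header."""
    with open(path, "w") as fh:
        for k, v in table.metadata.items():
            fh.write(f"# {k}={v}\n")
        fh.write("d,t,delta_pct,sigma_pct\n")
        for i, d in enumerate(table.distances):
            for j, t in enumerate(table.thicknesses):
                fh.write(f"{d:.10g},{t:.10g},"
                         f"{table.values[i, j]:.17g},"
                         f"{table.uncertainties[i, j]:.17g}\n")


def read_table(path) -> DoseDifferenceTable:
    """Read a table written by :func:`write_table`; validates the format."""
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" not in body:
                raise TableParseError(
                    f"{path}:{header_lines}: metadata line without '='")
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise TableParseError(f"{path}: missing metadata key {key!r}")
    for key in ("source_energy_MeV",):
        meta[key] = float(meta[key])
    for key in ("n_histories", "seed"):
        meta[key] = int(meta[key])
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    for col in ("d", "t", "delta_pct", "sigma_pct"):
        if col not in df.columns:
            raise TableParseError(f"{path}: missing column {col!r}")
    d_axis = np.unique(df["d"].to_numpy())
    t_axis = np.unique(df["t"].to_numpy())
    # require the file's row order to present both axes increasing
    d_seen = df["d"].to_numpy()
    if np.any(np.diff(d_seen) < 0):
        raise TableParseError(
            f"{path}: distance rows out of increasing order")
    if df.shape[0] != d_axis.size * t_axis.size:
        raise TableParseError(f"{path}: grid is not complete/rectangular")
    values = df["delta_pct"].to_numpy().reshape(d_axis.size, t_axis.size)
    sigmas = df["sigma_pct"].to_numpy().reshape(d_axis.size, t_axis.size)
    tsort = df["t"].to_numpy().reshape(d_axis.size, t_axis.size)
    if np.any(np.diff(tsort, axis=1) < 0):
        raise TableParseError(f"{path}: thickness columns out of order")
    return DoseDifferenceTable(d_axis, t_axis, values, sigmas, meta)
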