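"""The heterogeneity-correction engine.

Given a dose computed for homogeneous water (e.g. by a TG-43-based
planning system), correct it for a concentric bone layer of thickness t
whose inner surface sits at distance d from the source:

* thin layers (t < 0.4 cm): multiply by the distance-dependent
  dose-rate-constant factor CF(x) = c3 x^3 + c1 x + c0 with default
  coefficients (-0.00003, 0.006, 0.956), x = d in cm;
* thick layers (t >= 0.4 cm): multiply by 1 + dD%(d, t)/100, with dD%
  bilinearly interpolated from a pre-computed table.

Queries outside the table hull are clamped to it (flagged, warned) rather
than extrapolated.  Leave-one-out validation bounds the interpolation
error against direct simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dose_tables import DoseDifferenceTable

__all__ = [
    "ThinLayerModel",
    "CorrectionResult",
    "thin_layer_factor",
    "interpolate_delta",
    "apply_correction",
    "validate_loo",
    "loo_predict",
    "fit_thin_layer_model",
    "THICKNESS_THRESHOLD_CM",
]

THICKNESS_THRESHOLD_CM = 0.4


@dataclass(frozen=True)
class ThinLayerModel:
    """Cubic (no quadratic term) dose-rate-constant correction factor.

    CF(x) = c3 x^3 + c1 x + c0, x = bone-layer inner radius in cm.
    Defaults are the published fit for a thin (< 0.4 cm) cortical-bone
    shell around a Cs-137 source.
    """

    c3: float = -0.00003
    c1: float = 0.006
    c0: float = 0.956
    validity_range: tuple[float, float] = (0.1, 10.0)
    thickness_threshold: float = THICKNESS_THRESHOLD_CM


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected dose plus the dispatch path and provenance of the factor."""

    corrected_dose: float
    path: str  # "thin" | "thick"
    applied_factor: float
    applied_delta_pct: float | None
    clamped: bool
    provenance: dict = field(default_factory=dict)


def thin_layer_factor(x: float, model: ThinLayerModel | None = None) -> float:
    """Evaluate CF(x) = c3 x^3 + c1 x + c0; no extrapolation outside range."""
    model = model or ThinLayerModel()
    lo, hi = model.validity_range
    if not (lo <= x <= hi):
        raise ValueError(
            f"x = {x} cm outside thin-layer validity range [{lo}, {hi}] cm")
    return model.c3 * x**3 + model.c1 * x + model.c0


def _interpolator(table: DoseDifferenceTable, method: str):
    if table.distances.size < 2 or table.thicknesses.size < 2:
        raise ValueError("degenerate grid: need >= 2 points on each axis")
    return RegularGridInterpolator(
        (table.distances, table.thicknesses), table.values,
        method=method, bounds_error=True)


def interpolate_delta(table: DoseDifferenceTable, d: float, t: float,
                      *, method: str = "linear") -> float:
    """Interpolated dD% at (d, t); bilinear by default, exact at nodes.

    (d, t) must lie inside or on the grid hull; clamping of outside
    queries is the caller's policy (see :func:`apply_correction`).
    """
    itp = _interpolator(table, method)
    return float(itp([[d, t]])[0])


def _clamp(x: float, lo: float, hi: float) -> tuple[float, bool]:
    if x < lo:
        return lo, True
    if x > hi:
        return hi, True
    return x, False


def apply_correction(
    dose_water: float,
    d: float,
    t: float,
    table: DoseDifferenceTable | None = None,
    thin_model: ThinLayerModel | None = None,
) -> CorrectionResult:
    """Correct a homogeneous-water dose for a bone layer at (d, t).

    Thickness below the model threshold routes to the thin-layer
    polynomial; t >= threshold (including exactly the threshold) routes
    to table interpolation.  Out-of-hull (d, t) are clamped to the grid
    and flagged.
    """
    if dose_water <= 0:
        raise ValueError("dose_water must be positive")
    if d <= 0 or t <= 0:
        raise ValueError("distance and thickness must be positive")
    thin_model = thin_model or ThinLayerModel()
    if t < thin_model.thickness_threshold:
        lo, hi = thin_model.validity_range
        x, clamped = _clamp(d, lo, hi)
        if clamped:
            warnings.warn(f"thin-layer distance {d} cm clamped to [{lo}, {hi}]")
        cf = thin_layer_factor(x, thin_model)
        return CorrectionResult(
            corrected_dose=dose_water * cf,
            path="thin",
            applied_factor=cf,
            applied_delta_pct=None,
            clamped=clamped,
            provenance={"coefficients": (thin_model.c3, thin_model.c1,
                                         thin_model.c0), "x_cm": x},
        )
    if table is None:
        raise ValueError("thick-layer correction requires a dose table")
    dq, cd = _clamp(d, table.distances[0], table.distances[-1])
    tq, ct = _clamp(t, table.thicknesses[0], table.thicknesses[-1])
    clamped = cd or ct
    if clamped:
        warnings.warn(
            f"query ({d}, {t}) outside table hull; clamped to ({dq}, {tq})")
    i = int(np.searchsorted(table.distances, dq, side="right") - 1)
    j = int(np.searchsorted(table.thicknesses, tq, side="right") - 1)
    i = min(i, table.distances.size - 2)
    j = min(j, table.thicknesses.size - 2)
    delta = interpolate_delta(table, dq, tq)
    factor = 1.0 + delta / 100.0
    return CorrectionResult(
        corrected_dose=dose_water * factor,
        path="thick",
        applied_factor=factor,
        applied_delta_pct=delta,
        clamped=clamped,
        provenance={
            "bracketing_nodes": [
                (float(table.distances[i + a]), float(table.thicknesses[j + b]),
                 float(table.values[i + a, j + b]))
                for a in (0, 1) for b in (0, 1)
            ],
        },
    )


def loo_predict(table: DoseDifferenceTable, i: int, j: int,
                *, method: str = "linear") -> float:
    """Predict interior node (i, j) with its row and column removed.

    Deleting row i and column j leaves a rectangular grid on which the
    node's position is interpolated; for the bilinear method this is the
    bilinear blend of the four diagonal-neighbour nodes.
    """
    nd, nt = table.values.shape
    if not (0 < i < nd - 1 and 0 < j < nt - 1):
        raise ValueError("leave-one-out is defined for interior nodes only")
    d_ax = np.delete(table.distances, i)
    t_ax = np.delete(table.thicknesses, j)
    vals = np.delete(np.delete(table.values, i, axis=0), j, axis=1)
    itp = RegularGridInterpolator((d_ax, t_ax), vals, method=method,
                                  bounds_error=True)
    return float(itp([[table.distances[i], table.thicknesses[j]]])[0])


def validate_loo(table: DoseDifferenceTable, *, method: str = "linear",
                 return_details: bool = False):
    """Maximum leave-one-out interpolation error over interior nodes.

    For each interior node, the node's row and column are removed, its
    value re-interpolated from the remaining grid, and compared to the
    stored (directly simulated) value.  Returns the maximum absolute
    discrepancy in percentage-dose points, and with
    ``return_details=True`` also per-node records including the
    propagated MC noise floor sigma for each comparison.
    """
    nd, nt = table.values.shape
    if nd < 3 or nt < 3:
        raise ValueError("leave-one-out needs >= 3 nodes per axis")
    details = []
    for i in range(1, nd - 1):
        for j in range(1, nt - 1):
            pred = loo_predict(table, i, j, method=method)
            truth = table.values[i, j]
            err = abs(pred - truth)
            # noise floor: node sigma plus bilinear-weighted corner sigmas
            # (weights of the four diagonal neighbours sum to 1)
            du = table.distances
            tu = table.thicknesses
            wd = (du[i] - du[i - 1]) / (du[i + 1] - du[i - 1])
            wt = (tu[j] - tu[j - 1]) / (tu[j + 1] - tu[j - 1])
            wts = np.array([(1 - wd) * (1 - wt), (1 - wd) * wt,
                            wd * (1 - wt), wd * wt])
            sig_corners = np.array([
                table.uncertainties[i - 1, j - 1],
                table.uncertainties[i - 1, j + 1],
                table.uncertainties[i + 1, j - 1],
                table.uncertainties[i + 1, j + 1],
            ])
            floor = float(np.sqrt(table.uncertainties[i, j] ** 2
                                  + np.sum((wts * sig_corners) ** 2)))
            details.append({"i": i, "j": j, "d": float(du[i]),
                            "t": float(tu[j]), "predicted": pred,
                            "simulated": float(truth), "abs_error": err,
                            "noise_floor": floor})
    max_err = max(rec["abs_error"] for rec in details)
    if return_details:
        return max_err, details
    return max_err


def fit_thin_layer_model(x, ratio, *, validity_range=(0.1, 10.0),
                         thickness_threshold=THICKNESS_THRESHOLD_CM) -> ThinLayerModel:
    """Least-squares cubic fit with the quadratic coefficient fixed to 0.

    ``x`` are layer distances (cm) and ``ratio`` the simulated
    D_inhomogeneity / D_water dose ratios for a thin layer.
    """
    x = np.asarray(x, float)
    y = np.asarray(ratio, float)
    if x.size < 3:
        raise ValueError("need at least 3 points to fit the cubic")
    A = np.column_stack([x**3, x, np.ones_like(x)])
    (c3, c1, c0), *_ = np.linalg.lstsq(A, y, rcond=None)
    return ThinLayerModel(c3=float(c3), c1=float(c1), c0=float(c0),
                          validity_range=tuple(validity_range),
                          thickness_threshold=thickness_threshold)
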