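"""Dosimetric indices computed from a cumulative DVH.

Implements the dose-at-volume quantiles D_x (minimum dose received by the
hottest x% of a structure), the mean dose, and the target/OAR summary
indices used for plan comparison:

* homogeneity index      HI = (D5 − D95) / D_p × 100   (percent; 0 = perfectly flat)
* inhomogeneity coeff.   IC = (Dmax − Dmin) / Dmean    (dimensionless)
* integral dose          ID = Dmean × V                (Gy·cm³; total-energy surrogate)

Dmax/Dmin are DVH-based near-extreme estimators: Dmax is the dose at the
smallest resolvable volume (the last nonzero cumulative point) and Dmin the
highest dose still covering 100% of the volume — robust to binning and
consistent with D1-style definitions.  Interpolation is piecewise-linear on
the cumulative curve; flat segments resolve to the highest dose at the
requested volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import DVHCurve, DVHValidationError, PlanSet

__all__ = [
    "MetricRecord",
    "dose_at_volume",
    "volume_at_dose",
    "d_mean",
    "d_max",
    "d_min",
    "homogeneity_index",
    "inhomogeneity_coefficient",
    "integral_dose",
    "metric_battery",
    "records_to_frame",
    "CTV_METRICS",
    "OAR_METRICS",
]

#: Metrics reported for the target volume and for each organ at risk.
CTV_METRICS = ("Dmean", "D1", "D95", "D99", "HI", "IC")
OAR_METRICS = ("Dmean", "D1", "D50", "ID")


@dataclass(frozen=True)
class MetricRecord:
    """One dosimetric quantity for (patient, modality, structure).

    ``value`` is in Gy for D-metrics, percent for HI, dimensionless for IC
    and Gy·cm³ for ID.
    """

    patient_id: str
    modality: str
    structure: str
    metric: str
    value: float


def _require_cumulative(curve: DVHCurve) -> DVHCurve:
    if curve.kind != "cumulative":
        raise DVHValidationError("a cumulative curve is required")
    return curve


def dose_at_volume(curve: DVHCurve, x: float) -> float:
    """Dose D such that the relative volume at-or-above D equals ``x``%.

    Linear interpolation between bracketing points; flat segments resolve to
    the highest dose; the result is clamped to the curve's dose range.
    """
    _require_cumulative(curve)
    if not 0 < x <= 100:
        raise ValueError("x must be a percent volume in (0, 100]")
    frac = x / 100.0
    d, v = curve.dose_edges, curve.volume
    if frac <= v[-1]:
        return float(d[-1])
    if frac > v[0]:
        return float(d[0])
    # last index with volume >= frac (ties -> highest dose)
    i = int(np.searchsorted(-v, -frac, side="right")) - 1
    if v[i] == frac:
        return float(d[i])
    # v[i] > frac > v[i + 1]
    w = (v[i] - frac) / (v[i] - v[i + 1])
    return float(d[i] + w * (d[i + 1] - d[i]))


def doses_at_volumes(curve: DVHCurve, xs) -> np.ndarray:
    """Vectorized :func:`dose_at_volume` for an array of percent volumes."""
    _require_cumulative(curve)
    xs = np.asarray(xs, dtype=float)
    if np.any((xs <= 0) | (xs > 100)):
        raise ValueError("x must be a percent volume in (0, 100]")
    frac = xs / 100.0
    d, v = curve.dose_edges, curve.volume
    i = np.searchsorted(-v, -frac, side="right") - 1
    i = np.clip(i, 0, v.size - 2)
    denom = v[i] - v[i + 1]
    w = np.where(denom > 0, (v[i] - frac) / np.where(denom > 0, denom, 1.0), 0.0)
    out = d[i] + np.clip(w, 0.0, 1.0) * (d[i + 1] - d[i])
    # clamps; exact ties already resolve to the highest dose via searchsorted
    out = np.where(frac <= v[-1], d[-1], out)
    out = np.where(frac > v[0], d[0], out)
    return out


def volume_at_dose(curve: DVHCurve, dose: float) -> float:
    """Relative volume at-or-above ``dose`` (linear interpolation)."""
    _require_cumulative(curve)
    d, v = curve.dose_edges, curve.volume
    if dose <= d[0]:
        return float(v[0])
    if dose >= d[-1]:
        return float(v[-1])
    return float(np.interp(dose, d, v))


def d_mean(curve: DVHCurve) -> float:
    """Mean dose: Σ v_i × midpoint_i over the differential form.

    Residual cumulative volume at the last edge (curves not terminating at
    zero) is attributed to the last edge dose.
    """
    if curve.kind == "cumulative":
        diff = curve.as_differential()
        tail = curve.volume[-1] * curve.dose_edges[-1]
    else:
        diff, tail = curve, 0.0
    return float(np.dot(diff.volume, diff.bin_midpoints) + tail)


def d_max(curve: DVHCurve) -> float:
    """Dose at the smallest resolvable volume (last nonzero cumulative point)."""
    c = curve.as_cumulative()
    nz = np.nonzero(c.volume > 0)[0]
    if nz.size == 0:
        return float(c.dose_edges[0])
    return float(c.dose_edges[nz[-1]])


def d_min(curve: DVHCurve) -> float:
    """Highest dose still covering 100% of the volume."""
    c = curve.as_cumulative()
    full = np.nonzero(c.volume >= 1.0 - 1e-9)[0]
    if full.size == 0:
        return float(c.dose_edges[0])
    return float(c.dose_edges[full[-1]])


def homogeneity_index(curve: DVHCurve, prescription: float) -> float:
    """HI = (D5 − D95) / prescription × 100, in percent."""
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    _require_cumulative(curve)
    return (dose_at_volume(curve, 5) - dose_at_volume(curve, 95)) / prescription * 100.0


def inhomogeneity_coefficient(curve: DVHCurve) -> float:
    """IC = (Dmax − Dmin) / Dmean."""
    _require_cumulative(curve)
    mean = d_mean(curve)
    if mean == 0:
        raise ZeroDivisionError("IC undefined for a zero-dose curve")
    return (d_max(curve) - d_min(curve)) / mean


def integral_dose(curve: DVHCurve) -> float:
    """ID = Dmean × V in Gy·cm³ (simplified product form)."""
    if not np.isfinite(curve.abs_volume):
        raise DVHValidationError("integral dose needs the structure's absolute volume")
    return d_mean(curve) * curve.abs_volume


def metric_battery(plan: PlanSet) -> list[MetricRecord]:
    """All comparison-table metrics for one plan.

    CTV rows: Dmean, D1, D95, D99, HI, IC.  Each OAR: Dmean, D1, D50, ID.
    Missing structures are skipped (reported by omission, not fatal).
    """
    records: list[MetricRecord] = []

    def add(structure: str, metric: str, value: float) -> None:
        records.append(
            MetricRecord(plan.patient_id, plan.modality, structure, metric, value)
        )

    for label in plan.structures:
        curve = plan[label].as_cumulative()
        if label == "ctv":
            add(label, "Dmean", d_mean(curve))
            add(label, "D1", dose_at_volume(curve, 1))
            add(label, "D95", dose_at_volume(curve, 95))
            add(label, "D99", dose_at_volume(curve, 99))
            add(label, "HI", homogeneity_index(curve, plan.prescription_dose))
            add(label, "IC", inhomogeneity_coefficient(curve))
        else:
            add(label, "Dmean", d_mean(curve))
            add(label, "D1", dose_at_volume(curve, 1))
            add(label, "D50", dose_at_volume(curve, 50))
            add(label, "ID", integral_dose(curve))
    return records


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Long-format DataFrame with columns patient_id/modality/structure/metric/value."""
    return pd.DataFrame([r.__dict__ for r in records])
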