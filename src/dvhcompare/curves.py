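"""Dose–volume histogram containers.

A cumulative DVH gives, for each dose level ``D``, the fraction of a
structure's volume receiving at least ``D``; a differential DVH gives the
fraction receiving a dose inside each bin.  Relative (fractional) volume is
the canonical representation; the structure's absolute volume in cm³ is
carried as metadata and only enters the integral dose.

Conventions
-----------
* ``dose_edges`` are strictly increasing bin edges in Gy.
* A cumulative curve stores one volume value per edge (volume at-or-above
  that edge); a differential curve stores one fraction per half-open bin
  ``[edge_i, edge_{i+1})``, i.e. ``len(volume) == len(dose_edges) - 1``.
* The differential bin dose is the bin midpoint.
* Physical Gy and GyRBE share the same numeric axis: the pipeline compares
  plan exports, not beam physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "MODALITIES",
    "STRUCTURES",
    "DVHValidationError",
    "NonMonotoneCurveError",
    "NegativeVolumeError",
    "DVHCurve",
    "PlanSet",
    "cumulative_to_differential",
    "differential_to_cumulative",
]

MODALITIES = ("photon", "proton", "helium")

#: The eight study structures (paired organs counted per side).
STRUCTURES = (
    "ctv",
    "hippocampus_il",
    "hippocampus_cl",
    "inner_ear_il",
    "inner_ear_cl",
    "pituitary",
    "brainstem",
    "brain",
    "skin",
)

#: Tolerance on "cumulative curve starts at 1" / "differential sums to 1".
VOLUME_TOL = 5e-3


class DVHValidationError(ValueError):
    """A DVH curve or plan violates a structural invariant."""


class NonMonotoneCurveError(DVHValidationError):
    """A cumulative curve increases somewhere."""


class NegativeVolumeError(DVHValidationError):
    """A volume entry is negative."""


@dataclass(frozen=True)
class DVHCurve:
    """One structure's dose–volume histogram.

    Parameters
    ----------
    patient_id : str
        Opaque patient label.
    modality : str
        One of ``photon``, ``proton``, ``helium``.
    structure : str
        Structure label; the eight study structures or free-form.
    kind : str
        ``cumulative`` or ``differential``.
    dose_edges : ndarray
        Strictly increasing dose bin edges, Gy, all >= 0.
    volume : ndarray
        Relative volume at-or-above each edge (cumulative) or per-bin
        fraction (differential), dimensionless in [0, 1].
    abs_volume : float
        Structure volume, cm³, > 0.
    """

    patient_id: str
    modality: str
    structure: str
    kind: str
    dose_edges: np.ndarray = field(repr=False)
    volume: np.ndarray = field(repr=False)
    abs_volume: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_edges", np.asarray(self.dose_edges, dtype=float))
        object.__setattr__(self, "volume", np.asarray(self.volume, dtype=float))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        d, v = self.dose_edges, self.volume
        if self.modality not in MODALITIES:
            raise DVHValidationError(f"unknown modality {self.modality!r}")
        if self.kind not in ("cumulative", "differential"):
            raise DVHValidationError(f"unknown DVH kind {self.kind!r}")
        if d.ndim != 1 or d.size < 2:
            raise DVHValidationError("dose_edges must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(d) > 0):
            raise DVHValidationError("dose_edges must be strictly increasing")
        if d[0] < 0:
            raise DVHValidationError("dose_edges must be non-negative")
        if np.any(v < -1e-12):
            raise NegativeVolumeError("volumes must be non-negative")
        if self.kind == "cumulative":
            if v.size != d.size:
                raise DVHValidationError(
                    "cumulative curve needs one volume per dose edge"
                )
            if np.any(np.diff(v) > 1e-12):
                raise NonMonotoneCurveError("cumulative volume must be nonincreasing")
            if abs(v[0] - 1.0) > VOLUME_TOL:
                raise DVHValidationError(
                    f"cumulative curve must start at relative volume 1 (got {v[0]:.6f})"
                )
        else:
            if v.size != d.size - 1:
                raise DVHValidationError(
                    "differential curve needs one fraction per bin (len(edges) - 1)"
                )
            if abs(v.sum() - 1.0) > VOLUME_TOL:
                raise DVHValidationError(
                    f"differential fractions must sum to 1 (got {v.sum():.6f})"
                )
        if not (np.isnan(self.abs_volume) or self.abs_volume > 0):
            raise DVHValidationError("abs_volume must be positive")

    # ------------------------------------------------------------------
    @property
    def bin_midpoints(self) -> np.ndarray:
        """Midpoint dose of each bin (differential representation)."""
        return 0.5 * (self.dose_edges[:-1] + self.dose_edges[1:])

    def as_differential(self) -> "DVHCurve":
        return self if self.kind == "differential" else cumulative_to_differential(self)

    def as_cumulative(self) -> "DVHCurve":
        return self if self.kind == "cumulative" else differential_to_cumulative(self)

    def equals(self, other: "DVHCurve", atol: float = 0.0) -> bool:
        return (
            self.patient_id == other.patient_id
            and self.modality == other.modality
            and self.structure == other.structure
            and self.kind == other.kind
            and self.dose_edges.shape == other.dose_edges.shape
            and np.allclose(self.dose_edges, other.dose_edges, atol=atol, rtol=0)
            and np.allclose(self.volume, other.volume, atol=atol, rtol=0)
            and (
                (np.isnan(self.abs_volume) and np.isnan(other.abs_volume))
                or np.isclose(self.abs_volume, other.abs_volume, atol=atol, rtol=0)
            )
        )


def cumulative_to_differential(curve: DVHCurve) -> DVHCurve:
    """Adjacent differences of a cumulative curve.

    The resulting fractions sum to ``volume[0] - volume[-1]``; any residual
    volume at or above the last edge is not representable in the bin grid, so
    curves meant to round-trip should terminate at (numerically) zero volume.
    """
    if curve.kind != "cumulative":
        raise DVHValidationError("expected a cumulative curve")
    frac = -np.diff(curve.volume)
    frac = np.clip(frac, 0.0, None)  # guard tiny negative rounding
    return replace(curve, kind="differential", volume=frac)


def differential_to_cumulative(curve: DVHCurve) -> DVHCurve:
    """Reverse cumulative sum of per-bin fractions (last edge gets 0)."""
    if curve.kind != "differential":
        raise DVHValidationError("expected a differential curve")
    cum = np.concatenate([np.cumsum(curve.volume[::-1])[::-1], [0.0]])
    return replace(curve, kind="cumulative", volume=cum)


@dataclass(frozen=True)
class PlanSet:
    """All DVH curves for one patient under one modality.

    ``n_fractions × dose_per_fraction`` must equal ``prescription_dose``
    within tolerance, and each structure label appears exactly once.
    """

    patient_id: str
    modality: str
    prescription_dose: float
    n_fractions: int
    dose_per_fraction: float
    curves: Mapping[str, DVHCurve]

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", dict(self.curves))
        self.validate()

    def validate(self) -> None:
        if self.prescription_dose <= 0:
            raise DVHValidationError("prescription dose must be positive")
        if abs(self.n_fractions * self.dose_per_fraction - self.prescription_dose) > 1e-9:
            raise DVHValidationError(
                "n_fractions × dose_per_fraction must equal the prescription dose"
            )
        for label, curve in self.curves.items():
            if curve.structure != label:
                raise DVHValidationError(
                    f"curve keyed {label!r} carries structure {curve.structure!r}"
                )
            if curve.patient_id != self.patient_id or curve.modality != self.modality:
                raise DVHValidationError(
                    f"curve {label!r} does not belong to ({self.patient_id}, {self.modality})"
                )

    def __getitem__(self, structure: str) -> DVHCurve:
        return self.curves[structure]

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(self.curves)

    def equals(self, other: "PlanSet", atol: float = 0.0) -> bool:
        return (
            self.patient_id == other.patient_id
            and self.modality == other.modality
            and np.isclose(self.prescription_dose, other.prescription_dose, atol=atol)
            and self.n_fractions == other.n_fractions
            and np.isclose(self.dose_per_fraction, other.dose_per_fraction, atol=atol)
            and set(self.curves) == set(other.curves)
            and all(self.curves[s].equals(other.curves[s], atol=atol) for s in self.curves)
        )
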