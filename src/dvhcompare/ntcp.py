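"""Lyman–Kutcher–Burman NTCP via the generalized equivalent uniform dose.

The LKB model maps a heterogeneous dose distribution to a complication
probability through a probit dose–response:

    NTCP = Φ(t),      t = (gEUD − TD50) / (m · TD50)

where Φ is the standard normal CDF, TD50 the uniform whole-organ dose giving
a 50% complication probability, m the slope parameter, and the gEUD the
power mean of the bin doses with exponent 1/n:

    gEUD = [ Σ_i v_i · D_i^(1/n) ]^n

n is the volume-effect parameter (n = 1: parallel organ, gEUD = Dmean).
For a fraction v of the organ irradiated uniformly at dose D this reduces to
the classical partial-volume form with tolerance dose TD50(v) = TD50 · v^(−n).

Plan total doses enter without fractionation (LQ/EQD2) correction.  The
default parameter registry covers the endocrine and auditory endpoints used
for pediatric posterior-fossa plan comparison; cochlea parameters are
applied to the inner-ear DVHs via a configurable structure→endpoint map.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .curves import DVHCurve, PlanSet
from .dosimetry import d_mean

__all__ = [
    "LKBParameters",
    "NTCPRecord",
    "geud",
    "tolerance_dose_partial",
    "lkb_t",
    "ntcp_from_t",
    "ntcp_partial_volume",
    "ntcp_from_dvh",
    "ntcp_battery",
    "load_lkb_registry",
    "DEFAULT_ENDPOINT_MAP",
    "ntcp_records_to_frame",
]


@dataclass(frozen=True)
class LKBParameters:
    """One endpoint's LKB parameter row: TD50 [Gy], slope m, volume effect n."""

    structure: str
    endpoint: str
    td50: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValueError("TD50 must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if not 0 < self.n <= 1:
            raise ValueError("n must lie in (0, 1]")


@dataclass(frozen=True)
class NTCPRecord:
    """gEUD, probit deviate t and NTCP for one (patient, modality, endpoint)."""

    patient_id: str
    modality: str
    structure: str
    endpoint: str
    geud: float
    t: float
    ntcp: float


def geud(curve: DVHCurve, n: float) -> float:
    """Generalized equivalent uniform dose, power mean with exponent 1/n.

    Evaluated on the differential form with bin-midpoint doses; zero-dose
    bins contribute zero.  Any n > 0 is accepted here (the LKB registry
    restricts itself to 0 < n <= 1).
    """
    if n <= 0:
        raise ValueError("volume-effect parameter n must be positive")
    diff = curve.as_differential()
    doses = diff.bin_midpoints
    frac = diff.volume
    if frac.sum() == 0:
        raise ValueError("empty DVH curve")
    if n == 1.0:
        # parallel-organ shortcut; identical to the general path
        return d_mean(curve)
    total = float(np.dot(frac, np.power(doses, 1.0 / n)))
    return float(total ** n)


def tolerance_dose_partial(params: LKBParameters, v: float) -> float:
    """Partial-volume tolerance dose TD50(v) = TD50 · v^(−n)."""
    if not 0 < v <= 1:
        raise ValueError("relative volume v must lie in (0, 1]")
    return params.td50 * v ** (-params.n)


def lkb_t(geud_value: float, params: LKBParameters) -> float:
    """Probit deviate t = (gEUD − TD50) / (m · TD50)."""
    return (geud_value - params.td50) / (params.m * params.td50)


def ntcp_from_t(t: float) -> float:
    """Standard normal CDF of t (double-precision via the error function)."""
    return float(norm.cdf(t))


def ntcp_partial_volume(dose: float, v: float, params: LKBParameters) -> float:
    """Classical partial-volume LKB: fraction ``v`` irradiated uniformly at ``dose``.

    Uses t = (D − TD50(v)) / (m · TD50(v)) with TD50(v) = TD50 · v^(−n);
    algebraically identical to the gEUD route since gEUD = v^n · D there.
    """
    td50_v = tolerance_dose_partial(params, v)
    return ntcp_from_t((dose - td50_v) / (params.m * td50_v))


def ntcp_from_dvh(curve: DVHCurve, params: LKBParameters) -> NTCPRecord:
    """Chain gEUD → t → NTCP for one curve and parameter set."""
    g = geud(curve, params.n)
    t = lkb_t(g, params)
    return NTCPRecord(
        patient_id=curve.patient_id,
        modality=curve.modality,
        structure=curve.structure,
        endpoint=params.endpoint,
        geud=g,
        t=t,
        ntcp=ntcp_from_t(t),
    )


# ----------------------------------------------------------------------
# Parameter registry

#: structure label -> registry structure whose parameters apply
DEFAULT_ENDPOINT_MAP: Mapping[str, str] = {
    "inner_ear_il": "cochlea",
    "inner_ear_cl": "cochlea",
    "pituitary": "pituitary",
}


def load_lkb_registry(path: str | None = None) -> list[LKBParameters]:
    """Load LKB parameter rows from a CSV registry (structure,endpoint,TD50,m,n).

    With no path, the packaged default registry (endocrine dysfunction,
    tinnitus, hearing loss) is used.
    """
    if path is None:
        ref = resources.files("dvhcompare").joinpath("data/lkb_parameters.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    return [
        LKBParameters(
            structure=row["structure"],
            endpoint=row["endpoint"],
            td50=float(row["td50_gy"]),
            m=float(row["m"]),
            n=float(row["n"]),
        )
        for _, row in table.iterrows()
    ]


def ntcp_battery(
    plan: PlanSet,
    registry: Iterable[LKBParameters] | None = None,
    endpoint_map: Mapping[str, str] = DEFAULT_ENDPOINT_MAP,
) -> list[NTCPRecord]:
    """NTCP records for every (structure, endpoint) pairing in the plan.

    ``endpoint_map`` sends a plan structure label to the registry structure
    whose parameters apply (inner ears use cochlea parameters).
    """
    if registry is None:
        registry = load_lkb_registry()
    records = []
    for label in plan.structures:
        target = endpoint_map.get(label)
        if target is None:
            continue
        for params in registry:
            if params.structure == target:
                records.append(ntcp_from_dvh(plan[label], params))
    return records


def ntcp_records_to_frame(records: list[NTCPRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
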