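"""Seeded synthetic DVH cohorts for paired three-modality plan comparison.

The generator emulates the statistical structure of a pediatric
posterior-fossa ependymoma planning study: 15 patients, three modalities
(photon IMRT, scanned protons, scanned helium ions) planned on the same
anatomy, prescription 54 Gy in 30 × 1.8 Gy prescribed to the CTV median
dose, CTV coverage D95 ≥ 95% of prescription, and organ-at-risk dose
falloff that steepens from photons to protons to helium ions (helium ions
scatter less laterally, hence the steepest gradients and lowest OAR doses).

Generative model
----------------
* CTV: cumulative DVH is a symmetric sigmoid in dose centred at the
  prescription, ``v(D) = 1 / (1 + exp((D − D_p)/s))`` with a
  modality-specific spread ``s`` (helium < proton < photon).
* Ordinary OAR: logistic-like falloff that is exactly 1 at zero dose and
  exactly 0.5 at the configured median dose,

      v(D) = 1 / (1 + expm1(g·D) / expm1(g·D50)),

  truncated to [0, prescription].  ``D50 = baseline_structure ×
  lognormal patient effect × modality factor``; the gradient ``g`` is
  modality-specific.
* Brain and skin additionally carry a low-dose plateau component
  (an exponential bath with half-dose λ) holding most of the volume, so
  their median dose can fall below 1 Gy and exercise the exclusion rules.
  For these structures the configured D50 parameter plays the role of λ.

Per patient, all random effects (baseline multiplier, structure volume,
CTV spread jitter) are drawn from a per-(patient, structure) substream of
the global seed and shared across modalities, so the design is exactly
paired: with three identical modality profiles the three plans of a patient
are identical, and adding a structure never perturbs another structure's
draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .curves import DVHCurve, PlanSet

__all__ = [
    "StructureSpec",
    "ModalityProfile",
    "CohortConfig",
    "VoxelPhantom",
    "default_config",
    "generate_plan",
    "generate_cohort",
    "generate_voxel_phantom",
]


@dataclass(frozen=True)
class StructureSpec:
    """Population-level description of one structure's dose and volume.

    ``baseline_d50`` is the cohort-median OAR median dose in Gy before
    modality factors (for plateau structures: the low-dose bath half-dose);
    ``log_sigma`` the inter-patient lognormal spread; volumes in cm³.
    """

    name: str
    baseline_d50: float
    log_sigma: float
    volume_cm3: float
    volume_log_sigma: float
    plateau_weight: float | None = None  # fraction of volume in the high-dose part
    plateau_high_d50: float = 40.0  # centre of the high-dose component, Gy

    def __post_init__(self) -> None:
        if self.name != "ctv" and self.baseline_d50 <= 0:
            raise ValueError("baseline_d50 must be positive")
        if self.volume_cm3 <= 0:
            raise ValueError("volume_cm3 must be positive")
        if self.plateau_weight is not None and not 0 <= self.plateau_weight < 1:
            raise ValueError("plateau_weight must lie in [0, 1)")


@dataclass(frozen=True)
class ModalityProfile:
    """Modality-level dials: CTV spread, per-structure D50 factors, gradient."""

    modality: str
    ctv_spread: float  # Gy, controls the width of the CTV sigmoid
    oar_gradient: float  # 1/Gy, steepness of the OAR falloff
    oar_d50_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ctv_spread <= 0:
            raise ValueError("ctv_spread must be positive")
        if self.oar_gradient <= 0:
            raise ValueError("oar_gradient must be positive")
        if any(f <= 0 for f in self.oar_d50_factor.values()):
            raise ValueError("oar_d50_factor entries must be positive")

    def factor(self, structure: str) -> float:
        return self.oar_d50_factor.get(structure, 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort/simulation configuration; defaults reproduce the study schedule."""

    n_patients: int = 15
    seed: int = 0
    prescription_dose: float = 54.0
    n_fractions: int = 30
    dose_per_fraction: float = 1.8
    bin_width: float = 0.1  # Gy; <= 0.2% of prescription
    structures: tuple[StructureSpec, ...] = ()
    profiles: tuple[ModalityProfile, ...] = ()

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(self.n_fractions * self.dose_per_fraction - self.prescription_dose) > 1e-9:
            raise ValueError("schedule must satisfy n_fractions × dose_per_fraction = prescription")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def profile(self, modality: str) -> ModalityProfile:
        for p in self.profiles:
            if p.modality == modality:
                return p
        raise KeyError(modality)


@dataclass(frozen=True)
class VoxelPhantom:
    """Per-structure voxel dose arrays used as a brute-force oracle.

    Voxels are equal-sized within a structure; ``voxel_volumes[s] ×
    len(doses[s])`` equals the structure's absolute volume.
    """

    patient_id: str
    modality: str
    doses: dict[str, np.ndarray]
    voxel_volumes: dict[str, float]


# ----------------------------------------------------------------------
# Default study emulation

_DEFAULT_STRUCTURES = (
    StructureSpec("ctv", float("nan"), 0.0, 60.0, 0.30),
    StructureSpec("hippocampus_il", 21.0, 0.45, 1.3, 0.25),
    StructureSpec("hippocampus_cl", 18.0, 0.45, 1.3, 0.25),
    StructureSpec("inner_ear_il", 34.0, 0.25, 1.1, 0.20),
    StructureSpec("inner_ear_cl", 20.0, 0.40, 1.1, 0.20),
    StructureSpec("pituitary", 15.0, 0.50, 0.16, 0.25),
    StructureSpec("brainstem", 40.0, 0.12, 19.0, 0.20),
    StructureSpec("brain", 1.35, 0.40, 1295.0, 0.15, plateau_weight=0.20, plateau_high_d50=45.0),
    StructureSpec("skin", 0.50, 0.40, 700.0, 0.15, plateau_weight=0.04, plateau_high_d50=40.0),
)

_DEFAULT_PROFILES = (
    ModalityProfile(
        "photon",
        ctv_spread=0.55,
        oar_gradient=0.35,
        oar_d50_factor={},  # photon is the baseline scale
    ),
    ModalityProfile(
        "proton",
        ctv_spread=0.45,
        oar_gradient=0.50,
        oar_d50_factor={
            "hippocampus_il": 0.95,
            "hippocampus_cl": 0.83,
            "inner_ear_il": 0.85,
            "inner_ear_cl": 0.85,
            "pituitary": 0.80,
            "brainstem": 0.96,
            "brain": 0.26,
            "skin": 0.60,
        },
    ),
    ModalityProfile(
        "helium",
        ctv_spread=0.30,
        oar_gradient=0.70,
        oar_d50_factor={
            "hippocampus_il": 0.71,
            "hippocampus_cl": 0.61,
            "inner_ear_il": 0.68,
            "inner_ear_cl": 0.55,
            "pituitary": 0.60,
            "brainstem": 0.92,
            "brain": 0.075,
            "skin": 0.40,
        },
    ),
)


def default_config(n_patients: int = 15, seed: int = 0) -> CohortConfig:
    """The study-emulation configuration (15 patients, 54 Gy in 30 × 1.8 Gy)."""
    return CohortConfig(
        n_patients=n_patients,
        seed=seed,
        structures=_DEFAULT_STRUCTURES,
        profiles=_DEFAULT_PROFILES,
    )


# ----------------------------------------------------------------------
# Random effects

def _rng_for(seed: int, patient_idx: int, structure: str) -> np.random.Generator:
    """Per-(patient, structure) substream; stable under structure-list edits."""
    code = zlib.crc32(structure.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(patient_idx, code)))


@dataclass(frozen=True)
class _PatientEffects:
    d50_multiplier: float
    volume_multiplier: float
    ctv_spread_multiplier: float
    plateau_high_multiplier: float


def _draw_effects(config: CohortConfig, patient_idx: int, spec: StructureSpec) -> _PatientEffects:
    rng = _rng_for(config.seed, patient_idx, spec.name)
    # fixed draw order: D50 effect, volume effect, CTV spread jitter, plateau jitter
    d50_mult = float(np.exp(rng.normal(0.0, spec.log_sigma))) if spec.log_sigma > 0 else 1.0
    vol_mult = float(np.exp(rng.normal(0.0, spec.volume_log_sigma)))
    spread_mult = float(np.exp(rng.normal(0.0, 0.10)))
    high_mult = float(np.exp(rng.normal(0.0, 0.05)))
    # the patient effect (shared across modalities) is capped so that even
    # the largest modality factor keeps the falloff inside the plan range;
    # capping the shared effect, not the per-modality D50, preserves the
    # paired ratio between modalities exactly
    if spec.name != "ctv":
        max_factor = max(p.factor(spec.name) for p in config.profiles)
        cap = 0.92 * config.prescription_dose / (spec.baseline_d50 * max_factor)
        d50_mult = min(d50_mult, cap)
    return _PatientEffects(d50_mult, vol_mult, spread_mult, high_mult)


# ----------------------------------------------------------------------
# Curve families

def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(expm1(x)) without overflow (≈ x for large x)."""
    x = np.asarray(x, dtype=float)
    small = x < 30.0
    out = np.where(small, np.log(np.expm1(np.where(small, x, 1.0))), x)
    return out


def _falloff(dose: np.ndarray, d50: float, gradient: float) -> np.ndarray:
    """Normalized falloff: exactly 1 at D = 0 and exactly 0.5 at D = d50."""
    v = np.empty_like(dose)
    pos = dose > 0
    v[~pos] = 1.0
    v[pos] = expit(-(_log_expm1(gradient * dose[pos]) - _log_expm1(gradient * d50)))
    return v


def _ctv_curve(config: CohortConfig, spread: float, dose: np.ndarray) -> np.ndarray:
    dp = config.prescription_dose
    # cap the spread so D95 >= 0.95 Dp holds for every draw:
    # v(0.95 Dp) >= 0.95  <=>  s <= 0.05 Dp / ln 19
    s_max = 0.05 * dp / np.log(19.0) * 0.999
    s = min(spread, s_max)
    v = expit(-(dose - dp) / s)
    v[dose == 0] = 1.0
    return v


def _oar_curve(
    spec: StructureSpec,
    d50: float,
    profile: ModalityProfile,
    dose: np.ndarray,
    high_mult: float = 1.0,
) -> np.ndarray:
    if spec.plateau_weight is None:
        return _falloff(dose, d50, profile.oar_gradient)
    w = spec.plateau_weight
    high = _falloff(dose, spec.plateau_high_d50 * high_mult, profile.oar_gradient)
    bath = np.power(2.0, -dose / d50)  # low-dose plateau, half-dose at λ = d50
    return w * high + (1.0 - w) * bath


# ----------------------------------------------------------------------
# Generation

def generate_plan(config: CohortConfig, patient_idx: int, modality: str) -> PlanSet:
    """One patient's plan under one modality (deterministic in (seed, idx))."""
    profile = config.profile(modality)
    patient_id = f"P{patient_idx + 1:02d}"
    dp = config.prescription_dose
    h = config.bin_width

    oar_edges = np.round(np.arange(0.0, dp + h / 2, h), 10)
    ctv_top = dp + 8.0 * max(p.ctv_spread for p in config.profiles)
    ctv_edges = np.round(np.arange(0.0, ctv_top + h / 2, h), 10)

    curves = {}
    for spec in config.structures:
        eff = _draw_effects(config, patient_idx, spec)
        abs_volume = spec.volume_cm3 * eff.volume_multiplier
        if spec.name == "ctv":
            spread = profile.ctv_spread * eff.ctv_spread_multiplier
            v = _ctv_curve(config, spread, ctv_edges)
            edges = ctv_edges
        else:
            d50 = spec.baseline_d50 * eff.d50_multiplier * profile.factor(spec.name)
            v = _oar_curve(spec, d50, profile, oar_edges, eff.plateau_high_multiplier)
            edges = oar_edges
        v = v.copy()
        v[-1] = 0.0  # truncate: no volume at or above the top edge
        curves[spec.name] = DVHCurve(
            patient_id=patient_id,
            modality=modality,
            structure=spec.name,
            kind="cumulative",
            dose_edges=edges,
            volume=v,
            abs_volume=abs_volume,
        )
    return PlanSet(
        patient_id=patient_id,
        modality=modality,
        prescription_dose=dp,
        n_fractions=config.n_fractions,
        dose_per_fraction=config.dose_per_fraction,
        curves=curves,
    )


def generate_cohort(config: CohortConfig) -> list[PlanSet]:
    """All n_patients × 3 plans; fixed seed gives identical output."""
    if not config.structures or not config.profiles:
        raise ValueError("config must define structures and modality profiles")
    return [
        generate_plan(config, i, profile.modality)
        for i in range(config.n_patients)
        for profile in config.profiles
    ]


def generate_voxel_phantom(
    config: CohortConfig, patient_idx: int, modality: str, n_voxels: int = 20_000
) -> VoxelPhantom:
    """Voxel-dose oracle for one plan.

    Voxel doses are stratified inverse-CDF samples of the generated
    cumulative DVH (one voxel per equal volume stratum), so the empirical
    cumulative DVH matches the curve within one bin width everywhere and
    the voxel mean matches the DVH mean dose.
    """
    from .dosimetry import doses_at_volumes  # local import to avoid a cycle

    plan = generate_plan(config, patient_idx, modality)
    doses: dict[str, np.ndarray] = {}
    voxel_volumes: dict[str, float] = {}
    u = (np.arange(n_voxels) + 0.5) / n_voxels * 100.0
    for label in plan.structures:
        curve = plan[label]
        doses[label] = doses_at_volumes(curve, u)
        voxel_volumes[label] = curve.abs_volume / n_voxels
    return VoxelPhantom(
        patient_id=plan.patient_id, modality=modality, doses=doses, voxel_volumes=voxel_volumes
    )
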