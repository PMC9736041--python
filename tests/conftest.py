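import numpy as np
import pytest

from dvhcompare.curves import DVHCurve, PlanSet
from dvhcompare.simulate import default_config


def make_curve(edges, volumes, kind="cumulative", structure="ctv", modality="photon",
               patient="T01", abs_volume=float("nan")):
    return DVHCurve(
        patient_id=patient,
        modality=modality,
        structure=structure,
        kind=kind,
        dose_edges=np.asarray(edges, dtype=float),
        volume=np.asarray(volumes, dtype=float),
        abs_volume=abs_volume,
    )


def uniform_curve(dose, half_width=1e-9, **kw):
    """Whole volume at a single dose level (step DVH with a tiny bin)."""
    return make_curve([dose - half_width, dose + half_width], [1.0, 0.0], **kw)


def partial_volume_curve(dose, v, **kw):
    """Fraction ``v`` at ``dose``, the rest at (numerically) zero dose."""
    edges = [0.0, 1e-12, dose - 1e-9, dose + 1e-9]
    fractions = [1.0 - v, 0.0, v]
    return make_curve(edges, fractions, kind="differential", **kw)


def make_plan(curves, patient="T01", modality="photon", prescription=54.0):
    return PlanSet(
        patient_id=patient,
        modality=modality,
        prescription_dose=prescription,
        n_fractions=30,
        dose_per_fraction=prescription / 30,
        curves={c.structure: c for c in curves},
    )


@pytest.fixture(scope="session")
def study_config():
    return default_config(n_patients=15, seed=11)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    from dvhcompare.simulate import generate_cohort

    return generate_cohort(study_config)
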