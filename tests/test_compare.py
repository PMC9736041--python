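"""Paired comparison model: relative differences, exclusions, summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dvhcompare.compare import (
    ModalityComparison,
    apply_exclusion_rules,
    relative_difference,
)
from dvhcompare.dosimetry import metric_battery
from dvhcompare.simulate import default_config, generate_cohort


def frame_from(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "modality", "structure", "metric", "value"]
    )


def synthetic_metric_frame(n=10, effect=(0.6, 0.8, 1.0), base=20.0, seed=0):
    """Paired values: patient baseline × modality factor (no noise across modalities)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        patient_base = base * rng.lognormal(0, 0.3)
        for modality, factor in zip(("helium", "proton", "photon"), effect):
            rows.append((f"P{i}", modality, "organ", "D50", patient_base * factor))
    return frame_from(rows)


class TestPrimitives:
    def test_relative_difference_values(self):
        assert relative_difference(15.0, 20.0) == pytest.approx(-25.0)
        assert relative_difference(20.0, 20.0) == 0.0
        assert relative_difference(10.0, 20.0) < 0  # negative whenever a < b

    def test_exclusion_rule_examples(self):
        retained, na = apply_exclusion_rules(np.array([[0.5, 0.8, 0.9]]))
        assert not retained[0]
        retained, na = apply_exclusion_rules(np.array([[0.5, 1.2, 2.0]]))
        assert retained[0]

    def test_row_not_applicable_above_five(self):
        values = np.ones((15, 3)) * 5.0
        values[:6] = 0.5  # six patients below 1 Gy everywhere
        retained, na = apply_exclusion_rules(values)
        assert (~retained).sum() == 6
        assert na
        values[5] = 5.0  # exactly five excluded: still applicable
        retained, na = apply_exclusion_rules(values)
        assert (~retained).sum() == 5
        assert not na

    def test_exclusion_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 3, size=(12, 3))
        r1, na1 = apply_exclusion_rules(values)
        perm = rng.permutation(12)
        r2, na2 = apply_exclusion_rules(values[perm])
        assert np.array_equal(r1[perm], r2)
        assert na1 == na2
        r3, _ = apply_exclusion_rules(values[r1])
        assert r3.all()  # re-applying to retained rows excludes nothing


class TestModel:
    def test_constant_multiplicative_effect_recovered_exactly(self):
        results = ModalityComparison(synthetic_metric_frame()).fit()
        row = results.row("organ", "D50")
        c = row.contrast("helium_vs_proton")
        assert c.diff_mean == pytest.approx((0.6 / 0.8 - 1) * 100, abs=1e-9)
        assert c.diff_sem == pytest.approx(0.0, abs=1e-9)
        c2 = row.contrast("proton_vs_photon")
        assert c2.diff_mean == pytest.approx(-20.0, abs=1e-9)

    def test_null_effect_no_significance(self):
        results = ModalityComparison(
            synthetic_metric_frame(effect=(1.0, 1.0, 1.0))
        ).fit()
        row = results.row("organ", "D50")
        for c in row.contrasts:
            assert c.diff_mean == 0.0
            assert c.wilcoxon.degenerate
            assert not c.significant
        assert row.friedman.statistic == 0.0
        assert row.friedman.pvalue == 1.0

    def test_sem_of_constant_column_is_zero(self):
        frame = synthetic_metric_frame(n=6)
        frame.loc[frame.modality == "photon", "value"] = 20.0
        results = ModalityComparison(frame).fit()
        assert results.row("organ", "D50").sems["photon"] == 0.0

    def test_mismatched_patient_sets_raise(self):
        frame = synthetic_metric_frame(n=4)
        frame = frame.drop(frame[(frame.patient_id == "P0") & (frame.modality == "proton")].index)
        with pytest.raises(ValueError, match="mismatched|missing"):
            ModalityComparison(frame).fit()

    def test_pairwise_na_but_friedman_runs(self):
        """Brain-D50-style row: pair below threshold, third modality above."""
        rows = []
        rng = np.random.default_rng(2)
        for i in range(15):
            he, pr = rng.uniform(0.05, 0.3), rng.uniform(0.3, 0.9)
            ph = rng.uniform(1.5, 2.5)
            for modality, v in (("helium", he), ("proton", pr), ("photon", ph)):
                rows.append((f"P{i}", modality, "brain", "D50", v))
        results = ModalityComparison(frame_from(rows)).fit()
        row = results.row("brain", "D50")
        assert row.contrast("helium_vs_proton").not_applicable
        assert np.isnan(row.contrast("helium_vs_proton").diff_mean)
        assert not row.contrast("proton_vs_photon").not_applicable
        assert row.friedman is not None  # not all three below 1 Gy: row retained

    def test_all_modalities_below_threshold_excludes_row(self):
        rows = []
        for i in range(15):
            for modality in ("helium", "proton", "photon"):
                rows.append((f"P{i}", modality, "skin", "D50", 0.2 + 0.01 * i))
        results = ModalityComparison(frame_from(rows)).fit()
        row = results.row("skin", "D50")
        assert row.excluded_row
        assert row.friedman is None
        for c in row.contrasts:
            assert np.isnan(c.diff_mean)

    def test_threshold_not_applied_to_ntcp(self):
        rows = []
        for i in range(8):
            for modality, v in (("helium", 0.001), ("proton", 0.003), ("photon", 0.006)):
                rows.append((f"P{i}", modality, "pituitary", "endocrine", v + i * 1e-4))
        results = ModalityComparison(frame_from(rows), kind="ntcp").fit()
        row = results.row("pituitary", "endocrine")
        c = row.contrast("helium_vs_proton")
        assert c.kind == "absolute"
        assert c.diff_mean == pytest.approx(-0.002, abs=1e-12)
        assert not c.not_applicable


class TestCohortLevel:
    def test_oar_ordering_and_signs_on_default_cohort(self, study_cohort):
        records = [r for plan in study_cohort for r in metric_battery(plan)]
        results = ModalityComparison.from_metric_records(records).fit()
        for row in results.rows:
            if row.structure == "ctv":
                continue
            assert row.means["helium"] < row.means["proton"] < row.means["photon"]
            c = row.contrast("helium_vs_proton")
            if not c.not_applicable:
                assert c.diff_mean < 0
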