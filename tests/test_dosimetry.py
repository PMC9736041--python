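"""Dosimetric indices: hand-derived values, quantile ordering, voxel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvhcompare.curves import DVHValidationError
from dvhcompare.dosimetry import (
    d_mean,
    dose_at_volume,
    doses_at_volumes,
    homogeneity_index,
    inhomogeneity_coefficient,
    integral_dose,
    metric_battery,
    volume_at_dose,
)
from dvhcompare.simulate import default_config, generate_plan, generate_voxel_phantom

from conftest import make_curve, make_plan, uniform_curve


class TestDoseAtVolume:
    def test_uniform_dose(self):
        assert dose_at_volume(uniform_curve(54.0), 50) == pytest.approx(54.0, abs=1e-9)

    def test_hand_interpolation(self):
        c = make_curve([0, 20, 40], [1.0, 0.5, 0.0])
        assert dose_at_volume(c, 25) == pytest.approx(30.0)

    def test_exact_tie_resolves_to_highest_dose(self):
        c = make_curve([0, 10, 20, 30], [1.0, 0.5, 0.5, 0.0])
        assert dose_at_volume(c, 50) == 20.0

    def test_out_of_range_and_kind_errors(self):
        c = make_curve([0, 20, 40], [1.0, 0.5, 0.0])
        with pytest.raises(ValueError):
            dose_at_volume(c, 0)
        with pytest.raises(ValueError):
            dose_at_volume(c, 101)
        with pytest.raises(DVHValidationError):
            dose_at_volume(c.as_differential(), 50)

    def test_nonincreasing_in_x(self):
        c = make_curve([0, 5, 20, 40, 41], [1.0, 0.9, 0.5, 0.05, 0.0])
        xs = np.linspace(0.5, 100, 200)
        doses = doses_at_volumes(c, xs)
        assert np.all(np.diff(doses) <= 1e-12)
        # scalar and vectorized paths agree
        assert doses[3] == dose_at_volume(c, xs[3])


class TestMeanAndIndices:
    def test_d_mean_weighted(self):
        c = make_curve([0, 10, 20], [0.6, 0.4], kind="differential")
        assert d_mean(c) == pytest.approx(9.0)

    def test_d_mean_uniform(self):
        assert d_mean(uniform_curve(12.5)) == pytest.approx(12.5, abs=1e-9)

    def test_hi_hand_value(self):
        # D5 = 55, D95 = 53 as exact curve points, prescription 54
        c = make_curve([0, 53, 55, 56], [1.0, 0.95, 0.05, 0.0])
        assert homogeneity_index(c, 54.0) == pytest.approx(2.0 / 54.0 * 100, abs=1e-9)

    def test_hi_zero_on_uniform_and_scale_invariant(self):
        u = uniform_curve(54.0)
        assert homogeneity_index(u, 54.0) == pytest.approx(0.0, abs=1e-6)
        c = make_curve([0, 53, 55, 56], [1.0, 0.95, 0.05, 0.0])
        k = 1.7
        scaled = make_curve([0, 53 * k, 55 * k, 56 * k], [1.0, 0.95, 0.05, 0.0])
        assert homogeneity_index(scaled, 54.0 * k) == pytest.approx(
            homogeneity_index(c, 54.0)
        )

    def test_ic_hand_value(self):
        # Dmin 52, Dmax 56, Dmean ~ 54
        c = make_curve([0, 52, 54, 56, 58], [1.0, 1.0, 0.5, 1e-6, 0.0])
        assert inhomogeneity_coefficient(c) == pytest.approx(4.0 / 54.0, abs=1e-4)

    def test_ic_zero_on_uniform_and_nonnegative(self):
        assert inhomogeneity_coefficient(uniform_curve(30.0)) == 0.0
        c = make_curve([0, 5, 20, 40, 41], [1.0, 0.9, 0.5, 0.05, 0.0])
        assert inhomogeneity_coefficient(c) >= 0

    def test_integral_dose_product_and_additivity(self):
        c = uniform_curve(10.0, abs_volume=50.0)
        assert integral_dose(c) == pytest.approx(500.0, abs=1e-6)
        # additivity over a disjoint partition at equal density
        half = uniform_curve(10.0, abs_volume=25.0)
        assert integral_dose(half) * 2 == pytest.approx(integral_dose(c), abs=1e-6)
        with pytest.raises(DVHValidationError):
            integral_dose(uniform_curve(10.0))  # no volume metadata

    def test_integral_dose_linear_in_dose_scale(self):
        c = make_curve([0, 10, 20], [1.0, 0.4, 0.0], abs_volume=30.0)
        c2 = make_curve([0, 20, 40], [1.0, 0.4, 0.0], abs_volume=30.0)
        assert integral_dose(c2) == pytest.approx(2 * integral_dose(c))


class TestBattery:
    def test_uniform_plan_collapses(self):
        plan = make_plan(
            [
                uniform_curve(54.0, structure="ctv", abs_volume=60.0),
                uniform_curve(12.0, structure="pituitary", abs_volume=0.2),
            ]
        )
        recs = {(r.structure, r.metric): r.value for r in metric_battery(plan)}
        assert recs[("ctv", "D1")] == pytest.approx(recs[("ctv", "D95")], abs=1e-6)
        assert recs[("ctv", "Dmean")] == pytest.approx(54.0, abs=1e-6)
        assert recs[("ctv", "HI")] == pytest.approx(0.0, abs=1e-6)
        assert recs[("ctv", "IC")] == pytest.approx(0.0, abs=1e-9)
        assert recs[("pituitary", "D50")] == pytest.approx(12.0, abs=1e-6)

    def test_quantile_ordering_on_cohort(self, study_cohort):
        for plan in study_cohort[:6]:
            for label in plan.structures:
                c = plan[label]
                d = doses_at_volumes(c, [1, 5, 50, 95, 99])
                assert np.all(np.diff(d) <= 1e-12)  # D1 >= D5 >= D50 >= D95 >= D99


class TestVoxelOracle:
    @pytest.mark.parametrize("modality", ["photon", "helium"])
    def test_dvh_metrics_match_voxel_brute_force(self, modality):
        config = default_config(seed=2)
        plan = generate_plan(config, 1, modality)
        phantom = generate_voxel_phantom(config, 1, modality)
        for label in plan.structures:
            doses = phantom.doses[label]
            curve = plan[label]
            assert abs(d_mean(curve) - doses.mean()) < 0.5 * config.bin_width
            assert abs(dose_at_volume(curve, 50) - np.median(doses)) < 0.5 * config.bin_width

    def test_phantom_ecdf_matches_curve(self):
        """Binned voxel DVH equals the generated curve within one bin width."""
        config = default_config(seed=4)
        phantom = generate_voxel_phantom(config, 0, "proton", n_voxels=5000)
        plan = generate_plan(config, 0, "proton")
        h = config.bin_width
        for label in ("ctv", "brainstem", "brain"):
            curve = plan[label]
            doses = phantom.doses[label]
            n = doses.size
            for edge in curve.dose_edges[::7]:
                v_emp = np.mean(doses >= edge)
                lo = volume_at_dose(curve, edge + h) - 1.0 / n
                hi = volume_at_dose(curve, min(edge, curve.dose_edges[-1]) - h) + 1.0 / n
                assert lo <= v_emp <= hi

    def test_phantom_volume_bookkeeping(self):
        config = default_config(seed=4)
        phantom = generate_voxel_phantom(config, 0, "proton", n_voxels=1000)
        plan = generate_plan(config, 0, "proton")
        for label, doses in phantom.doses.items():
            assert doses.min() >= 0
            assert len(doses) * phantom.voxel_volumes[label] == pytest.approx(
                plan[label].abs_volume
            )
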