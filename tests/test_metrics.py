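"""DVH, V_x/D_x, HI, CI and the constraint checker."""

import numpy as np
import pytest

import opaplan as op
from opaplan.errors import DomainError, MeasurementError, MissingMetricError

from helpers import brute_force_vx


def make_grid(values):
    values = np.asarray(values, dtype=float)
    return op.VolumeGrid(values, (5.0, 5.0, 5.0))


def full_mask(grid):
    return np.ones(grid.shape, dtype=bool)


# --- DVH -------------------------------------------------------------------

def test_uniform_dose_gives_step_dvh():
    grid = make_grid(np.full((4, 4, 4), 10.0))
    dvh = op.compute_dvh(grid, full_mask(grid))
    assert dvh.volume_pct[0] == 100.0
    below = dvh.dose_edges_gy <= 10.0
    assert np.all(dvh.volume_pct[below] == 100.0)
    assert np.all(dvh.volume_pct[~below] == 0.0)


def test_half_and_half_dose_gives_v5_of_50():
    values = np.full((4, 4, 4), 4.0)
    values[:2] = 6.0
    dvh = op.compute_dvh(make_grid(values), full_mask(values))
    assert op.V_at_dose(dvh, 5.0) == pytest.approx(50.0)


def test_vx_matches_brute_force_voxel_count(rng):
    values = rng.gamma(4.0, 4.0, size=(12, 12, 12))
    grid = make_grid(values)
    mask = rng.random(grid.shape) < 0.6
    dvh = op.compute_dvh(grid, mask, bin_width_gy=0.05)
    for x in (5.0, 10.0, 15.0, 20.0):
        direct = brute_force_vx(values, mask, x)
        # agreement within one 0.05 Gy bin of volume change
        span = abs(op.V_at_dose(dvh, x - 0.05) - op.V_at_dose(dvh, x + 0.05))
        assert abs(op.V_at_dose(dvh, x) - direct) <= span + 1e-9


def test_dvh_is_monotone_and_bounded(rng):
    values = rng.exponential(8.0, size=(10, 10, 10))
    dvh = op.compute_dvh(make_grid(values), full_mask(values))
    assert np.all(np.diff(dvh.volume_pct) <= 1e-12)
    assert dvh.volume_pct[0] == 100.0 and dvh.volume_pct[-1] == 0.0


def test_empty_mask_raises_with_structure_name():
    grid = make_grid(np.zeros((3, 3, 3)))
    with pytest.raises(MeasurementError, match="HEART"):
        op.compute_dvh(grid, np.zeros(grid.shape, bool), structure="HEART")


# --- V_at_dose / D_at_volume ----------------------------------------------

def test_v_at_dose_examples():
    uniform = op.compute_dvh(make_grid(np.full((4, 4, 4), 10.0)),
                             np.ones((4, 4, 4), bool))
    assert op.V_at_dose(uniform, 5.0) == 100.0
    assert op.V_at_dose(uniform, 0.0) == 100.0
    capped = op.compute_dvh(make_grid(np.full((4, 4, 4), 15.0)),
                            np.ones((4, 4, 4), bool))
    assert op.V_at_dose(capped, 20.0) == 0.0


def test_v_at_dose_interpolation_matches_refined_bins(rng):
    values = rng.normal(20.0, 5.0, size=(14, 14, 14)).clip(0.0)
    grid = make_grid(values)
    mask = full_mask(values)
    coarse = op.compute_dvh(grid, mask, bin_width_gy=0.05)
    fine = op.compute_dvh(grid, mask, bin_width_gy=0.005)
    for x in (5.0, 12.3, 19.97, 25.01):
        assert op.V_at_dose(coarse, x) == pytest.approx(op.V_at_dose(fine, x), abs=0.5)


def test_d_at_volume_examples():
    uniform = op.compute_dvh(make_grid(np.full((5, 5, 5), 45.0)),
                             np.ones((5, 5, 5), bool))
    assert op.D_at_volume(uniform, 95.0) == pytest.approx(45.0, abs=0.05)
    values = np.linspace(10.0, 30.0, 125).reshape(5, 5, 5)
    dvh = op.compute_dvh(make_grid(values), np.ones((5, 5, 5), bool))
    assert op.D_at_volume(dvh, 100.0) == pytest.approx(10.0, abs=0.2)


def test_dx_on_linear_ramp_matches_closed_form():
    # dose uniform in volume from 40 to 50 Gy: D_v = 50 - v/10
    n = 200_000
    values = np.linspace(40.0, 50.0, n).reshape(50, 80, 50)
    dvh = op.compute_dvh(make_grid(values), np.ones(values.shape, bool),
                         bin_width_gy=0.05)
    assert op.D_at_volume(dvh, 5.0) == pytest.approx(49.5, abs=0.06)
    assert op.D_at_volume(dvh, 95.0) == pytest.approx(40.5, abs=0.06)


def test_vx_dx_inverse_consistency(rng):
    values = np.sort(rng.uniform(0.0, 40.0, size=(10, 10, 10)).ravel()).reshape(10, 10, 10)
    dvh = op.compute_dvh(make_grid(values), np.ones((10, 10, 10), bool))
    for d in (5.0, 17.5, 33.0):
        v = op.V_at_dose(dvh, d)
        if 0.0 < v <= 100.0:
            assert op.D_at_volume(dvh, v) == pytest.approx(d, abs=0.051)  # one bin


# --- HI / CI ---------------------------------------------------------------

def test_hi_is_one_for_uniform_dose():
    dvh = op.compute_dvh(make_grid(np.full((6, 6, 6), 45.0)), np.ones((6, 6, 6), bool))
    hi = op.homogeneity_index(dvh)
    assert hi.value == pytest.approx(1.0, abs=0.01)
    assert hi.acceptable


def test_hi_on_ramp_matches_closed_form():
    values = np.linspace(40.0, 50.0, 200_000).reshape(50, 80, 50)
    dvh = op.compute_dvh(make_grid(values), np.ones(values.shape, bool))
    hi = op.homogeneity_index(dvh)
    assert hi.value == pytest.approx(49.5 / 40.5, abs=0.01)


def test_hi_undefined_for_zero_d95():
    values = np.zeros((6, 6, 6))
    values[:1] = 50.0  # only ~17% of volume dosed
    dvh = op.compute_dvh(make_grid(values), np.ones((6, 6, 6), bool))
    with pytest.raises(DomainError):
        op.homogeneity_index(dvh)


def test_ci_exact_coverage_is_one():
    values = np.zeros((10, 10, 10))
    ptv = np.zeros((10, 10, 10), bool)
    ptv[3:7, 3:7, 3:7] = True
    values[ptv] = 45.0
    ci = op.conformity_index(make_grid(values), ptv, 45.0)
    assert ci.value == 1.0 and ci.acceptable


def test_ci_equal_volume_shell_gives_two():
    values = np.zeros((10, 10, 10))
    ptv = np.zeros((10, 10, 10), bool)
    ptv[0:2] = True  # 200 voxels
    shell = np.zeros_like(ptv)
    shell[4:6] = True  # 200 more voxels
    values[ptv | shell] = 45.0
    ci = op.conformity_index(make_grid(values), ptv, 45.0)
    assert ci.value == 2.0
    assert ci.acceptable and not ci.tolerable  # 2.0 closes the acceptable band
    assert op.conformity_index(make_grid(values), ptv, 44.0).value == 2.0


def test_ci_matches_brute_force_counting(rng):
    values = rng.uniform(0.0, 60.0, size=(12, 12, 12))
    ptv = rng.random((12, 12, 12)) < 0.2
    ptv[0, 0, 0] = True
    ci = op.conformity_index(make_grid(values), ptv, 45.0)
    expected = np.count_nonzero(values >= 45.0) / np.count_nonzero(ptv)
    assert ci.value == pytest.approx(expected)


# --- constraints -----------------------------------------------------------

def test_constraint_comparator_semantics():
    table = op.ConstraintTable(rows=[
        op.Constraint("LUNG_WHOLE", "V5_pct", "<=", 55.0),
        op.Constraint("HEART", "V40_pct", "<", 50.0),
    ])
    verdicts = op.evaluate_constraints(
        {"LUNG_WHOLE": {"V5_pct": 55.0}, "HEART": {"V40_pct": 50.0}}, table)
    assert verdicts[0].passed          # boundary passes under <=
    assert not verdicts[1].passed      # boundary fails under strict <


def test_missing_metric_raises_not_passes():
    table = op.ConstraintTable(rows=[op.Constraint("CORD", "max_dose_gy", "<", 45.0)])
    with pytest.raises(MissingMetricError):
        op.evaluate_constraints({"CORD": {}}, table)


def test_default_table_covers_all_clinical_rows():
    table = op.default_constraint_table()
    assert len(table.rows) == 18
    lung_rows = [r for r in table.rows if r.structure.startswith("LUNG")]
    assert len(lung_rows) == 15  # mean + 4 V-levels for whole/right/left


def test_reference_plan_metrics_pass_all_constraints():
    """Published mean dosimetric outcomes of constrained full-arc plans,
    entered as a fixture metric set, satisfy every planning constraint."""
    metrics = {
        "CORD": {"max_dose_gy": 36.92},
        "HEART": {"mean_dose_gy": 20.76, "V40_pct": 12.54},
        "LUNG_WHOLE": {"mean_dose_gy": 10.37, "V20_pct": 18.11, "V15_pct": 23.75,
                       "V10_pct": 30.89, "V5_pct": 48.55},
        "LUNG_R": {"mean_dose_gy": 9.81, "V20_pct": 16.75, "V15_pct": 21.79,
                   "V10_pct": 29.25, "V5_pct": 45.71},
        "LUNG_L": {"mean_dose_gy": 10.95, "V20_pct": 19.25, "V15_pct": 24.93,
                   "V10_pct": 32.79, "V5_pct": 50.46},
    }
    verdicts = op.evaluate_constraints(metrics)
    assert len(verdicts) == 18
    assert all(v.passed for v in verdicts)


def test_simulated_fa_plan_report(coarse_thorax):
    dose = op.simulate_dose(coarse_thorax, op.sequence_full_arcs())
    report = op.plan_report(dose, coarse_thorax, "FA")
    assert report.hi.acceptable  # simulated full-arc plan is homogeneous
    assert set(report.structures) >= {"PTV", "LUNG_WHOLE", "HEART", "CORD"}
    assert report.to_dict()["plan_type"] == "FA"
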