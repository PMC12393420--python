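"""Concentration response, half-max extraction, knockout screen, dose table."""

import numpy as np
import pandas as pd
import pytest

from dyrknet import (
    DoseResponseCurve,
    Perturbation,
    concentration_response,
    dose_simulation,
    estimate_half_max,
    generate_cascade,
    knockdown_screen,
)


def test_grid_has_101_points_and_starts_at_baseline(dyrk1a_curve, baseline):
    assert dyrk1a_curve.grid.size == 101
    assert dyrk1a_curve.converged.all()
    np.testing.assert_allclose(
        dyrk1a_curve.activities.iloc[:, 0].to_numpy(),
        baseline.state.to_numpy(),
        atol=1e-9,
    )


def test_dna_replication_is_monotone_along_the_grid(dyrk1a_curve):
    dna = dyrk1a_curve.activities.loc["DNA_replication"].to_numpy()
    assert np.all(np.diff(dna) >= -1e-9)


def test_normalized_endpoints_are_zero_and_one(dyrk1a_curve):
    nrm = dyrk1a_curve.normalized
    responding = nrm.dropna(how="all").index
    assert "DNA_replication" in responding and "pLIN52" in responding
    for sid in responding:
        assert nrm.loc[sid].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert nrm.loc[sid].iloc[-1] == pytest.approx(1.0, abs=1e-12)
    # inputs other than the target do not respond
    assert nrm.loc["CDK2"].isna().all()


def test_half_max_linear_interpolation_rule():
    """Normalized 0.45 at k=0.20 and 0.55 at k=0.21 interpolates to 0.205."""
    grid = np.array([0.0, 0.20, 0.21, 1.0])
    acts = pd.DataFrame(
        {0.0: [0.0], 0.20: [0.45], 0.21: [0.55], 1.0: [1.0]}, index=["X"]
    )
    curve = DoseResponseCurve(
        target="T", grid=grid, activities=acts, converged=np.ones(4, bool)
    )
    assert estimate_half_max(curve, "X") == pytest.approx(0.205)


def test_half_max_undefined_for_non_responders(dyrk1a_curve):
    assert estimate_half_max(dyrk1a_curve, "CDK2") is None
    assert dyrk1a_curve.half_max["CDK2"] is None


def test_half_max_unique_for_monotone_curves(dyrk1a_curve):
    """Monotone responses cross 0.5 exactly once; the estimate brackets it."""
    k = dyrk1a_curve.half_max["DNA_replication"]
    nrm = dyrk1a_curve.normalized.loc["DNA_replication"].to_numpy()
    crossings = np.sum(np.diff(np.sign(nrm - 0.5)) != 0)
    assert crossings == 1
    assert 0.0 < k < 1.0


def test_downstream_nodes_are_more_sensitive(dyrk1a_curve):
    """Half-max knockdown for the output precedes its upstream effectors."""
    hm = dyrk1a_curve.half_max
    assert hm["DNA_replication"] <= hm["pLIN52"]
    assert hm["DNA_replication"] <= hm["CycD"]


def test_grid_refinement_stability(dyrk1a_model, dyrk1a_curve):
    fine = concentration_response(dyrk1a_model, step=0.005)
    for node in ("DNA_replication", "CycD", "pLIN52"):
        assert abs(fine.half_max[node] - dyrk1a_curve.half_max[node]) < 0.005


def test_step_must_divide_one(dyrk1a_model):
    with pytest.raises(ValueError):
        concentration_response(dyrk1a_model, step=0.03)


def test_screen_reference_matches_full_knockdown_grid_point(ko_screen, dyrk1a_curve):
    np.testing.assert_allclose(
        ko_screen.reference.to_numpy(),
        dyrk1a_curve.activities.iloc[:, -1].to_numpy(),
        atol=1e-6,
    )


def test_screen_context_row_is_zero(ko_screen):
    # "zero" up to the steady-state stopping tolerance (<0.05% per window)
    assert np.allclose(ko_screen.deltas.loc["DYRK1A"].to_numpy(), 0.0, atol=1e-4)


def test_screen_e2f_rows_attenuate_dna_replication(ko_screen, baseline):
    rise = ko_screen.reference["DNA_replication"] - baseline.state["DNA_replication"]
    for sid in ("E2F1", "E2F2", "E2F3"):
        assert ko_screen.deltas.loc[sid, "DNA_replication"] <= -0.1 * rise
    for sid in ("CycD", "CycE_CDK2"):
        assert abs(ko_screen.deltas.loc[sid, "DNA_replication"]) < 0.1 * rise


def test_dose_table_contains_requested_doses(dyrk1a_model):
    table = dose_simulation(dyrk1a_model, doses=(0.15, 0.30, 0.45))
    assert list(table.index) == [0.0, 0.15, 0.30, 0.45]
    dna = table["DNA_replication"].to_numpy()
    cycd = table["CycD"].to_numpy()
    assert np.all(np.diff(dna) > 0)
    assert np.all(np.diff(cycd) > 0)


def test_dose_zero_equals_baseline(dyrk1a_model, baseline):
    table = dose_simulation(dyrk1a_model, doses=(0.5,))
    np.testing.assert_allclose(
        table.loc[0.0].to_numpy(), baseline.state.to_numpy(), atol=1e-9
    )


def test_doses_outside_unit_interval_rejected(dyrk1a_model):
    with pytest.raises(ValueError):
        dose_simulation(dyrk1a_model, doses=(1.5,))


def test_analyses_are_deterministic(dyrk1a_model):
    m, _ = generate_cascade(2, input_level=0.8)
    a = dose_simulation(m, target="A0", doses=(0.25, 0.75)).to_csv()
    b = dose_simulation(m, target="A0", doses=(0.25, 0.75)).to_csv()
    assert a == b
    sa = knockdown_screen(m, context=(Perturbation.knockdown("A0", 1.0),)).to_csv()
    sb = knockdown_screen(m, context=(Perturbation.knockdown("A0", 1.0),)).to_csv()
    assert sa == sb
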