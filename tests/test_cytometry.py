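"""Gating, mixture splitting, quadrant calibration and subject vectors."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from mitocohort import cytometry as cy
from mitocohort.cytometry import (
    CalibrationError,
    MissingConditionError,
    RosSplit,
    analyze_subject,
    assemble_vector,
    calibrate_quadrant,
    compute_psi,
    gate_populations,
    split_ros,
)
from mitocohort.synthgen import CytometrySimConfig, LogMixture, simulate_events


# ---------------------------------------------------------------------------
# gating

def test_gate_assignment_accuracy(control_tubes):
    _, tubes = control_tubes
    lym, mono = gate_populations(tubes["basal"])
    assert (lym["true_cell_type"] == "lymphocyte").mean() >= 0.99
    assert (mono["true_cell_type"] == "monocyte").mean() >= 0.99
    truth = tubes["basal"]["true_cell_type"]
    assert len(lym) >= 0.95 * (truth == "lymphocyte").sum()
    assert len(mono) >= 0.95 * (truth == "monocyte").sum()
    # the lymphocyte gate holds no CD14-positive event
    assert not lym["true_cell_type"].eq("monocyte").any()


def test_gate_idempotent(control_tubes):
    _, tubes = control_tubes
    lym, _ = gate_populations(tubes["basal"])
    lym2, mono2 = gate_populations(lym)
    pd.testing.assert_frame_equal(lym, lym2)
    assert len(mono2) == 0


def test_all_monocyte_input_empty_lymph_gate():
    cfg = CytometrySimConfig(seed=1, n_lymph=0, n_mono=2000)
    tab = simulate_events(cfg, "basal")
    lym, mono = gate_populations(tab)
    assert len(lym) == 0 and lym.attrs["low_n"]
    assert len(mono) > 1800


def test_missing_column_raises(control_tubes):
    _, tubes = control_tubes
    with pytest.raises(KeyError):
        gate_populations(tubes["basal"].drop(columns=["CD14"]))


# ---------------------------------------------------------------------------
# ROS splitting

def test_split_recovers_monocyte_fraction_across_seeds():
    pis = []
    for seed in range(6):
        cfg = CytometrySimConfig(seed=seed, n_lymph=0, n_mono=3000)
        tab = simulate_events(cfg, "basal")
        pis.append(split_ros(tab).pi_high)
    assert abs(np.mean(pis) - 0.758) < 0.02


def test_unimodal_population_flagged():
    cfg = replace(CytometrySimConfig(seed=2, n_lymph=6000, n_mono=0),
                  lymph_ros=LogMixture(1.2, 0.12, 1.2, 0.12, 0.0))
    tab = simulate_events(cfg, "basal")
    rs = split_ros(tab)
    assert not rs.bimodal
    assert np.isnan(rs.pi_high)
    assert rs.mfi_high == pytest.approx(tab["FL_green"].mean(), rel=1e-6)


def test_mfi_ratio_for_well_separated_components():
    """Components ~one decade apart give a high/low MFI ratio of 8-10."""
    cfg = CytometrySimConfig(seed=4, n_lymph=0, n_mono=6000)
    rs = split_ros(simulate_events(cfg, "basal"))
    assert rs.bimodal
    assert rs.mfi_high / rs.mfi_low >= 8.0
    assert rs.mfi_high > rs.mfi_low


def test_component_mfi_matches_lognormal_closed_form():
    """Linear-scale component MFI approaches the analytic lognormal mean when
    the components are far apart (truncation negligible)."""
    mix = LogMixture(0.8, 0.10, 2.0, 0.12, 0.6)
    cfg = replace(CytometrySimConfig(seed=8, n_lymph=60000, n_mono=0), lymph_ros=mix)
    rs = split_ros(simulate_events(cfg, "basal"))
    assert rs.mfi_high == pytest.approx(mix.linear_mean("high"), rel=0.02)
    assert rs.mfi_low == pytest.approx(mix.linear_mean("low"), rel=0.02)


def test_split_needs_enough_events(control_tubes):
    _, tubes = control_tubes
    with pytest.raises(ValueError):
        split_ros(tubes["basal"].head(50))


# ---------------------------------------------------------------------------
# membrane potential

def test_quadrant_threshold_between_basal_modes(control_tubes):
    cfg, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    lymc, _ = gate_populations(tubes["CCCP"])
    thr = calibrate_quadrant(lymc, lymb)
    lo = 10 ** cfg.lymph_psi.mu_low
    hi = 10 ** cfg.lymph_psi.mu_high
    assert lo < thr < hi
    psi = compute_psi(lymb, thr, "lymphocyte")
    assert abs(psi.pct_low - 100 * (1 - cfg.lymph_psi.pi_high)) < 2.0


def test_basal_passed_as_cccp_fails(control_tubes):
    _, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    with pytest.raises(CalibrationError):
        calibrate_quadrant(lymb)
    # right condition label but not left-shifted data
    fake = lymb.copy()
    fake["condition"] = "CCCP"
    with pytest.raises(CalibrationError):
        calibrate_quadrant(fake, lymb)


def test_pct_low_extremes(control_tubes):
    _, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    ratio = lymb["FL_red"] / lymb["FL_green"]
    below_all = compute_psi(lymb, ratio.min() / 2, "lymphocyte")
    assert below_all.pct_low == 0.0
    lymc, _ = gate_populations(tubes["CCCP"])
    thr = calibrate_quadrant(lymc, lymb)
    basal = compute_psi(lymb, thr, "lymphocyte")
    cccp = compute_psi(lymc, thr, "lymphocyte")
    assert cccp.pct_low > basal.pct_low  # depolarization raises the low fraction


def test_monocytes_never_split(control_tubes):
    _, tubes = control_tubes
    _, mono = gate_populations(tubes["basal"])
    psi = compute_psi(mono, 1.0, "monocyte")
    assert np.isnan(psi.pct_low)
    assert psi.mean_ratio > 0


def test_zero_intensity_events_excluded(control_tubes):
    _, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    corrupted = lymb.copy()
    corrupted.iloc[:5, corrupted.columns.get_loc("FL_green")] = 0.0
    psi = compute_psi(corrupted, 1.0, "lymphocyte")
    assert psi.n_excluded == 5
    assert psi.n_events == len(corrupted) - 5


# ---------------------------------------------------------------------------
# subject vectors

def _ros(mfi_high, mfi_low=10.0):
    return RosSplit(True, 1.0, 0.5, mfi_low, 1.0, mfi_high, 1.0, 1000)


def test_identical_conditions_give_unit_ratios(control_tubes):
    _, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    rs = split_ros(lymb)
    lymc, _ = gate_populations(tubes["CCCP"])
    thr = calibrate_quadrant(lymc, lymb)
    psi = compute_psi(lymb, thr, "lymphocyte")
    vec = assemble_vector("S", rs, rs, psi, psi, "lymphocyte")
    assert vec.values["b"] == pytest.approx(1.0)
    assert vec.values["d_high"] == pytest.approx(1.0)
    assert vec.values["d_low"] == pytest.approx(1.0)
    assert vec.values["d_low_pct"] == pytest.approx(1.0)


def test_vector_entries_match_hand_computation(control_tubes):
    """All 8 lymphocyte entries recompute from the component statistics."""
    _, tubes = control_tubes
    lymb, _ = gate_populations(tubes["basal"])
    lymp, _ = gate_populations(tubes["PMA"])
    lymc, _ = gate_populations(tubes["CCCP"])
    ros_b, ros_p = split_ros(lymb), split_ros(lymp)
    thr = calibrate_quadrant(lymc, lymb)
    psi_b, psi_c = compute_psi(lymb, thr, "lymphocyte"), compute_psi(lymc, thr, "lymphocyte")
    vec = assemble_vector("S", ros_b, ros_p, psi_b, psi_c, "lymphocyte").values
    assert vec["a"] == ros_b.mfi_high
    assert vec["b"] == pytest.approx(ros_p.mfi_high / ros_b.mfi_high)
    assert vec["c_high"] == psi_b.mean_ratio_high
    assert vec["c_low"] == psi_b.mean_ratio_low
    assert vec["c_low_pct"] == psi_b.pct_low
    assert vec["d_high"] == pytest.approx(psi_b.mean_ratio_high / psi_c.mean_ratio_high)
    assert vec["d_low"] == pytest.approx(psi_b.mean_ratio_low / psi_c.mean_ratio_low)
    assert vec["d_low_pct"] == pytest.approx(psi_c.pct_low / psi_b.pct_low)


def test_missing_condition_raises(control_tubes):
    _, tubes = control_tubes
    with pytest.raises(MissingConditionError):
        analyze_subject({"basal": tubes["basal"]}, "S")
    with pytest.raises(MissingConditionError):
        assemble_vector("S", None, _ros(20), None, None, "monocyte")


def test_analyze_subject_deterministic(control_tubes):
    _, tubes = control_tubes
    a = analyze_subject(tubes, "S")
    b = analyze_subject(tubes, "S")
    for ct in a:
        assert a[ct].values == b[ct].values
    # monocyte vector has 4 entries, lymphocyte 8
    assert len(a["monocyte"].to_series()) == 4
    assert len(a["lymphocyte"].to_series()) == 8
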