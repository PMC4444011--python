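import numpy as np
import pandas as pd
import pytest

from pausewave import (
    RecoveryTimeCourse,
    WaveSimParams,
    compare_conditions,
    estimate_recovery_time,
    fit_elongation_rate,
    normalize_timecourse,
    read_timecourse,
    simulate_recovery,
    write_timecourse,
)


# ---------------------------------------------------------------------------
# reference normalization
# ---------------------------------------------------------------------------


def _raw_frame(target_q, ref_qs, reference_genes=("ACTB", "B2M")):
    rows = []
    for t in (0, 10):
        for rep in (1, 2):
            rows.append(
                {"gene": "target", "position_bp": 854, "time_min": t,
                 "replicate": rep, "quantity": target_q}
            )
            for gene, q in zip(reference_genes, ref_qs):
                rows.append(
                    {"gene": gene, "position_bp": np.nan, "time_min": t,
                     "replicate": rep, "quantity": q}
                )
    return pd.DataFrame(rows)


def test_normalization_against_unit_references():
    tc = normalize_timecourse(_raw_frame(2.0, [1.0, 1.0]), ["ACTB", "B2M"])
    assert np.allclose(tc.signal, 2.0)


def test_normalization_ratio_invariance():
    a = normalize_timecourse(_raw_frame(2.0, [1.0, 4.0]), ["ACTB", "B2M"])
    b = normalize_timecourse(_raw_frame(4.0, [2.0, 8.0]), ["ACTB", "B2M"])
    assert np.allclose(a.signal, b.signal)


def test_normalization_modes_match_hand_coded_means(rng):
    refs = rng.uniform(0.5, 2.0, size=4)
    target = 3.7
    frame = _raw_frame(target, refs, ("ACTB", "B2M", "GAPDH", "RPL13A"))
    names = ["ACTB", "B2M", "GAPDH", "RPL13A"]
    geo = normalize_timecourse(frame, names, mode="geometric")
    ari = normalize_timecourse(frame, names, mode="arithmetic")
    # independent loop oracles
    prod = 1.0
    for q in refs:
        prod *= q
    gmean = prod ** (1 / len(refs))
    amean = sum(refs) / len(refs)
    assert geo.signal.flat[0] == pytest.approx(target / gmean)
    assert ari.signal.flat[0] == pytest.approx(target / amean)


def test_normalization_missing_reference_errors():
    frame = _raw_frame(1.0, [1.0, 1.0])
    frame = frame[~((frame["gene"] == "B2M") & (frame["time_min"] == 10))]
    with pytest.raises(ValueError, match="B2M"):
        normalize_timecourse(frame, ["ACTB", "B2M"])


# ---------------------------------------------------------------------------
# t50 estimation
# ---------------------------------------------------------------------------


def _course(times, values, position=1000):
    signal = np.asarray(values, float)[None, :, None]
    return RecoveryTimeCourse([position], times, signal)


def test_t50_of_noiseless_ramp_is_midpoint():
    """Flat at zero until 10 min, linear to plateau by 20 min -> t50 = 15."""
    tc = _course([0, 5, 10, 15, 20, 25, 30], [0, 0, 0, 0.5, 1, 1, 1])
    assert estimate_recovery_time(tc, 1000) == pytest.approx(15.0)


def test_t50_of_signal_already_at_plateau_is_zero():
    tc = _course([0, 5, 10, 15], [1.0, 1.0, 1.0, 1.0])
    assert estimate_recovery_time(tc, 1000) == pytest.approx(0.0)


def test_t50_no_recovery_sentinel_with_external_plateau():
    # flat residual signal never reaches half of the control plateau
    tc = _course([0, 5, 10, 15], [0.05, 0.05, 0.05, 0.05])
    t50 = estimate_recovery_time(tc, 1000, plateau=1.0)
    assert np.isnan(t50)


def test_t50_requires_enough_time_points():
    with pytest.raises(ValueError, match="4 time points"):
        estimate_recovery_time(_course([0, 5, 10], [0, 1, 1]), 1000)


def test_t50_closed_form_on_noiseless_wave():
    params = WaveSimParams(times=tuple(range(0, 61, 2)), noise_cv=0.0,
                           replicates=3, seed=0)
    tc = simulate_recovery(params)
    for x in params.positions:
        expected = x / (params.wave_speed_v * 1000) + params.fill_time_tau / 2
        assert estimate_recovery_time(tc, x) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------


def test_fit_exact_line_recovers_slope_and_zero_intercept():
    positions = np.array([2000.0, 4000.0, 8000.0])
    t50 = positions / 1000.0 / 2.0  # rate 2 kbp/min, no offset
    fit = fit_elongation_rate(positions, t50, n_boot=0)
    assert fit.slope_kbp_per_min == pytest.approx(2.0)
    assert fit.intercept_min == pytest.approx(0.0, abs=1e-9)
    assert fit.fit_r2 == pytest.approx(1.0)


def test_fit_constant_t50_flags_non_elongation_limited():
    fit = fit_elongation_rate([1000.0, 2000.0, 3000.0], [7.0, 7.0, 7.0],
                              n_boot=0)
    assert fit.slope_kbp_per_min == 0.0
    assert not fit.elongation_limited


def test_fit_requires_three_finite_positions():
    with pytest.raises(ValueError, match="3 positions"):
        fit_elongation_rate([1000.0, 2000.0, 3000.0], [1.0, 2.0, np.nan],
                            n_boot=0)


def test_fit_excludes_no_recovery_positions_but_reports_them():
    positions = np.array([1000.0, 2000.0, 3000.0, 4000.0])
    t50 = np.array([1.0, 2.0, 3.0, np.nan])
    fit = fit_elongation_rate(positions, t50, n_boot=0)
    assert fit.n_no_recovery == 1
    assert fit.slope_kbp_per_min == pytest.approx(1.0)


def test_slope_invariant_to_signal_rescaling():
    params = WaveSimParams(seed=3)
    tc = simulate_recovery(params)
    scaled = RecoveryTimeCourse(tc.positions, tc.times, tc.signal * 13.7)
    t50_a = [estimate_recovery_time(tc, p) for p in tc.positions]
    t50_b = [estimate_recovery_time(scaled, p) for p in scaled.positions]
    fit_a = fit_elongation_rate(tc.positions, t50_a, n_boot=0)
    fit_b = fit_elongation_rate(tc.positions, t50_b, n_boot=0)
    assert fit_a.slope_kbp_per_min == pytest.approx(fit_b.slope_kbp_per_min)


def test_bootstrap_ci_brackets_point_estimate():
    params = WaveSimParams(times=tuple(range(0, 61, 2)), seed=17)
    tc = simulate_recovery(params)
    t50 = [estimate_recovery_time(tc, p) for p in tc.positions]
    fit = fit_elongation_rate(tc.positions, t50, timecourse=tc, n_boot=500,
                              seed=17)
    lo, hi = fit.ci_slope
    assert lo < fit.slope_kbp_per_min < hi


def test_timecourse_round_trip(tmp_path):
    tc = simulate_recovery(WaveSimParams(seed=8))
    path = tmp_path / "tc.tsv"
    write_timecourse(tc, path)
    back = read_timecourse(path)
    assert np.array_equal(back.positions, tc.positions)
    assert np.allclose(back.signal, tc.signal)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


def test_identical_conditions_yield_unit_ratios_and_no_flags():
    tc = simulate_recovery(WaveSimParams(seed=4))
    cmp = compare_conditions(tc, tc)
    assert np.allclose(cmp.ratios.to_numpy(), 1.0)
    assert not cmp.tests["deficit"].any()


def _deficit_pair(seed, deficit_positions=(), factor=0.4, noise_cv=0.08):
    base = WaveSimParams(noise_cv=noise_cv)
    ctrl = simulate_recovery(
        WaveSimParams(noise_cv=noise_cv, seed=seed), "control"
    )
    trt = simulate_recovery(
        WaveSimParams(noise_cv=noise_cv, seed=seed + 50_000), "treated"
    )
    signal = trt.signal.copy()
    for i, p in enumerate(base.positions):
        if p in deficit_positions:
            signal[i] *= factor
    return ctrl, RecoveryTimeCourse(trt.positions, trt.times, signal, "treated")


def test_halved_distal_signal_flags_distal_positions_only():
    distal = tuple(854 + 10_000 * k for k in range(4, 9))
    ctrl, trt = _deficit_pair(seed=1, deficit_positions=distal)
    cmp = compare_conditions(ctrl, trt)
    flagged = set(cmp.tests.index[cmp.tests["deficit"]])
    assert flagged == set(distal)


def test_deficit_detection_controls_familywise_error():
    """Null runs rarely flag anything; planted runs recover the planted set."""
    false_runs = 0
    for seed in range(20):
        ctrl, trt = _deficit_pair(seed=100 + seed)
        if compare_conditions(ctrl, trt).tests["deficit"].any():
            false_runs += 1
    assert false_runs <= 3  # FWER controlled at 0.05

    planted = tuple(854 + 10_000 * k for k in range(4, 9))
    exact = 0
    for seed in range(10):
        ctrl, trt = _deficit_pair(seed=500 + seed, deficit_positions=planted)
        flagged = set(
            compare_conditions(ctrl, trt).tests.query("deficit").index
        )
        exact += flagged == set(planted)
    assert exact >= 9


def test_grid_mismatch_errors():
    a = simulate_recovery(WaveSimParams(seed=1))
    b = simulate_recovery(WaveSimParams(seed=1, times=tuple(range(0, 31, 5))))
    with pytest.raises(ValueError, match="grids"):
        compare_conditions(a, b)
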