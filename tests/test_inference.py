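"""Multi-exponential fitting, saturation/second-order fits, censoring."""

import numpy as np
import pytest

import glbkin as g
from glbkin.inference import Dependence, observability_bound


def _trace(times, signal, sampling=1.2e-3, dead=1.2e-3, noise=0.002,
           truth=None):
    instr = g.InstrumentProfile("stopped_flow", dead, sampling,
                                float(times[-1]), noise)
    return g.TimeCourse(times=times, signal=signal, instrument=instr,
                        wavelength=424.0, seed=0, truth=truth)


# ---------------------------------------------------------------------------
# multi-exponential decomposition


def test_constant_trace_selects_zero_phases():
    rng = np.random.default_rng(0)
    t = np.linspace(0.0012, 2.0, 500)
    y = 0.3 + rng.normal(0, 0.002, len(t))
    fit = g.fit_multiexponential((t, y))
    assert fit.n_phases == 0
    assert fit.baseline == pytest.approx(0.3, abs=0.001)


def test_noiseless_biexponential_recovered_exactly():
    t = np.linspace(0.2, 30.0, 600)
    y = 0.05 + 0.21 * np.exp(-0.319 * (t - t[0])) \
        + 0.14 * np.exp(-0.190 * (t - t[0]))
    fit = g.fit_multiexponential((t, y))
    assert fit.n_phases == 2
    assert fit.rates[0] == pytest.approx(0.319, rel=1e-6)
    assert fit.rates[1] == pytest.approx(0.190, rel=1e-6)
    assert fit.amplitudes[0] == pytest.approx(0.21, rel=1e-6)
    assert fit.amplitudes[1] == pytest.approx(0.14, rel=1e-6)


def test_noisy_single_exponential_monte_carlo():
    """0.002 AU noise on a 0.277/s decay over a 200 s trace: the selected
    model is single-phase and the median recovered rate is within 1%
    (spread well under 3% per replicate)."""
    rng = np.random.default_rng(7)
    t = np.arange(0.0, 200.0, 0.4)
    errors, n_correct = [], 0
    for _ in range(100):
        y = 0.1 + 0.3 * np.exp(-0.277 * t) + rng.normal(0, 0.002, len(t))
        fit = g.fit_multiexponential((t, y))
        if fit.n_phases == 1:
            n_correct += 1
            errors.append(abs(fit.rates[0] / 0.277 - 1))
    assert n_correct >= 95
    assert np.median(errors) <= 0.01
    assert np.percentile(errors, 90) <= 0.03


def test_phase_count_selection_at_three_fold_separation():
    """Rates 3x apart with a 60:40 amplitude split are reliably detected
    as two phases at default noise."""
    rng = np.random.default_rng(11)
    t = np.linspace(0.1, 40.0, 800)
    n_two = 0
    for _ in range(40):
        y = 0.05 + 0.21 * np.exp(-0.9 * t) + 0.14 * np.exp(-0.3 * t) \
            + rng.normal(0, 0.002, len(t))
        fit = g.fit_multiexponential((t, y))
        if fit.n_phases == 2:
            n_two += 1
    assert n_two >= 38  # >= 95%


def test_close_rates_demoted_to_single_phase():
    """Two generating rates within the 1.5x identifiability guard are
    reported as one phase."""
    t = np.linspace(0.1, 40.0, 500)
    y = 0.05 + 0.2 * np.exp(-0.30 * t) + 0.2 * np.exp(-0.32 * t)
    fit = g.fit_multiexponential((t, y))
    assert fit.n_phases == 1
    assert fit.demoted_from == 2 or 2 not in fit.selection_scores or \
        fit.selection_scores[1] <= fit.selection_scores[2]


def test_tiny_amplitude_phase_demoted():
    rng = np.random.default_rng(3)
    t = np.linspace(0.1, 40.0, 500)
    y = 0.05 + 0.3 * np.exp(-0.3 * t) + 0.004 * np.exp(-3.0 * t) \
        + rng.normal(0, 0.002, len(t))
    fit = g.fit_multiexponential((t, y))
    assert fit.n_phases == 1


def test_fit_requires_enough_points():
    with pytest.raises(ValueError):
        g.fit_multiexponential((np.arange(5.0), np.arange(5.0)))


def test_rate_uncertainties_cover_truth():
    rng = np.random.default_rng(5)
    t = np.arange(0.0, 60.0, 0.2)
    hits = 0
    for _ in range(30):
        y = 0.1 + 0.3 * np.exp(-0.277 * t) + rng.normal(0, 0.002, len(t))
        fit = g.fit_multiexponential((t, y), max_phases=1)
        if abs(fit.rates[0] - 0.277) <= 2.5 * fit.rate_stderr[0]:
            hits += 1
    assert hits >= 27


# ---------------------------------------------------------------------------
# trap saturation


def test_exact_hyperbola_inverted():
    pts = [(c, 1.0 * c / (5e-3 + c)) for c in (2e-3, 5e-3, 1e-2, 2e-2)]
    fit = g.fit_trap_saturation(pts)
    assert fit.k_max == pytest.approx(1.0, rel=1e-8)
    assert fit.c_half == pytest.approx(5e-3, rel=1e-6)
    assert not fit.extrapolation_warning


def test_saturated_limit_identical_rates():
    fit = g.fit_trap_saturation([(6.75e-3, 0.28), (13.5e-3, 0.28),
                                 (27.5e-3, 0.28)])
    assert fit.k_max == pytest.approx(0.28)
    assert fit.c_half == 0.0


def test_trap_fit_warns_on_extrapolation():
    pts = [(c, 1.0 * c / (0.1 + c)) for c in (2e-3, 5e-3, 1e-2)]
    fit = g.fit_trap_saturation(pts)
    assert fit.extrapolation_warning


def test_trap_fit_needs_three_concentrations():
    with pytest.raises(ValueError):
        g.fit_trap_saturation([(1e-3, 0.2), (2e-3, 0.25)])


# ---------------------------------------------------------------------------
# second-order regression and classification


def test_exact_line_slope_machine_precision():
    det = g.fit_second_order([(c, 726.0 * c) for c in
                              (5e-5, 1e-4, 2.5e-4, 5e-4, 1e-3)])
    assert det.second_order_k == pytest.approx(726.0, rel=1e-12)
    assert det.intercept == pytest.approx(0.0, abs=1e-10)
    lo, hi = det.slope_ci95
    assert lo <= 726.0 <= hi


def test_through_origin_slope():
    det = g.fit_second_order([(c, 100.0 * c + 0.0) for c in
                              (1e-4, 2e-4, 4e-4)], through_origin=True)
    assert det.second_order_k == pytest.approx(100.0, rel=1e-12)
    assert det.intercept == 0.0


def test_flat_rates_give_zero_slope():
    det = g.fit_second_order([(1e-5, 126.0), (4e-5, 126.0), (1.6e-4, 126.0)])
    assert det.second_order_k == pytest.approx(0.0, abs=1e-9)


def test_classify_dependence_three_ways():
    flat = [(1e-5, 126.0), (2e-5, 125.4), (4e-5, 126.2), (8e-5, 125.8),
            (1.6e-4, 126.1)]
    assert g.classify_dependence(flat) is Dependence.GATED_INDEPENDENT
    linear = [(c, 726.0 * c + 1e-3 * np.sin(i)) for i, c in
              enumerate((5e-5, 1e-4, 2.5e-4, 5e-4, 1e-3))]
    # slope term dominates the jitter by orders of magnitude
    assert g.classify_dependence(linear) is Dependence.BIMOLECULAR_DEPENDENT
    assert g.classify_dependence([(1e-5, 10.0), (2e-5, 11.0)]) \
        is Dependence.INDETERMINATE
    # three concentrations but under 4-fold span
    assert g.classify_dependence([(1e-5, 10.0), (2e-5, 10.1),
                                  (3e-5, 10.2)]) is Dependence.INDETERMINATE


# ---------------------------------------------------------------------------
# censoring


def test_half_time_rule_censors_fast_trace():
    """k_obs = 350/s has a 2 ms half-time, under the 3 ms observability
    floor of 1.2 ms sampling: censored with the ln2/3ms lower bound."""
    t = 0.0012 + 0.0012 * np.arange(400)
    y = 0.02 + 0.1 * np.exp(-350.0 * t)
    tc = _trace(t, y, truth={"expected_amplitude_au": 0.1})
    det = g.censored_bound(tc)
    assert det.censored
    assert det.lower_bound == pytest.approx(np.log(2) / 0.003, rel=1e-9)
    assert det.second_order_k is None


def test_amplitude_rule_censors_invisible_trace():
    t = 0.0012 + 0.0012 * np.arange(400)
    y = 0.02 + 0.1 * np.exp(-5000.0 * t)
    tc = _trace(t, y, truth={"expected_amplitude_au": 0.1})
    det = g.censored_bound(tc)
    assert det.censored
    assert det.details["fraction_amplitude_missing"] > 0.95


def test_slow_trace_not_censored():
    t = 0.0012 + 0.01 * np.arange(3000)  # long enough to reach baseline
    y = 0.02 + 0.1 * np.exp(-0.3 * t)
    tc = _trace(t, y, sampling=0.01, truth={"expected_amplitude_au": 0.1})
    det = g.censored_bound(tc)
    assert not det.censored
    # empirical half-time matches ln2 / k_obs
    assert det.details["t_half_s"] == pytest.approx(np.log(2) / 0.3, rel=0.05)


def test_observability_bound_value():
    assert observability_bound(1.2e-3) == pytest.approx(231.049, rel=1e-5)


def test_censored_determination_cannot_carry_constant():
    with pytest.raises(ValueError):
        g.RateDetermination(second_order_k=100.0, censored=True,
                            lower_bound=231.0)


# ---------------------------------------------------------------------------
# references


def test_reference_fold_changes():
    folds = g.compare_to_references(382.0)
    assert folds["sperm_whale_myoglobin"] == pytest.approx(131.7, rel=5e-3)
    folds = g.compare_to_references(726.0)
    assert folds["human_neuroglobin"] == pytest.approx(2904, rel=5e-3)
    assert g.compare_to_references(68.0)["SynHb"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        g.compare_to_references(0.0)


def test_reference_table_contents():
    assert g.NIR_REFERENCES == {
        "SynHb": 68.0,
        "Arabidopsis_class1_Glb": 58.0,
        "rice_Glb": 83.0,
        "sperm_whale_myoglobin": 2.9,
        "human_neuroglobin": 0.25,
        "neuroglobin_HisD_mutant": 956.0,
    }
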