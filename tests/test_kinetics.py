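"""Exponential synthesis kinetics, F tests, growth correction."""

import math

import numpy as np
import pytest

from turnoverlab import kinetics as kin
from turnoverlab.errors import FitError

LN2 = math.log(2.0)


def _series(label, t, k, noise_sd=0.0, rng=None):
    t = np.asarray(t, dtype=float)
    f = 1.0 - np.exp(-k * t)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, t.size)
    return kin.FractionalSynthesisSeries(label, tuple(t), tuple(f))


def test_exact_curve_recovery():
    s = kin.FractionalSynthesisSeries("p1", (7.0, 14.0, 28.0), (0.5, 0.75, 0.9375))
    fit = kin.fit_single_exponential(s)
    assert fit.k_obs == pytest.approx(LN2 / 7.0, rel=1e-8)
    assert fit.t_half_h == pytest.approx(7.0, rel=1e-8)
    assert fit.sem == pytest.approx(0.0, abs=1e-7)
    assert fit.df == 2


def test_fit_requires_three_points_and_time_span():
    with pytest.raises(FitError):
        kin.fit_single_exponential(
            kin.FractionalSynthesisSeries("x", (0.0, 24.0), (0.0, 0.5))
        )
    with pytest.raises(FitError):
        kin.fit_single_exponential(
            kin.FractionalSynthesisSeries("x", (5.0, 5.0, 5.0), (0.1, 0.1, 0.1))
        )


def test_no_detectable_synthesis_flag():
    s = kin.FractionalSynthesisSeries("x", (0.0, 24.0, 72.0), (0.0, 0.0, 0.0))
    fit = kin.fit_single_exponential(s)
    assert fit.k_obs == pytest.approx(0.0, abs=1e-9)
    assert "no_detectable_synthesis" in fit.flags


def test_half_life_rate_duality():
    for k in (0.01, 0.05, 0.099, 0.3):
        fit = kin.fit_single_exponential(
            _series("s", (0.0, 6.0, 24.0, 48.0, 96.0), k)
        )
        assert fit.k_obs * fit.t_half_h == pytest.approx(LN2, rel=1e-6)


def test_parameter_recovery_monte_carlo():
    """Gaussian noise sd 0.03, t = {0,24,48,72}: mean k̂ within ±0.005 of
    0.05 and the 95 % CI covers truth in 90-99 % of 200 seeded runs."""
    rng = np.random.default_rng(7)
    t = (0.0, 24.0, 48.0, 72.0)
    k_true = 0.05
    ks, covered = [], 0
    for _ in range(200):
        fit = kin.fit_single_exponential(_series("s", t, k_true, 0.03, rng))
        ks.append(fit.k_obs)
        covered += fit.ci95[0] <= k_true <= fit.ci95[1]
    assert abs(np.mean(ks) - k_true) < 0.005
    assert 0.90 * 200 <= covered <= 0.99 * 200


def test_weighted_fit_uses_sd():
    rng = np.random.default_rng(1)
    t = (0.0, 6.0, 24.0, 48.0, 96.0)
    f = tuple(1 - math.exp(-0.05 * x) for x in t)
    s = kin.FractionalSynthesisSeries("w", t, f, sd=(0.01,) * 5)
    fit_w = kin.fit_single_exponential(s, weighting="inverse_variance")
    assert fit_w.k_obs == pytest.approx(0.05, rel=1e-6)
    with pytest.raises(FitError):
        kin.fit_single_exponential(
            kin.FractionalSynthesisSeries("w", t, f), weighting="inverse_variance"
        )


# ---------------------------------------------------------------------------
# F test
# ---------------------------------------------------------------------------


def test_f_test_identical_series_gives_f_zero():
    rng = np.random.default_rng(3)
    s = _series("a", (0.0, 6.0, 24.0, 48.0), 0.08, 0.02, rng)
    cmp = kin.compare_rates_f_test([s, kin.FractionalSynthesisSeries("b", s.times_h, s.f)])
    assert cmp.F == pytest.approx(0.0, abs=1e-9)
    assert cmp.p == pytest.approx(1.0)


def test_f_test_pooling_consistency():
    """The shared fit equals a single fit on the concatenated points."""
    rng = np.random.default_rng(5)
    group = [
        _series("a", (0.0, 6.0, 24.0, 48.0), 0.08, 0.02, rng),
        _series("b", (0.0, 12.0, 36.0, 72.0), 0.08, 0.02, rng),
    ]
    cmp = kin.compare_rates_f_test(group)
    pooled = kin.fit_single_exponential(kin.FractionalSynthesisSeries.concat(group))
    assert cmp.shared_fit.k_obs == pytest.approx(pooled.k_obs, rel=1e-12)
    assert cmp.shared_fit.rss == pytest.approx(pooled.rss, rel=1e-12)
    assert cmp.df_num == 1
    assert cmp.df_den == 8 - 2


def test_f_test_detects_large_rate_difference():
    rng = np.random.default_rng(11)
    t = (6.0, 24.0, 48.0, 72.0)
    cmp = kin.compare_rates_f_test(
        [_series("slow", t, 0.05, 0.01, rng), _series("fast", t, 0.15, 0.01, rng)]
    )
    assert cmp.p < 0.001


def test_f_test_type_one_error_calibration():
    """Null (equal rates): rejection rate at alpha 0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(2024)
    t = (6.0, 24.0, 48.0, 72.0)
    rejections = 0
    n_sims = 400
    for _ in range(n_sims):
        cmp = kin.compare_rates_f_test(
            [_series("a", t, 0.08, 0.02, rng), _series("b", t, 0.08, 0.02, rng)]
        )
        rejections += cmp.p < 0.05
    assert 0.03 <= rejections / n_sims <= 0.07


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def test_growth_exact_doubling():
    fit = kin.fit_exponential_growth([(0.0, 1e5), (24.0, 2e5), (48.0, 4e5)])
    assert fit.k_cell == pytest.approx(0.02888, abs=1e-5)
    assert fit.t_double_h == pytest.approx(24.0, rel=1e-9)


def test_growth_constant_counts_flagged_non_proliferating():
    fit = kin.fit_exponential_growth([(0.0, 1e5), (24.0, 1e5), (48.0, 1e5)])
    assert fit.k_cell == 0.0
    assert math.isinf(fit.t_double_h)
    assert "non_proliferating" in fit.flags


def test_growth_rejects_bad_input():
    with pytest.raises(FitError):
        kin.fit_exponential_growth([(0.0, 1e5), (24.0, 2e5)])
    with pytest.raises(FitError):
        kin.fit_exponential_growth([(0.0, 1e5), (24.0, 0.0), (48.0, 1e5)])


def test_growth_noisy_monte_carlo():
    """CV 5 % around a 30-h doubling time: mean t̂ within ±1.5 h, 200 reps."""
    rng = np.random.default_rng(9)
    k = LN2 / 30.0
    t = np.array([0.0, 12.0, 24.0, 48.0, 72.0, 96.0])
    estimates = []
    for _ in range(200):
        counts = 1e5 * np.exp(k * t) * (1 + rng.normal(0, 0.05, t.size))
        fit = kin.fit_exponential_growth(list(zip(t, counts)))
        estimates.append(fit.t_double_h)
    assert abs(np.mean(estimates) - 30.0) < 1.5


# ---------------------------------------------------------------------------
# Growth correction
# ---------------------------------------------------------------------------


def _kfit(k, sem=0.001):
    return kin.KineticFitResult(
        label="x", k_obs=k, sem=sem, ci95=(k - 2 * sem, k + 2 * sem),
        rss=0.0, df=3, n_points=4, t_half_h=LN2 / k if k > 0 else math.inf,
    )


def test_growth_correction_arithmetic():
    est = kin.correct_for_growth(
        _kfit(0.0635), kin.GrowthFit(k_cell=0.0289, sem=0.001, t_double_h=LN2 / 0.0289)
    )
    assert est.k_to == pytest.approx(0.0346)
    assert est.t_half_to_h == pytest.approx(20.0, abs=0.05)
    assert est.sem_k_to == pytest.approx(math.hypot(0.001, 0.001), rel=1e-9)


def test_growth_correction_boundary_and_identity():
    g = kin.GrowthFit(k_cell=0.05, sem=0.0, t_double_h=LN2 / 0.05)
    est = kin.correct_for_growth(_kfit(0.05), g)
    assert est.k_to == 0.0
    assert math.isinf(est.t_half_to_h)
    assert "turnover_not_measurable" in est.flags

    g0 = kin.GrowthFit(k_cell=0.0, sem=0.0, t_double_h=math.inf)
    est0 = kin.correct_for_growth(_kfit(0.099), g0)
    assert est0.k_to == pytest.approx(0.099)
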