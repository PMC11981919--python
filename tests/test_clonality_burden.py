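"""Truncated binomial mixture, sensitivity correction and rate models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gastroclone import clonality_burden as cb


# ---------------------------------------------------------------------------
# binomial tail / sensitivity


@pytest.mark.parametrize("min_reads", [0, 1, 4, 6])
def test_binom_tail_matches_scipy(min_reads, rng):
    n = rng.integers(1, 150, size=100)
    for p in (0.01, 0.2, 0.5, 0.95):
        mine = cb.binom_tail_ge(min_reads, n, p)
        ref = stats.binom.sf(min_reads - 1, n, p)
        assert np.allclose(mine, ref, atol=1e-10)


def test_sensitivity_exact_values():
    # depth 30, peak one half: 1 - sum_{k<4} C(30,k) / 2^30 = 1 - 4526/2^30
    s = cb.estimate_sensitivity(np.full(8, 30), 0.5)
    assert s.S == pytest.approx(1 - 4526 / 2**30)
    # depth 8, peak one quarter
    s = cb.estimate_sensitivity(np.full(8, 8), 0.25)
    assert s.S == pytest.approx(float(stats.binom.sf(3, 8, 0.25)))
    assert s.S == pytest.approx(0.1138, abs=2e-4)
    # depths below the read threshold can never be detected
    assert cb.estimate_sensitivity([3, 3, 2], 0.5).S == 0.0


def test_sensitivity_monotone_in_depth_and_peak():
    depths = np.arange(4, 60)
    s_by_depth = [cb.estimate_sensitivity([d], 0.3).S for d in depths]
    assert (np.diff(s_by_depth) >= -1e-12).all()
    peaks = np.linspace(0.05, 0.9, 30)
    s_by_peak = [cb.estimate_sensitivity([20], p).S for p in peaks]
    assert (np.diff(s_by_peak) >= -1e-12).all()


def test_sensitivity_input_contracts():
    with pytest.raises(ValueError):
        cb.estimate_sensitivity([], 0.5)
    with pytest.raises(ValueError):
        cb.estimate_sensitivity([30], 0.0)


# ---------------------------------------------------------------------------
# truncated binomial mixture


def _single_clone_data(p, depth, n, seed, min_reads=4):
    rng = np.random.default_rng(seed)
    nr = np.full(n, depth)
    nv = rng.binomial(nr, p)
    keep = nv >= min_reads
    return nv[keep].astype(float), nr[keep].astype(float)


def test_mixture_recovers_single_clone():
    nv, nr = _single_clone_data(0.4, 40, 500, seed=1)
    fit = cb.fit_vaf_mixture(nv, nr, seed=0)
    assert fit.K == 1
    assert abs(fit.peak_vaf - 0.4) < 0.02


def test_mixture_recovers_two_clones():
    rng = np.random.default_rng(2)
    major = rng.random(500) < 0.7
    nr = np.full(500, 60)
    nv = np.where(major, rng.binomial(nr, 0.45), rng.binomial(nr, 0.10))
    keep = nv >= 4
    fit = cb.fit_vaf_mixture(nv[keep].astype(float), nr[keep].astype(float), seed=0)
    assert fit.K == 2
    assert abs(fit.peaks[0] - 0.45) < 0.03
    assert abs(fit.peaks[1] - 0.10) < 0.03


def test_mixture_degenerate_all_reads_variant():
    nr = np.full(20, 30.0)
    fit = cb.fit_vaf_mixture(nr.copy(), nr, seed=0)
    assert fit.degenerate and fit.K == 1 and fit.peaks[0] > 0.99


def test_mixture_input_contracts():
    with pytest.raises(ValueError):
        cb.fit_vaf_mixture([10.0] * 5, [30.0] * 5)  # too few variants
    with pytest.raises(ValueError):
        cb.fit_vaf_mixture([2.0] * 20, [30.0] * 20)  # below min_reads


def test_em_loglik_never_decreases():
    nv, nr = _single_clone_data(0.35, 30, 300, seed=3)
    for K in (1, 2, 3):
        init = np.linspace(0.2, 0.6, K)
        _, _, trace, _, _ = cb._em_once(nv, nr, init, 4, 200, 1e-8)
        assert (np.diff(trace) >= -1e-7).all()


def test_truncation_at_zero_reads_equals_plain_binomial():
    nv, nr = _single_clone_data(0.3, 25, 200, seed=4, min_reads=0)
    for p in (0.1, 0.3, 0.7):
        trunc = cb._component_loglik(nv, nr, p, min_reads=0)
        plain = stats.binom.logpmf(nv, nr, p)
        assert np.allclose(trunc, plain, atol=1e-9)


# ---------------------------------------------------------------------------
# burden correction and clonality


def test_corrected_burden_arithmetic():
    assert cb.corrected_burden(100, 1.0).corrected == 100
    assert cb.corrected_burden(100, 0.8).corrected == pytest.approx(125)
    # at the cohort-typical sensitivity of 0.95
    assert cb.corrected_burden(95, 0.95).corrected == pytest.approx(100)
    undef = cb.corrected_burden(50, 0.0)
    assert undef.excluded and np.isnan(undef.corrected)
    with pytest.raises(ValueError):
        cb.corrected_burden(10, 1.5)


def test_median_vaf_and_clonality_rule():
    med, mono = cb.median_vaf_and_clonality([5, 4, 9], [10, 10, 20])
    assert med == pytest.approx(0.45) and mono
    med, mono = cb.median_vaf_and_clonality([1, 2, 3], [10, 10, 20])
    assert med == pytest.approx(0.15) and not mono
    # boundary: exactly 0.25 is polyclonal (strict inequality)
    med, mono = cb.median_vaf_and_clonality([5], [20])
    assert med == 0.25 and not mono
    med, mono = cb.median_vaf_and_clonality([], [])
    assert np.isnan(med) and not mono


# ---------------------------------------------------------------------------
# mixed-effects rate models


def _cohort_frame(rng, slope=25.0, donor_sd=0.0, resid_sd=0.0, n_donors=8,
                  glands=6, im_effect=0.0):
    rows = []
    for d in range(n_donors):
        age = rng.uniform(30, 75)
        intercept = rng.normal(0, donor_sd)
        for _ in range(glands):
            im = int(rng.random() < 0.3)
            y = slope * age + intercept + im_effect * im + rng.normal(0, resid_sd)
            rows.append({"burden": y, "age": age, "donor": f"D{d}", "metaplasia": bool(im)})
    return pd.DataFrame(rows)


def test_noiseless_fit_is_exact():
    rng = np.random.default_rng(0)
    df = _cohort_frame(rng, slope=25.0)
    fit = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"], formula="age")
    assert fit.slope == pytest.approx(25.0, abs=1e-6)
    assert fit.donor_sd == pytest.approx(0.0, abs=1e-3)
    assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]


def test_identical_models_compare_trivially():
    rng = np.random.default_rng(1)
    df = _cohort_frame(rng, donor_sd=30, resid_sd=40)
    fit = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"], formula="age")
    stat, p = cb.compare_models(fit, fit)
    assert stat == 0.0 and p == 1.0


def test_non_nested_models_refused():
    rng = np.random.default_rng(2)
    df = _cohort_frame(rng, donor_sd=30, resid_sd=40)
    cov = {"metaplasia": df["metaplasia"], "ci_grade": ["mild"] * len(df)}
    fit_ci = cb.fit_burden_rate_model(
        df["burden"], df["age"], df["donor"],
        covariates={"ci_grade": np.where(np.arange(len(df)) % 2, "severe", "mild")},
        formula="age+ci",
    )
    fit_im = cb.fit_burden_rate_model(
        df["burden"], df["age"], df["donor"], covariates=cov, formula="age+im"
    )
    with pytest.raises(ValueError):
        cb.compare_models(fit_ci, fit_im)


def test_lrt_detects_strong_metaplasia_effect():
    """Burden ~ Age + IM beats Burden ~ Age when the IM effect is large."""
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        df = _cohort_frame(rng, donor_sd=50, resid_sd=100, im_effect=2000.0)
        cov = {"metaplasia": df["metaplasia"]}
        small = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"],
                                         covariates=cov, formula="age")
        large = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"],
                                         covariates=cov, formula="age+im")
        _, p = cb.compare_models(small, large)
        hits += p < 0.001
    assert hits >= 19


def test_lrt_type_i_error_near_nominal():
    """Null metaplasia effect: about 5% rejections at alpha 0.05."""
    rejections = 0
    n_reps = 200
    for rep in range(n_reps):
        rng = np.random.default_rng(3000 + rep)
        df = _cohort_frame(rng, donor_sd=50, resid_sd=100, im_effect=0.0)
        cov = {"metaplasia": df["metaplasia"]}
        small = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"],
                                         covariates=cov, formula="age")
        large = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"],
                                         covariates=cov, formula="age+im")
        _, p = cb.compare_models(small, large)
        rejections += p < 0.05
    rate = rejections / n_reps
    assert rate <= 0.10  # binomial noise band around the nominal 0.05


def test_fold_change_contracts():
    rng = np.random.default_rng(5)
    df = _cohort_frame(rng, slope=25.0)
    fit = cb.fit_burden_rate_model(df["burden"], df["age"], df["donor"], formula="age")
    age = 60.0
    expected = fit.expected_burden(age)
    assert cb.burden_fold_change(expected, age, fit) == pytest.approx(1.0)
    assert cb.burden_fold_change(0.0, age, fit) == pytest.approx(0.0)
    assert cb.burden_fold_change(2 * expected, age, fit) == pytest.approx(2.0)


def test_burden_table_on_small_cohort(small_cohort, small_filtered):
    table = cb.sample_burden_table(
        small_cohort.count_matrix, small_filtered, small_cohort.metadata, seed=0
    )
    ok = table[~table["excluded"]]
    assert len(ok) == small_cohort.count_matrix.n_samples
    # monoclonal glands with peaks between 0.25 and 0.5
    assert ok["monoclonal"].all()
    assert ok["median_vaf"].between(0.25, 0.55).all()
    # sensitivity near the cohort-typical value and corrected >= raw
    assert ok["sensitivity"].between(0.8, 1.0).all()
    assert (ok["corrected_snv"] >= ok["raw_snv"] - 1e-9).all()
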