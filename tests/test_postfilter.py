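"""Filtering stages against exact oracles and generator truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gastroclone import postfilter as pf


# ---------------------------------------------------------------------------
# quality stage


@pytest.mark.parametrize(
    "asmd, clpm, kept",
    [(140, 0, True), (139, 0, False), (200, 1, False), (150, 0, True)],
)
def test_quality_thresholds_inclusive(asmd, clpm, kept):
    df = pd.DataFrame({"asmd": [asmd], "clpm": [clpm]})
    assert pf.quality_filter(df)[0] == kept


def test_quality_requires_populated_fields():
    with pytest.raises(ValueError):
        pf.quality_filter(pd.DataFrame({"asmd": [np.nan], "clpm": [0]}))


# ---------------------------------------------------------------------------
# germline exact test


def test_germline_p_matches_exact_binomial_cdf():
    # balanced counts: consistent with heterozygous, p around one half
    assert pf.germline_binomial_test(30, 60) == pytest.approx(
        stats.binom.cdf(30, 60, 0.5)
    )
    assert 0.5 < pf.germline_binomial_test(30, 60) < 0.6
    # total dropout: closed form 0.5^60
    assert pf.germline_binomial_test(0, 60) == pytest.approx(0.5**60)
    # strong depletion: clearly somatic at q < 1e-5
    assert pf.germline_binomial_test(10, 100) < 1e-5
    # unassessable
    assert np.isnan(pf.germline_binomial_test(0, 0))


def test_bh_adjust_matches_hand_computation():
    # step-up: sorted p * n / rank with a cumulative minimum from the top
    assert pf.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert pf.bh_adjust([0.5]) == pytest.approx([0.5])
    assert pf.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    with pytest.raises(ValueError):
        pf.bh_adjust([0.5, 1.5])


def test_bh_adjust_monotone_and_bounded(rng):
    p = rng.uniform(size=200)
    q = pf.bh_adjust(p)
    assert (q <= 1).all() and (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# beta-binomial overdispersion


def _oracle_rho(nv, nr):
    """Independent dense-grid maximization via scipy.stats.betabinom."""
    mu = nv.sum() / nr.sum()
    ll = []
    for rho in pf.RHO_GRID:
        s = (1 - rho) / rho
        ll.append(stats.betabinom.logpmf(nv, nr, mu * s, (1 - mu) * s).sum())
    return pf.RHO_GRID[int(np.argmax(ll))]


def test_rho_private_clone_is_overdispersed():
    nv = np.array([15] + [0] * 9)
    nr = np.full(10, 30)
    est = pf.estimate_rho(nv, nr)
    assert est.flag == "ok" and est.rho > 0.1
    assert est.rho == _oracle_rho(nv, nr)


def test_rho_flat_scatter_is_near_binomial():
    nv = np.ones(10, dtype=int)
    nr = np.full(10, 30)
    est = pf.estimate_rho(nv, nr)
    assert est.flag == "ok" and est.rho < 0.1
    assert est.rho == _oracle_rho(nv, nr)


def test_rho_single_sample_is_undefined():
    est = pf.estimate_rho([5], [30])
    assert est.flag == "single_sample" and np.isnan(est.rho)


def test_rho_degenerate_pooled_vaf():
    est = pf.estimate_rho([0, 0, 0], [30, 30, 30])
    assert est.flag == "degenerate" and est.rho == pf.RHO_GRID[-1]


@pytest.mark.parametrize("trial", range(12))
def test_rho_grid_equals_dense_bruteforce_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    m = rng.integers(3, 12)
    nr = rng.integers(8, 60, size=m)
    if trial % 2:
        nv = rng.binomial(nr, rng.uniform(0.02, 0.3))  # artifact-like
    else:
        nv = np.zeros(m, dtype=int)
        nv[0] = rng.integers(4, nr[0] + 1)  # clone-private
    if nv.sum() in (0, nr.sum()):
        pytest.skip("degenerate draw")
    assert pf.estimate_rho(nv, nr).rho == _oracle_rho(nv, nr)


# ---------------------------------------------------------------------------
# classification


def _toy_matrix():
    from gastroclone.matrix import CountMatrix

    variants = pd.DataFrame(
        {
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "ref": ["C", "C", "CA", "C"],
            "alt": ["A", "T", "C", "G"],
            "var_class": ["SNV", "SNV", "indel", "SNV"],
            "asmd": [150.0, 150.0, 150.0, 100.0],
            "clpm": [0.0, 0.0, 0.0, 0.0],
        }
    )
    nv = np.array([[12, 0, 0], [1, 1, 1], [1, 1, 1], [14, 15, 16]])
    nr = np.full((4, 3), 30)
    return CountMatrix(variants=variants, samples=["s1", "s2", "s3"], nv=nv, nr=nr)


def test_classification_statuses_and_precedence():
    matrix = _toy_matrix()
    table = pf.classify_variants(matrix, {"s1": "D", "s2": "D", "s3": "D"})
    # private clone: somatic, overdispersed -> pass
    assert table.loc[0, "status"] == "pass"
    # flat low-VAF scatter: SNV artifact (rho < 0.1)
    assert table.loc[1, "status"] == "artifact"
    # same counts as an indel: rho threshold is 0.15, still below -> artifact
    assert table.loc[2, "status"] == "artifact"
    # balanced 0.5 VAF in all samples, but ASMD < 140: quality wins over germline
    assert table.loc[3, "status"] == "quality_fail"
    assert table.loc[3, "germline_q"] > 1e-5  # it would otherwise be germline


def test_rho_threshold_is_class_specific():
    # counts whose grid-MLE overdispersion lies between the SNV and indel
    # cutoffs: an artifact verdict for an indel, a pass for an SNV
    nv = np.array([6, 6, 0, 6])
    nr = np.array([26, 30, 45, 28])
    est = pf.estimate_rho(nv, nr)
    thresholds = pf.FilterThresholds()
    assert est.flag == "ok"
    assert thresholds.rho_snv < est.rho < thresholds.rho_indel


def test_classification_is_idempotent():
    matrix = _toy_matrix()
    donors = {"s1": "D", "s2": "D", "s3": "D"}
    t1 = pf.classify_variants(matrix, donors)
    t2 = pf.classify_variants(matrix, donors)
    assert (t1["status"] == t2["status"]).all()


def test_germline_q_cutoff_rule():
    # aggregate VAF mildly below half: p small but not < 1e-5 => germline
    p = pf.germline_binomial_test(120, 300)
    assert 1e-5 < p < 0.05


# ---------------------------------------------------------------------------
# generator-truth recovery


def test_filter_recovers_generator_truth(small_cohort, small_filtered):
    truth = small_cohort.variant_truth
    status = small_filtered["status"]

    germ = truth["origin"] == "germline"
    # germline recall on well-covered sites
    dm_depth = (small_cohort.count_matrix.nr * small_cohort.count_matrix.diploid).sum(axis=1)
    covered = germ & (dm_depth >= 100)
    recall = (status[covered] == "germline").mean()
    assert recall >= 0.99

    art = truth["origin"] == "artifact"
    caught = status[art].isin(["artifact", "quality_fail"]).mean()
    assert caught >= 0.90

    som = truth["origin"] == "somatic"
    false_artifact = (status[som] == "artifact").mean()
    assert false_artifact <= 0.05
    assert (status[som] == "pass").mean() > 0.9
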