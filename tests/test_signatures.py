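"""Catalog building, exposure EM, deconvolution and fold increases."""

import numpy as np
import pandas as pd
import pytest

from gastroclone import refsigs
from gastroclone import signatures as sg


@pytest.fixture(scope="module")
def refs():
    return refsigs.synthetic_sbs_signatures()


# ---------------------------------------------------------------------------
# catalogs


def _snv_frame(rows):
    return pd.DataFrame(rows, columns=["ref", "alt", "context"]).assign(var_class="SNV")


def test_sbs_catalog_pyrimidine_convention():
    cat = sg.build_sbs_catalog(_snv_frame([("C", "A", "ACA")]))
    assert cat.as_series()["A[C>A]A"] == 1 and cat.total == 1


def test_sbs_catalog_reverse_complements_purines():
    cat = sg.build_sbs_catalog(_snv_frame([("G", "T", "TGT")]))
    assert cat.as_series()["A[C>A]A"] == 1


def test_sbs_catalog_empty_and_invalid():
    cat = sg.build_sbs_catalog(_snv_frame([]))
    assert cat.total == 0
    with pytest.warns(UserWarning):
        cat = sg.build_sbs_catalog(_snv_frame([("C", "A", "AAA"), ("C", "T", "ACG")]))
    assert cat.total == 1 and cat.unclassified == 1


def test_id_catalog_homopolymer_channels():
    df = pd.DataFrame(
        {
            "ref": ["T", "TT", "A"],
            "alt": ["TT", "T", "AA"],
            "var_class": ["indel"] * 3,
            "hp_base": ["T", "T", "A"],
            "hp_len": [6, 6, 2],
        }
    )
    cat = sg.build_id_catalog(df)
    s = cat.as_series()
    # 1-bp T insertion in a 6-T run and the matching deletion
    assert s["1:Ins:T:5"] == 1 and s["1:Del:T:5"] == 1
    # purine homopolymers are complemented: A-run insertion counts as T
    assert s["1:Ins:T:2"] == 1
    assert cat.total == 3


def test_id_catalog_unclassifiable_goes_to_catchall():
    df = pd.DataFrame(
        {"ref": ["TACGT"], "alt": ["T"], "var_class": ["indel"], "hp_base": [""], "hp_len": [0]}
    )
    with pytest.warns(UserWarning):
        cat = sg.build_id_catalog(df)
    assert cat.total == 0 and cat.unclassified == 1


def test_catalog_totals_conserved(small_cohort):
    v = small_cohort.count_matrix.variants
    snvs = v[v["var_class"] == "SNV"]
    cat = sg.build_sbs_catalog(snvs)
    assert cat.total + cat.unclassified == len(snvs)


# ---------------------------------------------------------------------------
# exposure EM


def test_exposure_self_recovery(refs):
    cat = sg.MutationCatalog(list(refs.index), refs["SBS1"].to_numpy() * 100, "SBS")
    exp = sg.fit_exposures_em(cat, refs)
    assert exp.proportions["SBS1"] >= 0.99
    assert exp.proportions.sum() == pytest.approx(1.0, abs=1e-9)


def test_exposure_mixture_recovery(refs, rng):
    true = 0.5 * refs["SBS1"] + 0.5 * refs["SBS18"]
    counts = rng.multinomial(10_000, true.to_numpy() / true.sum())
    exp = sg.fit_exposures_em(sg.MutationCatalog(list(refs.index), counts, "SBS"), refs)
    assert abs(exp.proportions["SBS1"] - 0.5) < 0.05
    assert abs(exp.proportions["SBS18"] - 0.5) < 0.05


def test_exposure_single_channel_single_signature(refs):
    counts = np.zeros(96)
    counts[10] = 30
    with pytest.warns(UserWarning):  # below the minimum catalog size
        exp = sg.fit_exposures_em(
            sg.MutationCatalog(list(refs.index), counts, "SBS"), refs, subset=["SBS1"]
        )
    assert exp.proportions["SBS1"] == pytest.approx(1.0)


def test_exposure_contracts(refs):
    empty = sg.MutationCatalog(list(refs.index), np.zeros(96), "SBS")
    with pytest.raises(ValueError):
        sg.fit_exposures_em(empty, refs)
    cat = sg.MutationCatalog(list(refs.index), np.ones(96), "SBS")
    with pytest.raises(ValueError):
        sg.fit_exposures_em(cat, refs, subset=[])
    with pytest.raises(ValueError):
        sg.fit_exposures_em(cat, refs, subset=["SBS99"])


def _grid_oracle(counts, refs, pair, step=1e-3):
    """Dense 1-D simplex search for a two-signature exposure fit."""
    a = refs[pair[0]].to_numpy()
    b = refs[pair[1]].to_numpy()
    best_w, best_ll = 0.0, -np.inf
    for w in np.arange(0.0, 1.0 + step / 2, step):
        mix = np.maximum(w * a + (1 - w) * b, 1e-300)
        ll = float(counts @ np.log(mix))
        if ll > best_ll:
            best_w, best_ll = w, ll
    return best_w


@pytest.mark.parametrize("w_true", [0.0, 0.25, 0.6, 1.0])
def test_em_matches_dense_grid_on_two_signatures(refs, w_true, rng):
    pair = ("SBS1", "SBS18")
    true = w_true * refs[pair[0]] + (1 - w_true) * refs[pair[1]]
    counts = rng.multinomial(5000, true.to_numpy() / true.sum())
    cat = sg.MutationCatalog(list(refs.index), counts, "SBS")
    exp = sg.fit_exposures_em(cat, refs, subset=list(pair))
    assert abs(exp.proportions[pair[0]] - _grid_oracle(counts, refs, pair)) < 0.01


# ---------------------------------------------------------------------------
# deconvolution


def test_deconvolution_accepts_reference_column(refs):
    res = sg.deconvolve_to_reference(refs["SBS18"].to_numpy(), refs)
    assert res.cosine == pytest.approx(1.0, abs=1e-6) and res.accepted
    assert res.weights["SBS18"] > 0.99


def test_deconvolution_rejects_noise_in_expectation(refs, rng):
    cosines = []
    for _ in range(100):
        noise = rng.uniform(size=96)
        noise /= noise.sum()
        cosines.append(sg.deconvolve_to_reference(noise, refs).cosine)
    assert np.mean(cosines) < 0.90


def test_deconvolution_recovers_constructed_mixture(refs):
    mix = 0.6 * refs["SBS1"] + 0.4 * refs["SBS18"]
    res = sg.deconvolve_to_reference(mix.to_numpy(), refs)
    assert res.cosine > 0.99 and res.accepted
    assert abs(res.weights["SBS1"] - 0.6) < 0.05
    assert abs(res.weights["SBS18"] - 0.4) < 0.05


def test_cosine_symmetric_and_scale_invariant(rng):
    u, v = rng.uniform(size=50), rng.uniform(size=50)
    assert sg.cosine_similarity(u, v) == pytest.approx(sg.cosine_similarity(v, u))
    assert sg.cosine_similarity(u, v) == pytest.approx(sg.cosine_similarity(3.7 * u, v))
    assert sg.cosine_similarity(u, u) == pytest.approx(1.0)


def test_sbs5_40_reported_combined():
    exp = pd.Series({"SBS1": 0.2, "SBS5": 0.3, "SBS40a": 0.1, "SBS40c": 0.15, "SBS18": 0.25})
    merged = sg.merge_signature_exposures(exp)
    assert merged["SBS5/40"] == pytest.approx(0.55)
    assert "SBS5" not in merged.index and "SBS40a" not in merged.index


# ---------------------------------------------------------------------------
# fold increases and indel ratios


def test_fold_identity_and_scaling():
    exp = pd.Series({"SBS1": 0.2, "SBS5/40": 0.6, "SBS18": 0.2})
    fold = sg.signature_fold_increase(exp, 1000.0, exp, 1000.0)
    assert np.allclose(fold, 1.0)
    fold = sg.signature_fold_increase(exp, 2000.0, exp, 1000.0)
    assert np.allclose(fold, 2.0)


def test_fold_zero_baseline_flagged_infinite():
    exp = pd.Series({"SBS1": 0.5, "SBS18": 0.5})
    base = pd.Series({"SBS1": 1.0, "SBS18": 0.0})
    fold = sg.signature_fold_increase(exp, 100.0, base, 100.0)
    assert np.isinf(fold["SBS18"])


def test_id2_id1_ratio():
    assert sg.id2_id1_ratio({"ID1": 10, "ID2": 10}) == pytest.approx(1.0)
    assert sg.id2_id1_ratio({"ID1": 10, "ID2": 25}) == pytest.approx(2.5)
    assert sg.id2_id1_ratio({"ID1": 10, "ID2": 0}) == 0.0
    assert np.isnan(sg.id2_id1_ratio({"ID1": 0, "ID2": 5}))
    ids = refsigs.id83_channels()
    counts = np.zeros(83)
    counts[ids.index("1:Ins:T:5")] = 4
    counts[ids.index("1:Del:T:5")] = 8
    cat = sg.MutationCatalog(ids, counts, "ID")
    assert sg.id2_id1_ratio(cat) == pytest.approx(2.0)


def test_metaplasia_raises_id2_to_id1_ratio(rng):
    """Generator truth: the metaplastic indel mix shifts toward deletions."""
    from gastroclone.cohortsim import SimConfig

    cfg = SimConfig()
    base = cfg.baseline_id_mix["ID2"] / cfg.baseline_id_mix["ID1"]
    meta = cfg.metaplasia_id_mix["ID2"] / cfg.metaplasia_id_mix["ID1"]
    assert meta > base
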