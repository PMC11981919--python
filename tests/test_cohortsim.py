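"""Generator contracts: determinism, calibrated rates, VAF geometry."""

import numpy as np
import pytest

from gastroclone import refsigs
from gastroclone.cohortsim import (
    SimConfig,
    SimConfigError,
    _donor_profile,
    draw_depths,
    expected_vaf,
    render_reads,
    simulate_cohort,
    simulate_gland,
)
from gastroclone.matrix import CountMatrix


def _profile(age=60.0, config=None, seed=0, donor_sd=0.0):
    config = config or SimConfig(donor_sd=donor_sd)
    rng = np.random.default_rng(seed)
    prof = _donor_profile("D", age, "F", config, rng)
    prof["intercept_snv"] = 0.0 if donor_sd == 0 else prof["intercept_snv"]
    return prof, config, rng


def test_zero_rates_give_empty_cohort():
    cfg = SimConfig(
        n_donors=2, glands_per_donor=2, snv_rate=0, indel_rate=0,
        artifact_rate=0, n_germline_sites=0, n_phased_snps=0, seed=5,
    )
    cohort = simulate_cohort(cfg)
    assert cohort.count_matrix.n_variants == 0


def test_same_seed_bit_identical():
    a = simulate_cohort(SimConfig(n_donors=2, glands_per_donor=3, seed=42))
    b = simulate_cohort(SimConfig(n_donors=2, glands_per_donor=3, seed=42))
    assert np.array_equal(a.count_matrix.nv, b.count_matrix.nv)
    assert np.array_equal(a.count_matrix.nr, b.count_matrix.nr)
    assert a.count_matrix.variants.equals(b.count_matrix.variants)
    assert a.metadata.equals(b.metadata)


@pytest.mark.parametrize(
    "field, value",
    [
        ("snv_rate", -1.0),
        ("trisomy_timing", 1.5),
        ("contamination", 1.0),
        ("clonal_fraction_range", (0.0, 0.5)),
        ("age_range", (50.0, 20.0)),
        ("baseline_signature_mix", {"SBS1": 0.7, "SBS18": 0.7}),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(SimConfigError):
        cfg.validate()


def test_true_burden_is_poisson_with_rate_times_age():
    """Mean true SNV count at age 60 with the default 27.8/yr rate is 1668."""
    prof, cfg, rng = _profile(age=60.0, donor_sd=0.0)
    counts = [simulate_gland(prof, cfg, rng).n_snv for _ in range(400)]
    expected = 27.8 * 60
    se = np.sqrt(expected / len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se


def test_burden_linearity_recovers_rate():
    """Regressing true counts on age across glands recovers the configured rate."""
    cfg = SimConfig(donor_sd=0.0)
    rng = np.random.default_rng(3)
    ages = rng.uniform(25, 80, size=500)
    counts = []
    for age in ages:
        prof, _, _ = _profile(age=age, config=cfg, donor_sd=0.0)
        counts.append(simulate_gland(prof, cfg, rng).n_snv)
    slope, intercept = np.polyfit(ages, counts, 1)
    resid = counts - (slope * ages + intercept)
    se = np.sqrt(np.sum(resid**2) / (len(ages) - 2) / np.sum((ages - ages.mean()) ** 2))
    assert abs(slope - cfg.snv_rate) < 3 * se


def test_metaplasia_accelerates_signatures_per_config():
    """SBS18 channels are ~8x more frequent in metaplastic glands."""
    cfg = SimConfig(donor_sd=0.0)
    prof, _, rng = _profile(age=70.0, config=cfg)
    base, meta = [], []
    for _ in range(60):
        base.append(simulate_gland(prof, cfg, rng, metaplasia=False))
        meta.append(simulate_gland(prof, cfg, rng, metaplasia=True))

    def sig_count(glands, sig):
        return sum((g.mutations["signature"] == sig).sum() for g in glands)

    for sig, accel in (("SBS18", 8.0), ("SBS1", 3.0), ("SBS5/40", 1.0)):
        ratio = sig_count(meta, sig) / sig_count(base, sig)
        assert abs(ratio - accel) / accel < 0.15


def test_trisomy_timing_zero_has_no_duplicated_mutations():
    cfg = SimConfig(trisomy_timing=0.0, donor_sd=0.0)
    prof, _, rng = _profile(config=cfg)
    g = simulate_gland(prof, cfg, rng, trisomy=True)
    assert not g.mutations["duplicated"].any()


def test_trisomy_timing_one_balances_duplicated_and_not():
    """At t=1 every chromosome-20 mutation predates the gain; the two
    parental copies carry equal shares in expectation."""
    cfg = SimConfig(trisomy_timing=1.0, donor_sd=0.0, trisomy_prob=1.0)
    prof, _, rng = _profile(age=80.0, config=cfg)
    dup = tot = 0
    for _ in range(150):
        g = simulate_gland(prof, cfg, rng, trisomy=True)
        on20 = g.mutations["chrom"] == "20"
        dup += int((g.mutations["duplicated"] & on20).sum())
        tot += int(on20.sum())
    frac = dup / tot
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / tot)


def test_duplicated_flags_require_trisomy():
    prof, cfg, rng = _profile()
    g = simulate_gland(prof, cfg, rng, trisomy=False)
    assert g.trisomy is None and not g.mutations["duplicated"].any()


def test_expected_vaf_geometry():
    assert expected_vaf("somatic", 1.0) == 0.5
    assert expected_vaf("somatic", 1.0, duplicated=True, on_trisomic_chrom=True) == pytest.approx(2 / 3)
    assert expected_vaf("somatic", 1.0, on_trisomic_chrom=True) == pytest.approx(1 / 3)
    assert expected_vaf("germline", 0.9) == 0.5
    assert expected_vaf("germline", 1.0, on_trisomic_chrom=True, germline_on_dup_hap=True) == pytest.approx(2 / 3)


def test_rendered_reads_match_expected_vaf():
    cfg = SimConfig(contamination=0.0, clonal_fraction_range=(1.0, 1.0), donor_sd=0.0)
    prof, _, rng = _profile(age=80.0, config=cfg)
    g = simulate_gland(prof, cfg, rng)
    reads = render_reads(g, cfg, rng)
    assert np.allclose(reads["expected_vaf"], 0.5)
    vaf = reads["nv"].sum() / reads["nr"].sum()
    assert abs(vaf - 0.5) < 0.02


def test_depth_median_calibrated():
    cfg = SimConfig()
    depths = draw_depths(100_000, cfg, np.random.default_rng(0))
    assert 22 <= np.median(depths) <= 24


def test_germline_sites_sit_at_half_vaf(small_cohort):
    germ = (small_cohort.variant_truth["origin"] == "germline").to_numpy()
    vaf = small_cohort.count_matrix.vaf()[germ]
    dm = small_cohort.count_matrix.diploid[germ]
    assert abs(np.nanmean(vaf[dm]) - 0.5) < 0.01


def test_cohort_tsv_round_trip(tmp_path, small_cohort):
    path = tmp_path / "counts.tsv"
    small_cohort.count_matrix.to_tsv(path)
    back = CountMatrix.from_tsv(path)
    assert back.samples == small_cohort.count_matrix.samples
    assert np.array_equal(back.nv, small_cohort.count_matrix.nv)
    assert np.array_equal(back.diploid, small_cohort.count_matrix.diploid)


def test_vcf_round_trip(tmp_path, small_cohort):
    sub = small_cohort.count_matrix.subset_variants(
        np.arange(small_cohort.count_matrix.n_variants) < 50
    )
    path = tmp_path / "out.vcf"
    sub.write_vcf(path)
    back = CountMatrix.from_vcf(path)
    assert back.n_variants == sub.n_variants
    assert sorted(back.samples) == sorted(sub.samples)
    # counts survive the trip (rows are coordinate-sorted in the VCF)
    key = lambda m: sorted(zip(m.variants["chrom"], m.variants["pos"], m.nv.sum(axis=1)))
    assert key(back) == key(sub)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_donors=3, snv_rate=12.5, seed=9)
    p = tmp_path / "cfg.yaml"
    import yaml

    p.write_text(yaml.safe_dump(cfg.to_dict()))
    assert SimConfig.from_file(p) == cfg


def test_channel_conventions_are_cosmic_shaped():
    assert len(refsigs.sbs96_channels()) == 96
    assert len(set(refsigs.id83_channels())) == 83
    sigs = refsigs.synthetic_sbs_signatures()
    assert np.allclose(sigs.sum(axis=0), 1.0)
    ids = refsigs.synthetic_id_signatures()
    assert np.allclose(ids.sum(axis=0), 1.0)
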