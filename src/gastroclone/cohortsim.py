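"""Synthetic cohorts of microdissected gastric glands with known ground truth.

The generator emulates the statistical structure of a gland-microdissection
WGS cohort: monoclonal glands whose somatic burden grows linearly with age
(with a donor random intercept), trinucleotide channels drawn from a
signature mixture that is re-weighted in metaplastic glands, germline
heterozygous sites shared by all glands of a donor, recurrent sequencing
artifacts with near-binomial cross-sample scatter, negative-binomial depth
around a target median, and occasional chromosome-scale trisomies that
split mutations into duplicated (expected VAF 2/3 of the clonal scaling)
and non-duplicated (1/3) classes and impose 2/3 vs 1/3 haplotype VAFs on
phased heterozygous SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import refsigs
from .matrix import CountMatrix, concat_matrices

SITES = ("cardia", "fundus", "body", "antrum")
CI_GRADES = ("absent", "mild", "moderate", "severe")

#: approximate autosome lengths (Mb), used only as sampling weights
CHROM_MB = {
    "1": 248, "2": 242, "3": 198, "4": 190, "5": 182, "6": 171, "7": 159,
    "8": 145, "9": 138, "10": 134, "11": 135, "12": 133, "13": 114,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51,
}

DRIVER_GENES = ("ARID1A", "ARID1B", "ARID2", "CTNNB1", "EEF1A1", "LIPF", "KDM6A")
DRIVER_CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice")


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Cohort-generator settings.

    Defaults are the study conditions: 27.8 SNVs and 2.0 indels per year,
    2.8x / 4.4x metaplasia multipliers, signature accelerations SBS1 3x,
    SBS18 8x, SBS5/40 1x, and 23x median depth.  The baseline signature
    mix is chosen so the per-signature accelerations integrate exactly to
    the overall 2.8x SNV multiplier.
    """

    n_donors: int = 12
    age_range: tuple[float, float] = (25.0, 80.0)
    glands_per_donor: int = 7
    snv_rate: float = 27.8
    indel_rate: float = 2.0
    metaplasia_snv_fold: float = 2.8
    metaplasia_indel_fold: float = 4.4
    signature_accel: dict = field(
        default_factory=lambda: {"SBS1": 3.0, "SBS18": 8.0, "SBS5/40": 1.0}
    )
    baseline_signature_mix: dict = field(
        default_factory=lambda: {"SBS1": 0.2, "SBS5/40": 0.6, "SBS18": 0.2}
    )
    baseline_id_mix: dict = field(
        default_factory=lambda: {"ID1": 0.5, "ID2": 0.3, "ID5": 0.2}
    )
    metaplasia_id_mix: dict = field(
        default_factory=lambda: {"ID1": 0.45, "ID2": 0.45, "ID5": 0.10}
    )
    depth_median: float = 23.0
    depth_shape: float = 15.0
    clonal_fraction_range: tuple[float, float] = (0.75, 1.0)
    contamination: float = 0.1
    n_germline_sites: int = 30
    n_phased_snps: int = 40
    artifact_rate: float = 20.0
    trisomy_prob: float = 0.1
    trisomy_timing: float = 0.3
    trisomy_chrom: str = "20"
    n_metaplastic: int = 0
    donor_sd: float = 60.0
    driver_prob: float = 0.15
    area_mean: float = 0.05
    area_sigma: float = 0.5
    min_call_reads: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "snv_rate", "indel_rate", "metaplasia_snv_fold", "metaplasia_indel_fold",
            "artifact_rate", "donor_sd", "depth_median", "depth_shape", "area_mean",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        for name in ("n_donors", "glands_per_donor", "n_germline_sites",
                     "n_phased_snps", "n_metaplastic"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not (0 <= self.trisomy_timing <= 1):
            raise SimConfigError("trisomy_timing must lie in [0, 1]")
        if not (0 <= self.trisomy_prob <= 1):
            raise SimConfigError("trisomy_prob must lie in [0, 1]")
        if not (0 <= self.contamination < 1):
            raise SimConfigError("contamination must lie in [0, 1)")
        if not (0 <= self.driver_prob <= 1):
            raise SimConfigError("driver_prob must lie in [0, 1]")
        lo, hi = self.clonal_fraction_range
        if not (0 < lo <= hi <= 1):
            raise SimConfigError("clonal_fraction_range must satisfy 0 < lo <= hi <= 1")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise SimConfigError("age_range must satisfy 0 < min <= max")
        if abs(sum(self.baseline_signature_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("baseline_signature_mix must sum to 1")
        for name in ("baseline_id_mix", "metaplasia_id_mix"):
            if abs(sum(getattr(self, name).values()) - 1.0) > 1e-9:
                raise SimConfigError(f"{name} must sum to 1")
        if self.trisomy_chrom not in CHROM_MB:
            raise SimConfigError("trisomy_chrom must be an autosome label 1..22")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["clonal_fraction_range"] = list(self.clonal_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("age_range", "clonal_fraction_range"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class TrisomyTruth:
    chrom: str
    parental_copy: str  # duplicated haplotype, "A" or "B"
    timing: float


@dataclass
class GlandTruth:
    donor: str
    sample: str
    age: float
    site: str
    metaplasia: bool
    ci_grade: str
    clonal_fraction: float
    area: float
    mutations: pd.DataFrame  # channel, signature, var_class, chrom, cell_fraction, duplicated
    trisomy: Optional[TrisomyTruth] = None
    driver: Optional[dict] = None

    @property
    def n_snv(self) -> int:
        return int((self.mutations["var_class"] == "SNV").sum())

    @property
    def n_indel(self) -> int:
        return int((self.mutations["var_class"] == "indel").sum())


@dataclass
class SyntheticCohort:
    config: SimConfig
    count_matrix: CountMatrix
    metadata: pd.DataFrame
    gland_truths: list
    variant_truth: pd.DataFrame  # one row per count-matrix variant
    phased_snp_truth: pd.DataFrame  # donor, chrom, pos, hap

    def validate(self) -> None:
        assert len(self.variant_truth) == self.count_matrix.n_variants
        assert set(self.count_matrix.samples) == set(self.metadata["sample"])


# ---------------------------------------------------------------------------
# depth model


@lru_cache(maxsize=64)
def _nb_params(median: float, shape: float) -> tuple[float, float]:
    """Negative-binomial (n, p) whose median equals the requested depth median."""
    for mean in np.arange(median, median + 2.0, 0.05):
        p = shape / (shape + mean)
        if stats.nbinom.ppf(0.5, shape, p) == round(median):
            return shape, p
    p = shape / (shape + median)
    return shape, p


def draw_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    r, p = _nb_params(config.depth_median, config.depth_shape)
    return rng.negative_binomial(r, p, size=n).astype(np.int32)


# ---------------------------------------------------------------------------
# channel bookkeeping


def _channel_to_snv_alleles(channel: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """ref, alt, context for an SBS channel; half are emitted purine-stranded."""
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    context = five + ref + three
    if rng.random() < 0.5:
        context = refsigs.revcomp(context)
        ref = refsigs.COMPLEMENT[ref]
        alt = refsigs.COMPLEMENT[alt]
    return ref, alt, context


def _channel_to_indel_alleles(channel: str) -> tuple[str, str, str, int]:
    """ref, alt, homopolymer base and run length for a 1-bp ID channel."""
    size, kind, base, cat = channel.split(":")
    if size != "1":
        raise ValueError(f"generator only emits 1-bp indel channels, got {channel}")
    cat = int(cat)
    run = cat + 1 if kind == "Del" else cat
    if cat == 5:  # open-ended category: use the shortest run mapping to it
        run = 6 if kind == "Del" else 5
    if kind == "Del":
        run = max(run, 1)
        ref, alt = base * 2, base
    else:
        ref, alt = base, base * 2
    return ref, alt, base, run


def _channel_maps() -> tuple[dict, dict, dict]:
    """Cached channel -> allele lookup tables (pyrimidine and purine strand)."""
    global _CHANNEL_CACHE
    try:
        return _CHANNEL_CACHE
    except NameError:
        pass
    pyr, pur = {}, {}
    for ch in refsigs.sbs96_channels():
        five, rest = ch.split("[")
        sub, three = rest.split("]")
        ref, alt = sub.split(">")
        context = five + ref + three
        pyr[ch] = (ref, alt, context)
        pur[ch] = (refsigs.COMPLEMENT[ref], refsigs.COMPLEMENT[alt], refsigs.revcomp(context))
    ind = {ch: _channel_to_indel_alleles(ch)
           for ch in refsigs.id83_channels() if ch.startswith("1:")}
    _CHANNEL_CACHE = (pyr, pur, ind)
    return _CHANNEL_CACHE


def _alleles_from_channels(channels: np.ndarray, is_snv: np.ndarray,
                           rng: np.random.Generator):
    """Vectorised channel -> (ref, alt, context, hp_base, hp_len) mapping.

    Half the SNVs are emitted on the purine strand so that catalog building
    has to reverse-complement them back.
    """
    pyr, pur, ind = _channel_maps()
    n = len(channels)
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    context = np.full(n, "", dtype=object)
    hp_base = np.full(n, "", dtype=object)
    hp_len = np.zeros(n, dtype=int)
    flip = rng.random(n) < 0.5
    for i in range(n):
        ch = channels[i]
        if is_snv[i]:
            ref[i], alt[i], context[i] = (pur if flip[i] else pyr)[ch]
        else:
            ref[i], alt[i], hp_base[i], hp_len[i] = ind[ch]
    return ref, alt, context, hp_base, hp_len


# ---------------------------------------------------------------------------
# gland-level simulation


def _draw_channels(weights: pd.Series, n: int, rng: np.random.Generator) -> np.ndarray:
    w = weights.to_numpy(dtype=float)
    return rng.choice(weights.index.to_numpy(), size=n, p=w / w.sum())


def simulate_gland(
    donor_profile: dict,
    config: SimConfig,
    rng: np.random.Generator,
    metaplasia: bool = False,
    trisomy: Optional[bool] = None,
) -> GlandTruth:
    """Draw one gland's ground truth (mutation list, clonality, trisomy)."""
    age = donor_profile["age"]
    if age <= 0:
        raise SimConfigError("age must be > 0")
    sbs_refs = donor_profile["sbs_refs"]
    id_refs = donor_profile["id_refs"]

    cf = rng.uniform(*config.clonal_fraction_range)
    site = SITES[rng.integers(len(SITES))]
    ci = rng.choice(CI_GRADES, p=[0.4, 0.3, 0.2, 0.1])
    area = float(rng.lognormal(np.log(config.area_mean), config.area_sigma))

    if trisomy is None:
        trisomy = bool(rng.random() < config.trisomy_prob)
    tri = (
        TrisomyTruth(
            chrom=config.trisomy_chrom,
            parental_copy="A" if rng.random() < 0.5 else "B",
            timing=config.trisomy_timing,
        )
        if trisomy
        else None
    )

    base_snv = config.snv_rate * age + donor_profile["intercept_snv"]
    base_snv = max(base_snv, 0.0)
    mix = config.baseline_signature_mix
    if metaplasia:
        accel = {s: config.signature_accel.get(s, 1.0) for s in mix}
        total_accel = sum(mix[s] * accel[s] for s in mix)
        sig_means = {
            s: base_snv * mix[s] * accel[s] * (config.metaplasia_snv_fold / total_accel)
            for s in mix
        }
    else:
        sig_means = {s: base_snv * mix[s] for s in mix}

    chrom_labels = np.array(list(CHROM_MB))
    chrom_w = np.array(list(CHROM_MB.values()), dtype=float)
    chrom_w /= chrom_w.sum()

    rows = []
    for sig, mean in sig_means.items():
        n = rng.poisson(mean)
        if n == 0:
            continue
        channels = _draw_channels(sbs_refs[sig], n, rng)
        chroms = rng.choice(chrom_labels, size=n, p=chrom_w)
        for ch, chrom in zip(channels, chroms):
            rows.append((ch, sig, "SNV", chrom))

    base_indel = max(config.indel_rate * age + donor_profile["intercept_indel"], 0.0)
    id_mix = config.metaplasia_id_mix if metaplasia else config.baseline_id_mix
    fold = config.metaplasia_indel_fold if metaplasia else 1.0
    for sig, w in id_mix.items():
        n = rng.poisson(base_indel * fold * w)
        if n == 0:
            continue
        channels = _draw_channels(id_refs[sig], n, rng)
        chroms = rng.choice(chrom_labels, size=n, p=chrom_w)
        for ch, chrom in zip(channels, chroms):
            rows.append((ch, sig, "indel", chrom))

    mut = pd.DataFrame(rows, columns=["channel", "signature", "var_class", "chrom"])
    mut["cell_fraction"] = cf
    mut["duplicated"] = False
    if tri is not None and len(mut):
        # a pre-gain mutation on the to-be-duplicated parental copy becomes
        # duplicated; with two copies before the gain and three after,
        # P(duplicated | on chrom) = t / (3 - t)
        on_tri = (mut["chrom"] == tri.chrom).to_numpy()
        p_dup = tri.timing / (3.0 - tri.timing)
        mut.loc[on_tri, "duplicated"] = rng.random(on_tri.sum()) < p_dup

    driver = None
    if rng.random() < config.driver_prob:
        driver = {
            "gene": str(rng.choice(DRIVER_GENES)),
            "consequence": str(rng.choice(DRIVER_CONSEQUENCES)),
            "cell_fraction": cf,
        }

    return GlandTruth(
        donor=donor_profile["donor"],
        sample=donor_profile.pop("next_sample", f"{donor_profile['donor']}_g"),
        age=age,
        site=site,
        metaplasia=metaplasia,
        ci_grade=str(ci),
        clonal_fraction=cf,
        area=area,
        mutations=mut,
        trisomy=tri,
        driver=driver,
    )


# ---------------------------------------------------------------------------
# read rendering


def expected_vaf(
    kind: str,
    clonal_scaling: float,
    duplicated: bool = False,
    on_trisomic_chrom: bool = False,
    germline_on_dup_hap: bool = False,
) -> float:
    """Expected VAF of a variant in one sample.

    ``clonal_scaling`` is clone fraction x (1 - contamination).  Somatic
    diploid variants sit at half the scaling; on a trisomic chromosome
    duplicated variants sit at 2/3 and non-duplicated at 1/3 of it.
    Germline heterozygous sites stay at 0.5 except on a trisomic
    chromosome, where the duplicated haplotype rises toward 2/3.
    """
    g = clonal_scaling
    if kind == "germline":
        if not on_trisomic_chrom:
            return 0.5
        return g * (2.0 / 3.0) + (1 - g) * 0.5 if germline_on_dup_hap else g / 3.0 + (1 - g) * 0.5
    if kind == "somatic":
        if on_trisomic_chrom:
            return g * (2.0 / 3.0) if duplicated else g / 3.0
        return g / 2.0
    raise ValueError(f"unknown variant kind {kind!r}")


def render_reads(
    truth: GlandTruth, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Render NV/NR for a gland's own mutations (one count-matrix column)."""
    mut = truth.mutations
    g = truth.clonal_fraction * (1 - config.contamination)
    tri_chrom = truth.trisomy.chrom if truth.trisomy else None
    p = np.array(
        [
            expected_vaf(
                "somatic",
                g,
                duplicated=bool(d),
                on_trisomic_chrom=(c == tri_chrom),
            )
            for c, d in zip(mut["chrom"], mut["duplicated"])
        ]
    ) if len(mut) else np.zeros(0)
    nr = draw_depths(len(mut), config, rng)
    nv = rng.binomial(nr, p) if len(mut) else np.zeros(0, dtype=int)
    return pd.DataFrame({"nv": nv.astype(np.int32), "nr": nr, "expected_vaf": p})


# ---------------------------------------------------------------------------
# donor- and cohort-level assembly


def _donor_profile(donor_id: str, age: float, sex: str, config: SimConfig,
                   rng: np.random.Generator) -> dict:
    sbs = refsigs.synthetic_sbs_signatures()
    ids = refsigs.synthetic_id_signatures()
    return {
        "donor": donor_id,
        "age": age,
        "sex": sex,
        # donor-level burden offsets; a zero mutation rate admits no offset
        "intercept_snv": rng.normal(0.0, config.donor_sd) if config.snv_rate > 0 else 0.0,
        "intercept_indel": (
            rng.normal(0.0, config.donor_sd * config.indel_rate / max(config.snv_rate, 1e-9))
            if config.indel_rate > 0
            else 0.0
        ),
        "sbs_refs": {s: sbs[s] for s in config.baseline_signature_mix},
        "id_refs": {s: ids[s] for s in config.baseline_id_mix},
    }


def _germline_sites(donor_id: str, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Heterozygous germline sites: scattered autosomal + phased SNPs on the trisomy chromosome."""
    chrom_labels = np.array(list(CHROM_MB))
    chrom_w = np.array(list(CHROM_MB.values()), dtype=float)
    chrom_w /= chrom_w.sum()
    all_channels = np.array(refsigs.sbs96_channels())
    rows = []
    for _ in range(config.n_germline_sites):
        ch = str(rng.choice(all_channels))
        ref, alt, context = _channel_to_snv_alleles(ch, rng)
        chrom = str(rng.choice(chrom_labels, p=chrom_w))
        rows.append((chrom, int(rng.integers(1, CHROM_MB[chrom] * 10**6)), ref, alt, context, ""))
    for _ in range(config.n_phased_snps):
        ch = str(rng.choice(all_channels))
        ref, alt, context = _channel_to_snv_alleles(ch, rng)
        hap = "A" if rng.random() < 0.5 else "B"
        rows.append(
            (config.trisomy_chrom, int(rng.integers(1, CHROM_MB[config.trisomy_chrom] * 10**6)),
             ref, alt, context, hap)
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "context", "hap"])


def _artifact_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = rng.poisson(config.artifact_rate)
    chrom_labels = np.array(list(CHROM_MB))
    sbs_channels = np.array(refsigs.sbs96_channels())
    id_channels = np.array([c for c in refsigs.id83_channels() if c.startswith("1:")])
    rows = []
    for _ in range(n):
        chrom = str(rng.choice(chrom_labels))
        pos = int(rng.integers(1, CHROM_MB[chrom] * 10**6))
        err = float(rng.uniform(0.02, 0.15))
        if rng.random() < 0.8:
            ch = str(rng.choice(sbs_channels))
            ref, alt, context = _channel_to_snv_alleles(ch, rng)
            rows.append((chrom, pos, ref, alt, "SNV", context, "", 0, err, ch))
        else:
            ch = str(rng.choice(id_channels))
            ref, alt, base, run = _channel_to_indel_alleles(ch)
            rows.append((chrom, pos, ref, alt, "indel", "", base, run, err, ch))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "var_class", "context",
                 "hp_base", "hp_len", "error_vaf", "channel"],
    )


def _simulate_donor(
    donor_id: str,
    age: float,
    config: SimConfig,
    rng: np.random.Generator,
    n_metaplastic: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, list, pd.DataFrame]:
    """One donor: glands, shared germline/artifact sites, rendered counts."""
    sex = "M" if rng.random() < 0.5 else "F"
    profile = _donor_profile(donor_id, age, sex, config, rng)

    glands: list[GlandTruth] = []
    flags = [False] * config.glands_per_donor + [True] * n_metaplastic
    for i, meta in enumerate(flags):
        profile["next_sample"] = f"{donor_id}_gl{i:02d}"
        glands.append(simulate_gland(profile, config, rng, metaplasia=meta))

    germline = _germline_sites(donor_id, config, rng)
    artifacts = _artifact_sites(config, rng)

    # assemble the donor's variant table: somatic (per gland), germline, artifacts
    som_frames = []
    for gl in glands:
        m = gl.mutations.copy()
        m["origin_sample"] = gl.sample
        som_frames.append(m)
    som = pd.concat(som_frames, ignore_index=True) if som_frames else pd.DataFrame(
        columns=["channel", "signature", "var_class", "chrom", "cell_fraction",
                 "duplicated", "origin_sample"]
    )
    ref, alt, context, hp_base, hp_len = _alleles_from_channels(
        som["channel"].to_numpy(), (som["var_class"] == "SNV").to_numpy(), rng
    )
    lengths = som["chrom"].map({c: mb * 10**6 for c, mb in CHROM_MB.items()}).to_numpy(float)
    pos = (rng.random(len(som)) * (lengths - 1)).astype(np.int64) + 1

    variants = pd.DataFrame(
        {
            "chrom": som["chrom"].to_numpy(),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "var_class": som["var_class"].to_numpy(),
            "context": context,
            "hp_base": hp_base,
            "hp_len": hp_len,
        }
    )
    truth = pd.DataFrame(
        {
            "donor": donor_id,
            "origin": "somatic",
            "origin_sample": som["origin_sample"].to_numpy(),
            "signature": som["signature"].to_numpy(),
            "channel": som["channel"].to_numpy(),
            "duplicated": som["duplicated"].to_numpy(),
            "cell_fraction": som["cell_fraction"].to_numpy(),
            "hap": "",
        }
    )
    germ_var = pd.DataFrame(
        {
            "chrom": germline["chrom"], "pos": germline["pos"], "ref": germline["ref"],
            "alt": germline["alt"], "var_class": "SNV", "context": germline["context"],
            "hp_base": "", "hp_len": 0,
        }
    )
    germ_truth = pd.DataFrame(
        {
            "donor": donor_id, "origin": "germline", "origin_sample": "", "signature": "",
            "channel": "", "duplicated": False, "cell_fraction": 1.0, "hap": germline["hap"],
        }
    )
    art_var = artifacts[
        ["chrom", "pos", "ref", "alt", "var_class", "context", "hp_base", "hp_len"]
    ].copy()
    art_truth = pd.DataFrame(
        {
            "donor": donor_id, "origin": "artifact", "origin_sample": "", "signature": "",
            "channel": artifacts["channel"], "duplicated": False,
            "cell_fraction": artifacts["error_vaf"], "hap": "",
        }
    )
    var_parts = [f for f in (variants, germ_var, art_var) if len(f)]
    truth_parts = [f for f in (truth, germ_truth, art_truth) if len(f)]
    if var_parts:
        variants = pd.concat(var_parts, ignore_index=True)
        truth = pd.concat(truth_parts, ignore_index=True)

    # mapping-quality annotations: real variants pass; a share of artifacts fails
    n_var = len(variants)
    asmd = rng.uniform(140, 170, size=n_var)
    clpm = np.zeros(n_var)
    art_idx = np.flatnonzero((truth["origin"] == "artifact").to_numpy())
    fail = art_idx[rng.random(len(art_idx)) < 0.3]
    asmd[fail] = rng.uniform(100, 139, size=len(fail))
    clpm[fail] = rng.integers(0, 2, size=len(fail))
    variants["asmd"] = np.round(asmd, 1)
    variants["clpm"] = clpm

    # render per-sample counts
    origin = truth["origin"].to_numpy()
    origin_sample = truth["origin_sample"].to_numpy()
    duplicated = truth["duplicated"].to_numpy()
    hap = truth["hap"].to_numpy()
    err_vaf = truth["cell_fraction"].to_numpy()  # for artifacts this is the error VAF
    chroms = variants["chrom"].to_numpy()

    n_samp = len(glands)
    nv = np.zeros((n_var, n_samp), dtype=np.int32)
    nr = np.zeros_like(nv)
    diploid = np.ones_like(nv, dtype=bool)
    for j, gl in enumerate(glands):
        g = gl.clonal_fraction * (1 - config.contamination)
        tri = gl.trisomy
        p = np.zeros(n_var)
        germ = origin == "germline"
        art = origin == "artifact"
        own = origin_sample == gl.sample
        p[art] = err_vaf[art]
        if tri is None:
            p[germ] = 0.5
            p[own] = g / 2.0
        else:
            on_tri = chroms == tri.chrom
            p[germ & ~on_tri] = 0.5
            dup_hap = germ & on_tri & (hap == tri.parental_copy)
            oth_hap = germ & on_tri & (hap != tri.parental_copy)
            p[dup_hap] = g * (2 / 3) + (1 - g) * 0.5
            p[oth_hap] = g / 3 + (1 - g) * 0.5
            p[own & ~on_tri] = g / 2.0
            p[own & on_tri & duplicated] = g * (2 / 3)
            p[own & on_tri & ~duplicated] = g / 3.0
            diploid[on_tri, j] = False
        depths = draw_depths(n_var, config, rng)
        nr[:, j] = depths
        nv[:, j] = rng.binomial(depths, p)

    # calling emulation: a variant must reach min_call_reads in some sample
    called = nv.max(axis=1) >= config.min_call_reads
    matrix = CountMatrix(
        variants=variants.loc[called].reset_index(drop=True),
        samples=[gl.sample for gl in glands],
        nv=nv[called],
        nr=nr[called],
        diploid=diploid[called],
    )
    truth = truth.loc[called].reset_index(drop=True)

    meta = pd.DataFrame(
        {
            "sample": [gl.sample for gl in glands],
            "donor": donor_id,
            "age": age,
            "sex": sex,
            "site": [gl.site for gl in glands],
            "metaplasia": [gl.metaplasia for gl in glands],
            "ci_grade": [gl.ci_grade for gl in glands],
            "area": [gl.area for gl in glands],
        }
    )
    phased = germline.loc[germline["hap"] != "", ["chrom", "pos", "hap"]].copy()
    phased.insert(0, "donor", donor_id)
    return matrix, meta, truth, glands, phased


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort; identical config (incl. seed) is bit-reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ages = rng.uniform(*config.age_range, size=config.n_donors)
    # extra metaplastic glands are spread round-robin over donors
    extra = np.zeros(config.n_donors, dtype=int)
    for k in range(config.n_metaplastic):
        extra[k % config.n_donors] += 1

    matrices, metas, truths, glands, phased = [], [], [], [], []
    for i in range(config.n_donors):
        m, md, tr, gl, ph = _simulate_donor(
            f"D{i:02d}", float(ages[i]), config, rng, n_metaplastic=int(extra[i])
        )
        matrices.append(m)
        metas.append(md)
        truths.append(tr)
        glands.extend(gl)
        phased.append(ph)

    cohort = SyntheticCohort(
        config=config,
        count_matrix=concat_matrices(matrices),
        metadata=pd.concat(metas, ignore_index=True),
        gland_truths=glands,
        variant_truth=pd.concat(truths, ignore_index=True),
        phased_snp_truth=pd.concat(phased, ignore_index=True),
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# targeted-panel rendering (for phased-SNP trisomy detection)


def simulate_panel_counts(
    phased_snps: pd.DataFrame,
    trisomic: bool,
    rng: np.random.Generator,
    clonal_fraction: float = 1.0,
    contamination: float = 0.1,
    depth_mean: float = 30.0,
    dup_hap: str = "A",
) -> pd.DataFrame:
    """Render SNP counts for one panel microdissection (diploid or trisomic)."""
    g = clonal_fraction * (1 - contamination)
    hap = phased_snps["hap"].to_numpy()
    if trisomic:
        p = np.where(hap == dup_hap, g * (2 / 3) + (1 - g) * 0.5, g / 3 + (1 - g) * 0.5)
    else:
        p = np.full(len(hap), 0.5)
    nr = rng.poisson(depth_mean, size=len(hap)).astype(np.int32)
    nv = rng.binomial(nr, p).astype(np.int32)
    out = phased_snps[["chrom", "pos", "hap"]].copy()
    out["nv"] = nv
    out["nr"] = nr
    return out


# ---------------------------------------------------------------------------
# cohort serialization


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.count_matrix.to_tsv(outdir / "counts.tsv")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    cohort.variant_truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
    cohort.phased_snp_truth.to_csv(outdir / "phased_snps.tsv", sep="\t", index=False)
    (outdir / "simconfig.yaml").write_text(yaml.safe_dump(cohort.config.to_dict()))
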