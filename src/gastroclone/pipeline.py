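"""End-to-end orchestration: simulate -> filter -> burden -> signatures ->
CNV timing -> trisomy -> mutant fraction, with per-stage TSV/JSON outputs
and a provenance header logging every threshold and seed."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv_timing as ct
from . import clonality_burden as cb
from . import mutant_fraction as mf
from . import postfilter as pf
from . import refsigs
from . import signatures as sg
from . import trisomy_phase as tp
from .cohortsim import SimConfig, SyntheticCohort, simulate_cohort, simulate_panel_counts, write_cohort


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    min_reads: int = 4
    germline_q_cutoff: float = 1e-5
    rho_snv: float = 0.1
    rho_indel: float = 0.15
    cosine_accept: float = 0.90
    clonality_cutoff: float = 0.25
    delta_vaf: float = 0.1
    panel_min_depth: int = 6
    n_panel_samples: int = 12
    seed: int = 0
    outdir: str = "gastroclone_out"

    def validate(self) -> None:
        self.sim.validate()
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        for name in ("rho_snv", "rho_indel", "cosine_accept", "clonality_cutoff", "delta_vaf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.germline_q_cutoff <= 1):
            raise ValueError("germline_q_cutoff must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["sim"] = SimConfig.from_dict(d.get("sim", {}))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})


def run_pipeline(config: PipelineConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Run every stage on a (simulated) cohort and write a report bundle.

    Identical config + seed reproduces identical outputs.  A stage failure
    aborts with the stage name in the error.  Returns a report dict (also
    written as report.json in the output directory).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "min_reads", "germline_q_cutoff", "rho_snv", "rho_indel",
                "cosine_accept", "clonality_cutoff", "delta_vaf", "panel_min_depth",
            )
        },
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        if cohort is None:
            sim = SimConfig.from_dict({**config.sim.to_dict(), "seed": config.seed})
            cohort = simulate_cohort(sim)
        write_cohort(cohort, outdir / "cohort")
        report["stages"]["simulate"] = {
            "n_variants": cohort.count_matrix.n_variants,
            "n_samples": cohort.count_matrix.n_samples,
        }

        stage = "filter"
        donors = dict(zip(cohort.metadata["sample"], cohort.metadata["donor"]))
        thresholds = pf.FilterThresholds(
            germline_q=config.germline_q_cutoff,
            rho_snv=config.rho_snv,
            rho_indel=config.rho_indel,
        )
        filter_table = pf.classify_variants(cohort.count_matrix, donors, thresholds)
        pf.write_filter_table(cohort.count_matrix, filter_table, outdir / "filtered.tsv")
        report["stages"]["filter"] = filter_table["status"].value_counts().to_dict()

        stage = "burden"
        burden = cb.sample_burden_table(
            cohort.count_matrix, filter_table, cohort.metadata,
            min_reads=config.min_reads, seed=config.seed,
        )
        burden.to_csv(outdir / "burden.tsv", sep="\t", index=False)
        nonmeta = burden[~burden["metaplasia"].astype(bool) & ~burden["excluded"]]
        models: dict = {}
        rate_snv = None
        if len(nonmeta) >= 3 and nonmeta["donor"].nunique() >= 2:
            rate_snv = cb.fit_burden_rate_model(
                nonmeta["corrected_snv"], nonmeta["age"], nonmeta["donor"], formula="age"
            )
            rate_indel = cb.fit_burden_rate_model(
                nonmeta["corrected_indel"], nonmeta["age"], nonmeta["donor"], formula="age"
            )
            models = {
                "snv_per_year": rate_snv.slope,
                "snv_ci": rate_snv.slope_ci,
                "indel_per_year": rate_indel.slope,
                "indel_ci": rate_indel.slope_ci,
            }
            meta_rows = burden[burden["metaplasia"].astype(bool) & ~burden["excluded"]]
            if len(meta_rows):
                models["meta_fold_snv_mean"] = float(np.nanmean(
                    cb.burden_fold_change(meta_rows["corrected_snv"], meta_rows["age"], rate_snv)
                ))
                models["meta_fold_indel_mean"] = float(np.nanmean(
                    cb.burden_fold_change(meta_rows["corrected_indel"], meta_rows["age"], rate_indel)
                ))
        (outdir / "rate_models.json").write_text(json.dumps(models, indent=2, default=float))
        report["stages"]["burden"] = models

        stage = "signatures"
        refs = refsigs.synthetic_sbs_signatures()
        subset = [s for s in config.sim.baseline_signature_mix if s in refs.columns]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exposures = sg.sample_exposure_table(
                cohort.count_matrix, filter_table, refs, subset=subset,
                min_reads=config.min_reads,
            )
        exposures.to_csv(outdir / "signature_exposures.tsv", sep="\t")
        sig_report: dict = {"n_samples": len(exposures)}
        if rate_snv is not None:
            folds = sg.signature_fold_table(exposures, burden, rate_snv)
            folds.to_csv(outdir / "signature_folds.tsv", sep="\t", index=False)
            if len(folds):
                sig_report["median_folds"] = {
                    c.replace("fold_", ""): float(folds[c].median())
                    for c in folds.columns if c.startswith("fold_")
                }
        report["stages"]["signatures"] = sig_report

        stage = "cnv_timing"
        timing_rows = []
        burden_ix = burden.set_index("sample")
        for gl in cohort.gland_truths:
            if gl.trisomy is None:
                continue
            region = ct.CNVRegion.trisomy(gl.trisomy.chrom)
            peak = burden_ix.loc[gl.sample, "peak_vaf"] if gl.sample in burden_ix.index else np.nan
            scaling = min(2 * peak, 1.0) if np.isfinite(peak) else 1.0
            est = ct.time_region_in_sample(
                cohort.count_matrix, filter_table, gl.sample, region,
                clonal_scaling=scaling, min_reads=config.min_reads,
            )
            if est is not None:
                timing_rows.append({
                    "sample": gl.sample, "chrom": gl.trisomy.chrom, "T": est.T,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "true_timing": gl.trisomy.timing,
                })
        pd.DataFrame(timing_rows).to_csv(outdir / "cnv_timing.tsv", sep="\t", index=False)
        report["stages"]["cnv_timing"] = {"n_timed": len(timing_rows)}

        stage = "trisomy"
        report["stages"]["trisomy"] = _trisomy_stage(config, cohort, outdir)

        stage = "mutant_fraction"
        report["stages"]["mutant_fraction"] = _mutant_fraction_stage(config, cohort, outdir)
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float, sort_keys=True))
    return report


def _trisomy_stage(config: PipelineConfig, cohort: SyntheticCohort, outdir: Path) -> dict:
    """Phase SNPs from trisomic WGS glands, simulate panel samples, call and test."""
    tri_report: dict = {"n_panel_calls": 0}
    tri_glands = [g for g in cohort.gland_truths if g.trisomy is not None]
    if tri_glands:
        donor = pd.Series([g.donor for g in tri_glands]).value_counts().index[0]
        donor_tris = [g for g in tri_glands if g.donor == donor]
        snps = cohort.phased_snp_truth[cohort.phased_snp_truth["donor"] == donor]
        vafs = snps[["chrom", "pos"]].copy()
        mat = cohort.count_matrix
        pos_ix = {
            (c, p): i
            for i, (c, p) in enumerate(zip(mat.variants["chrom"].astype(str), mat.variants["pos"]))
        }
        for g in donor_tris:
            j = mat.samples.index(g.sample)
            col = []
            for c_, p_ in zip(vafs["chrom"].astype(str), vafs["pos"]):
                i = pos_ix.get((c_, p_))
                col.append(
                    mat.nv[i, j] / mat.nr[i, j] if i is not None and mat.nr[i, j] > 0 else np.nan
                )
            vafs[g.sample] = col
        vafs = vafs.dropna()
        if len(vafs) >= 5:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                phased = tp.phase_snps_from_wgs(vafs)
            rng = np.random.default_rng(config.seed + 101)
            panel, truth_tri = {}, {}
            for k in range(config.n_panel_samples):
                name = f"{donor}_panel{k:02d}"
                truth_tri[name] = bool(rng.random() < 0.4)
                panel[name] = simulate_panel_counts(
                    phased.snps, truth_tri[name], rng,
                    contamination=config.sim.contamination,
                )
            calls = tp.call_trisomies(
                panel, phased, min_depth=config.panel_min_depth, delta_vaf=config.delta_vaf
            )
            calls["true_trisomy"] = calls["sample"].map(truth_tri)
            calls.to_csv(outdir / "trisomy_calls.tsv", sep="\t", index=False)
            tri_report = {
                "donor": donor,
                "phasing_concordance": phased.concordance,
                "n_panel_calls": int(calls["call"].sum()),
                "n_panel_true": int(sum(truth_tri.values())),
            }
    # site enrichment over WGS glands
    tri_by_sample = {g.sample: (g.trisomy is not None) for g in cohort.gland_truths}
    enr = pd.DataFrame({
        "site": cohort.metadata.set_index("sample")["site"],
        "tri": pd.Series(tri_by_sample),
    })
    table = (
        enr.groupby("site")["tri"]
        .agg([("called", "sum"), ("not_called", lambda s: int((~s).sum()))])
        .to_numpy()
    )
    tri_report["site_table"] = table.tolist()
    tri_report["site_fisher_p"] = tp.fisher_exact_rxc(table)
    (outdir / "trisomy_enrichment.json").write_text(
        json.dumps(tri_report, indent=2, default=float)
    )
    return tri_report


def _mutant_fraction_stage(config: PipelineConfig, cohort: SyntheticCohort, outdir: Path) -> dict:
    driver_rows = []
    for g in cohort.gland_truths:
        if g.driver is None:
            continue
        vaf = g.driver["cell_fraction"] * (1 - config.sim.contamination) / 2.0
        driver_rows.append({
            "sample": g.sample, "gene": g.driver["gene"],
            "consequence": g.driver["consequence"], "vaf": vaf,
            "local_ploidy": 2.0, "pos": 0,
        })
    drivers = pd.DataFrame(
        driver_rows, columns=["sample", "gene", "consequence", "vaf", "local_ploidy", "pos"]
    )
    if len(drivers):
        drivers = mf.annotate_drivers(drivers)
        drivers = drivers[drivers["is_driver"]]
    md = cohort.metadata[["sample", "donor", "age", "site", "metaplasia", "ci_grade", "area"]]
    fraction, per_md = mf.mutant_epithelium_fraction(md, drivers)
    per_md.to_csv(outdir / "mutant_fraction.tsv", sep="\t", index=False)
    mf_report: dict = {"cohort_fraction": fraction}
    donor_tab = mf.donor_proportions(per_md)
    if len(donor_tab) >= 3 and donor_tab["proportion"].nunique() > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fits = mf.fit_mutant_proportion_models(donor_tab)
                mf_report["model_comparisons"] = fits["comparisons"]
            except ValueError:
                pass
    return mf_report
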