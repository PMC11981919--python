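"""Parameter-recovery runs on synthetic cohorts.

Each replicate simulates a cohort at the generator defaults (12 donors,
~7 glands each, plus metaplastic glands), pushes it through filtering,
clonality/sensitivity-corrected burden estimation and the mixed-effects
rate model, and measures how well the pipeline recovers the parameters
the cohort was generated with: per-year SNV/indel rates, metaplasia
burden folds, and per-signature fold increases.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import clonality_burden as cb
from . import postfilter as pf
from . import refsigs
from . import signatures as sg
from .cohortsim import SimConfig, simulate_cohort


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) for replicate runs."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def burden_recovery_replicate(
    seed: int,
    n_metaplastic: int = 19,
    config_overrides: dict | None = None,
) -> dict:
    """One full simulate-filter-burden-signatures pass with known truth.

    Returns the fitted SNV/indel age slopes (non-metaplastic glands,
    Burden ~ Age + (1|Donor)), per-gland metaplasia burden folds, and
    per-signature fold increases for metaplastic glands.
    """
    overrides = dict(config_overrides or {})
    overrides.setdefault("n_metaplastic", n_metaplastic)
    overrides["seed"] = seed
    config = SimConfig.from_dict({**SimConfig().to_dict(), **overrides})
    cohort = simulate_cohort(config)

    donors = dict(zip(cohort.metadata["sample"], cohort.metadata["donor"]))
    filter_table = pf.classify_variants(cohort.count_matrix, donors)
    burden = cb.sample_burden_table(
        cohort.count_matrix, filter_table, cohort.metadata, seed=seed
    )
    usable = burden[~burden["excluded"]]
    nonmeta = usable[~usable["metaplasia"].astype(bool)]
    meta = usable[usable["metaplasia"].astype(bool)]

    rate_snv = cb.fit_burden_rate_model(
        nonmeta["corrected_snv"], nonmeta["age"], nonmeta["donor"], formula="age"
    )
    rate_indel = cb.fit_burden_rate_model(
        nonmeta["corrected_indel"], nonmeta["age"], nonmeta["donor"], formula="age"
    )
    out = {
        "slope_snv": rate_snv.slope,
        "slope_indel": rate_indel.slope,
        "fold_snv": np.asarray(
            cb.burden_fold_change(meta["corrected_snv"], meta["age"], rate_snv)
        ),
        "fold_indel": np.asarray(
            cb.burden_fold_change(meta["corrected_indel"], meta["age"], rate_indel)
        ),
        "n_glands": len(usable),
    }

    if len(meta):
        refs = refsigs.synthetic_sbs_signatures()
        subset = list(config.baseline_signature_mix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exposures = sg.sample_exposure_table(
                cohort.count_matrix, filter_table, refs, subset=subset
            )
            folds = sg.signature_fold_table(exposures, burden, rate_snv)
        out["signature_folds"] = {
            s: folds[f"fold_{s}"].to_numpy() for s in subset if f"fold_{s}" in folds
        }
    else:
        out["signature_folds"] = {}
    return out


def burden_recovery_summary(
    base_seed: int,
    n_replicates: int = 20,
    n_metaplastic: int = 19,
    config_overrides: dict | None = None,
) -> dict:
    """Aggregate recovery metrics over seeded replicates.

    Slopes are averaged over replicates; burden folds are averaged over
    all metaplastic glands pooled across replicates; signature folds are
    summarised by their pooled median.
    """
    reps = [
        burden_recovery_replicate(s, n_metaplastic, config_overrides)
        for s in replicate_seeds(base_seed, n_replicates)
    ]
    sig_names = sorted({k for r in reps for k in r["signature_folds"]})
    pooled_sig = {
        s: np.concatenate([r["signature_folds"].get(s, np.empty(0)) for r in reps])
        for s in sig_names
    }
    return {
        "n_replicates": len(reps),
        "slope_snv_mean": float(np.mean([r["slope_snv"] for r in reps])),
        "slope_indel_mean": float(np.mean([r["slope_indel"] for r in reps])),
        "slopes_snv": [r["slope_snv"] for r in reps],
        "slopes_indel": [r["slope_indel"] for r in reps],
        "fold_snv_mean": float(np.nanmean(np.concatenate([r["fold_snv"] for r in reps]))),
        "fold_indel_mean": float(np.nanmean(np.concatenate([r["fold_indel"] for r in reps]))),
        "signature_fold_median": {s: float(np.nanmedian(v)) for s, v in pooled_sig.items()},
        "n_glands_total": int(sum(r["n_glands"] for r in reps)),
    }
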