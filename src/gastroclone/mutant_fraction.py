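"""Fraction of epithelium colonized by driver-mutant clones.

The cell fraction carrying a driver mutation is VAF x local ploidy (1 for
sex chromosomes in male donors, 2 otherwise, higher under gains).
Multiplying by the microdissection's area gives mutant epithelial area;
the cohort estimate is total mutant area over total sampled area.  Age
and inflammation effects on per-donor mutant proportions are assessed
with ordinary linear models compared by F-tests.  Stromal contamination
lowers VAFs and hence biases the estimate downward.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

#: genes under positive selection in gastric epithelium (default panel)
SELECTION_GENES = ("ARID1A", "ARID1B", "ARID2", "CTNNB1", "EEF1A1", "LIPF", "KDM6A")
DISRUPTING = ("missense", "nonsense", "frameshift", "splice")
KNOWN_CONSEQUENCES = DISRUPTING + ("synonymous", "other")


def cell_fraction(vaf: float, local_ploidy: float) -> tuple[float, bool]:
    """Mutant cell fraction = VAF x local ploidy, capped at 1 (flagged)."""
    if not (0 <= vaf <= 1):
        raise ValueError("VAF must lie in [0, 1]")
    if local_ploidy < 1:
        raise ValueError("local ploidy must be >= 1")
    raw = vaf * local_ploidy
    return min(raw, 1.0), raw > 1.0


def annotate_drivers(
    variants: pd.DataFrame,
    gene_panel=SELECTION_GENES,
    hotspots=(),
) -> pd.DataFrame:
    """Flag driver mutations: disrupting changes in selection-positive genes
    plus supplied oncogene hotspots.

    ``variants`` needs ``gene`` and ``consequence`` columns; ``hotspots``
    is an iterable of (gene, pos) pairs matched against ``pos`` when
    present.  Unknown consequence terms are warned about and treated as
    "other" (non-disrupting).
    """
    out = variants.copy()
    cons = out["consequence"].astype(str).str.lower()
    unknown = sorted(set(cons) - set(KNOWN_CONSEQUENCES))
    if unknown:
        warnings.warn(f"unknown consequence terms treated as 'other': {unknown}")
        cons = cons.where(cons.isin(KNOWN_CONSEQUENCES), "other")
    disrupting = cons.isin(DISRUPTING)
    in_panel = out["gene"].isin(set(gene_panel))
    is_driver = disrupting & in_panel
    hotspot_set = set(hotspots)
    if hotspot_set and "pos" in out.columns:
        hot = [
            (g, p) in hotspot_set
            for g, p in zip(out["gene"], out["pos"])
        ]
        is_driver |= np.asarray(hot)
    out["is_driver"] = is_driver.to_numpy()
    return out


def microdissection_fractions(
    drivers: pd.DataFrame,
    combine: str = "max",
) -> pd.Series:
    """Per-sample mutant cell fraction from its driver mutations.

    ``drivers`` needs sample, vaf and local_ploidy columns (rows already
    restricted to drivers).  Multiple drivers in one microdissection are
    combined with the maximum cell fraction by default (clones assumed
    nested); ``combine="capped_sum"`` instead sums and caps at 1.
    """
    if combine not in ("max", "capped_sum"):
        raise ValueError("combine must be 'max' or 'capped_sum'")
    fracs = drivers.assign(
        _cf=[cell_fraction(v, p)[0] for v, p in zip(drivers["vaf"], drivers["local_ploidy"])]
    )
    grouped = fracs.groupby("sample")["_cf"]
    return grouped.max() if combine == "max" else grouped.sum().clip(upper=1.0)


def mutant_epithelium_fraction(
    microdissections: pd.DataFrame,
    drivers: pd.DataFrame,
    combine: str = "max",
) -> tuple[float, pd.DataFrame]:
    """Area-weighted cohort fraction of epithelium carrying a driver clone.

    ``microdissections``: sample + area (mm^2) [+ any metadata];
    ``drivers``: driver rows with sample, vaf, local_ploidy.  Returns the
    cohort fraction and the per-microdissection table.
    """
    md = microdissections.copy()
    if (md["area"] <= 0).any():
        raise ValueError("areas must be positive")
    per_sample = microdissection_fractions(drivers, combine) if len(drivers) else pd.Series(dtype=float)
    md["mutant_fraction"] = md["sample"].map(per_sample).fillna(0.0)
    total_area = md["area"].sum()
    if total_area <= 0:
        raise ValueError("total sampled area must be positive")
    cohort = float((md["area"] * md["mutant_fraction"]).sum() / total_area)
    return cohort, md


# ---------------------------------------------------------------------------
# linear models on per-donor proportions

MUTANT_MODELS = {
    "age": "proportion ~ age",
    "age+ci": "proportion ~ age + ci_grade",
    "age+im": "proportion ~ age + im_proportion",
}


def donor_proportions(md: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-microdissection fractions to one proportion per donor."""
    def agg(g):
        return pd.Series(
            {
                "proportion": float((g["area"] * g["mutant_fraction"]).sum() / g["area"].sum()),
                "age": float(g["age"].iloc[0]),
                "ci_grade": float(g["ci_num"].mean()) if "ci_num" in g else np.nan,
                "im_proportion": float(g["metaplasia"].astype(bool).mean())
                if "metaplasia" in g
                else np.nan,
            }
        )

    g = md.copy()
    if "ci_grade" in g.columns and g["ci_grade"].dtype == object:
        g["ci_num"] = g["ci_grade"].map({"absent": 0, "mild": 1, "moderate": 2, "severe": 3})
    out = g.groupby("donor").apply(agg, include_groups=False)
    return out.reset_index()


def fit_mutant_proportion_models(donor_table: pd.DataFrame) -> dict:
    """OLS fits of the three mutant-proportion models plus F-test comparisons.

    Returns {"fits": {key: result}, "comparisons": {"age+ci vs age": p, ...}}.
    Constant covariates are dropped with a warning.
    """
    df = donor_table.dropna(subset=["proportion", "age"]).copy()
    n_units = df["donor"].nunique() if "donor" in df else len(df)
    if n_units < 3:
        raise ValueError("need at least three donors")
    fits = {}
    for key, formula in MUTANT_MODELS.items():
        terms = [t for t in ("ci_grade", "im_proportion") if t in formula]
        use = formula
        for t in terms:
            if t not in df or df[t].isna().any() or df[t].nunique() <= 1:
                warnings.warn(f"covariate {t} constant or missing; dropped from {key}")
                use = "proportion ~ age"
        fits[key] = smf.ols(use, data=df).fit()
    comparisons = {}
    for key in ("age+ci", "age+im"):
        small, large = fits["age"], fits[key]
        if large.df_model > small.df_model:
            tbl = anova_lm(small, large)
            comparisons[f"{key} vs age"] = float(tbl["Pr(>F)"].iloc[1])
        else:
            comparisons[f"{key} vs age"] = 1.0
    return {"fits": fits, "comparisons": comparisons}
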