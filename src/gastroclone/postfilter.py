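"""Variant-level filtering: mapping quality, germline removal, artifact removal.

Three stages, applied in strict precedence order:

1. *quality*: a variant is kept only if the median alignment score of its
   supporting reads (ASMD) is >= 140 and the clipping median (CLPM) is 0.
2. *germline*: variant and total read counts are aggregated over the
   donor's largely-diploid samples and referred to a one-sided lower-tail
   exact binomial test against the heterozygous expectation p = 0.5;
   Benjamini-Hochberg-adjusted values >= 1e-5 mark the variant germline.
3. *artifact*: a beta-binomial is fitted to the per-sample (NV, NR) pairs
   with the mean fixed at the pooled VAF, maximizing over a fixed grid of
   overdispersion values log10(rho) in {-6, -5.95, ..., -0.05}.  Recurrent
   artifacts scatter almost binomially across samples (low rho), true
   clone-private variants are strongly overdispersed; variants with rho
   below 0.1 (SNVs) or 0.15 (indels) are artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

#: the overdispersion grid: log10(rho) from -6 to -0.05 in steps of 0.05
LOG10_RHO_GRID = np.round(np.arange(-6.0, -0.0499, 0.05), 2)
RHO_GRID = 10.0 ** LOG10_RHO_GRID

STATUS_ORDER = ("quality_fail", "germline", "artifact", "pass")


@dataclass
class FilterThresholds:
    asmd_min: float = 140.0
    clpm_max: float = 0.0
    germline_q: float = 1e-5
    rho_snv: float = 0.1
    rho_indel: float = 0.15


# ---------------------------------------------------------------------------
# quality stage


def quality_filter(variants: pd.DataFrame, thresholds: FilterThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask: ASMD >= 140 and CLPM == 0 (both boundaries per contract)."""
    thresholds = thresholds or FilterThresholds()
    for col in ("asmd", "clpm"):
        if col not in variants or variants[col].isna().any():
            raise ValueError(f"quality filter requires populated {col!r} column")
    return (
        (variants["asmd"].to_numpy(float) >= thresholds.asmd_min)
        & (variants["clpm"].to_numpy(float) <= thresholds.clpm_max)
    )


# ---------------------------------------------------------------------------
# germline stage


def germline_binomial_test(nv_total, nr_total):
    """One-sided lower-tail exact binomial p-value against p0 = 0.5.

    Counts are aggregated over largely diploid samples; a low aggregate VAF
    is evidence *against* the germline-heterozygous expectation.  NR = 0
    yields NaN (unassessable).
    """
    nv_total = np.asarray(nv_total, dtype=float)
    nr_total = np.asarray(nr_total, dtype=float)
    with np.errstate(invalid="ignore"):
        p = stats.binom.cdf(nv_total, nr_total, 0.5)
    return np.where(nr_total > 0, p, np.nan)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaNs propagate unadjusted."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# beta-binomial overdispersion stage


class RhoEstimate(NamedTuple):
    rho: float
    flag: str  # "ok" | "degenerate" | "single_sample"


def _betabinom_grid_loglik(nv: np.ndarray, nr: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Log-likelihood of each variant on every grid rho (mean fixed at mu).

    nv, nr: (n_var, n_samples); entries with nr == 0 are ignored.
    Returns (n_var, n_grid).  Uses the beta-binomial likelihood
    B(k + a, n - k + b) / B(a, b) with a = mu s, b = (1 - mu) s,
    s = (1 - rho)/rho, plus the rho-independent binomial coefficient.
    """
    nv = np.asarray(nv, dtype=float)
    nr = np.asarray(nr, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-9, 1 - 1e-9)
    s = (1.0 - RHO_GRID) / RHO_GRID  # (G,)
    a = mu[:, None] * s[None, :]  # (C, G)
    b = (1.0 - mu)[:, None] * s[None, :]
    assessed = nr > 0
    m_eff = assessed.sum(axis=1).astype(float)
    ll = m_eff[:, None] * (gammaln(a + b) - gammaln(a) - gammaln(b))
    for j in range(nv.shape[1]):
        k = nv[:, j][:, None]
        n = nr[:, j][:, None]
        term = gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        ll += np.where(assessed[:, j][:, None], term, 0.0)
    # rho-independent binomial coefficients (so reported loglik is complete)
    logc = np.where(assessed, gammaln(nr + 1) - gammaln(nv + 1) - gammaln(nr - nv + 1), 0.0)
    ll += logc.sum(axis=1)[:, None]
    return ll


def estimate_rho_matrix(
    nv: np.ndarray, nr: np.ndarray, chunk: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Grid-MLE overdispersion for many variants at once.

    Returns (rho, flag) arrays.  Variants with fewer than two assessed
    samples get rho = NaN and flag "single_sample"; pooled VAF 0 or 1
    pins rho at the upper grid boundary with flag "degenerate".
    """
    nv = np.atleast_2d(np.asarray(nv))
    nr = np.atleast_2d(np.asarray(nr))
    n_var = nv.shape[0]
    rho = np.full(n_var, np.nan)
    flags = np.full(n_var, "ok", dtype=object)

    assessed = nr > 0
    m_eff = assessed.sum(axis=1)
    nv_tot = np.where(assessed, nv, 0).sum(axis=1).astype(float)
    nr_tot = np.where(assessed, nr, 0).sum(axis=1).astype(float)
    single = m_eff < 2
    flags[single] = "single_sample"
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(nr_tot > 0, nv_tot / np.maximum(nr_tot, 1), np.nan)
    degenerate = (~single) & ((mu <= 0) | (mu >= 1))
    flags[degenerate] = "degenerate"
    rho[degenerate] = RHO_GRID[-1]

    todo = np.flatnonzero(~single & ~degenerate)
    for start in range(0, len(todo), chunk):
        idx = todo[start : start + chunk]
        ll = _betabinom_grid_loglik(nv[idx], nr[idx], mu[idx])
        rho[idx] = RHO_GRID[np.argmax(ll, axis=1)]
    return rho, flags


def estimate_rho(nv, nr) -> RhoEstimate:
    """Grid-MLE overdispersion for a single variant's per-sample counts."""
    rho, flags = estimate_rho_matrix(np.asarray(nv)[None, :], np.asarray(nr)[None, :])
    return RhoEstimate(float(rho[0]), str(flags[0]))


# ---------------------------------------------------------------------------
# classification


def classify_variants(
    matrix: CountMatrix,
    sample_donors: dict | pd.Series,
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Run all three stages per donor and return a per-variant filter table.

    ``sample_donors`` maps sample id -> donor id.  Each variant is assigned
    to the donor in whose samples it was assessed (NR > 0); germline BH
    families and the beta-binomial fit are per donor.  Re-running the
    classification is idempotent.
    """
    thresholds = thresholds or FilterThresholds()
    donors_of = pd.Series(sample_donors)
    donor_per_col = donors_of.reindex(matrix.samples)
    if donor_per_col.isna().any():
        missing = [s for s in matrix.samples if s not in donors_of.index]
        raise KeyError(f"samples without donor assignment: {missing[:5]}")

    n_var = matrix.n_variants
    out = pd.DataFrame(
        {
            "donor": pd.array([""] * n_var, dtype="object"),
            "germline_p": np.full(n_var, np.nan),
            "germline_q": np.full(n_var, np.nan),
            "rho": np.full(n_var, np.nan),
            "rho_flag": pd.array(["ok"] * n_var, dtype="object"),
            "status": pd.array(["pass"] * n_var, dtype="object"),
            "unassessable": np.zeros(n_var, dtype=bool),
        }
    )

    quality_ok = quality_filter(matrix.variants, thresholds)
    is_snv = (matrix.variants["var_class"] == "SNV").to_numpy()

    assessed_any = matrix.nr > 0
    for donor in pd.unique(donor_per_col):
        cols = np.flatnonzero((donor_per_col == donor).to_numpy())
        rows = np.flatnonzero(assessed_any[:, cols].any(axis=1))
        if len(rows) == 0:
            continue
        out.loc[rows, "donor"] = donor
        nv = matrix.nv[np.ix_(rows, cols)]
        nr = matrix.nr[np.ix_(rows, cols)]
        dm = matrix.diploid[np.ix_(rows, cols)]

        use = dm & (nr > 0)
        nv_tot = np.where(use, nv, 0).sum(axis=1)
        nr_tot = np.where(use, nr, 0).sum(axis=1)
        p = germline_binomial_test(nv_tot, nr_tot)
        q = bh_adjust(p)
        out.loc[rows, "germline_p"] = p
        out.loc[rows, "germline_q"] = q
        out.loc[rows, "unassessable"] = np.isnan(p)

        rho, rho_flags = estimate_rho_matrix(nv, nr)
        out.loc[rows, "rho"] = rho
        out.loc[rows, "rho_flag"] = rho_flags

    # precedence: quality_fail > germline > artifact > pass
    status = np.full(n_var, "pass", dtype=object)
    rho = out["rho"].to_numpy()
    rho_thr = np.where(is_snv, thresholds.rho_snv, thresholds.rho_indel)
    artifact = ~np.isnan(rho) & (rho < rho_thr) & (out["rho_flag"] == "ok").to_numpy()
    status[artifact] = "artifact"
    q = out["germline_q"].to_numpy()
    status[~np.isnan(q) & (q >= thresholds.germline_q)] = "germline"
    status[~quality_ok] = "quality_fail"
    out["status"] = status
    return out


def passing_mask(filter_table: pd.DataFrame) -> np.ndarray:
    return (filter_table["status"] == "pass").to_numpy()


def write_filter_table(matrix: CountMatrix, filter_table: pd.DataFrame, path) -> None:
    """Filter-annotated TSV: one row per variant, annotations then verdicts."""
    ann = matrix.variants.reset_index(drop=True)
    pd.concat([ann, filter_table.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )
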