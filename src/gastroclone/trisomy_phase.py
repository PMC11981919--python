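"""Trisomy detection in targeted-panel samples via WGS-phased SNPs.

Heterozygous SNPs on a trisomic chromosome separate into 2/3 and 1/3 VAF
groups by parental haplotype in whole-genome-sequenced trisomic samples,
which phases them without a population reference panel.  In shallow panel
samples the phased groups are then compared with a likelihood-ratio test:
one shared binomial (diploidy) versus one binomial per haplotype
(aneuploidy), chi-square with 1 df, Benjamini-Hochberg corrected across
the donor's panel samples.  A call additionally requires the haplotype
mean-VAF difference to reach 0.1.  Site enrichment of calls is tested
with an exact r x c Fisher test by full enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlog1py, xlogy

from .postfilter import bh_adjust

DEFAULT_MIN_DEPTH = 6  # "more than five reads": NR > 5
DEFAULT_DELTA_VAF = 0.1
DEFAULT_Q_CUTOFF = 0.05


@dataclass
class PhasedSNPSet:
    snps: pd.DataFrame  # chrom, pos, hap (A/B)
    source_samples: list
    concordance: float


@dataclass
class TrisomyCall:
    sample: str
    ll_one: float
    ll_two: float
    stat: float
    p: float
    delta_vaf: float
    n_snps: int
    q: float = np.nan
    call: bool = False
    flag: str = "ok"


# ---------------------------------------------------------------------------
# phasing


def phase_snps_from_wgs(vafs: pd.DataFrame, concordance_warn: float = 0.9) -> PhasedSNPSet:
    """Phase heterozygous SNPs from trisomic WGS samples' VAFs.

    ``vafs`` has columns chrom, pos and one VAF column per trisomic WGS
    sample.  Within each sample, SNPs above 0.5 are on the duplicated
    haplotype; labels are harmonised across samples by orientation flips
    (different samples may duplicate different parental copies), then
    fixed by majority vote.  The reported concordance is the mean
    per-sample agreement with the consensus.
    """
    sample_cols = [c for c in vafs.columns if c not in ("chrom", "pos")]
    if not sample_cols:
        raise ValueError("phasing requires at least one trisomic WGS sample")
    labels = vafs[sample_cols].to_numpy(dtype=float) > 0.5  # True = duplicated hap
    ref = labels[:, 0]
    oriented = np.empty_like(labels)
    for j in range(labels.shape[1]):
        agree = (labels[:, j] == ref).mean()
        oriented[:, j] = labels[:, j] if agree >= 0.5 else ~labels[:, j]
    consensus = oriented.mean(axis=1) >= 0.5
    concordance = float((oriented == consensus[:, None]).mean())
    if concordance < concordance_warn:
        warnings.warn(
            f"low phasing concordance ({concordance:.2f}); "
            "trisomy signal may be absent from the WGS samples"
        )
    snps = vafs[["chrom", "pos"]].copy()
    snps["hap"] = np.where(consensus, "A", "B")
    return PhasedSNPSet(snps=snps, source_samples=sample_cols, concordance=concordance)


# ---------------------------------------------------------------------------
# likelihood-ratio trisomy test


def _binom_loglik(nv, nr, p) -> float:
    if len(nv) == 0:
        return 0.0
    logc = gammaln(nr + 1) - gammaln(nv + 1) - gammaln(nr - nv + 1)
    return float(np.sum(logc + xlogy(nv, p) + xlog1py(nr - nv, -p)))


def lrt_trisomy_panel(
    counts_a: tuple,
    counts_b: tuple,
    sample: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
    pooled_null: bool = True,
) -> TrisomyCall:
    """Two-binomial likelihood-ratio statistic for one panel sample.

    ``counts_a``/``counts_b`` are (nv, nr) arrays for the two phased
    haplotype groups.  Sites with NR < min_depth are dropped.  The null
    success probability is the pooled MLE over both groups (``pooled_null``
    False uses the mean of per-site VAFs instead); the alternative fits
    one binomial per group.  p comes from chi-square with 1 df.
    """
    out = []
    for nv, nr in (counts_a, counts_b):
        nv = np.asarray(nv, dtype=float)
        nr = np.asarray(nr, dtype=float)
        keep = nr >= min_depth
        out.append((nv[keep], nr[keep]))
    (nva, nra), (nvb, nrb) = out
    if len(nva) == 0 or len(nrb) == 0:
        return TrisomyCall(sample, np.nan, np.nan, np.nan, np.nan, np.nan, 0,
                           flag="unassessable")
    if pooled_null:
        p0 = (nva.sum() + nvb.sum()) / (nra.sum() + nrb.sum())
    else:
        p0 = float(np.concatenate([nva / nra, nvb / nrb]).mean())
    pa = nva.sum() / nra.sum()
    pb = nvb.sum() / nrb.sum()
    ll_one = _binom_loglik(nva, nra, p0) + _binom_loglik(nvb, nrb, p0)
    ll_two = _binom_loglik(nva, nra, pa) + _binom_loglik(nvb, nrb, pb)
    stat = max(2.0 * (ll_two - ll_one), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    delta = abs(float((nva / nra).mean() - (nvb / nrb).mean()))
    return TrisomyCall(
        sample=sample, ll_one=ll_one, ll_two=ll_two, stat=stat, p=p,
        delta_vaf=delta, n_snps=int(len(nva) + len(nvb)),
    )


def call_trisomies(
    panel_counts: dict,
    phased: PhasedSNPSet | pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    delta_vaf: float = DEFAULT_DELTA_VAF,
) -> pd.DataFrame:
    """LRT + BH + delta-VAF calls for all panel samples of one donor.

    ``panel_counts`` maps sample id -> DataFrame with columns pos, nv, nr;
    sites are matched to the phased SNP set by position.
    """
    snps = phased.snps if isinstance(phased, PhasedSNPSet) else phased
    hap_of = dict(zip(snps["pos"], snps["hap"]))
    calls = []
    for sample, df in panel_counts.items():
        hap = df["pos"].map(hap_of)
        a = df[hap == "A"]
        b = df[hap == "B"]
        calls.append(
            lrt_trisomy_panel(
                (a["nv"].to_numpy(), a["nr"].to_numpy()),
                (b["nv"].to_numpy(), b["nr"].to_numpy()),
                sample=sample,
                min_depth=min_depth,
            )
        )
    table = pd.DataFrame([c.__dict__ for c in calls])
    table["q"] = bh_adjust(table["p"])
    table["call"] = (table["q"] < q_cutoff) & (table["delta_vaf"] >= delta_vaf)
    return table


# ---------------------------------------------------------------------------
# exact r x c Fisher test


def _log_table_prob(table: np.ndarray, logfact) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        logfact[rows].sum() + logfact[cols].sum() - logfact[n] - logfact[table].sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, remaining_cols, rows_out):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield np.array(rows_out + [last])
            return
        total = row_sums[i]

        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, total, []):
            new_cols = [rc - rv for rc, rv in zip(remaining_cols, row)]
            yield from rec(i + 1, new_cols, rows_out + [np.asarray(row)])

    yield from rec(0, list(col_sums), [])


def fisher_exact_rxc(table) -> float:
    """Exact conditional p for an r x c contingency table by full enumeration.

    p is the total multivariate-hypergeometric probability of all tables
    with the observed margins whose probability does not exceed the
    observed table's.  All-zero rows/columns are dropped first; a table
    with a single remaining row or column has p = 1.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    logfact = gammaln(np.arange(int(table.sum()) + 2) + 1.0)
    obs = _log_table_prob(table, logfact)
    total = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(cand, logfact)
        if lp <= obs + 1e-7:
            total += np.exp(lp)
    return float(min(total, 1.0))


def site_enrichment_table(calls: pd.DataFrame, sites: pd.Series) -> np.ndarray:
    """Build the trisomy-by-site table (rows: sites, cols: called / not called)."""
    merged = calls.set_index("sample").join(sites.rename("site"))
    rows = []
    for site, grp in merged.groupby("site"):
        rows.append([int(grp["call"].sum()), int((~grp["call"].astype(bool)).sum())])
    return np.asarray(rows, dtype=int)
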