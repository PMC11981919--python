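"""Molecular timing of copy-number gains from duplicated mutation fractions.

A chromosomal gain duplicates every SNV acquired before it on the gained
parental copy: in a trisomy, pre-gain mutations on that copy sit at VAF
2/3 while all other mutations sit at 1/3 (scaled by sample clonality).
Assigning the region's SNVs to the duplicated/non-duplicated clusters with
a two-component binomial mixture (means fixed at the copy-number-expected
VAFs) gives proportions P_D and P_ND, and the gain is timed as

    T = CN_total / (CN_dup + P_ND / P_D)

with T in [0, 1] spanning the mutation time of the lineage.  Confidence
intervals come from the exact conditional (binomial) treatment of the
rounded duplicated/non-duplicated counts, mapped through the same formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, xlog1py, xlogy


@dataclass
class CNVRegion:
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_dup: int
    kind: str  # "trisomy" or "cnn-loh"

    def __post_init__(self) -> None:
        if not (self.cn_total >= self.cn_dup >= 1):
            raise ValueError("need cn_total >= cn_dup >= 1")
        kind = self.kind.lower()
        if kind == "trisomy" and (self.cn_total, self.cn_dup) != (3, 2):
            raise ValueError("trisomy implies (cn_total, cn_dup) = (3, 2)")
        if kind in ("cnn-loh", "cnnloh") and (self.cn_total, self.cn_dup) != (2, 2):
            raise ValueError("cnn-LOH implies (cn_total, cn_dup) = (2, 2)")

    @classmethod
    def trisomy(cls, chrom: str, start: int = 1, end: int = 2**31 - 1) -> "CNVRegion":
        return cls(chrom, start, end, 3, 2, "trisomy")

    @classmethod
    def cnn_loh(cls, chrom: str, start: int = 1, end: int = 2**31 - 1) -> "CNVRegion":
        return cls(chrom, start, end, 2, 2, "cnn-loh")


@dataclass
class DupCluster:
    n_dup: int
    n_nondup: int
    p_dup: float
    p_nondup: float
    expected_vafs: tuple[float, float]  # (duplicated, non-duplicated) cluster means

    def __post_init__(self) -> None:
        if abs(self.p_dup + self.p_nondup - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")


@dataclass
class TimingEstimate:
    T: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    clamped: bool = False
    degenerate: bool = False


def expected_cluster_means(region: CNVRegion, clonal_scaling: float = 1.0) -> tuple[float, float]:
    """Fixed cluster means: clonal scaling x CN_dup/CN_total and x 1/CN_total."""
    return (
        clonal_scaling * region.cn_dup / region.cn_total,
        clonal_scaling * 1.0 / region.cn_total,
    )


def cluster_cn_mutations(
    nv, nr, region: CNVRegion, clonal_scaling: float = 1.0, min_snvs: int = 5
) -> DupCluster:
    """Assign region SNVs to duplicated/non-duplicated VAF clusters.

    A two-component binomial mixture with means fixed at the copy-number
    expectations; only the mixing weight is estimated (EM).  Each SNV goes
    to the component with the higher posterior responsibility, ties to
    non-duplicated so that timing is not inflated.
    """
    nv = np.asarray(nv, dtype=float)
    nr = np.asarray(nr, dtype=float)
    if len(nv) < min_snvs:
        raise ValueError(f"need at least {min_snvs} SNVs in the region, got {len(nv)}")
    p_d, p_nd = expected_cluster_means(region, clonal_scaling)
    ll_d = xlogy(nv, p_d) + xlog1py(nr - nv, -p_d)
    ll_nd = xlogy(nv, p_nd) + xlog1py(nr - nv, -p_nd)
    w = 0.5
    for _ in range(200):
        joint = np.stack([np.log(max(w, 1e-12)) + ll_d, np.log(max(1 - w, 1e-12)) + ll_nd])
        resp_d = np.exp(joint[0] - logsumexp(joint, axis=0))
        w_new = float(resp_d.mean())
        if abs(w_new - w) < 1e-10:
            w = w_new
            break
        w = w_new
    dup = resp_d > 0.5  # ties (0.5) fall to non-duplicated
    n_dup = int(dup.sum())
    n_nondup = int(len(nv) - n_dup)
    return DupCluster(
        n_dup=n_dup,
        n_nondup=n_nondup,
        p_dup=n_dup / len(nv),
        p_nondup=n_nondup / len(nv),
        expected_vafs=(p_d, p_nd),
    )


def _timing_from_q(q: float, region: CNVRegion) -> float:
    """T as a function of the duplicated proportion q (monotone increasing)."""
    if q <= 0:
        return 0.0
    return region.cn_total * q / (region.cn_dup * q + (1.0 - q))


def time_cnv(cluster: DupCluster, region: CNVRegion) -> TimingEstimate:
    """Point estimate T = CN_total / (CN_dup + P_ND/P_D), clamped to [0, 1]."""
    if cluster.p_dup <= 0:
        return TimingEstimate(T=0.0, degenerate=True)
    raw = region.cn_total / (region.cn_dup + cluster.p_nondup / cluster.p_dup)
    return TimingEstimate(T=min(raw, 1.0), clamped=raw > 1.0)


def timing_confidence(
    n_dup: int, n_nondup: int, region: CNVRegion, conf: float = 0.95
) -> tuple[float, float]:
    """Exact conditional 95% interval for T from rounded cluster counts.

    Conditioning the two Poisson counts on their total makes the
    duplicated count binomial; the Clopper-Pearson interval for its
    proportion is mapped through the timing formula and clamped to [0, 1].
    """
    n_dup = int(round(n_dup))
    n_nondup = int(round(n_nondup))
    n = n_dup + n_nondup
    if n == 0:
        raise ValueError("cannot form an interval from zero mutations")
    alpha = 1.0 - conf
    q_low = 0.0 if n_dup == 0 else float(stats.beta.ppf(alpha / 2, n_dup, n_nondup + 1))
    q_high = 1.0 if n_nondup == 0 else float(stats.beta.ppf(1 - alpha / 2, n_dup + 1, n_nondup))
    t_low = max(0.0, min(_timing_from_q(q_low, region), 1.0))
    t_high = max(0.0, min(_timing_from_q(q_high, region), 1.0))
    return t_low, t_high


def time_cnv_with_ci(cluster: DupCluster, region: CNVRegion, conf: float = 0.95) -> TimingEstimate:
    est = time_cnv(cluster, region)
    lo, hi = timing_confidence(cluster.n_dup, cluster.n_nondup, region, conf)
    est.ci_low, est.ci_high = min(lo, est.T), max(hi, est.T)
    return est


def timing_to_age(T: float, corrected_burden: float, rate_per_year: float) -> float:
    """Rough age at the gain: timing fraction of the sample's mutation time.

    Interprets T as the fraction of the lineage's mutation time before the
    gain; with burden/rate years of mutation time this gives an upper
    bound of the age at acquisition.
    """
    if rate_per_year <= 0:
        raise ValueError("rate must be positive")
    return T * corrected_burden / rate_per_year


# ---------------------------------------------------------------------------
# region I/O and per-sample driver


def read_regions_tsv(path) -> list[CNVRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNVRegion(str(r["chrom"]), int(r["start"]), int(r["end"]),
                  int(r["cn_total"]), int(r["cn_dup"]), str(r["kind"]))
        for _, r in df.iterrows()
    ]


def time_region_in_sample(
    matrix,
    filter_table: pd.DataFrame,
    sample: str,
    region: CNVRegion,
    clonal_scaling: float = 1.0,
    min_reads: int = 4,
) -> Optional[TimingEstimate]:
    """Cluster and time one region from a sample's passing SNVs; None if too sparse."""
    j = matrix.samples.index(sample)
    v = matrix.variants
    mask = (
        (filter_table["status"] == "pass").to_numpy()
        & (v["var_class"] == "SNV").to_numpy()
        & (v["chrom"].astype(str) == region.chrom).to_numpy()
        & (v["pos"].to_numpy() >= region.start)
        & (v["pos"].to_numpy() <= region.end)
        & (matrix.nv[:, j] >= min_reads)
    )
    if mask.sum() < 5:
        return None
    cluster = cluster_cn_mutations(
        matrix.nv[mask, j], matrix.nr[mask, j], region, clonal_scaling
    )
    return time_cnv_with_ci(cluster, region)
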