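"""Clonality, detection sensitivity, corrected burden and mutation-rate models.

Each microdissection is modelled as a mixture of clones via a truncated
binomial mixture over the per-variant (NV, NR) pairs; truncation at the
minimum supporting-read count (4) reflects what the variant caller can
emit.  Detection sensitivity S is the probability of seeing a variant in
at least 4 reads given the sample's empirical depth distribution and its
VAF peak; observed burdens are corrected by dividing by S.  Mutation
rates are estimated with linear mixed-effects models (age fixed effect,
donor random intercept), fitted by maximum likelihood so nested models
can be compared with likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize, stats
from scipy.special import logsumexp, xlog1py, xlogy

DEFAULT_MIN_READS = 4
CLONALITY_CUTOFF = 0.25

#: mixed-model formulas supported for burden-rate fitting
RATE_FORMULAS = {
    "age": "burden ~ age",
    "age+ci": "burden ~ age + ci_high",
    "age+im": "burden ~ age + im",
    "age+im+ci": "burden ~ age + im + ci_high",
    "age:site+im": "burden ~ age:site + im",
}


# ---------------------------------------------------------------------------
# binomial tail helpers


def binom_tail_ge(min_reads: int, n, p) -> np.ndarray:
    """P(X >= min_reads) for X ~ Binom(n, p), vectorised and cheap for small cutoffs.

    Computed as 1 - sum_{k < min_reads} C(n,k) p^k (1-p)^(n-k) with the
    binomial coefficients built by recurrence, so the expectation-
    maximisation inner loop avoids scipy's generic survival function.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if min_reads <= 0:
        return np.ones(np.broadcast(n, p).shape)
    at_one = p >= 1.0 - 1e-12
    p = np.minimum(p, 1.0 - 1e-12)
    # P(X <= m-1) = (1-p)^n * sum_{k<m} C(n,k) t^k with t = p/(1-p);
    # the C(n,k) recurrence is exact and zeroes out for k > n
    t = p / (1.0 - p)
    coef = np.ones(np.broadcast(n, p).shape)
    acc = coef.copy()
    tk = np.ones_like(acc)
    for k in range(1, min_reads):
        coef = coef * (n - k + 1) / k
        tk = tk * t
        acc = acc + coef * tk
    cdf = np.exp(xlog1py(n, -p)) * acc
    out = np.clip(1.0 - cdf, 0.0, 1.0)
    return np.where(at_one, (n >= min_reads).astype(float), out)


# ---------------------------------------------------------------------------
# truncated binomial VAF mixture


@dataclass
class VAFMixtureFit:
    K: int
    peaks: np.ndarray  # component success probabilities, descending
    weights: np.ndarray  # mixing proportions, same order
    loglik: float
    bic: float
    min_reads: int
    converged: bool = True
    degenerate: bool = False
    loglik_trace: list = field(default_factory=list)

    @property
    def peak_vaf(self) -> float:
        """VAF peak of the dominant clone (highest-weight component)."""
        return float(self.peaks[int(np.argmax(self.weights))])


class _TruncCache:
    """Per-fit caches: log binomial coefficients and the C(n,k) polynomial
    coefficients of the truncation tail, all independent of the peak p."""

    def __init__(self, nv, nr, min_reads):
        from scipy.special import gammaln

        self.min_reads = min_reads
        self.logc = gammaln(nr + 1) - gammaln(nv + 1) - gammaln(nr - nv + 1)
        coef = np.ones_like(np.asarray(nr, dtype=float))
        self.poly = [coef]
        for k in range(1, min_reads):
            coef = coef * (nr - k + 1) / k
            self.poly.append(coef)

    def log_tail(self, nr, p):
        """log P(X >= min_reads | nr, p) for scalar p via the cached polynomial."""
        if self.min_reads <= 0:
            return 0.0
        t = p / (1.0 - p)
        acc = self.poly[0].copy()
        tk = 1.0
        for k in range(1, self.min_reads):
            tk *= t
            acc += self.poly[k] * tk
        cdf = np.exp(nr * np.log1p(-p)) * acc
        return np.log(np.maximum(1.0 - cdf, 1e-300))


def _component_loglik(nv, nr, p, min_reads, cache=None):
    """log[ Binom(nv; nr, p) / P(X >= min_reads; nr, p) ] for one component."""
    if cache is None:
        cache = _TruncCache(nv, nr, min_reads)
    p = float(min(max(p, 1e-12), 1 - 1e-12))
    ll = cache.logc + nv * np.log(p) + (nr - nv) * np.log1p(-p)
    return ll - cache.log_tail(nr, p)


def _em_once(nv, nr, peaks0, min_reads, max_iter, tol):
    K = len(peaks0)
    peaks = np.array(peaks0, dtype=float)
    weights = np.full(K, 1.0 / K)
    cache = _TruncCache(nv, nr, min_reads)
    prev = -np.inf
    trace = []
    converged = False
    collapsed = False
    for _ in range(max_iter):
        comp = np.stack([_component_loglik(nv, nr, p, min_reads, cache) for p in peaks])
        joint = np.log(weights)[:, None] + comp
        norm = logsumexp(joint, axis=0)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(joint - norm[None, :])
        weights = resp.mean(axis=1)
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()
        for k in range(K):
            r = resp[k]
            if r.sum() < 1e-9:
                continue

            def neg(p, r=r):
                return -float(np.dot(r, _component_loglik(nv, nr, p, min_reads, cache)))

            res = optimize.minimize_scalar(
                neg, bounds=(1e-4, 1 - 1e-4), method="bounded",
                options={"xatol": 1e-5},
            )
            peaks[k] = res.x
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        # a collapsing mixture (two peaks meeting, or a component dying)
        # creeps in likelihood indefinitely while already equivalent to a
        # K-1 fit; stop and let BIC prefer the smaller model
        # peaks closer than half a percent are indistinguishable at
        # gland-level depths; treat the run as collapsed to K-1
        if K >= 2 and (
            np.min(np.diff(np.sort(peaks))) < 5e-3 or weights.min() < 2e-3
        ):
            converged = True
            collapsed = True
            break
        prev = ll
    order = np.argsort(-peaks)
    return peaks[order], weights[order], trace, converged, collapsed


def fit_vaf_mixture(
    nv,
    nr,
    k_max: int = 3,
    min_reads: int = DEFAULT_MIN_READS,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> VAFMixtureFit:
    """Fit the truncated binomial VAF mixture, choosing K in 1..k_max by BIC."""
    nv = np.asarray(nv, dtype=float)
    nr = np.asarray(nr, dtype=float)
    if len(nv) < 10:
        raise ValueError(f"mixture fit needs >= 10 variants, got {len(nv)}")
    if (nv < min_reads).any():
        raise ValueError(f"all variants must have NV >= min_reads = {min_reads}")
    if (nr <= 0).any():
        raise ValueError("depths must be positive")

    vaf = nv / nr
    if np.all(nv == nr):
        p_hat = 1 - 1e-4
        ll = float(_component_loglik(nv, nr, p_hat, min_reads).sum())
        return VAFMixtureFit(
            K=1, peaks=np.array([p_hat]), weights=np.array([1.0]), loglik=ll,
            bic=-2 * ll + np.log(len(nv)), min_reads=min_reads,
            degenerate=True, loglik_trace=[ll],
        )

    rng = np.random.default_rng(seed)
    best: Optional[VAFMixtureFit] = None
    for K in range(1, k_max + 1):
        quantiles = np.quantile(vaf, (2 * np.arange(K) + 1) / (2 * K))
        quantiles = np.clip(quantiles, 1e-3, 1 - 1e-3)
        best_k: Optional[VAFMixtureFit] = None
        for restart in range(n_restarts if K > 1 else 1):
            init = quantiles if restart == 0 else np.clip(
                quantiles * rng.uniform(0.6, 1.4, size=K), 1e-3, 1 - 1e-3
            )
            peaks, weights, trace, conv, collapsed = _em_once(
                nv, nr, init, min_reads, max_iter, tol
            )
            ll = trace[-1]
            bic = -2 * ll + (2 * K - 1) * np.log(len(nv))
            fit = VAFMixtureFit(
                K=K, peaks=peaks, weights=weights, loglik=ll, bic=bic,
                min_reads=min_reads, converged=conv, loglik_trace=trace,
            )
            if best_k is None or fit.bic < best_k.bic - 1e-9:
                best_k = fit
            if collapsed and restart == 0:
                # the well-initialised run already folded onto fewer peaks;
                # jittered restarts only rediscover the same collapse
                break
        assert best_k is not None
        if best is None or best_k.bic < best.bic - 1e-9:
            best = best_k
        elif K > 1:
            # adding a component stopped paying: larger K only ever
            # subdivides an already-merged peak, so stop the scan
            break
    assert best is not None
    if best.peaks.max() > 1 - 2e-4:
        best.degenerate = True
    return best


# ---------------------------------------------------------------------------
# sensitivity and burden


@dataclass
class SensitivityEstimate:
    S: float
    peak_used: float
    depth_summary: dict

    def __float__(self) -> float:
        return self.S


def estimate_sensitivity(
    depths, peak_vaf: float, min_reads: int = DEFAULT_MIN_READS
) -> SensitivityEstimate:
    """Mean over the empirical depth distribution of P(X >= min_reads | n, peak)."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("sensitivity needs a non-empty depth distribution")
    if not (0 < peak_vaf < 1):
        raise ValueError("peak_vaf must lie in (0, 1)")
    probs = binom_tail_ge(min_reads, depths, peak_vaf)
    return SensitivityEstimate(
        S=float(probs.mean()),
        peak_used=float(peak_vaf),
        depth_summary={
            "n": int(depths.size),
            "median": float(np.median(depths)),
            "mean": float(depths.mean()),
        },
    )


@dataclass
class BurdenEstimate:
    raw_count: int
    corrected: float
    var_class: str
    sensitivity: float
    median_vaf: float = np.nan
    monoclonal: bool = False
    excluded: bool = False


def corrected_burden(raw: int, S: float, var_class: str = "SNV") -> BurdenEstimate:
    """Sensitivity-corrected burden raw / S; S = 0 marks the sample excluded."""
    if S < 0 or S > 1:
        raise ValueError("sensitivity must lie in [0, 1]")
    if S == 0:
        return BurdenEstimate(raw, np.nan, var_class, S, excluded=True)
    return BurdenEstimate(raw, raw / S, var_class, S)


def median_vaf_and_clonality(nv, nr) -> tuple[float, bool]:
    """Median NV/NR over passing variants; monoclonal iff strictly above 0.25."""
    nv = np.asarray(nv, dtype=float)
    nr = np.asarray(nr, dtype=float)
    if len(nv) == 0:
        return np.nan, False
    med = float(np.median(nv / nr))
    return med, med > CLONALITY_CUTOFF


def sample_burden_table(
    matrix,
    filter_table: pd.DataFrame,
    metadata: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    k_max: int = 3,
    seed: int = 0,
    max_fit_variants: int = 300,
) -> pd.DataFrame:
    """Per-sample clonality, sensitivity and corrected burdens.

    For each sample: passing variants detected with NV >= min_reads define
    the raw burden; the VAF mixture is fitted on the detected SNVs; the
    sensitivity uses the empirical depths at those sites and the dominant
    VAF peak; burdens are reported separately for SNVs and indels.
    """
    passing = (filter_table["status"] == "pass").to_numpy()
    is_snv = (matrix.variants["var_class"] == "SNV").to_numpy()
    rows = []
    meta = metadata.set_index("sample")
    for j, sample in enumerate(matrix.samples):
        detected = passing & (matrix.nv[:, j] >= min_reads)
        det_snv = detected & is_snv
        det_ind = detected & ~is_snv
        nv = matrix.nv[det_snv, j]
        nr = matrix.nr[det_snv, j]
        row = {
            "sample": sample,
            "raw_snv": int(det_snv.sum()),
            "raw_indel": int(det_ind.sum()),
        }
        if det_snv.sum() >= 10:
            if len(nv) > max_fit_variants:
                # the peak location is precise well below genome-wide counts;
                # subsample deterministically for the mixture fit only
                sub = np.random.default_rng(seed + j).choice(
                    len(nv), size=max_fit_variants, replace=False
                )
                fit = fit_vaf_mixture(
                    nv[sub], nr[sub], k_max=k_max, min_reads=min_reads, seed=seed
                )
            else:
                fit = fit_vaf_mixture(nv, nr, k_max=k_max, min_reads=min_reads, seed=seed)
            sens = estimate_sensitivity(nr, fit.peak_vaf, min_reads)
            med, mono = median_vaf_and_clonality(nv, nr)
            snv_b = corrected_burden(row["raw_snv"], sens.S, "SNV")
            ind_b = corrected_burden(row["raw_indel"], sens.S, "indel")
            row.update(
                peak_vaf=fit.peak_vaf, K=fit.K, sensitivity=sens.S,
                corrected_snv=snv_b.corrected, corrected_indel=ind_b.corrected,
                median_vaf=med, monoclonal=mono, excluded=snv_b.excluded,
            )
        else:
            row.update(
                peak_vaf=np.nan, K=0, sensitivity=np.nan, corrected_snv=np.nan,
                corrected_indel=np.nan, median_vaf=np.nan, monoclonal=False,
                excluded=True,
            )
        for col in ("donor", "age", "site", "metaplasia", "ci_grade", "area"):
            if col in meta.columns:
                row[col] = meta.loc[sample, col]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-effects mutation-rate models


@dataclass
class RateModelFit:
    formula_key: str
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    donor_sd: float
    residual_sd: float
    loglik: float
    n_params: int
    n_obs: int
    fe_params: pd.Series
    result: object = None

    def expected_burden(self, age) -> np.ndarray:
        """Population-level (fixed-effects) expected burden at the given ages."""
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def _prepare_rate_frame(burdens, ages, donors, covariates=None) -> pd.DataFrame:
    df = pd.DataFrame({"burden": np.asarray(burdens, float),
                       "age": np.asarray(ages, float),
                       "donor": np.asarray(donors)})
    if covariates is not None:
        for k, v in covariates.items():
            df[k] = np.asarray(v)
    if "ci_grade" in df.columns and "ci_high" not in df.columns:
        df["ci_high"] = df["ci_grade"].isin(["moderate", "severe"]).astype(int)
    if "metaplasia" in df.columns and "im" not in df.columns:
        df["im"] = df["metaplasia"].astype(int)
    return df.dropna(subset=["burden", "age"])


def fit_burden_rate_model(
    burdens, ages, donors, covariates=None, formula: str = "age"
) -> RateModelFit:
    """ML fit of Burden ~ <fixed terms> + (1|Donor).

    ``formula`` is one of "age", "age+ci", "age+im", "age+im+ci",
    "age:site+im".  Chronic inflammation is coded absent/mild vs
    moderate/severe; metaplasia as a 0/1 indicator.
    """
    if formula not in RATE_FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {sorted(RATE_FORMULAS)}")
    df = _prepare_rate_frame(burdens, ages, donors, covariates)
    if df["donor"].nunique() < 2:
        raise ValueError("need at least two donors for a random-intercept model")
    if len(df) < 3:
        raise ValueError("need at least three samples")
    model = smf.mixedlm(RATE_FORMULAS[formula], df, groups=df["donor"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs")
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
        except Exception:
            res = model.fit(reml=False)
    fe = res.fe_params
    ci = res.conf_int()
    # a perfectly deterministic fit has zero residual variance and no
    # standard errors; report a degenerate interval at the estimate
    ci = ci.apply(lambda col: col.fillna(fe), axis=0)
    slope_name = "age" if "age" in fe.index else fe.index[1]
    donor_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    return RateModelFit(
        formula_key=formula,
        slope=float(fe[slope_name]),
        slope_ci=(float(ci.loc[slope_name, 0]), float(ci.loc[slope_name, 1])),
        intercept=float(fe.get("Intercept", 0.0)),
        donor_sd=float(np.sqrt(max(donor_var, 0.0))),
        residual_sd=float(np.sqrt(res.scale)),
        loglik=float(res.llf),
        n_params=int(len(res.params)),
        n_obs=int(len(df)),
        fe_params=fe,
        result=res,
    )


_NESTING = {
    "age": {"age+ci", "age+im", "age+im+ci", "age:site+im"},
    "age+ci": {"age+im+ci"},
    "age+im": {"age+im+ci", "age:site+im"},
}


def compare_models(fit_small: RateModelFit, fit_large: RateModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested ML fits: returns (statistic, p-value)."""
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("models must be fitted on identical data")
    if fit_small.formula_key == fit_large.formula_key:
        return 0.0, 1.0
    if fit_large.formula_key not in _NESTING.get(fit_small.formula_key, set()):
        raise ValueError(
            f"{fit_small.formula_key!r} is not nested in {fit_large.formula_key!r}"
        )
    df = fit_large.n_params - fit_small.n_params
    stat = max(2.0 * (fit_large.loglik - fit_small.loglik), 0.0)
    if df <= 0:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))


def burden_fold_change(corrected, age, rate_model: RateModelFit):
    """Observed / age-expected burden fold change (vectorised)."""
    corrected = np.asarray(corrected, dtype=float)
    expected = rate_model.expected_burden(age)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(expected > 0, corrected / expected, np.nan)
    return fold
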