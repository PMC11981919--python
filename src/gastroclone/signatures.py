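"""Mutation catalogs, signature-exposure fitting and fold-increase analysis.

Catalogs are 96-channel SBS (pyrimidine-centred trinucleotide classes) or
83-channel small-indel spectra.  Exposures to a set of reference
signatures are the maximum-likelihood weights of a multinomial mixture,
fitted by expectation-maximization (the log-likelihood is concave in the
weights, so no restarts are needed).  An "extracted" spectrum is accepted
as a combination of reference signatures when the cosine similarity of
its reconstruction reaches 0.90.  Per-signature fold increases in
metaplastic glands follow a three-step recipe: observed mutations per
signature (exposure x sensitivity-corrected burden), expected mutations
per signature (donor's non-metaplastic mean exposure x age-expected
burden), and their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import refsigs

COSINE_ACCEPT = 0.90
MIN_CATALOG_SIZE = 50  # smaller catalogs give noisy exposures; warn below this


@dataclass
class MutationCatalog:
    channels: list
    counts: np.ndarray
    var_class: str  # "SBS" or "ID"
    unclassified: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")
        if len(self.counts) != len(self.channels):
            raise ValueError("counts/channels length mismatch")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=pd.Index(self.channels, name="channel"))


@dataclass
class ExposureVector:
    proportions: pd.Series  # >= 0, sums to 1
    loglik: float
    n_mutations: float
    converged: bool = True

    def attributed_counts(self, burden: float) -> pd.Series:
        return self.proportions * burden


@dataclass
class DeconvolutionResult:
    weights: pd.Series
    cosine: float
    accepted: bool
    reconstruction: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# catalog construction


def build_sbs_catalog(variants: pd.DataFrame) -> MutationCatalog:
    """96-channel catalog from SNVs annotated with their +/-1 reference context.

    Purine-reference substitutions are reverse-complemented into the
    pyrimidine-centred convention; malformed annotations are skipped and
    tallied in ``unclassified``.
    """
    channels = refsigs.sbs96_channels()
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(96)
    skipped = 0
    snvs = variants[variants.get("var_class", "SNV") == "SNV"] if "var_class" in variants else variants
    for ref, alt, ctx in zip(snvs["ref"], snvs["alt"], snvs["context"]):
        try:
            counts[index[refsigs.sbs_channel(str(ref), str(alt), str(ctx))]] += 1
        except (ValueError, KeyError):
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} SNVs with invalid context annotation")
    return MutationCatalog(channels, counts, "SBS", unclassified=skipped)


def build_id_catalog(variants: pd.DataFrame) -> MutationCatalog:
    """83-channel catalog from indels with homopolymer annotations.

    Only 1-bp insertions/deletions at annotated homopolymer runs are
    classified from ref/alt plus (hp_base, hp_len); anything else counts
    as unclassified with a warning.  A precomputed ``channel`` column, if
    present, takes precedence.
    """
    channels = refsigs.id83_channels()
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(83)
    skipped = 0
    indels = variants[variants["var_class"] == "indel"] if "var_class" in variants else variants
    has_channel = "channel" in indels.columns
    for _, row in indels.iterrows():
        ch = None
        if has_channel and isinstance(row["channel"], str) and row["channel"] in index:
            ch = row["channel"]
        else:
            ref, alt = str(row["ref"]), str(row["alt"])
            if abs(len(ref) - len(alt)) == 1 and row.get("hp_base", ""):
                kind = "Del" if len(ref) > len(alt) else "Ins"
                try:
                    ch = refsigs.id_channel(kind, str(row["hp_base"]), int(row["hp_len"]))
                except ValueError:
                    ch = None
        if ch is None:
            skipped += 1
        else:
            counts[index[ch]] += 1
    if skipped:
        warnings.warn(f"{skipped} indels were unclassifiable and excluded from channels")
    return MutationCatalog(channels, counts, "ID", unclassified=skipped)


# ---------------------------------------------------------------------------
# exposure fitting


def _check_refs(refs: pd.DataFrame, channels) -> None:
    if list(refs.index) != list(channels):
        raise ValueError("reference signatures are not on the catalog's channel set")
    if (refs.to_numpy() < 0).any():
        raise ValueError("reference signatures must be non-negative")
    if not np.allclose(refs.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")


def fit_exposures_em(
    catalog: MutationCatalog,
    refs: pd.DataFrame,
    subset=None,
    max_iter: int = 10000,
    tol: float = 1e-8,
) -> ExposureVector:
    """ML multinomial-mixture exposures of ``catalog`` over reference columns."""
    if catalog.total <= 0:
        raise ValueError("cannot fit exposures to an empty catalog")
    if subset is not None:
        missing = [s for s in subset if s not in refs.columns]
        if missing:
            raise ValueError(f"signatures not in reference table: {missing}")
        if len(subset) == 0:
            raise ValueError("signature subset must be non-empty")
        refs = refs[list(subset)]
    if refs.shape[1] == 0:
        raise ValueError("signature subset must be non-empty")
    _check_refs(refs, catalog.channels)
    if catalog.total < MIN_CATALOG_SIZE:
        warnings.warn(
            f"catalog has only {catalog.total:.0f} mutations "
            f"(< {MIN_CATALOG_SIZE}); exposures will be noisy"
        )

    x = catalog.counts
    S = refs.to_numpy(dtype=float)  # (C, K)
    K = S.shape[1]
    w = np.full(K, 1.0 / K)
    prev = -np.inf
    converged = False
    nonzero = x > 0
    xs = x[nonzero]
    Ss = S[nonzero]
    for _ in range(max_iter):
        mix = Ss @ w  # (C,)
        mix = np.maximum(mix, 1e-300)
        ll = float(xs @ np.log(mix))
        r = Ss * w[None, :] / mix[:, None]  # responsibilities (C, K)
        w = (xs @ r) / xs.sum()
        w = np.maximum(w, 0.0)
        w /= w.sum()
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return ExposureVector(
        proportions=pd.Series(w, index=refs.columns),
        loglik=ll,
        n_mutations=catalog.total,
        converged=converged,
    )


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv_ = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv_ == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv_))


def deconvolve_to_reference(
    extracted, refs: pd.DataFrame, subset=None, accept: float = COSINE_ACCEPT
) -> DeconvolutionResult:
    """Express an extracted spectrum as a reference combination; accept at cosine >= 0.90."""
    extracted = np.asarray(extracted, dtype=float)
    if extracted.min() < 0:
        raise ValueError("extracted spectrum must be non-negative")
    total = extracted.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("extracted spectrum must sum to 1")
    # scale to a pseudo-catalog; the EM weights depend only on proportions
    catalog = MutationCatalog(list(refs.index), extracted * 1e4, "SBS")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exp = fit_exposures_em(catalog, refs, subset=subset)
    cols = list(subset) if subset is not None else list(refs.columns)
    recon = refs[cols].to_numpy() @ exp.proportions.to_numpy()
    cos = cosine_similarity(extracted, recon)
    return DeconvolutionResult(
        weights=exp.proportions,
        cosine=cos,
        accepted=cos >= accept,
        reconstruction=pd.Series(recon, index=refs.index),
    )


def merge_signature_exposures(
    exposures: pd.Series, groups: dict | None = None
) -> pd.Series:
    """Combine hard-to-separate signatures (by default SBS5 + SBS40* -> SBS5/40)."""
    if groups is None:
        flat = [n for n in exposures.index if n == "SBS5" or str(n).startswith("SBS40")]
        groups = {"SBS5/40": flat} if flat else {}
    out = exposures.copy()
    for merged, members in groups.items():
        members = [m for m in members if m in out.index]
        if not members:
            continue
        total = out[members].sum()
        out = out.drop(members)
        out[merged] = out.get(merged, 0.0) + total
    return out


# ---------------------------------------------------------------------------
# fold increases and indel summaries


def signature_fold_increase(
    exposure: pd.Series,
    corrected_burden: float,
    baseline_exposure: pd.Series,
    expected_burden: float,
) -> pd.Series:
    """Observed/expected mutations per signature (three-step procedure).

    observed_s = exposure_s x corrected burden; expected_s = donor
    non-metaplastic baseline_s x age-expected burden; fold_s is their
    ratio.  A zero baseline with non-zero observed yields +inf.
    """
    if expected_burden <= 0:
        raise ValueError("expected burden must be positive")
    if abs(float(baseline_exposure.sum()) - 1.0) > 1e-6:
        raise ValueError("baseline exposure proportions must sum to 1")
    baseline = baseline_exposure.reindex(exposure.index).fillna(0.0)
    observed = exposure * corrected_burden
    expected = baseline * expected_burden
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = observed / expected
    fold[(expected == 0) & (observed > 0)] = np.inf
    fold[(expected == 0) & (observed == 0)] = np.nan
    return fold


#: catalog channels treated as defining ID1 (long-run 1-bp T insertions)
ID1_CHANNELS = ("1:Ins:T:4", "1:Ins:T:5")
ID2_CHANNELS = ("1:Del:T:4", "1:Del:T:5")


def id2_id1_ratio(counts) -> float:
    """ID2 deletions over ID1 insertions.

    ``counts`` is either a mapping/Series with ID1/ID2 attributed counts,
    or an ID :class:`MutationCatalog` (then the defining long-homopolymer
    channels are counted).  Zero ID1 is undefined (NaN).
    """
    if isinstance(counts, MutationCatalog):
        s = counts.as_series()
        id1 = float(s[list(ID1_CHANNELS)].sum())
        id2 = float(s[list(ID2_CHANNELS)].sum())
    else:
        s = pd.Series(counts)
        id1, id2 = float(s.get("ID1", 0.0)), float(s.get("ID2", 0.0))
    if id1 <= 0:
        return np.nan
    return id2 / id1


# ---------------------------------------------------------------------------
# cohort-level glue


def sample_exposure_table(
    matrix,
    filter_table: pd.DataFrame,
    refs: pd.DataFrame,
    subset=None,
    min_reads: int = 4,
) -> pd.DataFrame:
    """Per-sample SBS exposures from detected passing variants."""
    passing = (filter_table["status"] == "pass").to_numpy()
    is_snv = (matrix.variants["var_class"] == "SNV").to_numpy()
    rows = []
    for j, sample in enumerate(matrix.samples):
        det = passing & is_snv & (matrix.nv[:, j] >= min_reads)
        catalog = build_sbs_catalog(matrix.variants.loc[det])
        if catalog.total == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exp = fit_exposures_em(catalog, refs, subset=subset)
        row = {"sample": sample, "n_mutations": catalog.total}
        row.update(exp.proportions.to_dict())
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["n_mutations"], index=pd.Index([], name="sample"))
    return pd.DataFrame(rows).set_index("sample")


def signature_fold_table(
    exposures: pd.DataFrame,
    burden_table: pd.DataFrame,
    rate_model,
) -> pd.DataFrame:
    """Fold increases for metaplastic glands against donor non-metaplastic baselines.

    ``exposures``: sample-indexed proportions (from
    :func:`sample_exposure_table`); ``burden_table``: per-sample corrected
    burdens/metadata; ``rate_model``: the age model fitted on
    non-metaplastic glands, supplying expected burdens.
    """
    sig_cols = [c for c in exposures.columns if c != "n_mutations"]
    bt = burden_table.set_index("sample")
    rows = []
    for donor, group in bt.groupby("donor"):
        base_samples = group.index[~group["metaplasia"].astype(bool)]
        base_samples = [s for s in base_samples if s in exposures.index]
        if not base_samples:
            continue
        baseline = exposures.loc[base_samples, sig_cols].mean()
        baseline /= baseline.sum()
        for sample in group.index[group["metaplasia"].astype(bool)]:
            if sample not in exposures.index:
                continue
            expected = float(rate_model.expected_burden(group.loc[sample, "age"]))
            if expected <= 0 or not np.isfinite(group.loc[sample, "corrected_snv"]):
                continue
            fold = signature_fold_increase(
                exposures.loc[sample, sig_cols],
                float(group.loc[sample, "corrected_snv"]),
                baseline,
                expected,
            )
            row = {"sample": sample, "donor": donor}
            row.update({f"fold_{s}": fold[s] for s in sig_cols})
            rows.append(row)
    return pd.DataFrame(rows)
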