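"""Variant-by-sample read-count matrices.

The :class:`CountMatrix` is the substrate of every statistical stage: per
variant and per microdissection it holds the variant-supporting read count
(NV) and the total depth (NR), together with variant-level annotations
(alleles, trinucleotide context, homopolymer annotation for indels, and
the ASMD/CLPM mapping-quality summaries) and a per-cell "largely diploid"
mask used by the germline test.

Serialization is a flat TSV with one row per variant: fixed annotation
columns followed by ``NV:<sample>`` / ``NR:<sample>`` / ``DM:<sample>``
triples (the DM columns are an extension carrying the diploid mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: annotation columns serialized before the per-sample triples
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_class",
    "context",
    "hp_base",
    "hp_len",
    "asmd",
    "clpm",
]


def infer_var_class(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class CountMatrix:
    variants: pd.DataFrame
    samples: list[str]
    nv: np.ndarray
    nr: np.ndarray
    diploid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nv = np.asarray(self.nv, dtype=np.int32)
        self.nr = np.asarray(self.nr, dtype=np.int32)
        if self.diploid is None:
            self.diploid = np.ones_like(self.nv, dtype=bool)
        self.diploid = np.asarray(self.diploid, dtype=bool)
        self.validate()

    # -- basic geometry ------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        shape = (self.n_variants, self.n_samples)
        for name, arr in (("NV", self.nv), ("NR", self.nr), ("diploid", self.diploid)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.nv < 0).any() or (self.nr < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.nv > self.nr).any():
            raise ValueError("NV must not exceed NR")
        missing = [c for c in ("chrom", "pos", "ref", "alt", "var_class") if c not in self.variants]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")

    def vaf(self) -> np.ndarray:
        """NV/NR with 0/0 reported as NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.nr > 0, self.nv / np.maximum(self.nr, 1), np.nan)

    # -- subsetting ----------------------------------------------------
    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = self.sample_index(sample_ids)
        return CountMatrix(
            variants=self.variants.reset_index(drop=True),
            samples=list(sample_ids),
            nv=self.nv[:, idx],
            nr=self.nr[:, idx],
            diploid=self.diploid[:, idx],
        )

    def subset_variants(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            nv=self.nv[mask],
            nr=self.nr[mask],
            diploid=self.diploid[mask],
        )

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {c: self.variants.get(c, pd.Series([""] * self.n_variants)) for c in VARIANT_COLUMNS}
        for j, s in enumerate(self.samples):
            cols[f"NV:{s}"] = self.nv[:, j]
            cols[f"NR:{s}"] = self.nr[:, j]
            cols[f"DM:{s}"] = self.diploid[:, j].astype(int)
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c[3:] for c in df.columns if c.startswith("NV:")]
        ann = df[[c for c in VARIANT_COLUMNS if c in df.columns]].copy()
        nv = df[[f"NV:{s}" for s in samples]].to_numpy(dtype=np.int32)
        nr = df[[f"NR:{s}" for s in samples]].to_numpy(dtype=np.int32)
        dm_cols = [f"DM:{s}" for s in samples]
        diploid = (
            df[dm_cols].to_numpy(dtype=bool) if all(c in df.columns for c in dm_cols) else None
        )
        return cls(variants=ann, samples=samples, nv=nv, nr=nr, diploid=diploid)

    def write_vcf(self, path) -> None:
        """Write a minimal multi-sample VCF 4.2 with per-sample AD/DP fields."""
        order = np.lexsort((self.variants["pos"].to_numpy(), self.variants["chrom"].astype(str).to_numpy()))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
            for chrom in pd.unique(self.variants["chrom"].astype(str).iloc[order]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i in order:
                row = self.variants.iloc[i]
                calls = [
                    f"{self.nr[i, j] - self.nv[i, j]},{self.nv[i, j]}:{self.nr[i, j]}"
                    for j in range(self.n_samples)
                ]
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t.\tAD:DP\t"
                    + "\t".join(calls)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "CountMatrix":
        """Read a multi-sample VCF with AD (ref,alt) per-sample depths."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, nvs, nrs = [], [], []
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise ValueError("VCF lacks per-sample AD field")
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0
            alt = rec.ALT[0] if rec.ALT else ""
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "var_class": infer_var_class(rec.REF, alt),
                }
            )
            nvs.append(ad[:, 1])
            nrs.append(ad.sum(axis=1))
        return cls(
            variants=pd.DataFrame(rows),
            samples=samples,
            nv=np.array(nvs, dtype=np.int32).reshape(len(rows), len(samples)),
            nr=np.array(nrs, dtype=np.int32).reshape(len(rows), len(samples)),
        )


def concat_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Stack per-donor matrices into one cohort matrix (block-diagonal counts).

    Depth outside a variant's own donor block is 0, i.e. "not assessed";
    every per-donor statistic downstream masks on NR > 0.
    """
    samples: list[str] = []
    for m in matrices:
        samples.extend(m.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids across matrices")
    n_var = sum(m.n_variants for m in matrices)
    nv = np.zeros((n_var, len(samples)), dtype=np.int32)
    nr = np.zeros_like(nv)
    dm = np.ones_like(nv, dtype=bool)
    r = c = 0
    frames = []
    for m in matrices:
        nv[r : r + m.n_variants, c : c + m.n_samples] = m.nv
        nr[r : r + m.n_variants, c : c + m.n_samples] = m.nr
        dm[r : r + m.n_variants, c : c + m.n_samples] = m.diploid
        frames.append(m.variants)
        r += m.n_variants
        c += m.n_samples
    variants = pd.concat(frames, ignore_index=True)
    return CountMatrix(variants=variants, samples=samples, nv=nv, nr=nr, diploid=dm)
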