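"""Mutation-channel conventions and a synthetic reference-signature catalog.

SBS channels follow the COSMIC 96-class convention: pyrimidine-centred
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) in all 16 trinucleotide
contexts, ordered by substitution then alphabetically by context.

ID channels follow the COSMIC 83-class convention: 1-bp insertions and
deletions at C/T homopolymers, longer repeat-unit indels, and
microhomology-flanked deletions.

The reference signatures shipped here are *synthetic* stand-ins: they are
constructed deterministically to carry the qualitative character of the
catalogued processes (SBS1: C>T at NpCpG from 5-methylcytosine
deamination; SBS18: reactive-oxygen C>A damage; SBS5/40: flat "clock-like"
background; ID1/ID2: 1-bp T slippage at long homopolymers) but their
channel weights are not the catalogue values.  Real COSMIC tables in the
standard TSV layout (channel column + one column per signature) are read
with :func:`read_cosmic_tsv`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def sbs96_channels() -> list[str]:
    """The 96 SBS channel labels in COSMIC order, e.g. ``A[C>A]A``."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


def id83_channels() -> list[str]:
    """The 83 small-indel channel labels in COSMIC order."""
    chans: list[str] = []
    for base in ("C", "T"):  # 1-bp deletions at homopolymers
        chans += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):  # 1-bp insertions at homopolymers
        chans += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in ("2", "3", "4", "5"):  # >=2-bp deletions at repeats
        chans += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in ("2", "3", "4", "5"):  # >=2-bp insertions at repeats
        chans += [f"{size}:Ins:R:{i}" for i in range(6)]
    # microhomology-flanked deletions
    chans += ["2:Del:M:1"]
    chans += [f"3:Del:M:{i}" for i in (1, 2)]
    chans += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    chans += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    assert len(chans) == 83
    return chans


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs_channel(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its +/-1 context to its pyrimidine-centred channel.

    ``context`` is the 3-mer around the variant on the reference strand;
    purine-reference changes are reverse-complemented.
    """
    if len(context) != 3 or context[1] != ref or ref == alt:
        raise ValueError(f"inconsistent SNV annotation: {ref}>{alt} @ {context}")
    if any(b not in BASES for b in context) or alt not in BASES:
        raise ValueError(f"non-ACGT base in {ref}>{alt} @ {context}")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def id_channel(kind: str, base: str, run_length: int) -> str:
    """Channel for a 1-bp insertion/deletion at a homopolymer run.

    ``run_length`` is the homopolymer length in the *reference* (the run
    containing the deleted base, or the run the insertion extends).
    Purine homopolymers are complemented to the C/T convention.
    """
    if kind not in ("Ins", "Del"):
        raise ValueError(f"unknown indel kind {kind!r}")
    if base in ("A", "G"):
        base = COMPLEMENT[base]
    if base not in ("C", "T"):
        raise ValueError(f"non-ACGT homopolymer base {base!r}")
    if kind == "Del":
        if run_length < 1:
            raise ValueError("deleted base must sit in a run of length >= 1")
        cat = min(run_length, 6) - 1
    else:
        cat = min(max(run_length, 0), 5)
    return f"1:{kind}:{base}:{cat}"


def _normalise(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix / matrix.sum(axis=0)


def synthetic_sbs_signatures() -> pd.DataFrame:
    """Deterministic synthetic SBS reference catalog (96 channels x 4 signatures).

    Columns: SBS1, SBS5/40, SBS18, SBS17b.  Column sums are 1.
    """
    chans = sbs96_channels()
    idx = pd.Index(chans, name="channel")
    mat = pd.DataFrame(0.0, index=idx, columns=["SBS1", "SBS5/40", "SBS18", "SBS17b"])

    # SBS1: dominated by N[C>T]G (5-methylcytosine deamination at CpG)
    for five in BASES:
        mat.loc[f"{five}[C>T]G", "SBS1"] = 0.22
    mat["SBS1"] += 0.12 / 96.0

    # SBS5/40: flat background, mild T>C tilt
    flat = pd.Series(1.0, index=idx)
    flat[[c for c in chans if "[T>C]" in c]] = 1.8
    mat["SBS5/40"] = flat

    # SBS18: C>A heavy, peaked at G/T-flanked contexts (oxidative damage)
    ca = pd.Series(0.0, index=idx)
    for c in chans:
        if "[C>A]" in c:
            ca[c] = 0.5
    for five, three in (("T", "T"), ("G", "A"), ("T", "A"), ("A", "A")):
        ca[f"{five}[C>A]{three}"] = 3.0
    ca += 0.01  # trace mass everywhere keeps the EM support full
    mat["SBS18"] = ca

    # SBS17b: T>G peaked at CTT-like contexts
    tg = pd.Series(0.01, index=idx)
    for five in BASES:
        tg[f"{five}[T>G]T"] = 2.0
    mat["SBS17b"] = tg

    return _normalise(mat)


def synthetic_id_signatures() -> pd.DataFrame:
    """Deterministic synthetic ID reference catalog (83 channels x 3 signatures).

    ID1: 1-bp T insertions at long homopolymers; ID2: 1-bp T deletions at
    long homopolymers; ID5: diffuse 1-bp deletions at short homopolymers.
    All mass sits on 1-bp channels so that simulated indels stay fully
    classifiable from homopolymer annotations alone.
    """
    chans = id83_channels()
    idx = pd.Index(chans, name="channel")
    mat = pd.DataFrame(0.0, index=idx, columns=["ID1", "ID2", "ID5"])
    one_bp = [c for c in chans if c.startswith("1:")]
    for cat, w in ((3, 0.15), (4, 0.3), (5, 0.5)):
        mat.loc[f"1:Ins:T:{cat}", "ID1"] = w
        mat.loc[f"1:Del:T:{cat}", "ID2"] = w
    mat.loc[one_bp, "ID1"] += 0.005
    mat.loc[one_bp, "ID2"] += 0.005
    id5 = pd.Series(0.0, index=idx)
    for cat in range(4):
        id5[f"1:Del:T:{cat}"] += 0.14
        id5[f"1:Del:C:{cat}"] += 0.11
    mat["ID5"] = id5
    return _normalise(mat)


def read_cosmic_tsv(path) -> pd.DataFrame:
    """Read a COSMIC-format signature table (channel column + signature columns)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "channel"
    mat = df.astype(float)
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("signature columns must sum to 1")
    return mat


def write_cosmic_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("channel").reset_index().to_csv(path, sep="\t", index=False)
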