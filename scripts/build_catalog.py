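"""Regenerate the packaged reference signature catalog.

The catalog ships in src/tmbsubtype/data/cosmic_v2_style_catalog.tsv using
the COSMIC v2 96-category dialect (C>A..T>G blocks, flanks lexicographic).
The profiles are parametric emulations of well-characterized mutational
processes, built from their published qualitative descriptions (peak
contexts and substitution classes), NOT the numeric COSMIC matrix — use
`--catalog` on the CLI to supply the real file where licensing/network
allows.  Running this script rewrites the TSV deterministically.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tmbsubtype.signatures import CATEGORIES_96, SUBSTITUTIONS  # noqa: E402

FLANKS = "ACGT"


def blank() -> dict[str, float]:
    return {c: 0.0 for c in CATEGORIES_96}


def add(w, sub=None, five=None, three=None, weight=1.0):
    """Add weight to all categories matching the (sub, 5', 3') pattern."""
    subs = [sub] if isinstance(sub, str) else (sub or SUBSTITUTIONS)
    fives = [five] if isinstance(five, str) else (five or FLANKS)
    threes = [three] if isinstance(three, str) else (three or FLANKS)
    for s in subs:
        for f in fives:
            for t in threes:
                w[f"{f}[{s}]{t}"] += weight


def normalize(w) -> np.ndarray:
    v = np.array([w[c] for c in CATEGORIES_96], dtype=float)
    return v / v.sum()


def build() -> pd.DataFrame:
    sigs: dict[str, np.ndarray] = {}

    # Signature 1 — deamination clock: C>T at NpCpG
    w = blank()
    add(w, weight=0.06)
    add(w, sub="C>T", three="G", weight=11.0)
    add(w, sub="C>T", weight=0.3)
    add(w, sub="T>C", weight=0.35)
    sigs["Signature 1"] = normalize(w)

    # Signature 2 — APOBEC: C>T at TpCpN (with minor C>G at TpCpN)
    w = blank()
    add(w, weight=0.04)
    add(w, sub="C>T", five="T", weight=10.0)
    add(w, sub="C>G", five="T", weight=2.0)
    sigs["Signature 2"] = normalize(w)

    # Signature 3 — HR deficiency: near-flat across all classes
    w = blank()
    rng = np.random.default_rng(3)
    for i, c in enumerate(CATEGORIES_96):
        w[c] = 1.0 + 0.35 * np.sin(0.7 * i) + 0.15 * rng.uniform()
    add(w, sub="C>T", three="G", weight=0.6)
    sigs["Signature 3"] = normalize(w)

    # Signature 4 — tobacco carcinogens: C>A across a broad flank spectrum
    w = blank()
    add(w, weight=0.10)
    for f, fw in zip(FLANKS, (1.1, 1.4, 0.9, 1.0)):
        for t, tw in zip(FLANKS, (1.2, 1.1, 0.8, 0.9)):
            add(w, sub="C>A", five=f, three=t, weight=7.0 * fw * tw)
    add(w, sub="C>G", weight=0.7)
    add(w, sub="C>T", weight=0.7)
    add(w, sub="T>A", weight=0.45)
    sigs["Signature 4"] = normalize(w)

    # Signature 5 — flat with a T>C lean
    w = blank()
    add(w, weight=0.55)
    add(w, sub="T>C", weight=2.0)
    add(w, sub="T>C", five="A", weight=1.2)
    add(w, sub="C>T", weight=0.4)
    sigs["Signature 5"] = normalize(w)

    # Signature 6 — MMR deficiency: C>T at [A/C/G]pCpG plus diffuse C>T
    w = blank()
    add(w, weight=0.05)
    add(w, sub="C>T", five=["A", "C", "G"], three="G", weight=5.0)
    add(w, sub="C>T", five="G", weight=4.0)
    add(w, sub="C>T", five="C", three=["A", "C"], weight=2.5)
    add(w, sub="C>T", weight=1.2)
    add(w, sub="T>C", three="T", weight=1.4)
    sigs["Signature 6"] = normalize(w)

    # Signature 7 — UV: C>T at dipyrimidines (5' C or T)
    w = blank()
    add(w, weight=0.03)
    add(w, sub="C>T", five=["C", "T"], weight=9.0)
    add(w, sub="C>T", five=["C", "T"], three=["C", "T"], weight=4.0)
    sigs["Signature 7"] = normalize(w)

    # Signature 13 — APOBEC: C>G at TpCpN
    w = blank()
    add(w, weight=0.04)
    add(w, sub="C>G", five="T", weight=10.0)
    add(w, sub="C>T", five="T", weight=1.5)
    sigs["Signature 13"] = normalize(w)

    # Signature 17 — T>G at NpTpT with a CpTpT peak
    w = blank()
    add(w, weight=0.05)
    add(w, sub="T>G", five="C", three="T", weight=12.0)
    add(w, sub="T>G", five="A", three="T", weight=4.0)
    add(w, sub="T>G", five="G", three="T", weight=3.0)
    add(w, sub="T>C", three="T", weight=1.2)
    sigs["Signature 17"] = normalize(w)

    # Signature 18 — C>A concentrated at specific flanks (unlike broad Sig 4)
    w = blank()
    add(w, weight=0.05)
    add(w, sub="C>A", five="G", three="A", weight=9.0)
    add(w, sub="C>A", five="A", three="A", weight=5.0)
    add(w, sub="C>A", five="G", three="T", weight=4.0)
    sigs["Signature 18"] = normalize(w)

    # Signature 29 — chewing tobacco: C>A at CpCpN
    w = blank()
    add(w, weight=0.05)
    add(w, sub="C>A", five="C", weight=8.0)
    add(w, sub="C>G", five="C", weight=1.0)
    sigs["Signature 29"] = normalize(w)

    return pd.DataFrame(sigs, index=list(CATEGORIES_96))


def main() -> None:
    df = build()
    out = (
        Path(__file__).resolve().parents[1]
        / "src" / "tmbsubtype" / "data" / "cosmic_v2_style_catalog.tsv"
    )
    header = (
        "# Parametric emulation of well-characterized mutational-process profiles\n"
        "# in the COSMIC v2 96-category dialect. Columns sum to 1. These are NOT\n"
        "# the numeric COSMIC v2 values; regenerate with scripts/build_catalog.py\n"
        "# or substitute the real matrix via the same layout (index = category).\n"
    )
    with open(out, "w") as fh:
        fh.write(header)
        df.round(8).rename_axis("category").to_csv(fh, sep="\t")
    print(f"wrote {out} ({df.shape[0]} x {df.shape[1]})")

    cos = np.zeros((df.shape[1],) * 2)
    m = df.to_numpy()
    for i in range(df.shape[1]):
        for j in range(df.shape[1]):
            cos[i, j] = m[:, i] @ m[:, j] / (
                np.linalg.norm(m[:, i]) * np.linalg.norm(m[:, j])
            )
    off = cos[~np.eye(df.shape[1], dtype=bool)]
    print(f"max off-diagonal cosine: {off.max():.3f}")


if __name__ == "__main__":
    main()
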