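"""Relative qPCR expression (2^-ΔΔCt) and FDR adjustment.

The comparative-Ct method quantifies a target gene against a reference
gene (here typically β-actin) and a control sample: replicate Ct values
are averaged on the Ct scale, ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt_sample − ΔCt_control, and fold change = E^(−ΔΔCt) with
amplification efficiency E = 2 assumed exact.  p-value vectors from
differential-expression scans are adjusted by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionResult",
    "read_ct_table",
    "compute_ddct",
    "bh_adjust",
    "expression_matrix",
]

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    sample: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format Ct TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df[CT_COLUMNS]


def compute_ddct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_sample: str,
    efficiency: float = 2.0,
) -> list[ExpressionResult]:
    """2^-ΔΔCt relative expression of *target_gene* across samples.

    Replicates are averaged on the Ct scale before any Δ is taken.  The
    control sample's fold change is 1 by construction.  *efficiency*
    generalises the fold to E^(−ΔΔCt) for validated efficiencies below 2.
    """
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    df = table
    mean_ct = (
        df.groupby(["sample", "gene"], sort=False)["ct"].agg(["mean", "size"])
    )
    samples = list(dict.fromkeys(df["sample"]))
    if control_sample not in samples:
        raise ValueError(f"control sample {control_sample!r} not in table")
    for s in samples:
        if (s, reference_gene) not in mean_ct.index:
            raise ValueError(f"reference gene missing in sample {s!r}")
        if (s, target_gene) not in mean_ct.index:
            raise ValueError(f"target gene missing in sample {s!r}")

    def dct(sample: str) -> float:
        return (
            mean_ct.loc[(sample, target_gene), "mean"]
            - mean_ct.loc[(sample, reference_gene), "mean"]
        )

    dct_control = dct(control_sample)
    results = []
    for s in samples:
        d = dct(s)
        dd = d - dct_control
        results.append(
            ExpressionResult(
                gene=target_gene,
                sample=s,
                delta_ct=float(d),
                delta_delta_ct=float(dd),
                fold_change=float(efficiency ** (-dd)),
            )
        )
    return results


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expression_matrix(
    data: pd.DataFrame, transform: str = "log2p1"
) -> pd.DataFrame:
    """Transform a rectangular gene × sample abundance table.

    ``log2p1`` maps x to log2(x + 1); ``zscore_rows`` centres and scales
    each row to mean 0 and sd 1 (rows with zero variance stay 0-centred).
    """
    mat = data.astype(float)
    if mat.isna().any().any():
        raise ValueError("ragged or non-numeric input")
    if transform == "log2p1":
        return np.log2(mat + 1.0)
    if transform == "zscore_rows":
        centred = mat.sub(mat.mean(axis=1), axis=0)
        sd = mat.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)
        return centred.div(sd, axis=0)
    raise ValueError(f"unknown transform {transform!r}")
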