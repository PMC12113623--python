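"""Cohesion-based network stability.

Connectedness of taxon *i* is the mean of its positive (c+) and negative
(c-) retained-edge weights.  Sample-level cohesion weights connectedness by
relative abundance:

    C+_j = sum_i a_ij c+_i        C-_j = sum_i a_ij c-_i

with a_ij the relative abundance of taxon i in sample j.  Two stability
variants are emitted side by side because they differ in the literature this
pipeline follows: the |C-|/C+ ratio and the absolute difference |C- - C+|.
No null-model correction of connectedness is applied (documented
limitation); the statistic is computed over the significant network edges by
default, with a full-correlation-matrix mode available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import AsvTable, CooccurrenceNetwork, ValidationError

__all__ = [
    "connectedness",
    "cohesion",
    "stability_vs_richness",
    "RegressionResult",
]


def connectedness(
    net: CooccurrenceNetwork,
    mode: str = "network",
    rho: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-taxon mean positive and negative association strengths.

    ``mode="network"`` (default) averages over the taxon's retained edges;
    ``mode="full-matrix"`` averages over all off-diagonal entries of the
    supplied Spearman ``rho`` matrix, significant or not.  A taxon with no
    positive (negative) partners gets c+ = 0 (c- = 0).
    """
    if mode == "network":
        nodes = net.nodes
        if len(nodes) < 2:
            raise ValidationError("connectedness needs at least 2 taxa")
        rows = []
        for node in nodes:
            pos = [d["rho"] for _, _, d in net.graph.edges(node, data=True) if d["rho"] > 0]
            neg = [d["rho"] for _, _, d in net.graph.edges(node, data=True) if d["rho"] < 0]
            rows.append(
                {
                    "asv_id": node,
                    "pos_connectedness": float(np.mean(pos)) if pos else 0.0,
                    "neg_connectedness": float(np.mean(neg)) if neg else 0.0,
                }
            )
        return pd.DataFrame(rows)
    if mode == "full-matrix":
        if rho is None:
            raise ValidationError("full-matrix mode requires the rho matrix")
        arr = rho.to_numpy(dtype=float).copy()
        np.fill_diagonal(arr, np.nan)
        if arr.shape[0] < 2:
            raise ValidationError("connectedness needs at least 2 taxa")
        pos = np.where(arr > 0, arr, np.nan)
        neg = np.where(arr < 0, arr, np.nan)
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> 0
            cpos = np.nanmean(pos, axis=1)
            cneg = np.nanmean(neg, axis=1)
        return pd.DataFrame(
            {
                "asv_id": list(rho.index),
                "pos_connectedness": np.nan_to_num(cpos),
                "neg_connectedness": np.nan_to_num(cneg),
            }
        )
    raise ValidationError(f"unknown connectedness mode {mode!r}")


def cohesion(table: AsvTable, conn: pd.DataFrame) -> pd.DataFrame:
    """Per-sample positive/negative cohesion and both stability variants.

    Samples with zero total abundance over the connectedness taxa are
    flagged undefined (NaN cohesions); the ratio is NaN when C+ = 0.
    Cohesions are invariant to rescaling a sample's raw counts because they
    use per-sample relative abundances.
    """
    bad = (conn["pos_connectedness"] < 0).any() or (conn["neg_connectedness"] > 0).any()
    if bad:
        raise ValidationError("connectedness signs violate c+ >= 0 >= c-")
    taxa = [a for a in conn["asv_id"] if a in set(table.asv_ids)]
    rel = table.relative_abundance("sample")
    cpos = conn.set_index("asv_id")["pos_connectedness"]
    cneg = conn.set_index("asv_id")["neg_connectedness"]
    rows = []
    for sample in table.sample_ids:
        a = rel.loc[sample, taxa] if taxa else pd.Series(dtype=float)
        if not taxa or a.sum() <= 0:
            rows.append(
                {
                    "sample_id": sample,
                    "pos_cohesion": np.nan,
                    "neg_cohesion": np.nan,
                    "stability_ratio": np.nan,
                    "stability_absdiff": np.nan,
                }
            )
            continue
        c_plus = float((a * cpos.loc[taxa]).sum())
        c_minus = float((a * cneg.loc[taxa]).sum())
        ratio = abs(c_minus) / c_plus if c_plus > 0 else np.nan
        rows.append(
            {
                "sample_id": sample,
                "pos_cohesion": c_plus,
                "neg_cohesion": c_minus,
                "stability_ratio": ratio,
                "stability_absdiff": abs(c_minus - c_plus),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def stability_vs_richness(
    cohesion_df: pd.DataFrame,
    richness: pd.Series,
    variant: str = "stability_absdiff",
) -> RegressionResult:
    """OLS of per-sample network stability on ASV richness.

    Returns the slope, intercept, R^2 and the two-sided p-value of the
    slope's t-test.
    """
    if variant not in ("stability_absdiff", "stability_ratio"):
        raise ValidationError(f"unknown stability variant {variant!r}")
    df = cohesion_df.set_index("sample_id").join(richness.rename("richness"))
    df = df.dropna(subset=[variant, "richness"])
    if len(df) < 3:
        raise ValidationError("regression needs at least 3 samples")
    x = df["richness"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("richness has zero variance")
    y = df[variant].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(df),
    )
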