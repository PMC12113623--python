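"""Co-occurrence edge inference: abundance filter, Spearman + KLD dual
criterion, permutation p-values, Benjamini-Hochberg correction.

An edge (i, j) enters the network iff

    |rho(i, j)| >= rho_threshold   and
    kld(i, j)  <= kld_threshold    and
    q(i, j)    <  alpha

where rho is the Spearman correlation of the two taxa's abundance profiles
across samples, kld is the symmetrized Kullback-Leibler divergence between
their normalized profiles (in nats), and q is the BH-adjusted permutation
p-value of |rho|.  With the default ``kld_mode="max"`` the divergence
threshold is the maximum of the KLD matrix, which excludes nothing; this
literal reading is kept as the default and flagged loudly, with
``"quantile:x"`` available to make the clause bite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AsvTable, CooccurrenceNetwork, ValidationError

__all__ = [
    "filter_low_abundance",
    "spearman_matrix",
    "kld_matrix",
    "resampling_pvalues",
    "bh_adjust",
    "bh_adjust_matrix",
    "EdgeCandidateMatrices",
    "edge_candidates",
    "build_network",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Abundance filter
# ---------------------------------------------------------------------------


def filter_low_abundance(table: AsvTable, threshold: float = 1e-4) -> AsvTable:
    """Keep ASVs whose share of the table's grand total is strictly above
    ``threshold`` (default 0.01% of all fungal sequences)."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    totals = table.counts.sum(axis=0)
    grand = float(totals.sum())
    keep = totals.index[totals / grand > threshold]
    if len(keep) == 0:
        raise ValidationError(
            "abundance filter removed every ASV; lower the threshold"
        )
    return AsvTable(table.counts[list(keep)])


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------


def _profiles(table: AsvTable, abundance_mode: str) -> np.ndarray:
    if abundance_mode == "counts":
        return table.counts.to_numpy(dtype=float)
    if abundance_mode == "sample":
        return table.relative_abundance("sample").to_numpy()
    raise ValidationError(f"unknown abundance_mode {abundance_mode!r}")


def _rank_zscores(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column ranks (average for ties) centered and scaled so that
    ``z.T @ z`` is the Spearman correlation matrix.  Constant columns are
    flagged invalid and zeroed."""
    n = x.shape[0]
    ranks = stats.rankdata(x, axis=0)
    ranks -= ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0)
    valid = sd > 0
    z = np.zeros_like(ranks)
    z[:, valid] = ranks[:, valid] / (sd[valid] * math.sqrt(n))
    return z, valid


def spearman_matrix(
    table: AsvTable, abundance_mode: str = "sample"
) -> pd.DataFrame:
    """Pairwise Spearman correlations between ASV abundance profiles.

    Ties get average ranks; ASVs constant across all samples are flagged
    undefined (NaN rows/columns) and are excluded from edge candidacy.
    """
    if table.n_samples < 3:
        raise ValidationError("Spearman correlation needs at least 3 samples")
    z, valid = _rank_zscores(_profiles(table, abundance_mode))
    rho = np.clip(z.T @ z, -1.0, 1.0)
    rho[~valid, :] = np.nan
    rho[:, ~valid] = np.nan
    np.fill_diagonal(rho, np.where(valid, 1.0, np.nan))
    return pd.DataFrame(rho, index=table.asv_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# Symmetrized Kullback-Leibler divergence
# ---------------------------------------------------------------------------


def kld_matrix(
    table: AsvTable,
    pseudocount: float = 1e-6,
    abundance_mode: str = "sample",
) -> pd.DataFrame:
    """Symmetrized KLD (nats) between ASV profiles across samples.

    Each ASV's profile is shifted by ``pseudocount`` and normalized to a
    probability vector; kld(i, j) = 0.5 [KL(p_i || p_j) + KL(p_j || p_i)].
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    x = _profiles(table, abundance_mode) + pseudocount
    p = x / x.sum(axis=0, keepdims=True)  # columns are probability vectors
    logp = np.log(p)
    # KL(p_i||p_j) = sum_s p_si (log p_si - log p_sj)
    a = (p * logp).sum(axis=0)  # -entropy terms
    cross = p.T @ logp  # cross[i, j] = sum_s p_si log p_sj
    kl = a[:, None] - cross
    sym = 0.5 * (kl + kl.T)
    sym = np.maximum(sym, 0.0)
    np.fill_diagonal(sym, 0.0)
    return pd.DataFrame(sym, index=table.asv_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------


def resampling_pvalues(
    table: AsvTable,
    n_resamples: int = 1000,
    seed: int = 0,
    abundance_mode: str = "sample",
) -> pd.DataFrame:
    """Permutation p-values for |Spearman rho| under profile shuffling.

    The null distribution permutes each ASV's profile across samples
    independently per resample (dependence destroyed, marginals preserved);
    p(i, j) = (1 + #{|rho*| >= |rho_obs|}) / (1 + n_resamples), so p can
    never be zero.  Deterministic given ``seed``.
    """
    if n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100")
    z, valid = _rank_zscores(_profiles(table, abundance_mode))
    obs = np.abs(z.T @ z)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs, dtype=np.int64)
    thresh = obs - 1e-12  # tolerate float noise on exact ties
    for _ in range(n_resamples):
        idx = np.argsort(rng.random(z.shape), axis=0)
        zp = np.take_along_axis(z, idx, axis=0)
        null = np.abs(zp.T @ zp)
        exceed += null >= thresh
    p = (1.0 + exceed) / (1.0 + n_resamples)
    p[~valid, :] = np.nan
    p[:, ~valid] = np.nan
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=table.asv_ids, columns=table.asv_ids)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment of a flat p-value vector (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D array")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH over the unordered-pair upper triangle of a symmetric p-matrix.

    NaN entries (undefined candidates, diagonal) are excluded from the
    family and stay NaN; the result is scattered back symmetrically.
    """
    arr = p.to_numpy(dtype=float)
    n = arr.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = arr[iu]
    ok = ~np.isnan(flat)
    q_flat = np.full_like(flat, np.nan)
    if ok.any():
        q_flat[ok] = bh_adjust(flat[ok])
    q = np.full_like(arr, np.nan)
    q[iu] = q_flat
    q.T[iu] = q_flat
    return pd.DataFrame(q, index=p.index, columns=p.columns)


# ---------------------------------------------------------------------------
# Candidate matrices and network construction
# ---------------------------------------------------------------------------


@dataclass
class EdgeCandidateMatrices:
    """rho / kld / p / q matrices over a common ASV ordering."""

    asv_ids: list
    rho: pd.DataFrame
    kld: pd.DataFrame
    p_raw: pd.DataFrame
    q: pd.DataFrame

    def check_invariants(self) -> None:
        for name, m in (("rho", self.rho), ("kld", self.kld),
                        ("p_raw", self.p_raw), ("q", self.q)):
            a = m.to_numpy()
            if not np.allclose(a, a.T, equal_nan=True):
                raise ValidationError(f"{name} matrix is not symmetric")
        if np.nanmin(self.kld.to_numpy()) < 0:
            raise ValidationError("kld matrix has negative entries")
        q, p = self.q.to_numpy(), self.p_raw.to_numpy()
        mask = ~np.isnan(q) & ~np.isnan(p)
        if (q[mask] + 1e-12 < p[mask]).any():
            raise ValidationError("BH-adjusted q smaller than raw p")


def edge_candidates(
    table: AsvTable,
    n_resamples: int = 1000,
    seed: int = 0,
    pseudocount: float = 1e-6,
    abundance_mode: str = "sample",
) -> EdgeCandidateMatrices:
    """Compute all candidate matrices for ``build_network`` in one pass."""
    rho = spearman_matrix(table, abundance_mode)
    kld = kld_matrix(table, pseudocount, abundance_mode)
    p_raw = resampling_pvalues(table, n_resamples, seed, abundance_mode)
    q = bh_adjust_matrix(p_raw)
    mats = EdgeCandidateMatrices(
        asv_ids=table.asv_ids, rho=rho, kld=kld, p_raw=p_raw, q=q
    )
    mats.check_invariants()
    return mats


def _kld_threshold(kld: pd.DataFrame, kld_mode: str) -> float:
    arr = kld.to_numpy()
    iu = np.triu_indices(arr.shape[0], k=1)
    vals = arr[iu]
    vals = vals[~np.isnan(vals)]
    if kld_mode == "max":
        logger.warning(
            "kld_mode='max': the divergence threshold equals the matrix "
            "maximum, so the KLD clause excludes no candidate edge"
        )
        return float(vals.max()) if vals.size else 0.0
    if kld_mode.startswith("quantile:"):
        try:
            frac = float(kld_mode.split(":", 1)[1])
        except ValueError as exc:
            raise ValidationError(f"bad kld_mode {kld_mode!r}") from exc
        if not 0.0 < frac <= 1.0:
            raise ValidationError("kld quantile must lie in (0, 1]")
        return float(np.quantile(vals, frac)) if vals.size else 0.0
    raise ValidationError(
        f"kld_mode must be 'max' or 'quantile:x', got {kld_mode!r}"
    )


def build_network(
    mats: EdgeCandidateMatrices,
    rho_threshold: float = 0.6,
    kld_mode: str = "max",
    alpha: float = 0.05,
) -> CooccurrenceNetwork:
    """Retain edges meeting all three clauses; nodes are ASVs with >= 1 edge.

    Retention: |rho| >= rho_threshold (two-sided, so negative associations
    are kept), kld <= threshold chosen by ``kld_mode``, and q < alpha
    (strict).  Edge weight is the signed rho.
    """
    rho = mats.rho.to_numpy()
    kld = mats.kld.to_numpy()
    q = mats.q.to_numpy()
    n = rho.shape[0]
    kld_thr = _kld_threshold(mats.kld, kld_mode)
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        keep = (
            (np.abs(rho[iu]) >= rho_threshold)
            & (kld[iu] <= kld_thr)
            & (q[iu] < alpha)
        )
    keep &= ~np.isnan(rho[iu]) & ~np.isnan(q[iu])
    ids = mats.asv_ids
    edges = [
        (ids[i], ids[j], rho[i, j], q[i, j])
        for i, j in zip(iu[0][keep], iu[1][keep])
    ]
    if not edges:
        logger.warning("no edge met all retention criteria; network is empty")
    net = CooccurrenceNetwork.from_edges(edges)
    _recheck_edges(net, mats, rho_threshold, kld_thr, alpha)
    return net


def _recheck_edges(
    net: CooccurrenceNetwork,
    mats: EdgeCandidateMatrices,
    rho_threshold: float,
    kld_thr: float,
    alpha: float,
) -> None:
    """Post-hoc guard: every retained edge satisfies all three clauses."""
    for u, v, d in net.graph.edges(data=True):
        rho = mats.rho.at[u, v]
        if not (
            abs(rho) >= rho_threshold
            and mats.kld.at[u, v] <= kld_thr
            and mats.q.at[u, v] < alpha
            and math.isclose(d["rho"], rho)
        ):  # pragma: no cover - defensive
            raise AssertionError(f"edge ({u}, {v}) violates a retention clause")
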