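"""Spatial statistics: Bray-Curtis dissimilarity, haversine distances,
distance-decay regression, Mantel / partial Mantel permutation tests, and the
classical-MDS spatial axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .core import AsvTable, ValidationError

__all__ = [
    "EARTH_RADIUS_KM",
    "bray_curtis",
    "geo_distance",
    "DistanceDecayResult",
    "distance_decay",
    "MantelResult",
    "mantel",
    "partial_mantel",
    "MdsAxis",
    "classical_mds",
    "mds_spatial_axis",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def bray_curtis(table: AsvTable, on: str = "counts") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik), computed on the
    table's values as-is by default (``on="counts"``, vegan's behaviour) or
    on per-sample relative abundances (``on="relabund"``).
    """
    if on == "counts":
        x = table.counts.to_numpy(dtype=float)
    elif on == "relabund":
        x = table.relative_abundance("sample").to_numpy()
    else:
        raise ValidationError(f"unknown bray_curtis mode {on!r}")
    if (x.sum(axis=1) <= 0).any():
        raise ValidationError("empty sample in Bray-Curtis input")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def geo_distance(metadata: pd.DataFrame) -> pd.DataFrame:
    """Haversine great-circle distance (km) between samples."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    for col in ("latitude", "longitude"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks column {col!r}")
        if meta[col].isna().any():
            bad = meta.index[meta[col].isna()][0]
            raise ValidationError(f"sample {bad!r} is missing {col}")
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    ids = list(meta.index)
    return pd.DataFrame(d, index=ids, columns=ids)


def _upper(mat: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    arr = mat.to_numpy() if isinstance(mat, pd.DataFrame) else np.asarray(mat)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("expected a square matrix")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValidationError("matrix is not symmetric")
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu]


# ---------------------------------------------------------------------------
# Distance-decay regression
# ---------------------------------------------------------------------------


@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n_pairs: int
    transform: str

    def slope_ci(self, level: float = 0.95) -> Tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        t = stats.t.ppf(0.5 + level / 2.0, self.n_pairs - 2)
        return (self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr)


def distance_decay(
    bc_dissim: Union[pd.DataFrame, np.ndarray],
    geo_dist: Union[pd.DataFrame, np.ndarray],
    distance_transform: str = "log10",
) -> DistanceDecayResult:
    """OLS of community similarity (1 - Bray-Curtis) on geographic distance
    over all unordered sample pairs.

    ``distance_transform`` is "log10" (default; zero-distance pairs are
    dropped) or "identity" (distance in km).  The p-value is the slope's
    two-sided t-test; note sample pairs are not independent, so it is
    descriptive rather than exact.
    """
    sim = 1.0 - _upper(bc_dissim)
    d = _upper(geo_dist)
    if distance_transform == "log10":
        keep = d > 0
        sim, d = sim[keep], d[keep]
        x = np.log10(d)
    elif distance_transform == "identity":
        x = d
    else:
        raise ValidationError(f"unknown distance transform {distance_transform!r}")
    if len(x) < 3:
        raise ValidationError("distance-decay needs at least 3 usable pairs")
    if np.ptp(x) == 0:
        raise ValidationError("all pairwise distances are equal")
    fit = stats.linregress(x, sim)
    return DistanceDecayResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope_stderr=float(fit.stderr),
        n_pairs=len(x),
        transform=distance_transform,
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    method: str


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def mantel(
    dA: Union[pd.DataFrame, np.ndarray],
    dB: Union[pd.DataFrame, np.ndarray],
    n_perm: int = 999,
    method: str = "spearman",
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    r correlates the upper triangles; the one-sided p-value permutes dB's
    rows and columns jointly: p = (1 + #{r* >= r}) / (1 + n_perm).
    """
    a = _upper(dA)
    arrB = dB.to_numpy() if isinstance(dB, pd.DataFrame) else np.asarray(dB)
    b = _upper(arrB)
    if a.shape != b.shape:
        raise ValidationError("distance matrices are not conformable")
    r_obs = _corr(a, b, method)
    rng = np.random.default_rng(seed)
    n = arrB.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b_perm = arrB[np.ix_(perm, perm)][iu]
        if _corr(a, b_perm, method) >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, method=method)


def partial_mantel(
    dA: Union[pd.DataFrame, np.ndarray],
    dB: Union[pd.DataFrame, np.ndarray],
    dC: Union[pd.DataFrame, np.ndarray],
    n_perm: int = 999,
    method: str = "spearman",
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test of dA ~ dB controlling dC.

    The first-order partial correlation is computed from the three pairwise
    matrix correlations; the permutation p-value permutes dB (rows and
    columns jointly) and recomputes the partial statistic.
    """
    a = _upper(dA)
    arrB = dB.to_numpy() if isinstance(dB, pd.DataFrame) else np.asarray(dB)
    b = _upper(arrB)
    c = _upper(dC)
    if not (a.shape == b.shape == c.shape):
        raise ValidationError("distance matrices are not conformable")

    r_ac = _corr(a, c, method)

    def partial_r(b_vec: np.ndarray) -> float:
        r_ab = _corr(a, b_vec, method)
        r_bc = _corr(b_vec, c, method)
        denom = math.sqrt((1.0 - r_ac**2) * (1.0 - r_bc**2))
        if denom == 0:
            return 0.0
        return (r_ab - r_ac * r_bc) / denom

    r_obs = partial_r(b)
    rng = np.random.default_rng(seed)
    n = arrB.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b_perm = arrB[np.ix_(perm, perm)][iu]
        if partial_r(b_perm) >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, method=method)


# ---------------------------------------------------------------------------
# Classical MDS spatial axis
# ---------------------------------------------------------------------------


@dataclass
class MdsAxis:
    scores: pd.Series  # z-scored first-axis coordinates
    variance_fraction: float  # lambda_1 / sum of positive eigenvalues
    eigenvalues: np.ndarray


def classical_mds(dist: Union[pd.DataFrame, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances and eigendecomposes; returns the
    embedding coordinates over the positive-eigenvalue axes and the full
    eigenvalue spectrum in descending order.  For an exact Euclidean input
    the embedding reproduces the pairwise distances.
    """
    d = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("expected a square distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = eigh(b)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    if vals[0] <= 0:
        raise ValidationError("degenerate configuration: all points coincide")
    pos = vals > vals[0] * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])[None, :]
    return coords, vals


def mds_spatial_axis(metadata: pd.DataFrame) -> MdsAxis:
    """First classical-MDS axis of the Euclidean coordinate distance matrix.

    Classical (metric) MDS double-centers the squared Euclidean distances of
    the raw (latitude, longitude) pairs and eigendecomposes; the first-axis
    scores are z-scored and the variance fraction is computed over positive
    eigenvalues.  The axis sign is fixed so scores correlate non-negatively
    with latitude (eigenvectors are sign-ambiguous).
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if len(meta) < 3:
        raise ValidationError("MDS needs at least 3 samples")
    coords = meta[["latitude", "longitude"]].to_numpy(dtype=float)
    embed, vals = classical_mds(squareform(pdist(coords)))
    pos = vals > vals[0] * 1e-12
    axis1 = embed[:, 0]
    orient = coords[:, 0] if np.ptp(coords[:, 0]) > 0 else coords[:, 1]
    if np.ptp(orient) > 0 and np.corrcoef(axis1, orient)[0, 1] < 0:
        axis1 = -axis1
    sd = axis1.std()
    if sd == 0:
        raise ValidationError("degenerate first axis")
    scores = (axis1 - axis1.mean()) / sd
    return MdsAxis(
        scores=pd.Series(scores, index=meta.index, name="mds_axis1"),
        variance_fraction=float(vals[0] / vals[pos].sum()),
        eigenvalues=vals,
    )
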