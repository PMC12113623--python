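"""Synthetic ASV tables with planted co-occurrence structure and ground truth.

The generator emulates the data the inference stages assume: compositional
read counts over three habitats with a signed, modular correlation structure
among a subset of taxa, habitat-dependent richness, and a spatial similarity
gradient along a 1-D transect.

Model
-----
Latent variables follow a Gaussian copula built from a per-module factor
model: for ASV *i* in module *m*,

    z_i(s) = s_i * ( sqrt(r_b) G(s) + sqrt(r_w - r_b) g_m(s) + sqrt(1 - r_w) e_i(s) )

with independent standard-normal factors, so every within-module latent pair
has Pearson correlation exactly ``s_i s_j r_w`` and cross-module pairs
``s_i s_j r_b``.  Sign flips ``s_i`` plant negative edges.  Because the
pipeline's statistic is Spearman's rho, the user-facing ``within_module_rho``
and ``between_module_rho`` are *Spearman* targets, converted to latent
Pearson correlations via the bivariate-normal identity r = 2 sin(pi rho / 6);
any monotone marginal then preserves the planted rank correlations.

Latents map to expected abundances through log-normal marginals; background
(non-module) taxa additionally carry an exponential spatial kernel (each has
a preferred transect position, so community similarity decays with distance)
and a per-habitat occupancy mask (so expected richness differs between
habitats).  Module taxa are treated as cosmopolitan: masking or shared
spatial factors would attenuate or distort the planted rank correlations the
truth set guarantees.  Reads are drawn multinomially at a log-normal
per-sample depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    GUILDS,
    HABITATS,
    AsvTable,
    CooccurrenceNetwork,
    ValidationError,
)

__all__ = [
    "SyntheticSpec",
    "TruthSet",
    "SyntheticData",
    "generate",
    "truth_recovery_report",
    "RecoveryReport",
]

#: degrees of latitude per km on the sphere used by the haversine distance
_KM_PER_DEG_LAT = 111.19492664455873  # pi/180 * 6371.0088


def spearman_to_pearson(rho: float) -> float:
    """Latent bivariate-normal Pearson r giving Spearman correlation ``rho``."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic community.

    Defaults mirror the study design: 33/42/17 sites across alpine meadow,
    desert steppe and alpine shrubland (scalable by ``sample_scale``), a
    sequencing depth of ~20k reads/sample, saprotroph-dominated guilds
    (70.91 / 19.33 / 9.80 %), and a ~1700 km transect.
    """

    n_samples_per_habitat: Tuple[int, int, int] = (33, 42, 17)
    sample_scale: float = 1.0
    n_asvs: int = 500
    n_modules: int = 4
    #: ASVs per planted module; None partitions *all* ASVs evenly into modules.
    module_size: Optional[int] = 25
    within_module_rho: float = 0.7
    between_module_rho: float = 0.0
    frac_negative_edges: float = 0.2
    sequencing_depth: float = 20000.0
    depth_dispersion: float = 0.3  # coefficient of variation of depth
    #: per-habitat multiplier on background-ASV occupancy probability
    richness_effect: Tuple[float, float, float] = (1.0, 0.95, 0.75)
    base_occupancy: float = 0.9
    spatial_decay_rate: float = 0.002  # per km, background-ASV kernel
    transect_length_km: float = 1700.0
    origin_latitude: float = 28.31
    origin_longitude: float = 85.0
    abundance_mu_sd: float = 1.0  # spread of ASV base log-abundances
    abundance_sigma: float = 1.5  # per-sample log-abundance noise scale
    guild_proportions: Tuple[float, float, float, float] = (
        0.7091,
        0.1933,
        0.0980,
        0.0,
    )  # saprotroph, symbiotroph, pathotroph, unknown (normalized)
    phylum_proportions: Tuple[Tuple[str, float], ...] = (
        ("Ascomycota", 0.62),
        ("Basidiomycota", 0.26),
        ("Mortierellomycota", 0.06),
        ("Glomeromycota", 0.04),
        ("Chytridiomycota", 0.02),
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("within_module_rho", "between_module_rho"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (-1, 1), got {v}")
        if self.within_module_rho < 0:
            raise ValidationError(
                "within_module_rho must be >= 0; plant negative edges via "
                "frac_negative_edges"
            )
        if not 0.0 <= self.frac_negative_edges <= 0.5:
            raise ValidationError("frac_negative_edges must lie in [0, 0.5]")
        if self.between_module_rho > self.within_module_rho:
            raise ValidationError(
                "correlation blocks are not positive definite: "
                "between_module_rho exceeds within_module_rho; choose a "
                "smaller between_module_rho or larger within_module_rho"
            )
        if spearman_to_pearson(self.within_module_rho) >= 1.0:
            raise ValidationError(
                "correlation block is not positive definite; choose a smaller "
                "within_module_rho"
            )
        if self.n_modules > self.n_asvs:
            raise ValidationError("n_modules cannot exceed n_asvs")
        if self.module_size is not None and self.module_size * self.n_modules > self.n_asvs:
            raise ValidationError("module_size * n_modules exceeds n_asvs")
        if self.sequencing_depth <= 0:
            raise ValidationError("sequencing_depth must be > 0")
        if any(n < 0 for n in self.n_samples_per_habitat):
            raise ValidationError("sample counts must be >= 0")

    def habitat_counts(self) -> List[int]:
        return [int(round(n * self.sample_scale)) for n in self.n_samples_per_habitat]


@dataclass
class TruthSet:
    """Planted ground truth: signed edges, module map, habitat effects drawn."""

    edges: pd.DataFrame  # columns node_u, node_v, sign (+1/-1)
    modules: pd.Series  # ASV id -> module id (-1 = background)
    habitat_effects: Dict[str, Dict[str, float]]

    def edge_set(self) -> FrozenSet[FrozenSet[str]]:
        return frozenset(
            frozenset((u, v))
            for u, v in zip(self.edges["node_u"], self.edges["node_v"])
        )

    def edge_signs(self) -> Dict[FrozenSet[str], int]:
        return {
            frozenset((u, v)): int(s)
            for u, v, s in zip(
                self.edges["node_u"], self.edges["node_v"], self.edges["sign"]
            )
        }


@dataclass
class SyntheticData:
    table: AsvTable
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: TruthSet

    def __iter__(self):
        return iter((self.table, self.metadata, self.taxonomy, self.truth))


def _flip_fraction(frac_negative_edges: float) -> float:
    """Node-flip probability f with 2 f (1-f) = frac_negative_edges."""
    return 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * frac_negative_edges))


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw a synthetic (table, metadata, taxonomy, truth) quadruple.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts_h = spec.habitat_counts()
    n_samples = sum(counts_h)
    if n_samples < 2:
        raise ValidationError("need at least 2 samples in total")
    n = spec.n_asvs

    # --- sample layout: contiguous habitat segments along the transect ----
    habitats = np.repeat(list(HABITATS), counts_h)
    bounds = np.concatenate([[0.0], np.cumsum(counts_h) / n_samples]) * spec.transect_length_km
    positions = np.empty(n_samples)
    start = 0
    for k, c in enumerate(counts_h):
        positions[start:start + c] = np.sort(
            rng.uniform(bounds[k], bounds[k + 1], size=c)
        )
        start += c
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    # --- module structure and sign flips -----------------------------------
    module_size = (
        spec.module_size if spec.module_size is not None else n // spec.n_modules
    )
    modules = np.full(n, -1, dtype=int)
    for m in range(spec.n_modules):
        modules[m * module_size:(m + 1) * module_size] = m
    asv_ids = [f"ASV_{i + 1:05d}" for i in range(n)]

    f_flip = _flip_fraction(spec.frac_negative_edges)
    signs = np.where(rng.random(n) < f_flip, -1, 1)
    signs[modules < 0] = 1

    r_w = spearman_to_pearson(spec.within_module_rho)
    r_b = spearman_to_pearson(spec.between_module_rho)

    # --- latent Gaussian copula --------------------------------------------
    G = rng.standard_normal(n_samples)  # global factor (between-module)
    g = rng.standard_normal((n_samples, spec.n_modules))  # module factors
    e = rng.standard_normal((n_samples, n))  # idiosyncratic noise
    z = np.empty((n_samples, n))
    in_mod = modules >= 0
    if in_mod.any():
        lam_b = math.sqrt(max(r_b, 0.0))
        lam_m = math.sqrt(max(r_w - r_b, 0.0))
        lam_e = math.sqrt(max(1.0 - r_w, 0.0))
        z[:, in_mod] = (
            lam_b * G[:, None]
            + lam_m * g[:, modules[in_mod]]
            + lam_e * e[:, in_mod]
        ) * signs[in_mod][None, :]
    z[:, ~in_mod] = e[:, ~in_mod]

    # --- expected intensities ----------------------------------------------
    mu = rng.normal(0.0, spec.abundance_mu_sd, size=n)
    log_w = mu[None, :] + spec.abundance_sigma * z

    # spatial turnover: background taxa prefer a transect position
    centers = rng.uniform(0.0, spec.transect_length_km, size=n)
    kernel = np.ones((n_samples, n))
    bg = ~in_mod
    if bg.any() and spec.spatial_decay_rate > 0:
        d = np.abs(positions[:, None] - centers[bg][None, :])
        kernel[:, bg] = np.exp(-spec.spatial_decay_rate * d)

    # habitat occupancy of background taxa drives richness differences
    occ = np.ones((len(HABITATS), n))
    probs = np.clip(
        spec.base_occupancy * np.asarray(spec.richness_effect), 0.0, 1.0
    )
    occ_draw = rng.random((len(HABITATS), n)) < probs[:, None]
    occ[:, bg] = occ_draw[:, bg]
    hab_index = np.searchsorted(np.cumsum(counts_h), np.arange(n_samples), side="right")
    w = np.exp(log_w) * kernel * occ[hab_index, :]

    # --- sequencing depths and multinomial counts ---------------------------
    cv = max(spec.depth_dispersion, 1e-9)
    sigma2 = math.log1p(cv * cv)
    depth_mu = math.log(spec.sequencing_depth) - sigma2 / 2.0
    depths = np.maximum(
        rng.lognormal(depth_mu, math.sqrt(sigma2), size=n_samples), 100
    ).astype(np.int64)
    row_tot = w.sum(axis=1, keepdims=True)
    if (row_tot <= 0).any():
        raise ValidationError(
            "a sample has zero expected abundance; raise base_occupancy or "
            "richness_effect"
        )
    p = w / row_tot
    counts = np.vstack([rng.multinomial(depths[s], p[s]) for s in range(n_samples)])
    table = AsvTable(pd.DataFrame(counts, index=sample_ids, columns=asv_ids))

    # --- metadata: coordinates + habitat-correlated environment -------------
    mult = dict(zip(HABITATS, spec.richness_effect))
    mat_coef, ndvi_coef = 4.0, 0.5
    habitat_effects = {
        "richness_multiplier": dict(mult),
        "MAT": {h: -2.0 + mat_coef * mult[h] for h in HABITATS},
        "NDVI": {h: 0.1 + ndvi_coef * mult[h] for h in HABITATS},
    }
    elev_mean = {"alpine_meadow": 4500.0, "desert_steppe": 4400.0, "alpine_shrubland": 4000.0}
    map_mean = {"alpine_meadow": 450.0, "desert_steppe": 250.0, "alpine_shrubland": 550.0}
    hvec = habitats
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "habitat": hvec,
            "latitude": spec.origin_latitude + positions / _KM_PER_DEG_LAT,
            "longitude": np.full(n_samples, spec.origin_longitude),
            "elevation": [elev_mean[h] for h in hvec] + rng.normal(0, 150, n_samples),
            "MAT": [habitat_effects["MAT"][h] for h in hvec] + rng.normal(0, 0.5, n_samples),
            "MAP": [map_mean[h] for h in hvec] + rng.normal(0, 40, n_samples),
            "NDVI": np.clip(
                [habitat_effects["NDVI"][h] for h in hvec] + rng.normal(0, 0.05, n_samples),
                0.0,
                1.0,
            ),
            "pH": rng.normal(7.5, 0.5, n_samples),
            "TN": np.abs(rng.normal(2.0, 0.4, n_samples)),
            "TC": np.abs(rng.normal(20.0, 5.0, n_samples)),
            "NH4": np.abs(rng.normal(5.0, 1.5, n_samples)),
            "NO3": np.abs(rng.normal(8.0, 3.0, n_samples)),
            "AP": np.abs(rng.normal(6.0, 2.0, n_samples)),
        }
    )

    # --- taxonomy / guilds ---------------------------------------------------
    gp = np.asarray(spec.guild_proportions, dtype=float)
    gp = gp / gp.sum()
    phyla, pp = zip(*spec.phylum_proportions)
    pp = np.asarray(pp, dtype=float)
    pp = pp / pp.sum()
    taxonomy = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "phylum": rng.choice(phyla, size=n, p=pp),
            "guild": rng.choice(GUILDS, size=n, p=gp),
        }
    )

    # --- planted truth -------------------------------------------------------
    truth_rows = []
    if r_w > abs(r_b) and spec.within_module_rho > 0:
        for m in range(spec.n_modules):
            idx = np.flatnonzero(modules == m)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    truth_rows.append(
                        (asv_ids[i], asv_ids[j], int(signs[i] * signs[j]))
                    )
    truth = TruthSet(
        edges=pd.DataFrame(truth_rows, columns=["node_u", "node_v", "sign"]),
        modules=pd.Series(modules, index=asv_ids, name="module"),
        habitat_effects=habitat_effects,
    )
    return SyntheticData(table=table, metadata=meta, taxonomy=taxonomy, truth=truth)


# ---------------------------------------------------------------------------
# Truth recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    precision: float  # NaN when the inferred edge set is empty
    recall: float
    sign_accuracy: float  # NaN when there are no true positives
    n_true: int
    n_inferred: int
    n_true_positive: int


def truth_recovery_report(
    truth: TruthSet, inferred: CooccurrenceNetwork
) -> RecoveryReport:
    """Edge-set precision/recall of an inferred network against planted truth,
    plus sign accuracy on the true positives."""
    universe = set(truth.modules.index)
    if inferred.n_nodes and not (set(inferred.graph.nodes) & universe):
        raise ValidationError("inferred network shares no ASVs with the truth set")
    true_edges = truth.edge_set()
    true_signs = truth.edge_signs()
    inf_edges = inferred.edge_set()
    tp = true_edges & inf_edges
    precision = len(tp) / len(inf_edges) if inf_edges else float("nan")
    recall = len(tp) / len(true_edges) if true_edges else float("nan")
    if tp:
        correct = 0
        for edge in tp:
            u, v = sorted(edge)
            inferred_sign = 1 if inferred.graph[u][v]["rho"] >= 0 else -1
            correct += inferred_sign == true_signs[edge]
        sign_accuracy = correct / len(tp)
    else:
        sign_accuracy = float("nan")
    return RecoveryReport(
        precision=precision,
        recall=recall,
        sign_accuracy=sign_accuracy,
        n_true=len(true_edges),
        n_inferred=len(inf_edges),
        n_true_positive=len(tp),
    )
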