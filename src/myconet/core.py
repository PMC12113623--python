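"""Core domain types for fungal community co-occurrence analysis.

The pipeline's shared currency is the ASV table (samples x amplicon sequence
variants, integer read counts) together with per-sample metadata, a
taxonomy/guild annotation, and a signed, weighted co-occurrence network over
ASVs.  Everything downstream (edge inference, topology, keystone roles,
cohesion, spatial statistics) consumes these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "GUILDS",
    "METADATA_REQUIRED_COLUMNS",
    "METADATA_ENV_COLUMNS",
    "ValidationError",
    "AsvTable",
    "validate_sample_metadata",
    "validate_taxonomy",
    "CooccurrenceNetwork",
    "ModulePartition",
    "richness",
    "VennPartition",
    "venn_partition",
]

#: Habitat labels of the three surveyed ecosystem types.
HABITATS: Tuple[str, ...] = ("alpine_meadow", "desert_steppe", "alpine_shrubland")

#: Closed set of fungal trophic guilds.
GUILDS: Tuple[str, ...] = ("saprotroph", "symbiotroph", "pathotroph", "unknown")

METADATA_REQUIRED_COLUMNS: Tuple[str, ...] = (
    "sample_id",
    "habitat",
    "latitude",
    "longitude",
)

#: Environmental variables; individual cells may be missing, consumers that
#: need one fail fast naming it.
METADATA_ENV_COLUMNS: Tuple[str, ...] = (
    "elevation",
    "MAT",
    "MAP",
    "NDVI",
    "pH",
    "TN",
    "TC",
    "NH4",
    "NO3",
    "AP",
)


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


# ---------------------------------------------------------------------------
# ASV table
# ---------------------------------------------------------------------------


class AsvTable:
    """A samples x ASVs table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and ASV ids as columns.
        Values must be non-negative integers; every sample must contain at
        least one read; ids on both axes must be unique.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValidationError("ASV table must have at least one sample and one ASV")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate ASV id: {dup!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("ASV table contains non-numeric values")
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValidationError(
                f"missing count at sample {counts.index[r]!r}, ASV {counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[r]!r}, ASV {counts.columns[c]!r}"
            )
        if np.issubdtype(values.dtype, np.floating):
            frac = np.mod(values, 1.0)
            if (frac != 0).any():
                r, c = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {counts.index[r]!r}, "
                    f"ASV {counts.columns[c]!r}"
                )
        row_sums = values.sum(axis=1)
        if (row_sums <= 0).any():
            empty = counts.index[int(np.argmax(row_sums <= 0))]
            raise ValidationError(f"sample {empty!r} has zero total reads")
        self.counts = counts.astype(np.int64)

    # -- identifiers --------------------------------------------------------

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    # -- derived quantities --------------------------------------------------

    def relative_abundance(self, mode: str = "sample") -> pd.DataFrame:
        """Relative abundances of the counts.

        ``mode="sample"`` normalizes each sample to sum to 1 (used for
        Bray-Curtis and cohesion weighting); ``mode="total"`` divides every
        count by the table's grand total (used by the low-abundance filter,
        whose threshold is a fraction of all fungal sequences).
        """
        if mode == "sample":
            return self.counts.div(self.counts.sum(axis=1), axis=0)
        if mode == "total":
            return self.counts / float(self.counts.to_numpy().sum())
        raise ValidationError(f"unknown relative-abundance mode {mode!r}")

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        """A table restricted to the given ASVs (sample set unchanged)."""
        keep = [a for a in self.asv_ids if a in set(asv_ids)]
        if not keep:
            raise ValidationError("ASV subset is empty")
        return AsvTable(self.counts[keep])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AsvTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AsvTable({self.n_samples} samples x {self.n_asvs} ASVs)"


def richness(table: AsvTable) -> pd.Series:
    """Per-sample ASV richness: the number of ASVs with count > 0."""
    return (table.counts > 0).sum(axis=1).rename("richness")


# ---------------------------------------------------------------------------
# Sample metadata and taxonomy
# ---------------------------------------------------------------------------


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and return it indexed by sample_id.

    Habitat and coordinates are mandatory and checked; environmental
    variables may contain missing cells (consumers fail fast per variable).
    """
    missing = [c for c in METADATA_REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    if meta["habitat"].isna().any():
        bad = meta.loc[meta["habitat"].isna(), "sample_id"].iloc[0]
        raise ValidationError(f"sample {bad!r} has no habitat label")
    unknown = set(meta["habitat"]) - set(HABITATS)
    if unknown:
        raise ValidationError(f"unknown habitat label(s): {sorted(unknown)}")
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if vals.isna().any():
            bad = meta.loc[vals.isna(), "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r} has missing/non-numeric {col}")
        if ((vals < lo) | (vals > hi)).any():
            bad = meta.loc[(vals < lo) | (vals > hi), "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r} has {col} outside [{lo}, {hi}]")
        meta[col] = vals
    return meta.set_index("sample_id", drop=False)


def validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    """Validate an ASV -> (phylum, guild) map; guilds from the closed set."""
    for col in ("asv_id", "phylum", "guild"):
        if col not in tax.columns:
            raise ValidationError(f"taxonomy table missing column {col!r}")
    if tax["asv_id"].duplicated().any():
        dup = tax.loc[tax["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise ValidationError(f"duplicate asv_id in taxonomy: {dup!r}")
    bad = set(tax["guild"].fillna("unknown")) - set(GUILDS)
    if bad:
        raise ValidationError(f"guild label(s) outside closed set: {sorted(bad)}")
    tax = tax.copy()
    tax["guild"] = tax["guild"].fillna("unknown")
    return tax.set_index("asv_id", drop=False)


# ---------------------------------------------------------------------------
# Co-occurrence network
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceNetwork:
    """Signed, weighted, undirected co-occurrence network over ASVs.

    Edge attributes: ``rho`` (signed Spearman correlation, the edge weight),
    ``q`` (BH-adjusted p-value; NaN for networks without a significance
    stage, e.g. planted truth), and ``sign`` ("+" or "-").
    """

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, float, float]],
        nodes: Optional[Iterable[str]] = None,
    ) -> "CooccurrenceNetwork":
        """Build a network from ``(u, v, rho, q)`` records.

        Nodes and edges are inserted in sorted order so that serialized
        output is deterministic.
        """
        g = nx.Graph()
        records = []
        for u, v, rho, q in edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            a, b = sorted((str(u), str(v)))
            records.append((a, b, float(rho), float(q)))
        records.sort(key=lambda r: (r[0], r[1]))
        node_set = {n for r in records for n in r[:2]}
        if nodes is not None:
            node_set |= {str(n) for n in nodes}
        g.add_nodes_from(sorted(node_set))
        for a, b, rho, q in records:
            g.add_edge(a, b, rho=rho, q=q, sign="+" if rho >= 0 else "-")
        return cls(g)

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> FrozenSet[FrozenSet[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    def edges_dataframe(self) -> pd.DataFrame:
        """Flat edge list (node_u, node_v, rho, sign, q), sorted."""
        rows = [
            {
                "node_u": min(u, v),
                "node_v": max(u, v),
                "rho": d["rho"],
                "sign": d["sign"],
                "q": d.get("q", np.nan),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["node_u", "node_v", "rho", "sign", "q"])
        return df.sort_values(["node_u", "node_v"]).reset_index(drop=True)

    def induced_subgraph(self, nodes: Iterable[str]) -> "CooccurrenceNetwork":
        keep = sorted(set(nodes) & set(self.graph.nodes))
        sub = nx.Graph()
        sub.add_nodes_from(keep)
        sub.add_edges_from(
            (u, v, d) for u, v, d in self.graph.edges(data=True)
            if u in sub and v in sub
        )
        return CooccurrenceNetwork(sub)

    def drop_negative_edges(self) -> "CooccurrenceNetwork":
        """Copy of the network with all negative edges removed."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.graph.nodes))
        g.add_edges_from(
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d["rho"] >= 0
        )
        return CooccurrenceNetwork(g)


@dataclass
class ModulePartition:
    """Assignment of every network node to exactly one module."""

    membership: Dict[str, int]
    modularity: float

    def modules(self) -> Dict[int, List[str]]:
        out: Dict[int, List[str]] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, []).append(node)
        return {m: sorted(ns) for m, ns in out.items()}

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


# ---------------------------------------------------------------------------
# Venn partition of detected ASVs across habitats
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Partition of detected ASVs over the 2^3 - 1 habitat membership regions."""

    detected: Dict[str, int]
    unique: Dict[str, int]
    shared_all: int
    regions: Dict[Tuple[str, ...], int] = field(default_factory=dict)

    @property
    def total_detected(self) -> int:
        return sum(self.regions.values())


def venn_partition(table: AsvTable, metadata: pd.DataFrame) -> VennPartition:
    """Count detected, habitat-unique, and universally shared ASVs.

    An ASV is *detected* in a habitat when its summed count over that
    habitat's samples is > 0.  The seven non-empty membership regions
    partition the detected-ASV set.
    """
    meta = validate_sample_metadata(
        metadata if "sample_id" in metadata.columns else metadata.reset_index()
    )
    missing = set(table.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValidationError(
            f"samples without metadata: {sorted(missing)[:3]}"
        )
    habitats_present = set(meta.loc[table.sample_ids, "habitat"])
    empty = [h for h in HABITATS if h not in habitats_present]
    if empty:
        raise ValidationError(f"habitat(s) with zero samples: {empty}")
    detected_sets: Dict[str, frozenset] = {}
    for h in HABITATS:
        samples = [s for s in table.sample_ids if meta.at[s, "habitat"] == h]
        sums = table.counts.loc[samples].sum(axis=0)
        detected_sets[h] = frozenset(sums.index[sums > 0])
    regions: Dict[Tuple[str, ...], int] = {}
    all_detected = frozenset().union(*detected_sets.values())
    for asv in all_detected:
        member = tuple(h for h in HABITATS if asv in detected_sets[h])
        regions[member] = regions.get(member, 0) + 1
    detected = {h: len(detected_sets[h]) for h in HABITATS}
    unique = {h: regions.get((h,), 0) for h in HABITATS}
    return VennPartition(
        detected=detected,
        unique=unique,
        shared_all=regions.get(HABITATS, 0),
        regions=regions,
    )
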