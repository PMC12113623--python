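"""Zi-Pi keystone analysis: within-module degree z-score, participation
coefficient, and the four-way node-role classification.

Roles (thresholds Zi = 2.5, Pi = 0.62, strict inequalities):

* network hub — Zi > 2.5 and Pi > 0.62
* module hub  — Zi > 2.5 and Pi <= 0.62
* connector   — Zi <= 2.5 and Pi > 0.62
* peripheral  — otherwise (boundary values fall here)

Degrees are unweighted, the standard convention for this framework.
"""

from __future__ import annotations

import warnings
from typing import Dict

import numpy as np
import pandas as pd

from .core import CooccurrenceNetwork, ModulePartition, ValidationError

__all__ = [
    "zi_pi",
    "classify_roles",
    "keystone_census",
    "ROLES",
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
]

ROLES = ("network_hub", "module_hub", "connector", "peripheral")
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def zi_pi(net: CooccurrenceNetwork, partition: ModulePartition) -> pd.DataFrame:
    """Per-node within-module degree z-score (Zi) and participation
    coefficient (Pi).

    Zi standardizes a node's within-module degree against the mean and
    (population) standard deviation of within-module degrees in its module;
    a module whose within-degrees are constant assigns Zi = 0.  Pi is
    1 - sum_s (k_is / k_i)^2 over modules s; isolated nodes get Pi = 0 with
    a warning.
    """
    g = net.graph
    missing = set(g.nodes) - set(partition.membership)
    if missing:
        raise ValidationError(
            f"partition does not cover node(s): {sorted(missing)[:3]}"
        )
    member = partition.membership
    nodes = sorted(g.nodes)

    within: Dict[str, int] = {}
    per_module: Dict[str, Dict[int, int]] = {}
    for node in nodes:
        counts: Dict[int, int] = {}
        for nbr in g.neighbors(node):
            counts[member[nbr]] = counts.get(member[nbr], 0) + 1
        per_module[node] = counts
        within[node] = counts.get(member[node], 0)
        # conservation check: module-wise links sum to total degree
        if sum(counts.values()) != g.degree(node):  # pragma: no cover
            raise AssertionError(f"degree bookkeeping broken at node {node!r}")

    # module-wise mean/sd of within-degree
    mod_stats: Dict[int, tuple] = {}
    for mod in set(member[n] for n in nodes):
        vals = np.array([within[n] for n in nodes if member[n] == mod], dtype=float)
        mod_stats[mod] = (vals.mean(), vals.std())

    records = []
    isolated = 0
    for node in nodes:
        k = g.degree(node)
        mean, sd = mod_stats[member[node]]
        zi = (within[node] - mean) / sd if sd > 0 else 0.0
        if k == 0:
            isolated += 1
            pi = 0.0
        else:
            pi = 1.0 - sum((ks / k) ** 2 for ks in per_module[node].values())
        records.append(
            {"node": node, "module": member[node], "Zi": zi, "Pi": pi}
        )
    if isolated:
        warnings.warn(
            f"{isolated} isolated node(s): Pi set to 0 by convention",
            stacklevel=2,
        )
    return pd.DataFrame(records, columns=["node", "module", "Zi", "Pi"])


def classify_roles(
    zipi: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Attach the node role implied by (Zi, Pi); classes are mutually
    exclusive and exhaustive, with boundary equality falling to peripheral."""
    if zi_threshold <= 0 or pi_threshold <= 0:
        raise ValidationError("role thresholds must be positive")
    out = zipi.copy()
    zi_hi = out["Zi"] > zi_threshold
    pi_hi = out["Pi"] > pi_threshold
    role = np.where(
        zi_hi & pi_hi,
        "network_hub",
        np.where(zi_hi, "module_hub", np.where(pi_hi, "connector", "peripheral")),
    )
    out["role"] = role
    return out


def keystone_census(
    roles: pd.DataFrame, taxonomy: pd.DataFrame | None = None
) -> Dict[str, pd.DataFrame]:
    """Contingency counts of roles by phylum and guild, plus overall guild
    fractions.  Nodes missing from the taxonomy are labelled 'unknown'."""
    df = roles.copy()
    if taxonomy is not None:
        tax = (
            taxonomy.set_index("asv_id")
            if "asv_id" in taxonomy.columns and taxonomy.index.name != "asv_id"
            else taxonomy
        )
        df["phylum"] = df["node"].map(tax["phylum"]).fillna("unknown")
        df["guild"] = df["node"].map(tax["guild"]).fillna("unknown")
    else:
        df["phylum"] = "unknown"
        df["guild"] = "unknown"
    by_role = (
        df.groupby(["role", "phylum", "guild"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    guild_fracs = (
        df.groupby("guild", sort=True).size().rename("count").reset_index()
    )
    guild_fracs["fraction"] = guild_fracs["count"] / len(df)
    return {"census": by_role, "guild_fractions": guild_fracs, "nodes": df}
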