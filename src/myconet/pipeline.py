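"""End-to-end orchestration: config handling, per-stage seeds, artifacts,
and a machine-readable run manifest.

A single YAML config names either input files or a synthetic spec, an output
directory, a global seed, and per-stage parameters (all thresholds default
to the pipeline's standard values: 0.01% abundance, |rho| >= 0.6, alpha
0.05, 1000 resamples, Zi/Pi 2.5/0.62).  Per-stage seeds are derived from the
global seed by hashing the stage name, so stages can be rerun in isolation.
The manifest contains no timestamps: identical config + seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io
from .cohesion import cohesion, connectedness, stability_vs_richness
from .core import (
    HABITATS,
    ValidationError,
    richness,
    venn_partition,
)
from .inference import build_network, edge_candidates, filter_low_abundance
from .keystone import classify_roles, keystone_census, zi_pi
from .simulate import SyntheticSpec, generate, truth_recovery_report
from .spatial import (
    bray_curtis,
    distance_decay,
    geo_distance,
    mantel,
    mds_spatial_axis,
    partial_mantel,
)
from .topology import (
    detect_modules,
    global_metrics,
    habitat_summary,
    subnetwork_metrics_all,
)

__all__ = ["DEFAULT_STAGE_PARAMS", "ConfigError", "load_config", "stage_seed", "run_all"]

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("MAT", "MAP")
SOIL_VARS = ("pH", "TN", "TC", "NH4", "NO3", "AP")

DEFAULT_STAGE_PARAMS: Dict[str, Dict[str, Any]] = {
    "filter": {"threshold": 1e-4},
    "network": {
        "rho_threshold": 0.6,
        "alpha": 0.05,
        "n_resamples": 1000,
        "kld_mode": "max",
        "pseudocount": 1e-6,
        "abundance_mode": "sample",
    },
    "topology": {"method": "greedy", "subnetwork_modules": True},
    "keystone": {"zi_threshold": 2.5, "pi_threshold": 0.62},
    "stability": {"mode": "network", "variant": "stability_absdiff"},
    "spatial": {
        "distance_transform": "log10",
        "mantel_permutations": 999,
        "mantel_method": "spearman",
        "bray_curtis_on": "relabund",
    },
}


class ConfigError(ValidationError):
    """Raised when a run configuration is invalid or incomplete."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _resolve_config(config: Dict[str, Any]) -> Dict[str, Any]:
    cfg = copy.deepcopy(config)
    for field in ("seed", "output_dir"):
        if field not in cfg:
            raise ConfigError(f"config missing required field: {field!r}")
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ConfigError("config must name exactly one of 'synthetic' or 'inputs'")
    if "inputs" in cfg:
        for field in ("asv_table", "metadata"):
            if field not in cfg["inputs"]:
                raise ConfigError(f"config missing required field: inputs.{field!r}")
    for stage, params in DEFAULT_STAGE_PARAMS.items():
        merged = dict(params)
        user = cfg.get(stage, {}) or {}
        unknown = set(user) - set(params)
        if unknown:
            raise ConfigError(f"unknown {stage} option(s): {sorted(unknown)}")
        merged.update(user)
        cfg[stage] = merged
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _yaml_safe(obj: Any) -> Any:
    """Recursively convert tuples to lists and numpy scalars to Python ones
    so the manifest dumps with the safe YAML dumper."""
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _env_distance(meta: pd.DataFrame, variables) -> pd.DataFrame:
    """Euclidean distance over z-scored environmental variables."""
    cols = []
    for var in variables:
        if var not in meta.columns:
            raise ValidationError(f"metadata lacks environmental variable {var!r}")
        if meta[var].isna().any():
            raise ValidationError(f"environmental variable {var!r} has missing values")
        cols.append(var)
    x = meta[cols].to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(z))
    ids = list(meta.index)
    return pd.DataFrame(d, index=ids, columns=ids)


def run_all(
    config: Union[str, Path, Dict[str, Any]],
    output_dir: Optional[Union[str, Path]] = None,
) -> Path:
    """Execute every stage and write all artifacts plus ``manifest.yaml``.

    Returns the output directory.  Any stage failure propagates with the
    stage name prefixed to the error message.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _resolve_config(config)
    out = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: Dict[str, Any] = {
        "config": cfg,
        "stage_seeds": {
            s: stage_seed(seed, s) for s in ("simulate", "network", "topology", "spatial")
        },
        "inputs": {},
        "outputs": [],
    }

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    try:
                        wrapped = type(exc)(f"[stage {name}] {exc}")
                    except Exception:
                        return False  # propagate the original unchanged
                    raise wrapped from exc
                return False

        return _Ctx()

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    # ------------------------------------------------------------ inputs --
    truth = None
    taxonomy = None
    with _stage("inputs"):
        if "synthetic" in cfg:
            spec = SyntheticSpec(**{**cfg["synthetic"], "seed": stage_seed(seed, "simulate")})
            data = generate(spec)
            table, metadata, taxonomy, truth = data
            _emit("asv_table.tsv", lambda p: io.write_asv_table(table, p))
            _emit("metadata.csv", lambda p: io.write_sample_metadata(metadata, p))
            _emit("taxonomy.tsv", lambda p: io.write_taxonomy(taxonomy, p))
            _emit("truth_edges.tsv", lambda p: io.write_tidy(truth.edges, p))
            _emit(
                "truth_modules.tsv",
                lambda p: io.write_tidy(
                    truth.modules.rename_axis("asv_id").reset_index(), p
                ),
            )
            metadata = io.validate_sample_metadata(metadata)
        else:
            inputs = cfg["inputs"]
            orientation = inputs.get("orientation", "samples_in_rows")
            table = io.read_asv_table(inputs["asv_table"], orientation)
            metadata = io.read_sample_metadata(inputs["metadata"])
            if inputs.get("taxonomy"):
                taxonomy = io.read_taxonomy(inputs["taxonomy"])
            for key in ("asv_table", "metadata", "taxonomy"):
                if inputs.get(key):
                    manifest["inputs"][key] = _sha256(Path(inputs[key]))

    # ------------------------------------------------- diversity summaries --
    with _stage("diversity"):
        rich = richness(table)
        _emit(
            "richness.tsv",
            lambda p: io.write_tidy(rich.rename_axis("sample_id").reset_index(), p),
        )
        habitats_present = set(metadata.loc[table.sample_ids, "habitat"])
        if set(HABITATS) <= habitats_present:
            venn = venn_partition(table, metadata)
            rows = [
                {
                    "region": "+".join(region),
                    "n_habitats": len(region),
                    "count": count,
                }
                for region, count in sorted(venn.regions.items())
            ]
            _emit("venn_partition.tsv", lambda p: io.write_tidy(pd.DataFrame(rows), p))
        else:
            logger.info("skipping Venn partition: not all habitats sampled")

    # ----------------------------------------------------------- network --
    with _stage("filter"):
        filtered = filter_low_abundance(table, cfg["filter"]["threshold"])
        _emit("filtered_table.tsv", lambda p: io.write_asv_table(filtered, p))

    with _stage("network"):
        np_cfg = cfg["network"]
        mats = edge_candidates(
            filtered,
            n_resamples=np_cfg["n_resamples"],
            seed=stage_seed(seed, "network"),
            pseudocount=np_cfg["pseudocount"],
            abundance_mode=np_cfg["abundance_mode"],
        )
        net = build_network(
            mats,
            rho_threshold=np_cfg["rho_threshold"],
            kld_mode=np_cfg["kld_mode"],
            alpha=np_cfg["alpha"],
        )
        _emit("network.graphml", lambda p: io.write_network(net, p, out / "network_edges.tsv"))
        manifest["outputs"].append("network_edges.tsv")
        if truth is not None:
            report = truth_recovery_report(truth, net)
            _emit(
                "truth_recovery.tsv",
                lambda p: io.write_tidy(pd.DataFrame([asdict(report)]), p),
            )

    # ---------------------------------------------------------- topology --
    with _stage("topology"):
        top_cfg = cfg["topology"]
        partition = None
        if net.n_edges > 0:
            partition = detect_modules(
                net, seed=stage_seed(seed, "topology"), method=top_cfg["method"]
            )
            modules_df = pd.DataFrame(
                sorted(partition.membership.items()), columns=["node", "module"]
            )
            _emit("modules.tsv", lambda p: io.write_tidy(modules_df, p))
        gm = global_metrics(net, partition)
        _emit(
            "global_metrics.tsv",
            lambda p: io.write_tidy(pd.DataFrame([gm.as_dict()]), p),
        )
        sub = subnetwork_metrics_all(
            net,
            table,
            detect_sub_modules=top_cfg["subnetwork_modules"],
            seed=stage_seed(seed, "topology"),
        )
        _emit("subnetwork_metrics.tsv", lambda p: io.write_tidy(sub, p))
        _emit(
            "subnetwork_habitat_means.tsv",
            lambda p: io.write_tidy(habitat_summary(sub, metadata), p),
        )

    # ---------------------------------------------------------- keystone --
    with _stage("keystone"):
        if partition is not None:
            roles = classify_roles(
                zi_pi(net, partition),
                zi_threshold=cfg["keystone"]["zi_threshold"],
                pi_threshold=cfg["keystone"]["pi_threshold"],
            )
            census = keystone_census(roles, taxonomy)
            _emit("node_roles.tsv", lambda p: io.write_tidy(census["nodes"], p))
            _emit("keystone_census.tsv", lambda p: io.write_tidy(census["census"], p))
            _emit(
                "guild_fractions.tsv",
                lambda p: io.write_tidy(census["guild_fractions"], p),
            )
        else:
            logger.warning("empty network: keystone stage skipped")

    # --------------------------------------------------------- stability --
    with _stage("stability"):
        st_cfg = cfg["stability"]
        if net.n_edges > 0:
            conn = connectedness(
                net,
                mode=st_cfg["mode"],
                rho=mats.rho if st_cfg["mode"] == "full-matrix" else None,
            )
            coh = cohesion(table, conn)
            _emit("cohesion.tsv", lambda p: io.write_tidy(coh, p))
            try:
                reg = stability_vs_richness(coh, rich, variant=st_cfg["variant"])
                _emit(
                    "stability_regression.tsv",
                    lambda p: io.write_tidy(
                        pd.DataFrame([{"variant": st_cfg["variant"], **asdict(reg)}]), p
                    ),
                )
            except ValidationError as exc:
                logger.warning("stability regression skipped: %s", exc)
        else:
            logger.warning("empty network: stability stage skipped")

    # ------------------------------------------------------------ spatial --
    with _stage("spatial"):
        sp_cfg = cfg["spatial"]
        bc = bray_curtis(table, on=sp_cfg["bray_curtis_on"])
        geo = geo_distance(metadata.loc[table.sample_ids])
        decay = distance_decay(bc, geo, sp_cfg["distance_transform"])
        _emit(
            "distance_decay.tsv",
            lambda p: io.write_tidy(pd.DataFrame([asdict(decay)]), p),
        )
        n_perm = sp_cfg["mantel_permutations"]
        method = sp_cfg["mantel_method"]
        sseed = stage_seed(seed, "spatial")
        meta_t = metadata.loc[table.sample_ids]
        climate = _env_distance(meta_t, CLIMATE_VARS)
        soil = _env_distance(meta_t, SOIL_VARS)
        tests = {
            "bray_curtis~geographic": mantel(bc, geo, n_perm, method, sseed),
            "bray_curtis~climate": mantel(bc, climate, n_perm, method, sseed + 1),
            "bray_curtis~soil": mantel(bc, soil, n_perm, method, sseed + 2),
            "bray_curtis~climate|soil": partial_mantel(
                bc, climate, soil, n_perm, method, sseed + 3
            ),
            "bray_curtis~soil|climate": partial_mantel(
                bc, soil, climate, n_perm, method, sseed + 4
            ),
        }
        mantel_df = pd.DataFrame(
            [{"comparison": k, **asdict(v)} for k, v in tests.items()]
        )
        _emit("mantel_results.tsv", lambda p: io.write_tidy(mantel_df, p))
        axis = mds_spatial_axis(meta_t)
        axis_df = axis.scores.rename_axis("sample_id").reset_index()
        axis_df["variance_fraction"] = axis.variance_fraction
        _emit("mds_axis.tsv", lambda p: io.write_tidy(axis_df, p))

    # ----------------------------------------------------------- manifest --
    with _stage("manifest"):
        manifest["outputs"] = sorted(set(manifest["outputs"]))
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(_yaml_safe(manifest), fh, sort_keys=True, default_flow_style=False)
    return out
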