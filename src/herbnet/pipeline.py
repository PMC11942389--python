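"""End-to-end orchestration: simulate -> deg -> network -> ci -> metabo
-> report.

Every stage reads and writes plain delimited text under a single output
directory, so stages can also be run standalone on pre-existing files.
All randomness flows from the config seeds; identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contribution import compute_ci, top_k_cumulative
from .deg import screen_degs
from .exceptions import ConfigError, InputError
from .metabolomics import MetaboliteScreen
from .network import build_ct_network, components_from_table, filter_components, intersect_targets
from .plsda import permutation_validate, q2_cross_validation
from .simulate import (
    CountSimSpec,
    MetaboSimSpec,
    NetworkSimSpec,
    gen_counts,
    gen_ct_network,
    gen_metabolites,
)

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger("herbnet.pipeline")

STAGES = ("simulate", "deg", "network", "ci", "metabo")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "simulate": {
        "counts": {
            "n_genes": 500,
            "n_tumor": 20,
            "n_normal": 20,
            "n_deg": 20,
            "planted_log2fc": 3.0,
            "dispersion": 0.1,
            "base_mean_range": [10.0, 1000.0],
        },
        "network": {
            "n_components_A": 18,
            "n_components_B": 18,
            "n_targets": 60,
            "core_component_degree": 15,
            "background_degree_mean": 3.0,
            "ob_dl_pass_fraction": 0.8,
        },
        "metabolites": {
            "n_metabolites": 200,
            "n_per_group": 10,
            "n_diff": 10,
            "planted_fc": 4.0,
            "cv_noise": 0.1,
        },
    },
    "deg": {
        "p_threshold": 0.05,
        "fc_threshold": 2.0,
        "normalize": "cpm",
        "pseudocount": 1.0,
    },
    "network": {"ob_min": 30.0, "dl_min": 0.18},
    "ci": {"mode": "balanced", "top_k": 10},
    "metabo": {
        "vip_threshold": 1.0,
        "p_threshold": 0.05,
        "fc_theta": 1.0,
        "fc_mode": "two-sided",
        "n_components": 2,
        "n_permutations": 100,
    },
}

# threshold keys that must be strictly positive
_POSITIVE_KEYS = {
    ("deg", "p_threshold"),
    ("deg", "fc_threshold"),
    ("network", "ob_min"),
    ("network", "dl_min"),
    ("ci", "top_k"),
    ("metabo", "vip_threshold"),
    ("metabo", "p_threshold"),
    ("metabo", "fc_theta"),
    ("metabo", "n_components"),
    ("metabo", "n_permutations"),
}


@dataclass
class PipelineConfig:
    """Validated, fully-merged pipeline configuration."""

    data: dict

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def __getitem__(self, key):
        return self.data[key]


def _merge(default: dict, override: dict, path: str, violations: list) -> dict:
    out = {}
    for key, dval in default.items():
        if isinstance(dval, dict):
            oval = override.get(key, {})
            if not isinstance(oval, dict):
                violations.append(f"{path}{key}: expected a mapping")
                oval = {}
            out[key] = _merge(dval, oval, f"{path}{key}.", violations)
        else:
            out[key] = override.get(key, dval)
    for key in override:
        if key not in default:
            violations.append(f"{path}{key}: unknown key")
    return out


def validate_config(source) -> PipelineConfig:
    """Load, merge with defaults, and validate a configuration.

    ``source`` may be a path to a YAML file or a dict. Raises
    :class:`~herbnet.exceptions.ConfigError` carrying *all* violations,
    not just the first.
    """
    if isinstance(source, (str, Path)):
        try:
            with open(source) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"malformed config file: {exc}"]) from exc
    elif isinstance(source, dict):
        raw = source
    elif source is None:
        raw = {}
    else:
        raise ConfigError([f"unsupported config source {type(source).__name__}"])
    if not isinstance(raw, dict):
        raise ConfigError(["top level of config must be a mapping"])

    violations: list = []
    merged = _merge(DEFAULT_CONFIG, raw, "", violations)

    for section, key in _POSITIVE_KEYS:
        val = merged[section][key]
        if not isinstance(val, (int, float)) or val <= 0:
            violations.append(f"{section}.{key}: must be a positive number, got {val!r}")
    for stage, flag in merged["stages"].items():
        if not isinstance(flag, bool):
            violations.append(f"stages.{stage}: must be true/false")
    if merged["ci"]["mode"] not in ("balanced", "literal"):
        violations.append(f"ci.mode: expected 'balanced' or 'literal', got {merged['ci']['mode']!r}")
    if merged["metabo"]["fc_mode"] not in ("two-sided", "greater"):
        violations.append(
            f"metabo.fc_mode: expected 'two-sided' or 'greater', got {merged['metabo']['fc_mode']!r}"
        )
    if violations:
        raise ConfigError(violations)
    return PipelineConfig(merged)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    parameters: dict
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "parameters": self.parameters,
                "counts": self.counts,
                "timings": self.timings,
            },
            indent=2,
            sort_keys=True,
        )


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def _read(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"required input {path} not found (run earlier stages first)")
    return pd.read_csv(path, sep="\t", **kw)


def run_pipeline(config: PipelineConfig | dict | None, out_dir) -> RunReport:
    """Run the enabled stages in order, writing tables under ``out_dir``.

    Stages whose toggle is off read their inputs from files already in
    ``out_dir`` (written by an earlier run or by hand)."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config.data
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed, parameters=cfg)
    seed = config.seed

    def timed(stage):
        t0 = time.perf_counter()

        def done(counts):
            report.counts[stage] = counts
            report.timings[stage] = round(time.perf_counter() - t0, 4)
            logger.info("[%s] done in %.2fs: %s", stage, report.timings[stage], counts)

        return done

    if cfg["stages"]["simulate"]:
        done = timed("simulate")
        sc = cfg["simulate"]["counts"]
        counts, groups, deg_truth = gen_counts(
            CountSimSpec(seed=seed, base_mean_range=tuple(sc["base_mean_range"]),
                         **{k: v for k, v in sc.items() if k != "base_mean_range"})
        )
        _write(counts, out / "counts.tsv")
        groups.to_frame().to_csv(out / "count_groups.tsv", sep="\t")

        sn = cfg["simulate"]["network"]
        components, edges, core_id = gen_ct_network(NetworkSimSpec(seed=seed + 1, **sn))
        _write(components, out / "components.tsv", index=False)
        _write(edges, out / "edges.tsv", index=False)

        sm = cfg["simulate"]["metabolites"]
        intens, mgroups, met_truth = gen_metabolites(MetaboSimSpec(seed=seed + 2, **sm))
        _write(intens, out / "metabolites.tsv")
        mgroups.to_frame().to_csv(out / "metabolite_groups.tsv", sep="\t")

        with open(out / "truth.json", "w") as fh:
            json.dump(
                {"deg_genes": deg_truth, "core_component": core_id,
                 "diff_metabolites": met_truth},
                fh, indent=2, sort_keys=True,
            )
        done({
            "genes": len(counts), "samples": counts.shape[1],
            "components": len(components), "edges": len(edges),
            "metabolites": len(intens),
        })

    if cfg["stages"]["deg"]:
        done = timed("deg")
        counts = _read(out / "counts.tsv", index_col=0)
        groups = _read(out / "count_groups.tsv", index_col=0)["group"]
        table = screen_degs(counts, groups, **cfg["deg"])
        _write(table, out / "deg_table.tsv")
        done({
            "input": len(table),
            "passing": int(table["is_deg"].sum()),
            "dropped": int((~table["is_deg"]).sum()),
        })

    if cfg["stages"]["network"]:
        done = timed("network")
        comp_table = _read(out / "components.tsv")
        edges = _read(out / "edges.tsv")
        records = components_from_table(comp_table)
        kept = filter_components(records, cfg["network"]["ob_min"], cfg["network"]["dl_min"])
        kept_ids = {r.component_id for r in kept}
        kept_edges = edges[edges["component_id"].isin(kept_ids)]
        net = build_ct_network(kept, kept_edges.itertuples(index=False))
        _write(net.node_table(), out / "network_nodes.tsv", index=False)
        _write(net.edge_table(), out / "network_edges.tsv", index=False)

        overlap: list = []
        deg_path = out / "deg_table.tsv"
        if deg_path.exists():
            deg_table = _read(deg_path, index_col=0)
            disease = set(deg_table.index[deg_table["is_deg"]])
            overlap = intersect_targets(net.targets, disease)
        pd.DataFrame({"target_id": overlap}).to_csv(
            out / "target_overlap.tsv", sep="\t", index=False
        )
        done({
            "input": len(records),
            "passing": len(kept),
            "dropped": len(records) - len(kept),
            "network_components": len(net.components),
            "network_targets": len(net.targets),
            "tedge": net.tedge,
            "disease_overlap": len(overlap),
        })

    if cfg["stages"]["ci"]:
        done = timed("ci")
        nodes = _read(out / "network_nodes.tsv")
        edges = _read(out / "network_edges.tsv")
        comp_nodes = nodes[nodes["role"] == "component"]
        records = components_from_table(
            comp_nodes.rename(columns={"node_id": "component_id", "herbs": "herb"})
            .assign(ob=0.0, dl=0.0)[["component_id", "herb", "ob", "dl"]]
        )
        net = build_ct_network(records, edges.itertuples(index=False))
        results = compute_ci(net, mode=cfg["ci"]["mode"])
        _write(results, out / "ci_table.tsv", index=False)
        k = min(int(cfg["ci"]["top_k"]), len(results))
        summary = {
            "n_components": len(net.components),
            "n_targets": len(net.targets),
            "tedge": net.tedge,
            "top_k": k,
            "cumulative_ci": top_k_cumulative(results, k),
        }
        with open(out / "ci_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        done({"input": len(results), "passing": len(results), "dropped": 0, **summary})

    if cfg["stages"]["metabo"]:
        done = timed("metabo")
        intens = _read(out / "metabolites.tsv", index_col=0)
        mgroups = _read(out / "metabolite_groups.tsv", index_col=0)["group"]
        mc = cfg["metabo"]
        screen = MetaboliteScreen(
            vip_threshold=mc["vip_threshold"], p_threshold=mc["p_threshold"],
            fc_theta=mc["fc_theta"], fc_mode=mc["fc_mode"],
            n_components=mc["n_components"],
        ).fit(intens, mgroups)
        _write(screen.results_, out / "metabolite_screen.tsv")
        q2 = q2_cross_validation(intens.T, mgroups, n_components=mc["n_components"])
        perm = permutation_validate(
            intens.T, mgroups, n_components=mc["n_components"],
            n_permutations=int(mc["n_permutations"]), seed=seed + 3,
        )
        summary = {
            "r2x": screen.model_.r2x_,
            "r2y": screen.model_.r2y_,
            "q2": q2,
            "permutation_valid": bool(perm.valid),
            "n_permutations": perm.n_permutations,
            "n_pass": int(screen.results_["passes"].sum()),
            "n_up": screen.n_up_,
            "n_down": screen.n_down_,
        }
        with open(out / "metabo_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        done({
            "input": len(screen.results_),
            "passing": summary["n_pass"],
            "dropped": len(screen.results_) - summary["n_pass"],
            "n_up": summary["n_up"],
            "n_down": summary["n_down"],
        })

    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
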