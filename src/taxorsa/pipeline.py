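"""Config-driven orchestration of the full analysis.

A :class:`RunConfig` names (or simulates) a taxonomy, an activation
table and optionally a stage sequence, and the pipeline runs
representation -> correspondence -> trajectory, writing matrices and a
JSON report with provenance (config echo, derived seeds, input hashes,
package version). One top-level seed is split deterministically per
stage by hashing the stage name, so adding a stage never shifts another
stage's randomness.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from . import io as tio
from .correspondence import correspondence_summary, structure_variance_test
from .errors import ConfigError, DataError, TaxoRSAError
from .representation import (
    ActivationSet,
    category_mean_patterns,
    category_rsm,
)
from .synthetic import (
    DynamicsParams,
    HierParams,
    hierarchical_activations,
    random_taxonomy,
    staged_activations,
)
from .taxonomy import (
    TaxonomyTree,
    map_to_superordinates,
    superordinates_at_level,
    taxonomy_similarity_matrix,
)
from .trajectory import correspondence_trajectory, plateau_stage

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def split_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict``)."""

    seed: int
    output_dir: str
    taxonomy: Mapping[str, Any]
    activations: Mapping[str, Any]
    superordinates: Mapping[str, Any] = field(default_factory=dict)
    stages: Mapping[str, Any] | None = None
    branches: tuple[str, ...] = ()
    correlation: str = "pearson"
    permutations: int = 199
    plateau_epsilon: float = 0.05

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {
            "seed", "output_dir", "taxonomy", "activations", "superordinates",
            "stages", "branches", "correlation", "permutations",
            "plateau_epsilon",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed", "output_dir", "taxonomy", "activations"):
            if key not in raw:
                raise ConfigError(f"config key {key!r} is required")
        if raw.get("correlation", "pearson") not in ("pearson", "spearman"):
            raise ConfigError("correlation must be 'pearson' or 'spearman'")
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=str(raw["output_dir"]),
            taxonomy=dict(raw["taxonomy"]),
            activations=dict(raw["activations"]),
            superordinates=dict(raw.get("superordinates") or {}),
            stages=dict(raw["stages"]) if raw.get("stages") else None,
            branches=tuple(raw.get("branches") or ()),
            correlation=raw.get("correlation", "pearson"),
            permutations=int(raw.get("permutations", 199)),
            plateau_epsilon=float(raw.get("plateau_epsilon", 0.05)),
        )
        cfg._validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def _validate(self) -> None:
        for role, block in (("taxonomy", self.taxonomy),
                            ("activations", self.activations)):
            has_path = "path" in block
            has_sim = "simulate" in block
            if has_path == has_sim:
                raise ConfigError(
                    f"{role}: exactly one of 'path' or 'simulate' is required"
                )
        if self.stages is not None:
            if ("manifest" in self.stages) == ("simulate" in self.stages):
                raise ConfigError(
                    "stages: exactly one of 'manifest' or 'simulate' is required"
                )
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")
        if self.plateau_epsilon <= 0:
            raise ConfigError("plateau_epsilon must be > 0")
        # every referenced file must exist before any computation starts
        for path in self._input_paths():
            if not os.path.exists(path):
                raise ConfigError(f"input file not found: {path}")

    def _input_paths(self) -> list[str]:
        paths = []
        if "path" in self.taxonomy:
            paths.append(self.taxonomy["path"])
            if "leaf_set" in self.taxonomy:
                paths.append(self.taxonomy["leaf_set"])
        if "path" in self.activations:
            paths.append(self.activations["path"])
        if self.superordinates.get("scheme"):
            paths.append(self.superordinates["scheme"])
        if self.stages and "manifest" in self.stages:
            paths.append(self.stages["manifest"])
        return paths

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "taxonomy": dict(self.taxonomy),
            "activations": dict(self.activations),
            "superordinates": dict(self.superordinates),
            "stages": dict(self.stages) if self.stages else None,
            "branches": list(self.branches),
            "correlation": self.correlation,
            "permutations": self.permutations,
            "plateau_epsilon": self.plateau_epsilon,
        }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TaxoRSAError):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _load_taxonomy(cfg: RunConfig) -> tuple[TaxonomyTree, dict]:
    block = cfg.taxonomy
    if "simulate" in block:
        sim = block["simulate"]
        tree = random_taxonomy(
            depth=int(sim.get("depth", 4)),
            branching=sim.get("branching", 3),
            seed=split_seed(cfg.seed, "taxonomy"),
        )
        prov = {"simulated": sim, "n_leaves": len(tree.leaf_set)}
    else:
        from .taxonomy import parse_taxonomy

        fmt = block.get("format", "newick")
        if "leaf_set" in block:
            leaves = tio.load_leaf_set(block["leaf_set"])
        else:
            raise ConfigError("taxonomy: 'leaf_set' file is required with 'path'")
        tree = parse_taxonomy(block["path"], fmt, leaves)
        prov = {"path": block["path"], "sha256": _hash_file(block["path"])}
    return tree, prov


def _load_activations(cfg: RunConfig, tree: TaxonomyTree) -> tuple[ActivationSet, dict]:
    block = cfg.activations
    if "simulate" in block:
        sim = dict(block["simulate"])
        params = HierParams(
            depth=int(sim.get("depth", cfg.taxonomy.get("simulate", {}).get("depth", 4))),
            branching=sim.get(
                "branching", cfg.taxonomy.get("simulate", {}).get("branching", 3)
            ),
            n_units=int(sim.get("n_units", 200)),
            level_sd=sim.get("level_sd", 1.0),
            noise_sd=float(sim.get("noise_sd", 0.5)),
            n_stimuli_per_category=int(sim.get("n_stimuli_per_category", 10)),
            seed=split_seed(cfg.seed, "activations"),
        )
        acts = hierarchical_activations(tree, params)
        prov = {"simulated": sim, "seed": params.seed}
    else:
        acts = tio.load_activation_table(block["path"])
        prov = {"path": block["path"], "sha256": _hash_file(block["path"])}
    return acts, prov


def _build_scheme(cfg: RunConfig, tree: TaxonomyTree):
    block = cfg.superordinates
    if not block:
        return None
    if "scheme" in block:
        return tio.load_scheme(block["scheme"])
    if "names" in block:
        return map_to_superordinates(tree, block["names"])
    if "level" in block:
        return map_to_superordinates(
            tree, superordinates_at_level(tree, int(block["level"]))
        )
    raise ConfigError("superordinates: expected 'scheme', 'names' or 'level'")


def _load_stages(cfg: RunConfig, tree: TaxonomyTree, hier_seed: int):
    block = cfg.stages
    if "manifest" in block:
        rows = tio.load_stage_manifest(block["manifest"])
        stages = [tio.load_activation_table(r["activation_path"]) for r in rows]
        labels = [str(r["stage_label"]) for r in rows]
        perf = (
            [float(r["performance"]) for r in rows]
            if rows and "performance" in rows[0] and rows[0]["performance"] is not None
            and not any(_is_nan(r.get("performance")) for r in rows)
            else None
        )
        return stages, labels, perf
    sim = dict(block["simulate"])
    hier = HierParams(
        depth=int(sim.get("depth", 4)),
        branching=sim.get("branching", 3),
        n_units=int(sim.get("n_units", 200)),
        level_sd=sim.get("level_sd", 1.0),
        noise_sd=float(sim.get("noise_sd", 0.5)),
        n_stimuli_per_category=int(sim.get("n_stimuli_per_category", 10)),
        seed=hier_seed,
    )
    dyn = DynamicsParams(
        tau_by_level=tuple(sim["tau_by_level"]),
        task_level=int(sim.get("task_level", hier.depth)),
        attenuation=float(sim.get("attenuation", 1.0)),
        stages=tuple(sim["stages"]),
    )
    acts = staged_activations(tree, hier, dyn)
    return acts, [a.layer_tag for a in acts], None


def _is_nan(x) -> bool:
    try:
        return bool(np.isnan(float(x)))
    except (TypeError, ValueError):
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis and write all outputs.

    Returns the report dict (also written as ``report.json``). The run
    is deterministic given config + seed; on error, partially written
    outputs are removed.
    """
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _out(name: str) -> str:
        path = os.path.join(out_dir, name)
        written.append(path)
        return path

    try:
        with _stage("taxonomy"):
            tree, tax_prov = _load_taxonomy(config)
            tax = taxonomy_similarity_matrix(tree)
        with _stage("activations"):
            acts, act_prov = _load_activations(config, tree)
        with _stage("representation"):
            patterns = category_mean_patterns(acts)
            rep = category_rsm(patterns, config.correlation)
            if set(rep.names) != set(tax.names):
                raise DataError(
                    "activation categories do not match the taxonomy leaf set"
                )
            rep = rep.reindex(tax.names)
        with _stage("correspondence"):
            scheme = _build_scheme(config, tree)
            summary = correspondence_summary(
                rep, tax, scheme=scheme, tree=tree,
                branches=config.branches, method=config.correlation,
            )
        with _stage("structure_test"):
            test = structure_variance_test(
                acts,
                n_permutations=config.permutations,
                seed=split_seed(config.seed, "structure_test"),
                method=config.correlation,
            )

        report: dict[str, Any] = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "config": config.to_dict(),
            "inputs": {"taxonomy": tax_prov, "activations": act_prov},
            "layer_tag": acts.layer_tag,
            "n_categories": len(rep.names),
            "correspondence": {
                "r_global": summary.r_global,
                "r_by_branch": summary.r_by_branch,
                "r_coarse": summary.r_coarse,
                "r_fine_mean": summary.r_fine_mean,
                "r_fine_by_superordinate": summary.r_fine_by_superordinate,
                "n_pairs": {
                    "global": summary.n_pairs_global,
                    "coarse": summary.n_pairs_coarse,
                    "fine": summary.n_pairs_fine,
                },
            },
            "structure_test": {
                "observed_variance": test.observed_variance,
                "p_value": test.p_value,
                "n_permutations": test.n_permutations,
                "seed": test.seed,
            },
        }

        if config.stages is not None:
            with _stage("trajectory"):
                stage_acts, labels, perf = _load_stages(
                    config, tree, split_seed(config.seed, "stages")
                )
                record = correspondence_trajectory(
                    stage_acts, tax, scheme, stage_labels=labels,
                    performance=perf, method=config.correlation,
                )
                eps = config.plateau_epsilon
                report["trajectory"] = {
                    "stage_index": list(record.stage_index),
                    "stage_label": list(record.stage_label),
                    "r_global": list(record.r_global),
                    "r_coarse": list(record.r_coarse),
                    "r_fine_mean": list(record.r_fine_mean),
                    "performance": (
                        list(record.performance)
                        if record.performance is not None else None
                    ),
                    "plateau_epsilon": eps,
                    "plateau_stage": {
                        "r_global": plateau_stage(record.r_global, eps),
                        "r_coarse": plateau_stage(record.r_coarse, eps),
                        "r_fine_mean": plateau_stage(record.r_fine_mean, eps),
                    },
                }

        with _stage("write_outputs"):
            tio.write_matrix(tax, _out("taxonomic_similarity.tsv"))
            tio.write_matrix(rep, _out("representational_similarity.tsv"))
            if "simulate" in config.taxonomy:
                tio.write_newick(tree, _out("taxonomy.nwk"))
            if scheme is not None:
                tio.write_scheme(scheme, _out("superordinate_scheme.tsv"))
            tio.write_report(report, _out("report.json"))
        return report
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
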