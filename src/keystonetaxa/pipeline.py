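"""End-to-end orchestration: prep -> ordination -> screens -> RMT network
-> modules/roles -> module-trait -> random-forest panel, with a manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import stage_seed
from .table_io import (
    CountTable,
    TraitTable,
    align_tables,
    read_count_table,
    read_trait_table,
    write_network,
)
from . import prep, stats, rmt, roles, biomarker

log = logging.getLogger("keystonetaxa")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error

    def record(self) -> dict:
        return {"stage": self.stage, "error_type": type(self.error).__name__,
                "message": str(self.error)}


@dataclass
class RunConfig:
    """Every knob of the pipeline, serialisable to/from YAML.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    counts_path: str | None = None
    traits_path: str | None = None
    taxonomy_path: str | None = None

    min_prevalence: float = 0.5
    level: str = "ASV"
    genus_floor: float = 0.001
    family_floor: float = 0.01
    shannon_base: float = 2.0
    transform: str = "log"

    bh_alpha: float = 0.05
    anosim_permutations: int = 999

    grid_min: float = 0.30
    grid_max: float = 0.95
    grid_step: float = 0.01
    n_min: int = 50
    edge_p_filter: bool = True
    threshold_override: float | None = None

    zi_cutoff: float = 2.5
    pi_cutoff: float = 0.62
    min_module_size: int = 3
    module_trait_method: str = "pearson"

    rf_trees: int = 500
    rf_folds: int = 5
    mda_threshold: float = 2.0

    run_ordination: bool = True
    run_screens: bool = True
    run_network: bool = True
    run_rf: bool = True

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    """Wrap a stage body so failures halt with a named, machine-readable error."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.1f s", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    counts: CountTable | None = None,
    traits: TraitTable | None = None,
) -> Path:
    """Run every enabled stage and write TSV/GraphML outputs plus
    manifest.json to ``outdir``.  Inputs come from the config paths unless
    in-memory tables are passed directly.  Deterministic for a fixed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "keystonetaxa",
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {},
        "stages": {},
    }

    try:
        counts, traits = _load_inputs(config, counts, traits)
        manifest["stages"]["load"] = {
            "n_taxa": counts.shape[0], "n_samples": counts.shape[1],
            "traits": traits.trait_names,
        }

        filtered, rel, transformed = _prep_stage(config, counts, outdir)
        manifest["stages"]["prep"] = {
            "n_taxa_after_prevalence": filtered.shape[0],
            "transform": config.transform,
            "level": config.level,
        }

        if config.run_ordination:
            manifest["stages"]["ordination"] = _ordination_stage(
                config, filtered, rel, traits, outdir, manifest
            )
        if config.run_screens:
            manifest["stages"]["screens"] = _screen_stage(config, rel, traits, outdir)

        network = None
        if config.run_network:
            network, netinfo = _network_stage(config, transformed, outdir)
            manifest["stages"]["network"] = netinfo
            manifest["stages"]["roles"] = _roles_stage(
                config, network, transformed, traits, outdir
            )
        if config.run_rf:
            manifest["stages"]["random_forest"] = _rf_stage(config, rel, traits, outdir)
    except PipelineError as exc:
        manifest["failed"] = exc.record()
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    return outdir


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


@_stage("load")
def _load_inputs(config, counts, traits):
    if counts is None:
        if config.counts_path is None:
            raise ValueError("no counts: set counts_path or pass a table")
        counts = read_count_table(config.counts_path, config.taxonomy_path)
    if traits is None:
        if config.traits_path is None:
            raise ValueError("no traits: set traits_path or pass a table")
        traits = read_trait_table(config.traits_path)
    counts, traits, _ = align_tables(counts, traits)
    return counts, traits


@_stage("prep")
def _prep_stage(config, counts, outdir):
    filtered = prep.prevalence_filter(counts, config.min_prevalence)
    rel = prep.to_relative_abundance(filtered, level=config.level)
    transformed = prep.transform_for_correlation(rel, method=config.transform)
    rel.proportions.rename_axis("taxon").to_csv(
        outdir / "relative_abundance.tsv", sep="\t"
    )
    return filtered, rel, transformed


@_stage("ordination")
def _ordination_stage(config, filtered, rel, traits, outdir, manifest):
    info: dict = {}
    div = prep.alpha_diversity(filtered, shannon_base=config.shannon_base)
    div.frame().rename_axis("sample").to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    dist = stats.bray_curtis(rel)
    ordination = stats.pcoa(dist)
    ordination.coordinates.rename_axis("sample").to_csv(outdir / "pcoa.tsv", sep="\t")
    info["pcoa_prop_explained"] = ordination.proportion_explained[:3].tolist()
    seed = stage_seed(config.seed, "anosim")
    manifest["seeds"]["anosim"] = seed
    res = stats.anosim(dist, traits.group, n_perm=config.anosim_permutations, seed=seed)
    info["anosim"] = {"R": res.R, "p": res.p, "n_perm": res.n_perm}
    return info


@_stage("screens")
def _screen_stage(config, rel, traits, outdir):
    info: dict = {}
    diff = stats.differential_screen(rel, traits, floor=config.genus_floor)
    diff.to_csv(outdir / "differential_screen.tsv", sep="\t", index=False)
    info["n_differential_q05"] = int((diff["q"] < config.bh_alpha).sum()) if not diff.empty else 0
    tscreen = stats.trait_screen(rel, traits, floor=config.genus_floor)
    tscreen.to_csv(outdir / "trait_screen.tsv", sep="\t", index=False)
    info["n_trait_hits_q05"] = int((tscreen["q"] < config.bh_alpha).sum()) if not tscreen.empty else 0
    edges = stats.cooccurrence_network(rel, floor=config.genus_floor, alpha=config.bh_alpha)
    edges.to_csv(outdir / "cooccurrence_edges.tsv", sep="\t", index=False)
    info["n_cooccurrence_edges"] = len(edges)
    return info


@_stage("network")
def _network_stage(config, transformed, outdir):
    sim = rmt.similarity_matrix(transformed)
    if config.threshold_override is not None:
        threshold = config.threshold_override
        scan = None
    else:
        grid = np.round(
            np.arange(config.grid_min, config.grid_max + 1e-9, config.grid_step), 6
        )
        scan = rmt.select_threshold(sim, grid=grid, n_min=config.n_min)
        scan.to_tsv(outdir / "threshold_scan.tsv")
        threshold = scan.selected
    network = rmt.build_network(sim, threshold, edge_p_filter=config.edge_p_filter)
    info = {
        "selected_threshold": threshold,
        "n_nodes": len(network.nodes),
        "n_edges": network.n_edges,
        "n_isolated_dropped": len(network.dropped_isolated),
    }
    return network, info


@_stage("roles")
def _roles_stage(config, network, transformed, traits, outdir):
    roles.annotate_network(network)
    network.topology.rename_axis("taxon").to_csv(outdir / "node_roles.tsv", sep="\t")
    census = roles.role_census(network.topology)
    census.to_csv(outdir / "role_census.tsv", sep="\t")
    write_network(network, outdir, stem="network")
    mt = roles.module_trait_correlation(
        transformed,
        network.module_of,
        traits,
        method=config.module_trait_method,
        min_module_size=config.min_module_size,
    )
    mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    return {
        "Q": network.Q,
        "n_modules": len(set(network.module_of.values())),
        "role_census": census["count"].to_dict(),
        "peripheral_fraction": float(census.loc["peripheral", "fraction"]),
    }


@_stage("random_forest")
def _rf_stage(config, rel, traits, outdir):
    keep = prep.abundance_floor(rel, config.genus_floor)
    X = rel.proportions.loc[keep, traits.sample_ids].T
    y = traits.group.to_numpy()
    seed = stage_seed(config.seed, "random_forest")
    sel = biomarker.mda_select(
        X, y, threshold=config.mda_threshold, n_trees=config.rf_trees, seed=seed
    )
    table = sel.mda.rename_axis("feature").reset_index()
    table["single_feature_auc"] = [
        biomarker.single_feature_auc(X[f], y) for f in table["feature"]
    ]
    table.to_csv(outdir / "rf_importance.tsv", sep="\t", index=False)

    curve = biomarker.cv_feature_curve(
        X, y, folds=config.rf_folds, n_trees=config.rf_trees, seed=seed
    )
    curve.to_csv(outdir / "rf_cv_curve.tsv", sep="\t", index=False)

    info = {
        "seed": seed,
        "n_features": X.shape[1],
        "panel": sel.features,
        "n_panel": len(sel.features),
    }
    if sel.features:
        res = biomarker.panel_auc(
            X, y, panel=sel.features, folds=config.rf_folds,
            n_trees=config.rf_trees, seed=seed,
        )
        res.roc.to_csv(outdir / "rf_roc.tsv", sep="\t", index=False)
        info["panel_auc"] = res.auc
    return info
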