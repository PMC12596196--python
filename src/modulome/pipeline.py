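"""End-to-end pipeline: decompose → threshold → enrich → activities.

A single config file (YAML or JSON) drives every stage; all randomness
flows from one top-level seed so a rerun with the same config and
inputs reproduces identical member sets and an identical M matrix.
Each stage reads and writes plain-text intermediates in the output
directory, so running the stages separately (the CLI subcommands)
yields byte-identical outputs to a single ``run_pipeline`` call.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import activity as activity_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import ica as ica_mod
from . import membership as membership_mod

logger = logging.getLogger("modulome")

LOG_FORMAT = "%(asctime)s [%(name)s] %(levelname)s %(message)s"


@dataclass
class PipelineConfig:
    # paths
    expression: str = ""
    metadata: str = ""
    trn: str | None = None
    annotation: str | None = None
    output_dir: str = "modulome_out"
    expression_layout: str = "genes_by_samples"
    input_is_tpm: bool = False  # True: raw TPM, apply log10(TPM+1) first
    # randomness
    seed: int = 0
    # ica block
    dimension: int | None = None
    sweep_grid: list[int] = field(default_factory=lambda: list(ica_mod.SWEEP_GRID))
    n_runs: int = ica_mod.DEFAULT_N_RUNS
    tolerance: float = ica_mod.DEFAULT_TOLERANCE
    max_iter: int = ica_mod.DEFAULT_MAX_ITER
    # clustering block
    epsilon: float = ica_mod.DEFAULT_EPSILON
    min_cluster_size: int = ica_mod.DEFAULT_MIN_CLUSTER_SIZE
    # membership block
    k2_cutoff: float = membership_mod.DEFAULT_K2_CUTOFF
    optimize_cutoff: bool = False
    cutoff_grid: list[int] = field(default_factory=lambda: list(membership_mod.DEFAULT_CUTOFF_GRID))
    categories: dict = field(default_factory=dict)  # component_id -> curated category
    # enrichment block
    regulatory_fdr: float = enrichment_mod.DEFAULT_REGULATORY_FDR
    term_fdr: float = enrichment_mod.DEFAULT_TERM_FDR
    quadrant_cut: float = enrichment_mod.DEFAULT_QUADRANT_CUT
    # activity block
    equal_var: bool = False
    activity_clusters: int = 2
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("tolerance", "epsilon", "k2_cutoff", "regulatory_fdr", "term_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def seeds(self) -> list[int]:
        return [(self.seed + i) % (2**31) for i in range(self.n_runs)]


def setup_logging(output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    handlers = [logging.StreamHandler(sys.stderr),
                logging.FileHandler(os.path.join(output_dir, "run.log"))]
    logging.basicConfig(level=logging.INFO, format=LOG_FORMAT, handlers=handlers, force=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    x = expression_mod.read_expression(config.expression, layout=config.expression_layout)
    meta = expression_mod.read_metadata(config.metadata)
    if config.input_is_tpm:
        x = expression_mod.tpm_to_logtpm(x)
    return x, meta


def stage_decompose(config: PipelineConfig) -> ica_mod.RobustDecomposition:
    """Center, (optionally) sweep dimensionality, run the ICA ensemble,
    and consensus-cluster. Writes M.tsv / A.tsv / ica_manifest.json."""
    setup_logging(config.output_dir)
    logger.info("[decompose] loading inputs")
    x, meta = _load_inputs(config)
    xc = expression_mod.batch_center(x, meta)
    dead = expression_mod.zero_variance_genes(xc)
    if dead:
        xc = expression_mod.ExpressionMatrix(xc.data.drop(index=dead), is_centered=True)

    dimension = config.dimension
    if dimension is None:
        logger.info("[decompose] dimension sweep over %s", config.sweep_grid)
        dimension, diagnostics = ica_mod.dimension_sweep(
            xc, dims=config.sweep_grid, n_runs=config.n_runs,
            tolerance=config.tolerance, epsilon=config.epsilon,
            min_cluster_size=config.min_cluster_size, k2_cutoff=config.k2_cutoff,
        )
        diagnostics.to_csv(os.path.join(config.output_dir, "dimension_sweep.tsv"),
                           sep="\t", index=False)
        logger.info("[decompose] selected dimension %d", dimension)

    runs = ica_mod.run_ensemble(
        xc, dimension, n_runs=config.n_runs, tolerance=config.tolerance,
        seeds=config.seeds(), max_iter=config.max_iter,
    )
    decomp = ica_mod.cluster_components(
        runs, xc, epsilon=config.epsilon, min_cluster_size=config.min_cluster_size
    )
    ev = ica_mod.explained_variance(xc, decomp)
    logger.info("[decompose] K=%d robust components, explained variance %.3f", decomp.K, ev)
    params = {
        "dimension": dimension, "n_runs": config.n_runs, "tolerance": config.tolerance,
        "epsilon": config.epsilon, "min_cluster_size": config.min_cluster_size,
        "seed": config.seed, "explained_variance": ev,
    }
    ica_mod.write_decomposition(decomp, config.output_dir, params=params)
    return decomp


def stage_threshold(config: PipelineConfig) -> list[membership_mod.IModulon]:
    """Threshold gene weights into member sets; writes imodulons.json."""
    setup_logging(config.output_dir)
    decomp = ica_mod.read_decomposition(config.output_dir)
    cutoff = float(config.k2_cutoff)
    if config.optimize_cutoff:
        if config.trn:
            trn = enrichment_mod.TRN.from_csv(config.trn, gene_universe=_universe(config, decomp))
            cutoff = membership_mod.optimize_cutoff(decomp.M, trn, grid=config.cutoff_grid,
                                                    default=config.k2_cutoff)
        else:
            logger.warning("[threshold] optimize_cutoff requested without a TRN; "
                           "using default cutoff %.0f", cutoff)
    imodulons = membership_mod.build_imodulons(decomp, k2_cutoff=cutoff,
                                               categories=config.categories)
    membership_mod.write_imodulons(imodulons, os.path.join(config.output_dir, "imodulons.json"))
    with open(os.path.join(config.output_dir, "threshold_manifest.json"), "w") as fh:
        json.dump({"k2_cutoff": cutoff, "optimized": bool(config.optimize_cutoff and config.trn)},
                  fh, indent=2)
    logger.info("[threshold] K² cutoff %.0f; %d/%d components non-empty",
                cutoff, sum(1 for im in imodulons if im.members), len(imodulons))
    return imodulons


def _universe(config: PipelineConfig, decomp) -> frozenset:
    return frozenset(decomp.M.index)


def _read_imodulons(config: PipelineConfig, decomp) -> list[membership_mod.IModulon]:
    with open(os.path.join(config.output_dir, "imodulons.json")) as fh:
        payload = json.load(fh)
    return [
        membership_mod.IModulon(
            component_id=e["component_id"],
            weights=decomp.M[e["component_id"]],
            threshold=e["threshold"],
            members=frozenset(e["members"]),
            category=e.get("category"),
        )
        for e in payload
    ]


def stage_enrich(config: PipelineConfig) -> list[enrichment_mod.EnrichmentResult]:
    """Score iModulons against the TRN; writes enrichment.tsv and
    trn_expansion.json."""
    setup_logging(config.output_dir)
    if not config.trn:
        raise ValueError("enrich stage requires a TRN path in the config")
    decomp = ica_mod.read_decomposition(config.output_dir)
    imodulons = _read_imodulons(config, decomp)
    trn = enrichment_mod.TRN.from_csv(config.trn, gene_universe=_universe(config, decomp))
    results = enrichment_mod.enrich_all(
        [im for im in imodulons if im.members], trn,
        regulatory_fdr=config.regulatory_fdr, quadrant_cut=config.quadrant_cut,
    )
    enrichment_mod.write_enrichment(results, os.path.join(config.output_dir, "enrichment.tsv"))
    regulatory = [r for r in results if r.is_regulatory]
    total, novel, fraction = enrichment_mod.count_trn_expansion(regulatory, imodulons, trn)
    with open(os.path.join(config.output_dir, "trn_expansion.json"), "w") as fh:
        json.dump({"total_associations": total, "novel_associations": novel,
                   "expansion_fraction": fraction, "n_regulatory": len(regulatory)},
                  fh, indent=2)
    logger.info("[enrich] %d regulatory iModulons; TRN expansion %d novel (%.1f%%)",
                len(regulatory), novel, 100 * fraction)
    return results


def stage_activities(config: PipelineConfig) -> pd.DataFrame:
    """Cluster activity rows, optional differential activity; writes
    activity_clusters.tsv, activity_tree.nwk and (if groups are
    configured) differential_activity.tsv."""
    setup_logging(config.output_dir)
    decomp = ica_mod.read_decomposition(config.output_dir)
    if decomp.K >= 2:
        Z, labels = activity_mod.cluster_activity_rows(decomp.A, n_clusters=min(config.activity_clusters, decomp.K))
        labels.to_csv(os.path.join(config.output_dir, "activity_clusters.tsv"), sep="\t")
        with open(os.path.join(config.output_dir, "activity_tree.nwk"), "w") as fh:
            fh.write(activity_mod.linkage_to_newick(Z, list(decomp.A.index)))
    table = pd.DataFrame()
    if config.group_a and config.group_b:
        table = activity_mod.differential_activity_table(
            decomp, config.group_a, config.group_b, equal_var=config.equal_var
        )
        table.to_csv(os.path.join(config.output_dir, "differential_activity.tsv"),
                     sep="\t", index=False)
        logger.info("[activities] differential activity over %d components", len(table))
    return table


def run_pipeline(config: PipelineConfig) -> str:
    """Run every stage in order and write the top-level manifest.

    Returns the output directory. Any stage failure aborts with a
    stage-tagged error; the manifest is only written on success.
    """
    setup_logging(config.output_dir)
    stages = [("decompose", stage_decompose), ("threshold", stage_threshold)]
    if config.trn:
        stages.append(("enrich", stage_enrich))
    stages.append(("activities", stage_activities))
    for name, fn in stages:
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    manifest = {
        "config": asdict(config),
        "inputs": {
            "expression_sha256": _sha256(config.expression),
            "metadata_sha256": _sha256(config.metadata),
            "trn_sha256": _sha256(config.trn) if config.trn else None,
        },
        "stages": [name for name, _ in stages],
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", config.output_dir)
    return config.output_dir
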