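"""End-to-end orchestration: counts -> ternary -> binary -> scan -> networks.

``run_pipeline`` executes the stages in order, writing every intermediate
artifact as TSV so each output is re-readable by the package's own readers,
and logging per-stage tallies (genes fitted, genes NA, cells per group,
eligible networks per threshold) to the standard logger.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from coactive import networks as net
from coactive.coactivation import (
    binarize,
    define_maturity_groups,
    marker_coactivation_scan,
)
from coactive.contextualize import ContextConfig, contextualize_matrix
from coactive.mixture import EMConfig, build_ternary_matrix, log2cpm
from coactive.readwrite import (
    read_counts,
    read_gene_list,
    write_fit_table,
    write_ternary,
)

logger = logging.getLogger("coactive")


@dataclass
class RunConfig:
    counts_path: str
    out_dir: str
    counts_format: str | None = None
    gene_list_path: str | None = None
    mature_marker: str = "OMP"
    immature_marker: str = "GAP43"
    alpha: float = 0.01
    contextualize: bool = False
    thresholds: tuple[float, ...] = net.DEFAULT_THRESHOLDS
    min_nodes: int = 5
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    context: ContextConfig = field(default_factory=ContextConfig)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and return a manifest of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    stamp = {"config_hash": _config_hash(config), "seed": config.seed}

    em = EMConfig(
        max_iter=config.em.max_iter,
        tol=config.em.tol,
        min_nonzero_cells=config.em.min_nonzero_cells,
        seed=config.seed,
        z_call_threshold=config.em.z_call_threshold,
    )
    ctx = ContextConfig(
        n_context_genes=config.context.n_context_genes,
        n_repetitions=config.context.n_repetitions,
        seed=config.seed,
    )

    stage = "read_counts"
    try:
        counts = read_counts(config.counts_path, config.counts_format)
        if config.gene_list_path:
            keep = [g for g in read_gene_list(config.gene_list_path) if g in counts.index]
            if not keep:
                raise ValueError("gene list leaves an empty universe")
            counts = counts.loc[keep]
        logger.info("loaded %d genes x %d cells", *counts.shape)

        stage = "log2cpm"
        logexpr = log2cpm(counts)

        stage = "mixture_fit"
        ternary, fits = build_ternary_matrix(logexpr, em)
        n_na = int(ternary.isna().any(axis=1).sum())
        logger.info("fitted %d genes; %d genes NA", len(fits), n_na)
        if config.contextualize and n_na:
            stage = "contextualize"
            ternary = contextualize_matrix(ternary, logexpr, em, ctx)
            logger.info(
                "after contextualization: %d genes still NA",
                int(ternary.isna().any(axis=1).sum()),
            )
        manifest["ternary"] = out / "ternary.tsv"
        write_ternary(ternary, manifest["ternary"])
        manifest["fits"] = out / "mixture_fits.tsv"
        write_fit_table(fits, list(counts.index), manifest["fits"])

        stage = "binarize"
        binary = binarize(ternary, na_policy="zero")
        manifest["binary"] = out / "binary.tsv"
        binary.astype(int).to_csv(manifest["binary"], sep="\t")

        stage = "maturity_scan"
        scan_df = None
        groups = None
        try:
            groups = define_maturity_groups(
                binary, config.mature_marker, config.immature_marker
            )
            logger.info(
                "groups: %d mature, %d immature, %d excluded",
                len(groups.mature_cells),
                len(groups.immature_cells),
                len(groups.excluded_cells),
            )
            scan_df = marker_coactivation_scan(binary, groups, alpha=config.alpha)
            manifest["marker_scan"] = out / "marker_scan.tsv"
            scan_df.to_csv(manifest["marker_scan"], sep="\t")
        except ValueError as exc:
            logger.warning("maturity scan skipped: %s", exc)

        stage = "networks"
        prevalence = net.edge_prevalence(binary)
        nets = net.build_all_networks(binary, prevalence, config.thresholds[1] if len(config.thresholds) > 1 else config.thresholds[0], groups)
        summary = pd.DataFrame(
            {
                "cell": [c.cell for c in nets],
                "n_nodes": [c.n_nodes for c in nets],
                "n_edges": [c.n_edges for c in nets],
                "centralization": [c.centralization for c in nets],
                "group": [c.group for c in nets],
            }
        )
        manifest["network_summary"] = out / "network_summary.tsv"
        summary.to_csv(manifest["network_summary"], sep="\t", index=False)
        edges = [
            (c.cell, a, b) for c in nets for a, b in sorted(map(tuple, map(sorted, c.graph.edges())))
        ]
        manifest["network_edges"] = out / "network_edges.tsv"
        pd.DataFrame(edges, columns=["cell", "gene_a", "gene_b"]).to_csv(
            manifest["network_edges"], sep="\t", index=False
        )

        if groups is not None and groups.mature_cells and groups.immature_cells:
            stage = "centralization_comparison"
            comparisons = net.compare_group_centralization(
                binary,
                groups,
                thresholds=config.thresholds,
                min_nodes=config.min_nodes,
                prevalence=prevalence,
            )
            comp_df = pd.DataFrame([asdict(c) for c in comparisons])
            manifest["centralization_comparison"] = out / "centralization_comparison.tsv"
            comp_df.to_csv(manifest["centralization_comparison"], sep="\t", index=False)
            for c in comparisons:
                logger.info(
                    "threshold %.3f: %d mature vs %d immature networks, p=%.4g",
                    c.threshold,
                    c.n_mature,
                    c.n_immature,
                    c.p_value,
                )
    except Exception as exc:
        partial = {k: str(v) for k, v in manifest.items()}
        (Path(config.out_dir) / "manifest.json").write_text(
            json.dumps({"failed_stage": stage, "artifacts": partial, **stamp}, indent=2)
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {"artifacts": {k: str(v) for k, v in manifest.items()}, **stamp}, indent=2
        )
    )
    manifest["manifest"] = manifest_path
    return manifest
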