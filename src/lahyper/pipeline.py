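"""End-to-end workflow: screen -> LA scan -> selection -> grouping -> hypergraph.

``run`` executes the full supervised or unsupervised analysis from an
expression matrix on disk (or an in-memory matrix) and writes a
reproducible output directory:

* ``triplets.tsv``    selected gene triplets with LA scores
* ``modules.tsv``     gene -> module membership, one row per membership
* ``hyperedges.tsv``  the thresholded module hypergraph edge list
* ``graph.graphml``   clique expansion of the thresholded hypergraph
* ``manifest.json``   configuration, stage summaries and screen statistics
* ``run.log``         per-stage log

Identical configuration and seed give byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import expression as expr
from . import grouping, hypergraph, selection
from .expression import ExpressionMatrix
from .scan import scan_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Hyper-parameters and paths for one analysis run.

    Defaults mirror a large-cohort setting: screen constant ``c=0.5``,
    selection target ``fdr_target=0.01``, fold-change threshold 2
    (supervised) or 10 (unsupervised), minimum cluster size 100 (reduced
    automatically, with a warning, when fewer genes are clusterable).
    """

    expression_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "lahyper_out"
    mode: str = "unsupervised"  # "supervised" | "unsupervised"
    c: float = 0.5
    fdr_target: float = 0.01
    min_fold_change: float | None = None  # default 2 supervised / 10 unsupervised
    min_cluster_size: int = 100
    min_set_size: int = 5
    max_set_size: int = 500
    max_zero_fraction: float = 0.10
    n_permutations: int = 1
    seed: int = 0
    null_density: str = "normal"
    genes_subset: list[str] | None = None
    top_variance: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("supervised", "unsupervised"):
            raise ValueError("mode must be 'supervised' or 'unsupervised'")
        if self.mode == "supervised" and self.gmt_path is None:
            raise ValueError("supervised mode requires a gene-set (GMT) file")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.min_fold_change is None:
            self.min_fold_change = 2.0 if self.mode == "supervised" else 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_triplets_tsv(path: Path, records, gene_ids: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tgene_k\tlambda\n")
        for r in records:
            fh.write(f"{gene_ids[r.i]}\t{gene_ids[r.j]}\t{gene_ids[r.k]}\t{r.lam:.10g}\n")


def _write_modules_tsv(path: Path, assignment: grouping.ModuleAssignment) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for gene in sorted(assignment.membership):
            for mod in assignment.membership[gene]:
                fh.write(f"{gene}\t{mod}\n")


def run(config: RunConfig, matrix: ExpressionMatrix | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``matrix`` may be given directly (e.g. a synthetic dataset); otherwise
    it is loaded from ``config.expression_path``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("lahyper")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "complete": False}
    try:
        _run_stages(config, matrix, out, manifest)
        manifest["complete"] = True
    except Exception as exc:  # annotate the failing stage, then re-raise
        manifest["error"] = f"{manifest.get('failed_stage', 'setup')}: {exc}"
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
    return out


def _run_stages(config: RunConfig, matrix: ExpressionMatrix | None, out: Path, manifest: dict) -> None:
    # --- preprocess ---------------------------------------------------
    manifest["failed_stage"] = "preprocess"
    if matrix is None:
        if config.expression_path is None:
            raise ValueError("no expression matrix given (path or in-memory)")
        matrix = expr.load_expression(config.expression_path, config.max_zero_fraction)
    if config.genes_subset is not None:
        wanted = set(config.genes_subset)
        idx = [i for i, g in enumerate(matrix.gene_ids) if g in wanted]
        matrix = matrix.subset_genes(idx)
    if config.top_variance is not None and config.top_variance < matrix.n_genes:
        variances = matrix.values.var(axis=1)
        order = np.argsort(-variances, kind="stable")[: config.top_variance]
        matrix = matrix.subset_genes(np.sort(order))
    if matrix.n_genes < 3 or matrix.n_samples < 4:
        raise ValueError("need at least 3 genes and 4 samples after filtering")
    transformed = expr.normal_scores(matrix)
    summary = expr.screen_summary(transformed, config.c)
    mask = expr.eligible_pairs(transformed, summary)
    manifest["stages"]["preprocess"] = {
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "mu": summary.mu,
        "sigma": summary.sigma,
        "interval": [summary.lower, summary.upper],
        "n_eligible_pairs": mask.n_eligible_pairs,
        "suggested_c": expr.suggest_c(summary.sigma, matrix.n_samples)
        if summary.sigma > 0
        else None,
    }

    # --- scan + selection ---------------------------------------------
    manifest["failed_stage"] = "scan"
    scans = scan_all(transformed, mask)
    raw_per_scout = sum(s.n_triplets for s in scans.values())
    manifest["failed_stage"] = "selection"
    curves = {}
    for scout, res in scans.items():
        if res.n_triplets < 10:
            continue
        null = selection.permuted_scan(
            transformed, scout, mask, config.n_permutations, config.seed
        )
        curves[scout] = selection.fdr_curve(
            res.lams, null, config.fdr_target, null_density=config.null_density
        )
    selected = selection.select_triplets(scans, curves)
    _write_triplets_tsv(out / "triplets.tsv", selected, transformed.gene_ids)
    manifest["stages"]["selection"] = {
        "raw_per_scout_triplets": raw_per_scout,
        "deduplicated_scanned_triplets": raw_per_scout // 3,
        "n_selected": len(selected),
        "fdr_target": config.fdr_target,
    }
    if not selected:
        raise ValueError("no triplet passed the fdr selection; nothing to aggregate")

    # --- grouping ------------------------------------------------------
    manifest["failed_stage"] = "grouping"
    gene_ids = transformed.gene_ids
    if config.mode == "supervised":
        collection = grouping.read_gmt(config.gmt_path)
        assignment = grouping.assign_supervised(
            gene_ids, collection, config.min_set_size, config.max_set_size
        )
    else:
        counts = grouping.build_pair_count_matrix([r.genes for r in selected], len(gene_ids))
        D, kept, _ = grouping.pair_profile_distance(counts)
        min_size = config.min_cluster_size
        if min_size > max(2, kept.size // 2):
            reduced = max(2, kept.size // 5)
            logger.warning(
                "min_cluster_size %d too large for %d clusterable genes; using %d",
                min_size, kept.size, reduced,
            )
            min_size = reduced
        assignment = grouping.cluster_unsupervised(
            D, min_size, gene_ids=[gene_ids[i] for i in kept]
        )
    _write_modules_tsv(out / "modules.tsv", assignment)
    manifest["stages"]["grouping"] = {
        "mode": config.mode,
        "n_modules": len(assignment.modules()),
        "n_assigned_genes": len(assignment.membership),
        "n_dropped_genes": len(assignment.dropped),
    }

    # --- hypergraph -----------------------------------------------------
    manifest["failed_stage"] = "hypergraph"
    id_triples = [tuple(gene_ids[g] for g in r.genes) for r in selected]
    lifted, discarded = hypergraph.lift_triplets(id_triples, assignment)
    if not lifted:
        raise ValueError("no triplet survived lifting to modules")
    graph = hypergraph.build_hypergraph(lifted, assignment)
    sparse = hypergraph.threshold_edges(graph, config.min_fold_change)
    hypergraph.write_hyperedges_tsv(sparse, out / "hyperedges.tsv")
    hypergraph.write_graphml(sparse, out / "graph.graphml")
    manifest["stages"]["hypergraph"] = {
        "total_lifted": graph.total_lifted,
        "discarded_triplets": discarded,
        "n_edges_full": graph.n_edges,
        "n_edges_thresholded": sparse.n_edges,
        "n_vertices_thresholded": sparse.n_vertices,
        "min_fold_change": config.min_fold_change,
        "median_degree": sparse.median_degree,
    }
    manifest.pop("failed_stage", None)
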