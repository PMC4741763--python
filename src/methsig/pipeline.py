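"""End-to-end pipeline: (simulate | load) -> DMPs -> signature -> enrichment
-> expression integration -> clustering -> report.

The JSON report records the package version, a hash of the configuration,
the seed, and every count, p-value, threshold and universe size used, so
a run is auditable and identical configs yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import cluster_samples, export_tree_and_heatmap
from .diffmeth import DELTA_THRESHOLD, P_THRESHOLD, Q_THRESHOLD, test_pair, write_dmp_table
from .errors import ConfigError
from .expression import (call_de_pair, gene_list_overlap, intersect_de_common,
                         quantile_normalize)
from .io import (read_beta_matrix, read_expression_matrix, read_probe_annotation,
                 read_sample_sheet, write_signature_outputs)
from .signature import (category_enrichment, filter_promoter_probes,
                        probes_to_genes, signature_from_tables)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("methsig")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and universes for one pipeline run.

    Exactly one of ``simulation`` or the input paths (beta, annotation,
    sample sheet, expression) must be provided.  ``expression_paths``
    maps tissue label -> TSV path.
    """

    simulation: SimulationConfig | None = None
    beta_path: str | None = None
    annotation_path: str | None = None
    sample_sheet_path: str | None = None
    expression_paths: dict = field(default_factory=dict)
    delta_threshold: float = DELTA_THRESHOLD
    p_threshold: float = P_THRESHOLD
    calling_mode: str = "raw_p"  # or "fdr"
    q_threshold: float = Q_THRESHOLD
    fold_threshold: float = 2.0
    score_threshold: float = 13.0
    diff_method: str = "moderated"  # or "welch"
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "methsig_out"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.beta_path is not None
        if has_sim == has_paths:
            raise ConfigError("provide exactly one of a simulation block or input paths")
        if has_paths and (self.annotation_path is None or self.sample_sheet_path is None):
            raise ConfigError("file inputs require beta, annotation and sample sheet paths")
        if not (0 < self.delta_threshold < 1) or not (0 < self.p_threshold < 1):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.calling_mode not in ("raw_p", "fdr"):
            raise ConfigError(f"unknown calling mode {self.calling_mode!r}")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj
        fields = encode(self)
        fields.pop("out_dir", None)
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    manifest: dict
    signature: object
    dmp_tables: list
    de_tables: list


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        ds = simulate_dataset(sim)
        return ds.annotation, ds.beta, ds.samples, ds.expression
    beta = read_beta_matrix(config.beta_path)
    annotation = read_probe_annotation(config.annotation_path)
    samples = read_sample_sheet(config.sample_sheet_path)
    expression = {t: read_expression_matrix(p) for t, p in config.expression_paths.items()}
    return annotation, beta, samples, expression


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report plus per-stage artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation, beta, samples, expression = _load_inputs(config)
    tissues = samples.tissues

    log.info("differential methylation over %d tissue pairs", len(tissues))
    dmp_tables = [test_pair(beta, samples, t, method=config.diff_method) for t in tissues]
    call_kwargs = dict(delta_threshold=config.delta_threshold,
                       p_threshold=config.p_threshold,
                       mode=config.calling_mode, q_threshold=config.q_threshold)
    signature = signature_from_tables(dmp_tables, **call_kwargs)
    manifest = {}
    for table in dmp_tables:
        path = out_dir / f"dmp_{table.tissue}.tsv"
        write_dmp_table(table, path)
        manifest[f"dmp_{table.tissue}"] = str(path)

    hyper_map = probes_to_genes(signature.common_hyper_probes, annotation)
    hypo_map = probes_to_genes(signature.common_hypo_probes, annotation)
    hyper_promoter = filter_promoter_probes(signature.common_hyper_probes, annotation)
    hypo_promoter = filter_promoter_probes(signature.common_hypo_probes, annotation)
    hypo_promoter_genes = probes_to_genes(hypo_promoter, annotation).genes

    enrichments = {}
    for name, probes in (("hyper", signature.common_hyper_probes),
                         ("hypo", signature.common_hypo_probes)):
        if probes:
            enr = category_enrichment(probes, "enhancer", signature.universe, annotation)
            enrichments[name] = {
                "hits": enr.hits, "subset": enr.subset_size,
                "category_in_universe": enr.category_size,
                "universe": enr.universe_size,
                "fraction": enr.fraction, "fold_enrichment": enr.fold_enrichment,
                "p_value": enr.test.p_value, "log10_p": enr.test.log10_p,
            }
        else:
            enrichments[name] = {"hits": 0, "subset": 0, "p_value": 1.0, "log10_p": 0.0}

    manifest.update(write_signature_outputs(signature, annotation, out_dir / "signature"))

    de_tables = []
    integration = {}
    if expression:
        for tissue in tissues:
            if tissue not in expression:
                raise ConfigError(f"no expression matrix for tissue {tissue!r}")
            norm = quantile_normalize(expression[tissue])
            de_tables.append(call_de_pair(norm, samples, tissue,
                                          fold_threshold=config.fold_threshold,
                                          score_threshold=config.score_threshold))
        common_up, common_down = intersect_de_common(de_tables)
        tested_genes = frozenset.intersection(
            *[frozenset(t.data.index) for t in de_tables])
        meth_genes = probes_to_genes(signature.universe, annotation).genes
        overlap_universe = len(tested_genes & meth_genes)
        if overlap_universe:
            hypo_up = gene_list_overlap(hypo_promoter_genes & tested_genes,
                                        common_up & meth_genes, overlap_universe)
            integration = {
                "n_common_up": len(common_up),
                "n_common_down": len(common_down),
                "overlap_universe": overlap_universe,
                "n_hypo_promoter_genes": len(hypo_promoter_genes),
                "n_hypo_and_up": len(hypo_up.overlap),
                "overlap_p": hypo_up.test.p_value,
                "overlap_log10_p": hypo_up.test.log10_p,
                "hypo_and_up_genes": sorted(hypo_up.overlap),
            }

    cluster_section = {}
    signature_probes = sorted(signature.common_hyper_probes | signature.common_hypo_probes)
    if len(signature_probes) >= 2:
        result = cluster_samples(beta, signature_probes)
        manifest.update(export_tree_and_heatmap(result, beta, signature_probes,
                                                out_dir / "clustering"))
        phenotype = {row["sample_id"]: row["phenotype"] for _, row in samples.data.iterrows()}
        g1, g2 = result.cut_sets()
        inv = frozenset(s for s, p in phenotype.items() if p == "invasive")
        separates = {g1, g2} == {inv, frozenset(phenotype) - inv}
        cluster_section = {
            "leaf_order": list(result.leaf_order),
            "two_cluster_cut": {s: l for s, l in sorted(result.two_cluster_labels.items())},
            "separates_phenotypes": bool(separates),
        }

    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "delta_beta": config.delta_threshold, "p": config.p_threshold,
            "calling_mode": config.calling_mode, "q": config.q_threshold,
            "fold": config.fold_threshold, "diff_score": config.score_threshold,
            "diff_method": config.diff_method,
        },
        "pairs": {
            t.tissue: {
                "n_tested": int(len(t.data)), "n_excluded": t.n_excluded,
                "n_hyper": int((t.data["direction"] == "hyper").sum()),
                "n_hypo": int((t.data["direction"] == "hypo").sum()),
            } for t in dmp_tables
        },
        "signature": {
            "universe_probes": len(signature.universe),
            "n_common_hyper": len(signature.common_hyper_probes),
            "n_common_hypo": len(signature.common_hypo_probes),
            "n_hyper_genes": len(hyper_map.genes),
            "n_hypo_genes": len(hypo_map.genes),
            "n_hyper_promoter_probes": len(hyper_promoter),
            "n_hypo_promoter_probes": len(hypo_promoter),
        },
        "enhancer_enrichment": enrichments,
        "integration": integration,
        "clustering": cluster_section,
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["report"] = str(report_path)
    return PipelineResult(report=report, manifest=manifest, signature=signature,
                          dmp_tables=dmp_tables, de_tables=de_tables)
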