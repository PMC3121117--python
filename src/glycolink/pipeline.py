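"""End-to-end orchestration: expression signature -> network screening ->
glycan signature -> candidate integration, with a JSON run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import correlation_matrix, de_test, intersect_signature
from .glycan import (
    assemble_glycan_signature,
    glycan_signature_gts,
    lectin_de_test,
    lectin_gt_correlation,
    quantify_lectin,
)
from .integrate import (
    candidate_glycosyltransferases,
    load_pathway_annotation,
    pathway_annotation,
    select_enzymes,
)
from .io import (
    logger,
    parse_edge_list,
    parse_expression_table,
    parse_lectin_table,
    parse_lgg_map,
    write_matrix_tsv,
)
from .network import screen_networks
from .types import GlycolinkError, PipelineConfig


@dataclass
class PipelineResult:
    """Outputs of one full run; ``manifest`` carries the stage counts."""

    signature: object
    de_results: dict
    screen_records: list
    network_signature_genes: set[str]
    lectin_de: pd.DataFrame
    correlations: pd.DataFrame
    glycan_signature: pd.DataFrame
    candidates: pd.DataFrame
    manifest: dict


def run_pipeline(paths: dict[str, str], config: PipelineConfig | None = None,
                 outdir: str | Path | None = None,
                 extra_enzymes: set[str] | None = None) -> PipelineResult:
    """Run every stage from input files and optionally write all outputs.

    ``paths`` must name: expression, metadata, networks, lectin, lgg.
    Optional: network_enzymes (one gene per line, added to the enzyme
    universe for the network side of the union). Any stage failure aborts
    with the stage name and cause. With the same config and inputs the
    manifest is byte-identical across runs.
    """
    config = config or PipelineConfig()
    stage = "parse"
    try:
        matrix = parse_expression_table(paths["expression"],
                                        paths["metadata"])
        networks = parse_edge_list(paths["networks"])
        lectin_raw = parse_lectin_table(paths["lectin"])
        lgg = parse_lgg_map(paths["lgg"])
        if extra_enzymes is None and "network_enzymes" in paths:
            extra_enzymes = {
                line.strip()
                for line in Path(paths["network_enzymes"]).read_text().split()
                if line.strip()
            }

        stage = "expression_signature"
        de_results = {l: de_test(matrix, l, config)
                      for l in matrix.lineages()}
        signature = intersect_signature(de_results)

        stage = "network_screening"
        records, net_genes = screen_networks(networks, signature, matrix,
                                             config)

        stage = "glycan_signature"
        signals = quantify_lectin(lectin_raw, config.lectin_floor)
        lectin_de = lectin_de_test(signals, matrix.annotations, config)
        correlations = lectin_gt_correlation(signals, matrix, lgg, config)
        glycan_sig = assemble_glycan_signature(lectin_de, lgg, signature)

        stage = "integration"
        network_gts = select_enzymes(net_genes, lgg, extra_enzymes)
        glycan_gts = glycan_signature_gts(glycan_sig)
        candidates = candidate_glycosyltransferases(network_gts, glycan_gts)
        annotated = pathway_annotation(candidates, load_pathway_annotation())
    except GlycolinkError as exc:
        raise GlycolinkError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": {
            "genes_tested": matrix.n_genes,
            "samples": matrix.n_samples,
            "lineages": matrix.lineages(),
            "per_lineage_passes": {l: len(r.passing_genes())
                                   for l, r in sorted(de_results.items())},
            "signature_genes": len(signature),
            "reference_networks": len(networks),
            "networks_in_signature": sum(r.in_signature for r in records),
            "network_signature_genes": len(net_genes),
            "lectins": len(lectin_raw.lectin_ids),
            "lectins_significant": int(lectin_de["passes"].sum()),
            "glycan_signature_lectins":
                int(glycan_sig["lectin_id"].nunique()) if len(glycan_sig)
                else 0,
            "glycan_signature_gts": len(glycan_gts),
            "network_signature_gts": len(network_gts),
            "candidate_gts": len(candidates),
        },
    }
    result = PipelineResult(signature=signature, de_results=de_results,
                            screen_records=records,
                            network_signature_genes=net_genes,
                            lectin_de=lectin_de, correlations=correlations,
                            glycan_signature=glycan_sig,
                            candidates=annotated, manifest=manifest)
    if outdir is not None:
        write_outputs(result, matrix, outdir)
    return result


def write_outputs(result: PipelineResult, matrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lineage, res in result.de_results.items():
        res.table.to_csv(outdir / f"de_{lineage}.tsv", sep="\t", index=False,
                         float_format="%.9g")
    result.signature.table.to_csv(outdir / "expression_signature.tsv",
                                  sep="\t", index=False, float_format="%.9g")
    write_matrix_tsv(correlation_matrix(matrix),
                     outdir / "sample_correlation.tsv", index_name="sample")
    with open(outdir / "network_screen.json", "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in result.screen_records], fh, indent=1,
                  sort_keys=True)
    pd.Series(sorted(result.network_signature_genes), name="gene").to_csv(
        outdir / "network_signature_genes.tsv", sep="\t", index=False)
    result.lectin_de.to_csv(outdir / "lectin_de.tsv", sep="\t", index=False,
                            float_format="%.9g")
    result.correlations.to_csv(outdir / "lectin_gt_correlation.tsv",
                               sep="\t", index=False, float_format="%.9g")
    result.glycan_signature.to_csv(outdir / "glycan_signature.tsv", sep="\t",
                                   index=False)
    result.candidates.to_csv(outdir / "candidate_glycosyltransferases.tsv",
                             sep="\t", index=False)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline outputs written to %s", outdir)
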