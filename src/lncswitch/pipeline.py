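"""End-to-end orchestration of the discovery pipeline.

Stages read only declared inputs (manifest paths or the outputs of earlier
stages) and write plain TSV/JSON, so re-running any stage from on-disk
intermediates reproduces the end-to-end run byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cerna import candidates_for_lncrna, inverse_expression_filter
from .expression import ExpressionDataset
from .genes import GeneAnnotation
from .io import (
    load_annotation,
    load_datasets,
    load_manifest,
    load_peak_collections,
    read_bed,
    read_mirna_fold_ratios,
    _resolve,
)
from .neighbors import fold_change_correlation, nearest_gene
from .promoter import enrichment_table, peak_incidence, promoter_region, tf_enrichment
from .selection import (
    SelectionThresholds,
    abundance_filter,
    cross_tissue_compare,
    log2_fold_change,
    select_candidates,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "lncswitch-tsv-1"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _split_datasets(datasets: List[ExpressionDataset]):
    smooth = [d for d in datasets if d.treatment_direction != "toward_differentiated"]
    skeletal = [d for d in datasets if d.treatment_direction == "toward_differentiated"]
    if len(skeletal) > 1:
        raise ValueError("at most one skeletal (toward_differentiated) dataset")
    return smooth, skeletal[0] if skeletal else None


def run_select(
    manifest: dict,
    thresholds: SelectionThresholds = SelectionThresholds(),
    outdir: Optional[Path] = None,
) -> dict:
    """Candidate selection stage: candidate table plus stage counts."""
    annotation = load_annotation(manifest)
    datasets = load_datasets(manifest)
    smooth, _ = _split_datasets(datasets)
    lnc_ids = {g.gene_id for g in annotation.lncrnas()}
    universe = set.intersection(*(set(d.gene_ids) for d in smooth)) & lnc_ids
    surviving = abundance_filter(smooth, thresholds, gene_ids=lnc_ids)
    candidates = select_candidates(smooth, annotation, thresholds)

    summary = {
        "thresholds": asdict(thresholds),
        "datasets": [d.name for d in smooth],
        "stage_counts": {
            "annotated_lncrnas": len(lnc_ids),
            "gene_universe": len(universe),
            "surviving_abundance": len(surviving),
            "concordant": int(len(candidates)),
            "significant": int(candidates["significant"].sum()),
            "synthetic_up": int((candidates["phenotype_class"] == "synthetic_up").sum()),
            "contractile_up": int(
                (candidates["phenotype_class"] == "contractile_up").sum()
            ),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(candidates, outdir / "candidates.tsv")
        with (outdir / "run_summary.json").open("w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return {
        "annotation": annotation,
        "datasets": datasets,
        "candidates": candidates,
        "summary": summary,
    }


def run_full(
    manifest: dict,
    thresholds: SelectionThresholds = SelectionThresholds(),
    outdir: Optional[Path] = None,
) -> dict:
    """All stages: selection, cross-tissue, enrichment, neighbours, ceRNA."""
    state = run_select(manifest, thresholds, outdir)
    annotation: GeneAnnotation = state["annotation"]
    datasets = state["datasets"]
    smooth, skeletal = _split_datasets(datasets)
    candidates = state["candidates"]
    significant = candidates[candidates["significant"]].reset_index(drop=True)

    # cross-tissue direction comparison (significant candidates only)
    cross = pd.DataFrame()
    if skeletal is not None and len(significant):
        cross = cross_tissue_compare(significant, skeletal, thresholds)
        state["summary"]["stage_counts"]["same_direction"] = int(
            (cross["status"] == "same_direction").sum()
        )
        state["summary"]["stage_counts"]["opposite_direction"] = int(
            (cross["status"] == "opposite_direction").sum()
        )
    state["cross_tissue"] = cross

    # promoter TF enrichment between the two candidate classes
    enrichment = pd.DataFrame()
    peak_sets = load_peak_collections(manifest)
    classes = set(significant["phenotype_class"])
    if peak_sets and {"synthetic_up", "contractile_up"} <= classes:
        promoters = [
            promoter_region(annotation[g]) for g in significant["gene_id"]
        ]
        incidence = peak_incidence(promoters, list(peak_sets.values()))
        labels = dict(zip(significant["gene_id"], significant["phenotype_class"]))
        results = tf_enrichment(incidence, labels, alternative="synthetic_up")
        results += tf_enrichment(incidence, labels, alternative="contractile_up")
        enrichment = enrichment_table(results)
        state["enrichment_results"] = results
    else:
        state["enrichment_results"] = []
        logger.info(
            "promoter enrichment skipped: needs peak files and both candidate classes"
        )
    state["enrichment"] = enrichment

    # nearest coding gene + fold-change correlation across all datasets
    coding = annotation.coding_genes()
    neighbor_rows = []
    for row in significant.itertuples():
        pair = nearest_gene(annotation[row.gene_id], coding)
        if pair is None:
            continue
        lnc_fc, nbr_fc = [], []
        for ds in datasets:
            if row.gene_id in ds.fpkm.index and pair.neighbor_gene_id in ds.fpkm.index:
                lnc_fc.append(
                    log2_fold_change(ds, row.gene_id, thresholds.pseudocount).log2fc
                )
                nbr_fc.append(
                    log2_fold_change(
                        ds, pair.neighbor_gene_id, thresholds.pseudocount
                    ).log2fc
                )
        r = (
            fold_change_correlation(lnc_fc, nbr_fc)
            if len(lnc_fc) >= 3 and np.isfinite(lnc_fc).all() and np.isfinite(nbr_fc).all()
            else None
        )
        neighbor_rows.append(
            {
                "lncrna_id": pair.lncrna_id,
                "neighbor_gene_id": pair.neighbor_gene_id,
                "distance_bp": pair.distance_bp,
                "correlation_r": float("nan") if r is None else r,
                "n_points": len(lnc_fc),
            }
        )
    neighbors = pd.DataFrame(
        neighbor_rows,
        columns=["lncrna_id", "neighbor_gene_id", "distance_bp", "correlation_r", "n_points"],
    )
    state["neighbors"] = neighbors

    # ceRNA nomination for significant candidates
    cerna_rows = []
    base = manifest["_base_dir"]
    if manifest.get("mirna_sites") and manifest.get("mirna_fold_ratios"):
        track = read_bed(_resolve(base, manifest["mirna_sites"]))
        ratios = read_mirna_fold_ratios(_resolve(base, manifest["mirna_fold_ratios"]))
        for row in significant.itertuples():
            direction = (
                "down_on_differentiation"
                if row.phenotype_class == "synthetic_up"
                else "up_on_differentiation"
            )
            cands = candidates_for_lncrna(annotation[row.gene_id], track)
            for cand in inverse_expression_filter(cands, direction, ratios):
                cerna_rows.append(
                    {
                        "lncrna_id": cand.lncrna_id,
                        "mirna_id": cand.mirna_id,
                        "n_binding_sites": cand.n_binding_sites,
                        **{
                            f"fold_ratio_t{i + 1}": v
                            for i, v in enumerate(cand.mirna_fold_ratios)
                        },
                    }
                )
    cerna = pd.DataFrame(cerna_rows)
    state["cerna"] = cerna

    if outdir is not None:
        outdir = Path(outdir)
        _write_tsv(cross, outdir / "cross_tissue.tsv")
        _write_tsv(enrichment, outdir / "tf_enrichment.tsv")
        _write_tsv(neighbors, outdir / "neighbors.tsv")
        _write_tsv(cerna, outdir / "cerna.tsv")
        with (outdir / "run_summary.json").open("w") as fh:
            json.dump(state["summary"], fh, indent=1, sort_keys=True)
    return state


def run_from_manifest_path(
    manifest_path,
    thresholds: SelectionThresholds = SelectionThresholds(),
    outdir: Optional[Path] = None,
    full: bool = True,
) -> dict:
    manifest = load_manifest(manifest_path)
    if full:
        return run_full(manifest, thresholds, outdir)
    return run_select(manifest, thresholds, outdir)
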