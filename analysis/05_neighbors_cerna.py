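#!/usr/bin/env python
"""Characterise candidates as cis-acting regulators and miRNA sponges.

For every significant candidate: (i) find the nearest protein-coding gene
and correlate the pair's log2 fold changes across all four datasets
(cis-acting evidence); (ii) count miRcode-style binding sites in the
candidate's exons and keep the miRNAs whose fold ratios move opposite to
the candidate at every time point (ceRNA evidence).  Reads
results/candidates.tsv; writes results/neighbors.tsv and results/cerna.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lncswitch.cerna import candidates_for_lncrna, inverse_expression_filter
from lncswitch.evaluate import score_cerna, score_neighbors
from lncswitch.io import (
    load_annotation,
    load_datasets,
    load_manifest,
    read_bed,
    read_mirna_fold_ratios,
)
from lncswitch.neighbors import fold_change_correlation, nearest_gene
from lncswitch.pipeline import _write_tsv, read_tsv
from lncswitch.selection import SelectionThresholds, log2_fold_change
from lncswitch.simulate import GroundTruth

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synthetic_study"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = load_manifest(BUNDLE / "manifest.yaml")
    annotation = load_annotation(manifest)
    datasets = load_datasets(manifest)
    thr = SelectionThresholds()
    candidates = read_tsv(RESULTS / "candidates.tsv")
    significant = candidates[candidates["significant"]].reset_index(drop=True)
    coding = annotation.coding_genes()

    neighbor_rows = []
    for row in significant.itertuples():
        pair = nearest_gene(annotation[row.gene_id], coding)
        if pair is None:
            continue
        lnc_fc = [log2_fold_change(d, row.gene_id, thr.pseudocount).log2fc for d in datasets]
        nbr_fc = [
            log2_fold_change(d, pair.neighbor_gene_id, thr.pseudocount).log2fc
            for d in datasets
        ]
        r = fold_change_correlation(lnc_fc, nbr_fc)
        neighbor_rows.append(
            {
                "lncrna_id": pair.lncrna_id,
                "neighbor_gene_id": pair.neighbor_gene_id,
                "distance_bp": pair.distance_bp,
                "correlation_r": float("nan") if r is None else r,
                "n_points": len(lnc_fc),
            }
        )
    neighbors = pd.DataFrame(neighbor_rows)
    _write_tsv(neighbors, RESULTS / "neighbors.tsv")
    print(
        f"nearest-gene pairs: {len(neighbors)}, "
        f"median distance {neighbors['distance_bp'].median():.0f} bp, "
        f"mean fold-change correlation {np.nanmean(neighbors['correlation_r']):.3f}"
    )

    track = read_bed(BUNDLE / "mirna_sites.bed")
    ratios = read_mirna_fold_ratios(BUNDLE / "mirna_fold_ratios.tsv")
    cerna_rows = []
    for row in significant.itertuples():
        direction = (
            "down_on_differentiation"
            if row.phenotype_class == "synthetic_up"
            else "up_on_differentiation"
        )
        for cand in inverse_expression_filter(
            candidates_for_lncrna(annotation[row.gene_id], track), direction, ratios
        ):
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
    _write_tsv(cerna, RESULTS / "cerna.tsv")
    print(
        f"ceRNA nominations: {len(cerna)} lncRNA-miRNA pairs over "
        f"{cerna['lncrna_id'].nunique() if len(cerna) else 0} lncRNAs"
    )

    truth = GroundTruth.load(BUNDLE / "ground_truth.json")
    nb = score_neighbors(annotation, truth)
    ce = score_cerna(annotation, track, ratios, truth)
    print(
        f"vs truth: neighbour recovery {nb['recovery']:.2f}, "
        f"ceRNA exact-set recovery {ce['exact_fraction']:.2f}, "
        f"decoys excluded: {ce['all_decoys_excluded']}"
    )
    print(f"tables -> {RESULTS / 'neighbors.tsv'}, {RESULTS / 'cerna.tsv'}")


if __name__ == "__main__":
    main()
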