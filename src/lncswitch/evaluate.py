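"""Score pipeline outputs against a generator ground-truth manifest.

These functions are the bridge between the synthetic-data generator and
the recovery statistics: selection sensitivity / false positives,
enriched-TF recall, nearest-neighbour recovery and ceRNA set recovery.
They read only pipeline outputs and the serialized :class:`GroundTruth`,
never generator internals.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import pandas as pd

from .cerna import candidates_for_lncrna, inverse_expression_filter
from .genes import GeneAnnotation
from .intervals import LabelledInterval
from .neighbors import nearest_gene
from .promoter import EnrichmentResult
from .simulate import GroundTruth


def score_selection(candidates: pd.DataFrame, truth: GroundTruth) -> Dict[str, float]:
    """Sensitivity and false positives of the candidate table.

    A planted gene counts as recovered when it appears with the correct
    phenotype class and the ``significant`` flag set.  Every table row
    that does not match a planted (gene, class) pair is a false positive.
    """
    recovered = 0
    for gene_id, cls in truth.planted.items():
        hit = candidates[
            (candidates["gene_id"] == gene_id)
            & (candidates["phenotype_class"] == cls)
            & candidates["significant"]
        ]
        if len(hit):
            recovered += 1
    false_rows = candidates[
        [
            truth.planted.get(row.gene_id) != row.phenotype_class
            for row in candidates.itertuples()
        ]
    ]
    n_planted = len(truth.planted)
    return {
        "n_planted": n_planted,
        "n_recovered": recovered,
        "sensitivity": recovered / n_planted if n_planted else float("nan"),
        "false_positives": int(len(false_rows)),
        "n_rows": int(len(candidates)),
    }


def score_enrichment(
    results: Sequence[EnrichmentResult], truth: GroundTruth, alpha: float = 0.1
) -> Dict[str, object]:
    """Recall of truly enriched TFs at the reporting threshold ``alpha``."""
    called = sorted(r.tf_name for r in results if r.p_one_sided < alpha)
    enriched = set(truth.enriched_tfs)
    hits = sorted(enriched & set(called))
    return {
        "n_enriched_true": len(enriched),
        "n_called": len(called),
        "recovered": hits,
        "recall": len(hits) / len(enriched) if enriched else float("nan"),
        "false_calls": sorted(set(called) - enriched),
    }


def score_neighbors(annotation: GeneAnnotation, truth: GroundTruth) -> Dict[str, float]:
    """Fraction of planted lncRNAs whose nearest coding gene matches truth."""
    coding = annotation.coding_genes()
    correct = 0
    for lnc_id, info in truth.neighbors.items():
        pair = nearest_gene(annotation[lnc_id], coding)
        if pair is not None and pair.neighbor_gene_id == info["gene_id"]:
            correct += 1
    n = len(truth.neighbors)
    return {
        "n_pairs": n,
        "n_correct": correct,
        "recovery": correct / n if n else float("nan"),
    }


def score_cerna(
    annotation: GeneAnnotation,
    target_track: Sequence[LabelledInterval],
    mirna_fc_table: pd.DataFrame,
    truth: GroundTruth,
) -> Dict[str, object]:
    """Exact-set recovery of truly inverse miRNAs per planted lncRNA."""
    exact = 0
    decoys_excluded = True
    details: List[dict] = []
    for lnc_id, info in truth.cerna.items():
        cands = candidates_for_lncrna(annotation[lnc_id], target_track)
        kept = inverse_expression_filter(cands, info["direction"], mirna_fc_table)
        kept_set = {c.mirna_id for c in kept}
        truth_set = set(info["truly_inverse"])
        if kept_set == truth_set:
            exact += 1
        if kept_set & set(info["decoys"]):
            decoys_excluded = False
        details.append(
            {"lncrna_id": lnc_id, "kept": sorted(kept_set), "expected": sorted(truth_set)}
        )
    n = len(truth.cerna)
    return {
        "n_lncrnas": n,
        "n_exact": exact,
        "exact_fraction": exact / n if n else float("nan"),
        "all_decoys_excluded": decoys_excluded,
        "details": details,
    }


def score_cross_tissue(comparison: pd.DataFrame, truth: GroundTruth) -> Dict[str, float]:
    """Agreement of same/opposite-direction calls with the planted truth."""
    correct = 0
    total = 0
    for row in comparison.itertuples():
        expected = truth.skeletal_same_direction.get(row.gene_id)
        if expected is None or row.status == "not_comparable":
            continue
        total += 1
        if (row.status == "same_direction") == expected:
            correct += 1
    return {
        "n_compared": total,
        "n_correct": correct,
        "accuracy": correct / total if total else float("nan"),
    }
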