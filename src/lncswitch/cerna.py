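"""Competing-endogenous-RNA (ceRNA) candidate nomination.

A candidate lncRNA can act as a miRNA sponge when (i) its exonic sequence
carries predicted binding sites for a miRNA family and (ii) the miRNA's
expression moves opposite to the lncRNA's during differentiation.  Binding
sites come from a miRcode-style target track (BED intervals labelled with
the miRNA family); the inverse-expression evidence from a table of linear
fold ratios (differentiated / undifferentiated) at one or more time
points.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import pandas as pd

from .genes import GeneModel
from .intervals import LabelledInterval, intervals_overlap

logger = logging.getLogger(__name__)

LNCRNA_DIRECTIONS = ("down_on_differentiation", "up_on_differentiation")


@dataclass
class CeRNACandidate:
    lncrna_id: str
    mirna_id: str
    n_binding_sites: int
    mirna_fold_ratios: List[float] = field(default_factory=list)
    passes_inverse_filter: bool = False

    def __post_init__(self) -> None:
        if self.n_binding_sites < 1:
            raise ValueError("a ceRNA candidate needs >= 1 binding site")


def count_binding_sites(
    lncrna: GeneModel, target_track: Sequence[LabelledInterval]
) -> Dict[str, int]:
    """Per-miRNA counts of target-track intervals overlapping the exons.

    An interval counts when it overlaps >= 1 bp of any exon, and counts
    once even if it spans several exons (sites live on the spliced
    transcript).  Purely intronic intervals do not count.
    """
    counts: Counter = Counter()
    for rec in target_track:
        if rec.label is None:
            continue
        if any(intervals_overlap(rec.interval, exon) for exon in lncrna.exons):
            counts[rec.label] += 1
    return dict(counts)


def candidates_for_lncrna(
    lncrna: GeneModel, target_track: Sequence[LabelledInterval]
) -> List[CeRNACandidate]:
    return [
        CeRNACandidate(lncrna_id=lncrna.gene_id, mirna_id=mirna, n_binding_sites=n)
        for mirna, n in sorted(count_binding_sites(lncrna, target_track).items())
    ]


def inverse_expression_filter(
    candidates: Sequence[CeRNACandidate],
    lncrna_direction: str,
    mirna_fc_table: pd.DataFrame,
    mode: str = "all",
) -> List[CeRNACandidate]:
    """Keep miRNAs whose expression moves opposite to the lncRNA.

    For a lncRNA that goes *down* on differentiation, retain miRNAs whose
    fold ratio is > 1 at every time point (``mode="all"``, default) or at
    any time point (``mode="any"``); the mirror rule (< 1) applies to
    lncRNAs that go up.  miRNAs absent from the table are dropped with a
    warning.  Returns new candidate records with ``mirna_fold_ratios``
    filled and ``passes_inverse_filter=True``.
    """
    if lncrna_direction not in LNCRNA_DIRECTIONS:
        raise ValueError(f"lncrna_direction must be one of {LNCRNA_DIRECTIONS}")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    kept: List[CeRNACandidate] = []
    for cand in candidates:
        if cand.mirna_id not in mirna_fc_table.index:
            logger.warning(
                "miRNA %s (candidate for %s) absent from fold-ratio table; dropped",
                cand.mirna_id,
                cand.lncrna_id,
            )
            continue
        ratios = mirna_fc_table.loc[cand.mirna_id].astype(float).tolist()
        if lncrna_direction == "down_on_differentiation":
            hits = [r > 1.0 for r in ratios]
        else:
            hits = [r < 1.0 for r in ratios]
        passes = all(hits) if mode == "all" else any(hits)
        if passes:
            kept.append(
                CeRNACandidate(
                    lncrna_id=cand.lncrna_id,
                    mirna_id=cand.mirna_id,
                    n_binding_sites=cand.n_binding_sites,
                    mirna_fold_ratios=ratios,
                    passes_inverse_filter=True,
                )
            )
    return kept
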