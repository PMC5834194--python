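"""Nearest protein-coding neighbour assignment and fold-change correlation.

Cis-acting lncRNAs regulate transcription of nearby genes, so their
expression changes track those of their closest protein-coding gene.  The
neighbour is the coding gene with the smallest span-to-span gap on the
same chromosome (0 when the spans overlap), strand-agnostic; the evidence
is the Pearson correlation of the two genes' log2 fold changes across
differentiation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .genes import GeneModel


@dataclass
class NeighborPair:
    lncrna_id: str
    neighbor_gene_id: str
    distance_bp: int
    correlation_r: Optional[float] = None
    n_points: int = 0


def nearest_gene(
    lncrna: GeneModel, coding_genes: Iterable[GeneModel]
) -> Optional[NeighborPair]:
    """The coding gene minimising the span-to-span gap to the lncRNA.

    Overlapping spans have distance 0.  Ties are broken by smaller start
    coordinate, then lexicographically by gene_id.  Returns None when no
    coding gene shares the lncRNA's chromosome.
    """
    best = None
    for gene in coding_genes:
        gap = lncrna.span.gap_to(gene.span)
        if gap is None:
            continue
        key = (gap, gene.span.start, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, gene)
    if best is None:
        return None
    (gap, _, _), gene = best
    return NeighborPair(
        lncrna_id=lncrna.gene_id, neighbor_gene_id=gene.gene_id, distance_bp=gap
    )


def fold_change_correlation(
    lnc_fc: Sequence[float], nbr_fc: Sequence[float]
) -> Optional[float]:
    """Pearson r between two aligned log2 fold-change vectors.

    Needs >= 3 conditions; returns None when either vector has zero
    variance (r undefined).
    """
    x = np.asarray(lnc_fc, dtype=float)
    y = np.asarray(nbr_fc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fold-change vectors must be aligned (same length)")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 conditions")
    if np.isnan(x).any() or np.isnan(y).any():
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
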