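"""Strand-aware promoter windows and transcription-factor peak enrichment.

The promoter of a gene is the fixed window from 2,000 bases upstream to
500 bases downstream of its TSS (the 5'-most transcribed base), measured
along the direction of transcription.  A TF "hits" a promoter when at
least one of its ChIP-seq peaks overlaps the window by >= 1 bp; multiple
peaks count once.  Enrichment between the two candidate classes is the
one-sided Fisher exact (hypergeometric tail) test on the 2x2 table of
promoters with/without a hit, reported without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .genes import GeneModel
from .intervals import GenomicInterval, PeakCollection


@dataclass
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    upstream_bp: int = 2000
    downstream_bp: int = 500


@dataclass
class EnrichmentResult:
    """One TF's 2x2 enrichment table and one-sided p-value.

    a/b: candidate promoters of the tested class with / without a peak;
    c/d: the same for the other class.  ``p_one_sided`` is the exact upper
    hypergeometric tail P(X >= a) for over-representation in the tested
    class.
    """

    tf_name: str
    a: int
    b: int
    c: int
    d: int
    p_one_sided: float
    enriched_in: str


def promoter_region(
    gene: GeneModel,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
    chrom_length: Optional[int] = None,
) -> PromoterWindow:
    """The promoter window of a gene in internal 0-based coordinates.

    On the '+' strand the window is ``[tss - upstream, tss + downstream)``;
    on the '-' strand it is the mirror image about the 5' base,
    ``[tss - downstream + 1, tss + upstream + 1)``.  Either way it spans
    ``upstream_bp + downstream_bp`` bases and contains the TSS base,
    unless clipped at the chromosome boundary.  Unstranded genes have no
    defined promoter.
    """
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.gene_id}: promoter undefined without strand")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    else:
        start, end = tss - downstream_bp + 1, tss + upstream_bp + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(
        gene_id=gene.gene_id,
        interval=GenomicInterval(gene.chrom, start, end, gene.strand),
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


def peak_incidence(
    promoters: Sequence[PromoterWindow],
    peak_sets: Sequence[PeakCollection],
) -> pd.DataFrame:
    """Boolean gene x TF matrix: True iff >= 1 peak overlaps the promoter."""
    incidence = pd.DataFrame(
        False,
        index=[p.gene_id for p in promoters],
        columns=[ps.tf_name for ps in peak_sets],
    )
    for ps in peak_sets:
        trees: Dict[str, IntervalTree] = {}
        for peak in ps.peaks:
            trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end)
        for prom in promoters:
            tree = trees.get(prom.interval.chrom)
            if tree is not None and tree.overlaps(
                prom.interval.start, prom.interval.end
            ):
                incidence.loc[prom.gene_id, ps.tf_name] = True
    return incidence


def _one_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Upper hypergeometric tail P(X >= a) for the 2x2 table [[a,b],[c,d]].

    Drawing n1 = a + b promoters from a population of N = a+b+c+d of which
    K = a + c carry a peak.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def tf_enrichment(
    incidence: pd.DataFrame,
    class_labels: Mapping[str, str],
    alternative: str = "synthetic_up",
    other_class: Optional[str] = None,
) -> List[EnrichmentResult]:
    """Per-TF one-sided enrichment of peak incidence in one candidate class.

    ``class_labels`` maps gene_id -> phenotype class for every row of
    ``incidence``; ``alternative`` names the class tested for
    over-representation (the other class is inferred when not given).
    """
    classes = sorted(set(class_labels.values()))
    if alternative not in classes:
        raise ValueError(f"no genes labelled {alternative!r}")
    if other_class is None:
        others = [c for c in classes if c != alternative]
        if len(others) != 1:
            raise ValueError(f"cannot infer the comparison class from {classes}")
        other_class = others[0]
    test_genes = [g for g in incidence.index if class_labels.get(g) == alternative]
    ref_genes = [g for g in incidence.index if class_labels.get(g) == other_class]
    if not test_genes or not ref_genes:
        raise ValueError("both candidate classes must be non-empty")

    results = []
    for tf_name in incidence.columns:
        hits = incidence[tf_name]
        a = int(hits.loc[test_genes].sum())
        b = len(test_genes) - a
        c = int(hits.loc[ref_genes].sum())
        d = len(ref_genes) - c
        results.append(
            EnrichmentResult(
                tf_name=tf_name,
                a=a,
                b=b,
                c=c,
                d=d,
                p_one_sided=_one_sided_p(a, b, c, d),
                enriched_in=alternative,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf_name": r.tf_name,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_one_sided": r.p_one_sided,
                "enriched_in": r.enriched_in,
            }
            for r in results
        ]
    ).sort_values(["p_one_sided", "tf_name"]).reset_index(drop=True)
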