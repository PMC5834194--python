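"""Gene models and GTF input/output.

Genes are represented at gene level: transcripts are collapsed to a single
span with the union of their exons, and the transcription start site (TSS)
is the 5' end of that span.  Biotypes are normalised to the four classes
the pipeline distinguishes: ``lncRNA``, ``protein_coding``, ``miRNA_host``
and ``other``.  Genes whose biotype maps to ``other`` are carried in the
annotation but excluded from every analysis stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from .intervals import GenomicInterval

BIOTYPES = ("lncRNA", "protein_coding", "miRNA_host", "other")

#: Mapping from common annotation biotype strings (GENCODE `gene_type`,
#: Ensembl `gene_biotype`) to the internal classes.  Anything absent maps
#: to "other".
DEFAULT_BIOTYPE_MAP: Dict[str, str] = {
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "bidirectional_promoter_lncRNA": "lncRNA",
    "macro_lncRNA": "lncRNA",
    "protein_coding": "protein_coding",
    "miRNA_host": "miRNA_host",
}


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


@dataclass
class GeneModel:
    """A gene collapsed to one span plus the union of its exons."""

    gene_id: str
    gene_name: str
    biotype: str
    span: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            self.exons = [self.span]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.span.chrom or e.strand != self.span.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon chrom/strand disagrees with span"
                )
            if e.start < self.span.start or e.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Position of the 5'-most base: span.start on '+', span.end - 1 on '-'."""
        if self.strand == "-":
            return self.span.end - 1
        return self.span.start


@dataclass
class GeneAnnotation:
    """A collection of gene models keyed by gene_id."""

    genes: Dict[str, GeneModel] = field(default_factory=dict)
    genome_build: str = "unknown"

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def by_biotype(self, biotype: str) -> List[GeneModel]:
        if biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {biotype!r}")
        return [g for g in self.genes.values() if g.biotype == biotype]

    def lncrnas(self) -> List[GeneModel]:
        return self.by_biotype("lncRNA")

    def coding_genes(self) -> List[GeneModel]:
        return self.by_biotype("protein_coding")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path,
    biotype_map: Optional[Dict[str, str]] = None,
    genome_build: str = "unknown",
) -> GeneAnnotation:
    """Read a GENCODE-dialect GTF into a gene-level annotation.

    Coordinates are converted from the GTF 1-based inclusive convention to
    the internal 0-based half-open one (start - 1, end unchanged).  Exon
    records from all transcripts of a gene are merged into a union; genes
    with no exon records get a single exon equal to their span.  The
    biotype comes from the ``gene_type`` (or ``gene_biotype``) attribute
    through ``biotype_map``; unmapped values become ``other``.

    Raises :class:`GtfParseError` (naming the line number) on malformed
    lines, and ``ValueError`` if a gene's records mix strands.
    """
    biotype_map = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    path = Path(path)
    spans: Dict[str, GenomicInterval] = {}
    names: Dict[str, str] = {}
    biotypes: Dict[str, str] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    order: List[str] = []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"{path.name}:{lineno}: invalid coordinates {start1}-{end1}"
                )
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"{path.name}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)

            if gene_id not in spans and gene_id not in exons:
                order.append(gene_id)
            prior = spans.get(gene_id)
            if prior is not None and (prior.chrom != chrom or prior.strand != strand):
                raise ValueError(
                    f"gene {gene_id}: records on mixed strands/chromosomes "
                    f"(line {lineno})"
                )
            if feature == "gene":
                spans[gene_id] = iv
                names[gene_id] = attr.get("gene_name", gene_id)
                raw_bt = attr.get("gene_type", attr.get("gene_biotype", ""))
                biotypes[gene_id] = biotype_map.get(raw_bt, "other")
            elif feature == "exon":
                sibling = exons.setdefault(gene_id, [])
                if sibling and (
                    sibling[0].chrom != chrom or sibling[0].strand != strand
                ):
                    raise ValueError(
                        f"gene {gene_id}: exons on mixed strands (line {lineno})"
                    )
                sibling.append(iv)

    annotation = GeneAnnotation(genome_build=genome_build)
    for gene_id in order:
        gene_exons = _merge_exons(exons.get(gene_id, []))
        span = spans.get(gene_id)
        if span is None:
            # exon-only gene: span is the exon envelope
            span = GenomicInterval(
                gene_exons[0].chrom,
                min(e.start for e in gene_exons),
                max(e.end for e in gene_exons),
                gene_exons[0].strand,
            )
        if gene_exons:
            if gene_exons[0].chrom != span.chrom or gene_exons[0].strand != span.strand:
                raise ValueError(f"gene {gene_id}: exons disagree with gene record")
        annotation.add(
            GeneModel(
                gene_id=gene_id,
                gene_name=names.get(gene_id, gene_id),
                biotype=biotypes.get(gene_id, "other"),
                span=span,
                exons=gene_exons or [span],
            )
        )
    return annotation


def _merge_exons(exons: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of possibly overlapping exons from multiple transcripts."""
    exons = sorted(exons, key=lambda e: e.start)
    merged: List[GenomicInterval] = []
    for e in exons:
        if merged and e.start <= merged[-1].end:
            last = merged[-1]
            if e.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, e.end, last.strand)
        else:
            merged.append(e)
    return merged


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write gene + exon records, converting back to 1-based inclusive."""
    path = Path(path)
    with path.open("w") as fh:
        for gene in annotation.genes.values():
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'gene_type "{gene.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "lncswitch",
                        "gene",
                        str(gene.span.start + 1),
                        str(gene.span.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for e in gene.exons:
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            "lncswitch",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
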