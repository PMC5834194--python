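"""BED input/output, dataset manifests and auxiliary tables."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .expression import ExpressionDataset, read_expression_table
from .genes import GeneAnnotation, read_gtf
from .intervals import GenomicInterval, LabelledInterval, PeakCollection


class BedParseError(ValueError):
    pass


def read_bed(path) -> List[LabelledInterval]:
    """Read BED3/BED6 intervals (already 0-based half-open), keeping order.

    The name column, if present, is retained as the label; the strand
    column, if present, is applied to the interval.  Duplicate intervals
    are kept.
    """
    path = Path(path)
    records: List[LabelledInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path.name}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end})"
                )
            label = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            records.append(
                LabelledInterval(GenomicInterval(chrom, start, end, strand), label)
            )
    return records


def write_bed(records: List[LabelledInterval], path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.label or '.'}\t0\t{iv.strand}\n"
            )


def read_peak_bed(path, tf_name: Optional[str] = None) -> PeakCollection:
    """Read one transcription factor's peaks; tf_name defaults to the stem."""
    path = Path(path)
    records = read_bed(path)
    return PeakCollection(
        tf_name=tf_name or path.stem, peaks=[r.interval for r in records]
    )


def read_mirna_fold_ratios(path) -> pd.DataFrame:
    """miRNA fold-ratio table: first column mirna_id, one column per time point.

    Ratios are linear fold ratios (differentiated / undifferentiated); a
    value > 1 means the miRNA goes up upon differentiation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if df.shape[1] < 1:
        raise ValueError("fold-ratio table needs at least one time-point column")
    return df


def load_manifest(path) -> dict:
    """Load a YAML/JSON run manifest and resolve its paths.

    Expected keys: ``annotation`` (GTF path), ``datasets`` (list with
    ``name``, ``table``, ``control_samples``, ``treated_samples``,
    ``treatment_direction``), and optionally ``peaks`` (tf_name -> BED),
    ``mirna_sites`` (BED6 target track), ``mirna_fold_ratios`` (TSV),
    ``ground_truth`` (JSON), ``genome_build``, ``chrom_lengths``.
    """
    path = Path(path)
    with path.open() as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "datasets" not in manifest:
        raise ValueError(f"{path.name}: manifest must be a mapping with 'datasets'")
    manifest["_base_dir"] = path.parent
    return manifest


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def load_annotation(manifest: dict) -> GeneAnnotation:
    base = manifest["_base_dir"]
    return read_gtf(
        _resolve(base, manifest["annotation"]),
        genome_build=manifest.get("genome_build", "unknown"),
    )


def load_datasets(manifest: dict) -> List[ExpressionDataset]:
    base = manifest["_base_dir"]
    datasets = []
    for entry in manifest["datasets"]:
        datasets.append(
            read_expression_table(
                _resolve(base, entry["table"]), entry, name=entry.get("name")
            )
        )
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate dataset names in manifest: {names}")
    return datasets


def load_peak_collections(manifest: dict) -> Dict[str, PeakCollection]:
    base = manifest["_base_dir"]
    peaks = {}
    for tf_name, bed_path in (manifest.get("peaks") or {}).items():
        peaks[tf_name] = read_peak_bed(_resolve(base, bed_path), tf_name=tf_name)
    return peaks
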