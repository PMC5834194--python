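"""FPKM expression datasets and their tab-separated on-disk form.

Each dataset is one differentiation experiment: an FPKM matrix (genes x
samples) plus a control/treated sample split and a ``treatment_direction``
saying which phenotype the treatment pushes toward:

* ``toward_synthetic`` — e.g. growth-factor treatment that de-differentiates
  smooth muscle into the proliferative, synthetic phenotype;
* ``toward_contractile`` — e.g. myocardin overexpression or TGF-beta, which
  drive the differentiated, contractile phenotype;
* ``toward_differentiated`` — skeletal-muscle differentiation (myoblast to
  myotube), used only in the cross-tissue comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

TREATMENT_DIRECTIONS = (
    "toward_synthetic",
    "toward_contractile",
    "toward_differentiated",
)


@dataclass
class ExpressionDataset:
    name: str
    fpkm: pd.DataFrame  # genes x samples, non-negative
    control_samples: List[str]
    treated_samples: List[str]
    treatment_direction: str
    unknown_genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.treatment_direction not in TREATMENT_DIRECTIONS:
            raise ValueError(
                f"treatment_direction must be one of {TREATMENT_DIRECTIONS}, "
                f"got {self.treatment_direction!r}"
            )
        if not self.control_samples or not self.treated_samples:
            raise ValueError(f"dataset {self.name}: both groups must be non-empty")
        overlap = set(self.control_samples) & set(self.treated_samples)
        if overlap:
            raise ValueError(
                f"dataset {self.name}: samples in both groups: {sorted(overlap)}"
            )
        missing = [
            s
            for s in self.control_samples + self.treated_samples
            if s not in self.fpkm.columns
        ]
        if missing:
            raise ValueError(f"dataset {self.name}: samples not in table: {missing}")
        values = self.fpkm.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"dataset {self.name}: non-numeric FPKM values")
        if (values < 0).any():
            raise ValueError(f"dataset {self.name}: negative FPKM values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    def values_for(self, gene_id: str, group: str) -> np.ndarray:
        """Per-sample FPKM for one gene in 'control' or 'treated'."""
        samples = self.control_samples if group == "control" else self.treated_samples
        return self.fpkm.loc[gene_id, samples].to_numpy(dtype=float)

    def mean_fpkm(self, gene_id: str) -> float:
        """Mean FPKM over ALL samples of the dataset (abundance filter)."""
        samples = self.control_samples + self.treated_samples
        return float(self.fpkm.loc[gene_id, samples].mean())


def read_expression_table(path, manifest: dict, name: str = None) -> ExpressionDataset:
    """Read a Cuffnorm-style tab-separated FPKM table.

    ``manifest`` carries the sample grouping:
    ``{"control_samples": [...], "treated_samples": [...],
    "treatment_direction": ..., "name": ...}``.
    """
    path = Path(path)
    fpkm = pd.read_csv(path, sep="\t", index_col=0)
    try:
        fpkm = fpkm.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric cell in FPKM table") from exc
    for key in ("control_samples", "treated_samples", "treatment_direction"):
        if key not in manifest:
            raise ValueError(f"manifest for {path.name} missing key {key!r}")
    missing = [
        s
        for s in list(manifest["control_samples"]) + list(manifest["treated_samples"])
        if s not in fpkm.columns
    ]
    if missing:
        raise ValueError(f"{path.name}: manifest samples absent from header: {missing}")
    return ExpressionDataset(
        name=name or manifest.get("name", path.stem),
        fpkm=fpkm,
        control_samples=list(manifest["control_samples"]),
        treated_samples=list(manifest["treated_samples"]),
        treatment_direction=manifest["treatment_direction"],
    )


def write_expression_table(dataset: ExpressionDataset, path) -> None:
    df = dataset.fpkm.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
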