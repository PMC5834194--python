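"""Candidate lncRNA selection by cross-dataset fold-change concordance.

The selection procedure mirrors how smooth-muscle differentiation
experiments with *opposing* treatment directions are combined: a gene is a
candidate for the synthetic phenotype when its expression rises in every
dataset whose treatment pushes toward the synthetic state and falls in
every dataset pushing toward the contractile state (and the mirror image
for contractile candidates).  Per-dataset evidence is a log2 fold change of
group-mean FPKM plus a two-tailed Welch t-test; a zero-denominator guard
discards genes whose control group is mostly zeros, where an FPKM ratio is
meaningless.

Thresholds (defaults):

==================  =======  =====================================================
min_avg_fpkm        5        abundance: keep genes with mean FPKM >= 5 somewhere
min_abs_log2fc      0.5      per-dataset fold-change magnitude (strict inequality)
zero_fraction       0.5      invalid when >= 50% of denominator samples are zero
p_strict / n_strict 0.1 / 2  "significant" needs p < 0.1 in >= 2 datasets ...
p_loose             0.3      ... and p < 0.3 in every dataset
p_skeletal          0.2      single-dataset p cut-off for the skeletal comparison
==================  =======  =====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset
from .genes import GeneAnnotation


@dataclass(frozen=True)
class SelectionThresholds:
    min_avg_fpkm: float = 5.0
    min_abs_log2fc: float = 0.5
    zero_fraction: float = 0.5
    p_strict: float = 0.1
    n_strict: int = 2
    p_loose: float = 0.3
    p_skeletal: float = 0.2
    pseudocount: float = 0.0
    #: "all": drop a gene only when its mean FPKM is below min_avg_fpkm in
    #: every dataset; "any": drop when below in at least one dataset.
    abundance_policy: str = "all"

    def __post_init__(self) -> None:
        for name in (
            "min_avg_fpkm",
            "min_abs_log2fc",
            "zero_fraction",
            "p_strict",
            "p_loose",
            "p_skeletal",
            "pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p_strict > self.p_loose:
            raise ValueError("p_strict must be <= p_loose")
        if self.abundance_policy not in ("all", "any"):
            raise ValueError("abundance_policy must be 'all' or 'any'")

    def with_(self, **kwargs) -> "SelectionThresholds":
        return replace(self, **kwargs)


@dataclass
class FoldChangeRecord:
    """Per-gene, per-dataset differential-expression evidence.

    ``log2fc`` is log2((mean_treated + pc) / (mean_control + pc)).
    ``direction_for_selection`` re-orients the fold change so that a
    positive value always means "toward the contractile / differentiated
    state", making records comparable across datasets with opposing
    treatments.
    """

    gene_id: str
    dataset: str
    treatment_direction: str
    log2fc: float
    p_value: float  # NaN when undefined (a group with < 2 samples)
    denominator_valid: bool

    @property
    def direction_for_selection(self) -> float:
        if self.treatment_direction == "toward_synthetic":
            return -self.log2fc
        return self.log2fc


def abundance_filter(
    datasets: Sequence[ExpressionDataset],
    thresholds: SelectionThresholds,
    gene_ids: Optional[Iterable[str]] = None,
) -> Set[str]:
    """Genes retained by the mean-FPKM abundance filter.

    The gene universe is the intersection of the datasets' gene sets
    (optionally pre-restricted via ``gene_ids``).  Under the default
    ``"all"`` policy a gene is removed only when its mean FPKM over all
    samples is below ``min_avg_fpkm`` in *every* dataset; ``"any"``
    removes it as soon as one dataset is below.  The comparison is strict
    (a mean of exactly 5.0 is not "lower than 5").
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    universe = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        universe &= set(ds.gene_ids)
    if gene_ids is not None:
        universe &= set(gene_ids)
    if not universe:
        raise ValueError("empty gene universe across datasets")

    genes = sorted(universe)
    below = np.ones(len(genes), dtype=bool) if thresholds.abundance_policy == "all" else np.zeros(len(genes), dtype=bool)
    for ds in datasets:
        samples = ds.control_samples + ds.treated_samples
        means = ds.fpkm.loc[genes, samples].mean(axis=1).to_numpy()
        if thresholds.abundance_policy == "all":
            below &= means < thresholds.min_avg_fpkm
        else:
            below |= means < thresholds.min_avg_fpkm
    return {g for g, b in zip(genes, below) if not b}


def zero_denominator_check(
    dataset: ExpressionDataset,
    gene_id: str,
    which: str = "control",
    zero_fraction: float = 0.5,
) -> bool:
    """True (= ratio invalid) iff >= ``zero_fraction`` of the denominator
    group's FPKM values are zero.

    The denominator group is the control group for the treated/control
    ratios reported throughout the pipeline.
    """
    values = dataset.values_for(gene_id, which)
    return bool((values == 0).sum() / len(values) >= zero_fraction)


def log2_fold_change(
    dataset: ExpressionDataset,
    gene_id: str,
    pseudocount: float = 0.0,
    zero_fraction: float = 0.5,
) -> FoldChangeRecord:
    """Log2 fold change of group means plus a two-tailed Welch t-test.

    With the default pseudocount of 0, a mostly-zero control group would
    produce an unbounded ratio; the zero-denominator rule flags exactly
    those records invalid so they can never reach selection.  When both
    groups have zero variance, the t statistic is undefined and the record
    gets p = 1.0 with a warning.
    """
    if gene_id not in dataset.fpkm.index:
        raise KeyError(f"gene {gene_id!r} absent from dataset {dataset.name}")
    treated = dataset.values_for(gene_id, "treated")
    control = dataset.values_for(gene_id, "control")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = float(
            np.log2((treated.mean() + pseudocount) / (control.mean() + pseudocount))
        )
    if len(treated) < 2 or len(control) < 2:
        p_value = float("nan")
    elif treated.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        warnings.warn(
            f"gene {gene_id} in {dataset.name}: zero variance in both groups; p=1.0",
            stacklevel=2,
        )
        p_value = 1.0
    else:
        p_value = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    invalid = zero_denominator_check(dataset, gene_id, "control", zero_fraction)
    return FoldChangeRecord(
        gene_id=gene_id,
        dataset=dataset.name,
        treatment_direction=dataset.treatment_direction,
        log2fc=log2fc,
        p_value=p_value,
        denominator_valid=not invalid,
    )


def direction_concordance(
    records: Sequence[FoldChangeRecord], thresholds: SelectionThresholds
) -> str:
    """Classify one gene from its per-dataset records.

    Returns ``"synthetic_up"`` when log2fc > +min_abs_log2fc in every
    toward_synthetic dataset AND log2fc < -min_abs_log2fc in every
    toward_contractile dataset; ``"contractile_up"`` for the mirror
    pattern; ``"none"`` otherwise (including any invalid denominator).
    Inequalities are strict, so a fold change of exactly +-0.5 never
    qualifies.
    """
    if not records:
        raise ValueError("no fold-change records supplied")
    if any(not r.denominator_valid for r in records):
        return "none"
    thr = thresholds.min_abs_log2fc
    syn = all(
        r.log2fc > thr
        if r.treatment_direction == "toward_synthetic"
        else r.log2fc < -thr
        for r in records
    )
    con = all(
        r.log2fc < -thr
        if r.treatment_direction == "toward_synthetic"
        else r.log2fc > thr
        for r in records
    )
    if syn:
        return "synthetic_up"
    if con:
        return "contractile_up"
    return "none"


def significance_aggregate(
    p_values: Sequence[float], thresholds: SelectionThresholds
) -> bool:
    """Tiered significance rule across datasets.

    True iff at least ``n_strict`` datasets have p < p_strict AND every
    dataset has p < p_loose.  Undefined (NaN) p-values fail both clauses.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.isnan(p).any():
        return False
    return int((p < thresholds.p_strict).sum()) >= thresholds.n_strict and bool(
        (p < thresholds.p_loose).all()
    )


def fold_change_table(
    datasets: Sequence[ExpressionDataset],
    gene_ids: Iterable[str],
    thresholds: SelectionThresholds,
) -> Dict[str, Dict[str, FoldChangeRecord]]:
    """``{gene_id: {dataset_name: FoldChangeRecord}}`` for the given genes."""
    out: Dict[str, Dict[str, FoldChangeRecord]] = {}
    for gene_id in gene_ids:
        out[gene_id] = {
            ds.name: log2_fold_change(
                ds, gene_id, thresholds.pseudocount, thresholds.zero_fraction
            )
            for ds in datasets
        }
    return out


def select_candidates(
    datasets: Sequence[ExpressionDataset],
    annotation: GeneAnnotation,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Run the full selection on the smooth-muscle datasets.

    Only datasets with direction ``toward_synthetic`` / ``toward_contractile``
    participate (a skeletal ``toward_differentiated`` dataset is handled
    separately by :func:`cross_tissue_compare`), and the gene universe is
    restricted to annotated lncRNAs.  The result has one row per gene that
    survives abundance, zero-denominator and concordance checks, with
    per-dataset log2fc / p columns, its phenotype class, the tiered
    ``significant`` flag and a summary fold change
    (mean of the toward-contractile re-oriented per-dataset log2fc), sorted
    within each class by descending |summary|.
    """
    smooth = [d for d in datasets if d.treatment_direction != "toward_differentiated"]
    directions = {d.treatment_direction for d in smooth}
    if not {"toward_synthetic", "toward_contractile"} <= directions:
        raise ValueError(
            "selection needs datasets of both opposing treatment directions"
        )
    lnc_ids = {g.gene_id for g in annotation.lncrnas()}
    retained = abundance_filter(smooth, thresholds, gene_ids=lnc_ids)
    records = fold_change_table(smooth, sorted(retained), thresholds)

    rows = []
    for gene_id, per_ds in records.items():
        recs = list(per_ds.values())
        phenotype = direction_concordance(recs, thresholds)
        if phenotype == "none":
            continue
        significant = significance_aggregate([r.p_value for r in recs], thresholds)
        summary = float(np.mean([r.direction_for_selection for r in recs]))
        row = {
            "gene_id": gene_id,
            "gene_name": annotation[gene_id].gene_name,
            "phenotype_class": phenotype,
            "summary_log2fc_toward_contractile": summary,
            "mean_abs_log2fc": float(np.mean([abs(r.log2fc) for r in recs])),
            "significant": significant,
        }
        for ds in smooth:
            row[f"log2fc_{ds.name}"] = per_ds[ds.name].log2fc
            row[f"p_{ds.name}"] = per_ds[ds.name].p_value
        rows.append(row)

    columns = (
        ["gene_id", "gene_name", "phenotype_class"]
        + [f"log2fc_{ds.name}" for ds in smooth]
        + [f"p_{ds.name}" for ds in smooth]
        + ["summary_log2fc_toward_contractile", "mean_abs_log2fc", "significant"]
    )
    table = pd.DataFrame(rows, columns=columns)
    table["significant"] = table["significant"].astype(bool)
    table = table.sort_values(
        ["phenotype_class", "mean_abs_log2fc", "gene_id"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    return table


def cross_tissue_compare(
    candidates: pd.DataFrame,
    skeletal: ExpressionDataset,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Compare smooth-muscle candidates with skeletal-muscle differentiation.

    A candidate is *comparable* when the skeletal dataset supports a
    reliable call for it: present in the table, mean FPKM >= min_avg_fpkm,
    valid denominator, |log2fc| > min_abs_log2fc and p < p_skeletal
    (the skeletal analogue of the tiered rule, applied to the single
    dataset).  Comparable genes are classed ``same_direction`` when the
    sign of the smooth-muscle toward-contractile summary matches the sign
    of the skeletal change upon differentiation, else
    ``opposite_direction``; all others are ``not_comparable``.
    """
    if skeletal.treatment_direction != "toward_differentiated":
        raise ValueError("cross-tissue comparison expects a skeletal dataset")
    rows = []
    for _, cand in candidates.iterrows():
        gene_id = cand["gene_id"]
        smooth_fc = cand["summary_log2fc_toward_contractile"]
        status = "not_comparable"
        skel_fc = float("nan")
        skel_p = float("nan")
        if gene_id in skeletal.fpkm.index:
            rec = log2_fold_change(
                skeletal, gene_id, thresholds.pseudocount, thresholds.zero_fraction
            )
            skel_fc, skel_p = rec.log2fc, rec.p_value
            if (
                skeletal.mean_fpkm(gene_id) >= thresholds.min_avg_fpkm
                and rec.denominator_valid
                and abs(rec.log2fc) > thresholds.min_abs_log2fc
                and not np.isnan(rec.p_value)
                and rec.p_value < thresholds.p_skeletal
            ):
                status = (
                    "same_direction"
                    if np.sign(smooth_fc) == np.sign(skel_fc)
                    else "opposite_direction"
                )
        rows.append(
            {
                "gene_id": gene_id,
                "gene_name": cand["gene_name"],
                "phenotype_class": cand["phenotype_class"],
                "smooth_log2fc_toward_contractile": smooth_fc,
                "skeletal_log2fc": skel_fc,
                "skeletal_p": skel_p,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_name",
            "phenotype_class",
            "smooth_log2fc_toward_contractile",
            "skeletal_log2fc",
            "skeletal_p",
            "status",
        ],
    )
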