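"""Synthetic multi-dataset inputs with planted ground truth.

The generator emulates the structure of a multi-experiment lncRNA
discovery study at desk scale: three smooth-muscle FPKM datasets whose
treatments push in opposing phenotypic directions (one synthetic-inducing,
two contractile-inducing), one skeletal-muscle differentiation dataset,
ChIP-seq peak tracks for a few dozen transcription factors, a
miRcode-style miRNA target track, and a miRNA fold-ratio table.  Every
stage of the pipeline has planted true positives:

* candidate lncRNAs with a consistent +/- ``effect_log2fc`` across the
  smooth datasets (and a chosen same/opposite direction in the skeletal
  one);
* a designated nearest protein-coding neighbour per planted lncRNA that
  shares the planted effect (cis-acting behaviour);
* transcription factors whose peaks preferentially hit the promoters of
  synthetic-phenotype candidates;
* miRNA families with binding sites in planted lncRNA exons and fold
  ratios inverse to the lncRNA's differentiation direction, next to decoy
  families whose ratios straddle 1.

Expression noise is multiplicative log-normal (FPKM are positive and
continuous); a configurable fraction of genes is zero-inflated in the
control groups (to exercise the zero-denominator rule) or kept below the
abundance threshold in every dataset.  A single integer seed determines
every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionDataset
from .genes import GeneAnnotation, GeneModel, write_gtf
from .intervals import GenomicInterval, LabelledInterval, PeakCollection
from .io import write_bed
from .promoter import promoter_region


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    The default scale (300 lncRNAs, 100 coding genes, 1 synthetic- plus 2
    contractile-direction smooth datasets, 1 skeletal dataset, 4 samples
    per group, planted |log2fc| = 1, within-group CV = 0.1, ~20 TFs of
    which 3 truly enriched) keeps a full pipeline run well under a minute
    on one CPU while leaving every selection rule with work to do.
    """

    seed: int = 0
    n_lncrna: int = 300
    n_coding: int = 100
    n_datasets_synthetic: int = 1
    n_datasets_contractile: int = 2
    include_skeletal: bool = True
    samples_per_group: int = 4
    n_planted_synthetic_up: int = 15
    n_planted_contractile_up: int = 10
    effect_log2fc: float = 1.0
    baseline_fpkm_log_mean: float = 3.0  # natural-log scale; median ~20 FPKM
    baseline_fpkm_log_sd: float = 1.0
    noise_cv: float = 0.1
    frac_low_abundance: float = 0.15
    frac_zero_inflated: float = 0.05
    skeletal_same_direction_frac: float = 0.6
    n_tfs: int = 20
    enriched_tf_count: int = 3
    peak_hit_prob_enriched: float = 0.9
    peak_hit_prob_background: float = 0.1
    background_peaks_per_tf: int = 20
    n_mirnas: int = 30
    n_time_points: int = 2
    sites_per_pair_min: int = 1
    sites_per_pair_max: int = 4
    n_chromosomes: int = 3
    chrom_length: int = 4_000_000

    def __post_init__(self) -> None:
        if self.n_planted_synthetic_up + self.n_planted_contractile_up > self.n_lncrna:
            raise ValueError("planted counts exceed n_lncrna")
        if self.n_planted_synthetic_up > self.n_coding or self.n_planted_contractile_up > self.n_coding - self.n_planted_synthetic_up:
            raise ValueError("not enough coding genes for planted neighbours")
        for p in (
            self.peak_hit_prob_enriched,
            self.peak_hit_prob_background,
            self.frac_low_abundance,
            self.frac_zero_inflated,
            self.skeletal_same_direction_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if not 1 <= self.sites_per_pair_min <= self.sites_per_pair_max:
            raise ValueError("invalid sites_per_pair range")


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    planted: Dict[str, str] = field(default_factory=dict)  # lnc -> class
    neighbors: Dict[str, dict] = field(default_factory=dict)
    skeletal_same_direction: Dict[str, bool] = field(default_factory=dict)
    enriched_tfs: List[str] = field(default_factory=list)
    cerna: Dict[str, dict] = field(default_factory=dict)
    zero_inflated: List[str] = field(default_factory=list)
    low_abundance: List[str] = field(default_factory=list)
    mirna_roles: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**{f.name: d.get(f.name, f.default_factory()) for f in dataclasses.fields(cls)})

    def save(self, path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with Path(path).open() as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    annotation: GeneAnnotation
    datasets: List[ExpressionDataset]
    peaks: Dict[str, PeakCollection]
    target_track: List[LabelledInterval]
    mirna_fold_ratios: pd.DataFrame
    truth: GroundTruth
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    @property
    def smooth_datasets(self) -> List[ExpressionDataset]:
        return [d for d in self.datasets if d.treatment_direction != "toward_differentiated"]

    @property
    def skeletal_dataset(self) -> Optional[ExpressionDataset]:
        for d in self.datasets:
            if d.treatment_direction == "toward_differentiated":
                return d
        return None


# ---------------------------------------------------------------------------
# annotation


def _make_exons(
    span: GenomicInterval, rng: np.random.Generator
) -> List[GenomicInterval]:
    k = int(rng.integers(1, 5))
    inner = span.length - 2
    if k == 1 or inner < 2 * k * 30:
        return [span]
    cuts = np.sort(
        rng.choice(np.arange(span.start + 1, span.end - 1), size=2 * k - 2, replace=False)
    )
    bounds = [span.start, *cuts.tolist(), span.end]
    return [
        GenomicInterval(span.chrom, bounds[2 * i], bounds[2 * i + 1], span.strand)
        for i in range(k)
    ]


def generate_annotation(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GeneAnnotation, GroundTruth, Dict[str, int]]:
    """Place genes on synthetic chromosomes with known neighbour structure.

    Genes are laid out in widely separated blocks (>= 10 kb apart); each
    planted lncRNA shares its block with its designated protein-coding
    neighbour at a 0.5-2 kb gap, which makes that neighbour the unique
    nearest coding gene by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lnc_ids = [f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)]
    coding_ids = [f"PCG{i:04d}" for i in range(1, config.n_coding + 1)]

    planted_ids = list(
        rng.choice(
            lnc_ids,
            size=config.n_planted_synthetic_up + config.n_planted_contractile_up,
            replace=False,
        )
    )
    truth = GroundTruth()
    for i, gid in enumerate(planted_ids):
        truth.planted[gid] = (
            "synthetic_up" if i < config.n_planted_synthetic_up else "contractile_up"
        )
    partner_ids = list(
        rng.choice(coding_ids, size=len(planted_ids), replace=False)
    )
    for lnc, pcg in zip(planted_ids, partner_ids):
        truth.neighbors[lnc] = {"gene_id": pcg, "correlation_sign": 1}

    blocks: List[List[Tuple[str, str]]] = []
    for lnc, pcg in zip(planted_ids, partner_ids):
        blocks.append([(lnc, "lncRNA"), (pcg, "protein_coding")])
    for gid in lnc_ids:
        if gid not in truth.planted:
            blocks.append([(gid, "lncRNA")])
    used_partners = set(partner_ids)
    for gid in coding_ids:
        if gid not in used_partners:
            blocks.append([(gid, "protein_coding")])
    rng.shuffle(blocks)

    chrom_lengths = {
        f"chrS{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    chrom_names = list(chrom_lengths)
    annotation = GeneAnnotation(genome_build="synthetic")
    chrom_idx, cursor = 0, 5000
    margin = 5000  # room for promoters at both chromosome ends
    for block in blocks:
        lengths = [int(rng.integers(1000, 4001)) for _ in block]
        gaps = [int(rng.integers(500, 2001)) for _ in block[1:]]
        width = sum(lengths) + sum(gaps)
        while cursor + width + margin > config.chrom_length:
            chrom_idx += 1
            cursor = 5000
            if chrom_idx >= len(chrom_names):
                raise ValueError(
                    "cannot place all genes; increase chrom_length or n_chromosomes"
                )
        chrom = chrom_names[chrom_idx]
        pos = cursor
        for j, (gid, biotype) in enumerate(block):
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, pos, pos + lengths[j], strand)
            annotation.add(
                GeneModel(
                    gene_id=gid,
                    gene_name=gid,
                    biotype=biotype,
                    span=span,
                    exons=_make_exons(span, rng),
                )
            )
            pos += lengths[j]
            if j < len(gaps):
                pos += gaps[j]
        cursor = pos + int(rng.integers(10_000, 20_001))

    unplanted = [g for g in lnc_ids if g not in truth.planted]
    rng.shuffle(unplanted)
    n_zero = int(round(config.frac_zero_inflated * config.n_lncrna))
    n_low = int(round(config.frac_low_abundance * config.n_lncrna))
    truth.zero_inflated = sorted(unplanted[:n_zero])
    truth.low_abundance = sorted(unplanted[n_zero : n_zero + n_low])
    for gid in planted_ids:
        truth.skeletal_same_direction[gid] = bool(
            rng.random() < config.skeletal_same_direction_frac
        )
    return annotation, truth, chrom_lengths


# ---------------------------------------------------------------------------
# expression


def _dataset_plan(config: SimulationConfig) -> List[Tuple[str, str]]:
    plan = []
    syn_names = (
        ["pdgf_like"]
        if config.n_datasets_synthetic == 1
        else [f"synthetic_{i + 1}" for i in range(config.n_datasets_synthetic)]
    )
    con_default = ["myocd_like", "tgfb_like"]
    con_names = (
        con_default[: config.n_datasets_contractile]
        if config.n_datasets_contractile <= 2
        else [f"contractile_{i + 1}" for i in range(config.n_datasets_contractile)]
    )
    plan += [(n, "toward_synthetic") for n in syn_names]
    plan += [(n, "toward_contractile") for n in con_names]
    if config.include_skeletal:
        plan.append(("skeletal_diff", "toward_differentiated"))
    return plan


def _signed_effect(
    gid: str, direction: str, config: SimulationConfig, truth: GroundTruth
) -> float:
    """Planted log2 effect of treatment for one gene in one dataset."""
    e = config.effect_log2fc
    cls = truth.planted.get(gid)
    if cls is None:
        for lnc, info in truth.neighbors.items():
            if info["gene_id"] == gid:
                cls = truth.planted[lnc]
                gid = lnc
                break
    if cls is None:
        if gid in truth.zero_inflated:
            # mimic a synthetic-phenotype candidate; the zero-denominator
            # rule, not the effect size, must be what excludes it
            cls = "synthetic_up"
        else:
            return 0.0
    sign = 1.0 if cls == "synthetic_up" else -1.0
    if direction == "toward_synthetic":
        return sign * e
    if direction == "toward_contractile":
        return -sign * e
    # skeletal differentiation: same/opposite direction vs the smooth
    # toward-contractile change (which is -sign * e)
    if gid in truth.skeletal_same_direction:
        same = truth.skeletal_same_direction[gid]
        return -sign * e if same else sign * e
    return 0.0


def generate_expression(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> List[ExpressionDataset]:
    """FPKM matrices for every dataset in the study design.

    Per gene: a log-normal baseline (planted genes and their neighbours
    floored at 4x the abundance threshold so that recovery measures the
    selection rules, not the baseline draw), a per-dataset log-normal
    jitter emulating cross-experiment variability, the planted treatment
    effect on the treated group, and multiplicative log-normal sample
    noise with coefficient of variation ``noise_cv``.  Zero-inflated genes
    additionally get >= 50% zeros in every smooth-muscle control group.
    """
    gene_ids = list(annotation.genes)
    n = len(gene_ids)
    baseline = rng.lognormal(
        config.baseline_fpkm_log_mean, config.baseline_fpkm_log_sd, size=n
    )
    protected = set(truth.planted) | {
        info["gene_id"] for info in truth.neighbors.values()
    } | set(truth.zero_inflated)
    low = set(truth.low_abundance)
    for i, gid in enumerate(gene_ids):
        if gid in protected:
            baseline[i] = max(baseline[i], 20.0)
        elif gid in low:
            baseline[i] = rng.uniform(0.2, 2.0)

    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    m = config.samples_per_group
    n_zero_samples = math.ceil(m / 2)
    datasets = []
    for ds_name, direction in _dataset_plan(config):
        jitter = rng.lognormal(0.0, 0.25, size=n)
        effects = np.array(
            [_signed_effect(gid, direction, config, truth) for gid in gene_ids]
        )
        ctrl_mean = baseline * jitter
        trt_mean = ctrl_mean * np.exp2(effects)
        noise_c = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(n, m)))
        noise_t = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(n, m)))
        ctrl = ctrl_mean[:, None] * noise_c
        trt = trt_mean[:, None] * noise_t
        if direction != "toward_differentiated":
            zero_rows = [i for i, g in enumerate(gene_ids) if g in set(truth.zero_inflated)]
            if zero_rows:
                ctrl[np.array(zero_rows)[:, None], np.arange(n_zero_samples)] = 0.0
        ctrl_cols = [f"{ds_name}_ctrl_{i + 1}" for i in range(m)]
        trt_cols = [f"{ds_name}_trt_{i + 1}" for i in range(m)]
        fpkm = pd.DataFrame(
            np.hstack([ctrl, trt]), index=gene_ids, columns=ctrl_cols + trt_cols
        )
        fpkm.index.name = "gene_id"
        datasets.append(
            ExpressionDataset(
                name=ds_name,
                fpkm=fpkm,
                control_samples=ctrl_cols,
                treated_samples=trt_cols,
                treatment_direction=direction,
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# peaks


def generate_peaks(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    truth: GroundTruth,
    rng: np.random.Generator,
    chrom_lengths: Dict[str, int],
) -> Dict[str, PeakCollection]:
    """ChIP-seq peaks: enriched TFs favour synthetic-candidate promoters.

    Enriched TFs drop a peak into each synthetic_up candidate promoter
    with probability ``peak_hit_prob_enriched`` and into any other lncRNA
    promoter at the background rate; background TFs use the background
    rate everywhere.  Each TF also gets a few uniformly placed genomic
    background peaks.
    """
    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    enriched = sorted(
        rng.choice(tf_names, size=config.enriched_tf_count, replace=False).tolist()
    )
    truth.enriched_tfs = enriched
    synthetic_up = {g for g, c in truth.planted.items() if c == "synthetic_up"}
    promoters = [promoter_region(g) for g in annotation.lncrnas()]

    collections = {}
    for tf in tf_names:
        peaks = []
        for prom in promoters:
            p_hit = (
                config.peak_hit_prob_enriched
                if tf in enriched and prom.gene_id in synthetic_up
                else config.peak_hit_prob_background
            )
            if rng.random() < p_hit:
                width = int(rng.integers(150, 401))
                start = int(
                    rng.integers(prom.interval.start, prom.interval.end - width + 1)
                )
                peaks.append(GenomicInterval(prom.interval.chrom, start, start + width))
        for _ in range(config.background_peaks_per_tf):
            chrom = str(rng.choice(list(chrom_lengths)))
            width = int(rng.integers(150, 401))
            start = int(rng.integers(0, chrom_lengths[chrom] - width))
            peaks.append(GenomicInterval(chrom, start, start + width))
        collections[tf] = PeakCollection(tf_name=tf, peaks=peaks)
    return collections


# ---------------------------------------------------------------------------
# miRNA data


def generate_mirna_data(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> Tuple[List[LabelledInterval], pd.DataFrame]:
    """miRNA target track plus fold-ratio table with planted inversions.

    miRNA families get one of three expression roles across the
    differentiation time points: ``up_on_diff`` (fold ratio > 1 at every
    time point), ``down_on_diff`` (< 1 everywhere) or ``mixed``
    (straddling 1, so it can never satisfy the all-time-points inverse
    rule).  Each planted lncRNA receives exonic binding sites for a few
    truly inverse families (role opposite to the lncRNA's differentiation
    direction) and for a few mixed-role decoys.
    """
    mirna_ids = [f"miR-{i + 101}" for i in range(config.n_mirnas)]
    rng.shuffle(mirna_ids)
    third = config.n_mirnas // 3
    roles = {}
    for i, mid in enumerate(mirna_ids):
        roles[mid] = "up_on_diff" if i < third else ("down_on_diff" if i < 2 * third else "mixed")
    truth.mirna_roles = roles

    t = config.n_time_points
    ratios = {}
    for mid in mirna_ids:
        if roles[mid] == "up_on_diff":
            ratios[mid] = rng.uniform(1.3, 3.0, size=t)
        elif roles[mid] == "down_on_diff":
            ratios[mid] = rng.uniform(0.3, 0.8, size=t)
        else:
            vals = np.concatenate(
                [rng.uniform(1.2, 2.5, size=max(1, t // 2)), rng.uniform(0.4, 0.9, size=t - max(1, t // 2))]
            )
            rng.shuffle(vals)
            ratios[mid] = vals
    table = pd.DataFrame.from_dict(
        {m: ratios[m] for m in sorted(ratios)},
        orient="index",
        columns=[f"ratio_t{i + 1}" for i in range(t)],
    )
    table.index.name = "mirna_id"

    up_pool = sorted(m for m, r in roles.items() if r == "up_on_diff")
    down_pool = sorted(m for m, r in roles.items() if r == "down_on_diff")
    mixed_pool = sorted(m for m, r in roles.items() if r == "mixed")

    track: List[LabelledInterval] = []
    for lnc_id in sorted(truth.planted):
        gene = annotation[lnc_id]
        direction = (
            "down_on_differentiation"
            if truth.planted[lnc_id] == "synthetic_up"
            else "up_on_differentiation"
        )
        inverse_pool = up_pool if direction == "down_on_differentiation" else down_pool
        n_true = min(int(rng.integers(2, 5)), len(inverse_pool))
        n_decoy = min(int(rng.integers(1, 4)), len(mixed_pool))
        true_mirnas = sorted(rng.choice(inverse_pool, size=n_true, replace=False).tolist())
        decoy_mirnas = sorted(rng.choice(mixed_pool, size=n_decoy, replace=False).tolist())
        site_counts = {}
        exons = [e for e in gene.exons if e.length >= 40] or [
            max(gene.exons, key=lambda e: e.length)
        ]
        for mid in true_mirnas + decoy_mirnas:
            n_sites = int(
                rng.integers(config.sites_per_pair_min, config.sites_per_pair_max + 1)
            )
            site_counts[mid] = n_sites
            for _ in range(n_sites):
                exon = exons[int(rng.integers(0, len(exons)))]
                width = min(int(rng.integers(10, 23)), exon.length)
                start = int(rng.integers(exon.start, exon.end - width + 1))
                track.append(
                    LabelledInterval(
                        GenomicInterval(exon.chrom, start, start + width, gene.strand),
                        mid,
                    )
                )
        truth.cerna[lnc_id] = {
            "direction": direction,
            "truly_inverse": true_mirnas,
            "decoys": decoy_mirnas,
            "site_counts": site_counts,
        }
    track.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.label))
    return track, table


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SimulationConfig = SimulationConfig()) -> SimulatedBundle:
    """Run the whole generator; the config seed determines every value."""
    rng = np.random.default_rng(config.seed)
    annotation, truth, chrom_lengths = generate_annotation(config, rng)
    datasets = generate_expression(config, annotation, truth, rng)
    peaks = generate_peaks(config, annotation, truth, rng, chrom_lengths)
    track, table = generate_mirna_data(config, annotation, truth, rng)
    return SimulatedBundle(
        config=config,
        annotation=annotation,
        datasets=datasets,
        peaks=peaks,
        target_track=track,
        mirna_fold_ratios=table,
        truth=truth,
        chrom_lengths=chrom_lengths,
    )


def write_bundle(bundle: SimulatedBundle, outdir) -> Path:
    """Serialise a bundle to the on-disk formats the pipeline consumes.

    Writes annotation.gtf, one FPKM TSV per dataset, one peak BED per TF,
    the miRNA target track and fold-ratio table, ground_truth.json and a
    manifest.yaml tying everything together.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(bundle.annotation, outdir / "annotation.gtf")

    dataset_entries = []
    for ds in bundle.datasets:
        table_path = outdir / f"expr_{ds.name}.tsv"
        df = ds.fpkm.copy()
        df.index.name = "gene_id"
        df.to_csv(table_path, sep="\t", float_format="%.6g")
        dataset_entries.append(
            {
                "name": ds.name,
                "table": table_path.name,
                "control_samples": list(ds.control_samples),
                "treated_samples": list(ds.treated_samples),
                "treatment_direction": ds.treatment_direction,
            }
        )

    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    peak_entries = {}
    for tf, collection in sorted(bundle.peaks.items()):
        bed_path = peaks_dir / f"{tf}.bed"
        write_bed([LabelledInterval(p, tf) for p in collection.peaks], bed_path)
        peak_entries[tf] = f"peaks/{tf}.bed"

    write_bed(bundle.target_track, outdir / "mirna_sites.bed")
    ratios = bundle.mirna_fold_ratios.copy()
    ratios.index.name = "mirna_id"
    ratios.to_csv(outdir / "mirna_fold_ratios.tsv", sep="\t", float_format="%.6g")
    bundle.truth.save(outdir / "ground_truth.json")

    manifest = {
        "genome_build": bundle.annotation.genome_build,
        "annotation": "annotation.gtf",
        "chrom_lengths": dict(bundle.chrom_lengths),
        "datasets": dataset_entries,
        "peaks": peak_entries,
        "mirna_sites": "mirna_sites.bed",
        "mirna_fold_ratios": "mirna_fold_ratios.tsv",
        "ground_truth": "ground_truth.json",
    }
    manifest_path = outdir / "manifest.yaml"
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
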