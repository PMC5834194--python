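import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncswitch.expression import ExpressionDataset
from lncswitch.genes import GeneAnnotation, GeneModel
from lncswitch.intervals import GenomicInterval
from lncswitch.simulate import SimulationConfig, generate_bundle

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(name, direction, data, n_control=None):
    """Build an ExpressionDataset from {gene: (control values, treated values)}."""
    genes = list(data)
    ctrl_n = len(next(iter(data.values()))[0]) if n_control is None else n_control
    trt_n = len(next(iter(data.values()))[1])
    ctrl_cols = [f"{name}_c{i}" for i in range(ctrl_n)]
    trt_cols = [f"{name}_t{i}" for i in range(trt_n)]
    rows = [list(data[g][0]) + list(data[g][1]) for g in genes]
    fpkm = pd.DataFrame(rows, index=genes, columns=ctrl_cols + trt_cols, dtype=float)
    return ExpressionDataset(
        name=name,
        fpkm=fpkm,
        control_samples=ctrl_cols,
        treated_samples=trt_cols,
        treatment_direction=direction,
    )


def make_gene(gene_id, chrom, start, end, strand="+", biotype="lncRNA", exons=None):
    span = GenomicInterval(chrom, start, end, strand)
    exon_ivs = (
        [GenomicInterval(chrom, s, e, strand) for s, e in exons] if exons else None
    )
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=biotype,
        span=span,
        exons=exon_ivs or [span],
    )


def make_annotation(*genes):
    annotation = GeneAnnotation(genome_build="test")
    for g in genes:
        annotation.add(g)
    return annotation


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic study, shared across tests."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
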