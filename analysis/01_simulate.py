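#!/usr/bin/env python
"""Generate the synthetic multi-dataset study used by the downstream steps.

Produces one complete input bundle under scratch/synthetic_study/ (it is
regenerated deterministically from the seed, so it is not kept under
version control): a gene annotation with 300 lncRNAs and 100 coding
genes, one synthetic-direction and two contractile-direction smooth-muscle
FPKM datasets plus one skeletal differentiation dataset (4 vs 4 samples
each), ChIP-seq peaks for 20 transcription factors (3 truly enriched),
a miRNA target track and fold-ratio table, and the ground-truth manifest.
"""

from pathlib import Path

from lncswitch.simulate import SimulationConfig, generate_bundle, write_bundle

ROOT = Path(__file__).resolve().parents[1]
OUTDIR = ROOT / "scratch" / "synthetic_study"
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    bundle = generate_bundle(config)
    manifest = write_bundle(bundle, OUTDIR)
    truth = bundle.truth
    print(f"seed {SEED}: wrote bundle to {OUTDIR}")
    print(f"manifest: {manifest}")
    print(f"datasets: {[d.name for d in bundle.datasets]}")
    print(
        f"planted candidates: "
        f"{sum(c == 'synthetic_up' for c in truth.planted.values())} synthetic_up, "
        f"{sum(c == 'contractile_up' for c in truth.planted.values())} contractile_up"
    )
    print(f"truly enriched TFs: {', '.join(truth.enriched_tfs)}")
    print(
        f"nuisance genes: {len(truth.zero_inflated)} zero-inflated, "
        f"{len(truth.low_abundance)} low-abundance"
    )


if __name__ == "__main__":
    main()
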