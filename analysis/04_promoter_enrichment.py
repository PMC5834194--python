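#!/usr/bin/env python
"""Test transcription factors for enrichment in candidate promoters.

Extracts the strand-aware promoter window (-2,000..+500 around the TSS)
of every significant candidate, intersects the windows with each TF's
ChIP-seq peaks, and runs the one-sided Fisher exact test between the
synthetic_up and contractile_up promoter sets in both directions.  TFs
with p < 0.1 are reported.  Reads results/candidates.tsv; writes
results/tf_enrichment.tsv.
"""

from pathlib import Path

from lncswitch.evaluate import score_enrichment
from lncswitch.io import load_annotation, load_manifest, load_peak_collections
from lncswitch.pipeline import _write_tsv, read_tsv
from lncswitch.promoter import enrichment_table, peak_incidence, promoter_region, tf_enrichment
from lncswitch.simulate import GroundTruth

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synthetic_study"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = load_manifest(BUNDLE / "manifest.yaml")
    annotation = load_annotation(manifest)
    peak_sets = load_peak_collections(manifest)
    candidates = read_tsv(RESULTS / "candidates.tsv")
    significant = candidates[candidates["significant"]].reset_index(drop=True)

    promoters = [promoter_region(annotation[g]) for g in significant["gene_id"]]
    incidence = peak_incidence(promoters, list(peak_sets.values()))
    labels = dict(zip(significant["gene_id"], significant["phenotype_class"]))
    results = tf_enrichment(incidence, labels, alternative="synthetic_up")
    results += tf_enrichment(incidence, labels, alternative="contractile_up")
    _write_tsv(enrichment_table(results), RESULTS / "tf_enrichment.tsv")

    called = [r for r in results if r.p_one_sided < 0.1]
    for r in sorted(called, key=lambda r: r.p_one_sided):
        print(
            f"{r.tf_name}: enriched in {r.enriched_in} "
            f"(a={r.a}, b={r.b}, c={r.c}, d={r.d}, p={r.p_one_sided:.3g})"
        )
    truth = GroundTruth.load(BUNDLE / "ground_truth.json")
    syn_results = [r for r in results if r.enriched_in == "synthetic_up"]
    scores = score_enrichment(syn_results, truth, alpha=0.1)
    print(
        f"recall of truly enriched TFs: {scores['recall']:.2f} "
        f"({sorted(scores['recovered'])}); false calls: {scores['false_calls']}"
    )
    print(f"table -> {RESULTS / 'tf_enrichment.tsv'}")


if __name__ == "__main__":
    main()
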