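#!/usr/bin/env python
"""Compare candidate direction between smooth and skeletal muscle.

For each significant candidate, asks whether its change upon skeletal
differentiation (myoblast -> myotube) points the same way as its smooth-
muscle change toward the contractile phenotype.  The skeletal call reuses
the selection thresholds with the relaxed single-dataset p cut-off of 0.2.
Reads results/candidates.tsv; writes results/cross_tissue.tsv.
"""

from pathlib import Path

from lncswitch.evaluate import score_cross_tissue
from lncswitch.io import load_datasets, load_manifest
from lncswitch.pipeline import _write_tsv, read_tsv
from lncswitch.selection import SelectionThresholds, cross_tissue_compare
from lncswitch.simulate import GroundTruth

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synthetic_study"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = load_manifest(BUNDLE / "manifest.yaml")
    skeletal = next(
        d for d in load_datasets(manifest)
        if d.treatment_direction == "toward_differentiated"
    )
    candidates = read_tsv(RESULTS / "candidates.tsv")
    significant = candidates[candidates["significant"]].reset_index(drop=True)
    comparison = cross_tissue_compare(significant, skeletal, SelectionThresholds())
    _write_tsv(comparison, RESULTS / "cross_tissue.tsv")
    tally = comparison["status"].value_counts().to_dict()
    print(
        f"{tally.get('same_direction', 0)} same direction, "
        f"{tally.get('opposite_direction', 0)} opposite, "
        f"{tally.get('not_comparable', 0)} not comparable "
        f"(of {len(comparison)} significant candidates)"
    )
    truth = GroundTruth.load(BUNDLE / "ground_truth.json")
    scores = score_cross_tissue(comparison, truth)
    print(
        f"direction-call accuracy vs truth: {scores['accuracy']:.3f} "
        f"({scores['n_correct']}/{scores['n_compared']})"
    )
    print(f"table -> {RESULTS / 'cross_tissue.tsv'}")


if __name__ == "__main__":
    main()
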