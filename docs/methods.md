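# Methods

## Problem and model

Vascular smooth muscle cells (VSMCs) switch reversibly between a
proliferative *synthetic* phenotype and a differentiated *contractile*
phenotype.  Individual differentiation experiments disagree strongly at
the level of single lncRNAs, so the pipeline treats each dataset's known
treatment direction as prior information and demands *directional
concordance*: a candidate must move toward the same phenotype in every
dataset once the sign convention of each treatment is taken into account.
The default design has one dataset whose treatment induces the synthetic
phenotype (growth-factor-like), two that induce the contractile phenotype
(myocardin-like, TGF-β-like), and one skeletal-muscle differentiation
dataset used only for the cross-tissue comparison.

All genomic coordinates are 0-based half-open (BED convention); GTF input
is converted at the parsing boundary.  Genes are collapsed to gene level:
one span, the union of exons, TSS at the 5' end of the span.

## Selection procedure and its parameters

| parameter | default | meaning |
|---|---|---|
| `min_avg_fpkm` | 5 FPKM | abundance: a gene is dropped only when its mean FPKM over all samples is below this in **every** dataset (strict `<`); an "any dataset" policy is available by flag |
| `min_abs_log2fc` | 0.5 | per-dataset fold-change magnitude; strict inequality, so ±0.5 exactly never qualifies |
| `zero_fraction` | 0.5 | a fold change is invalid when ≥ this fraction of the control (denominator) samples are zero |
| `pseudocount` | 0 | added to both group means before the ratio; the zero-denominator rule, not a pseudocount, guards against division blow-ups |
| `p_strict`, `n_strict` | 0.1, 2 | "significant" needs p below `p_strict` in at least `n_strict` datasets … |
| `p_loose` | 0.3 | … and below `p_loose` in every dataset |
| `p_skeletal` | 0.2 | single-dataset p cut-off for the skeletal comparison |

The per-dataset test is a two-tailed Welch (unequal-variance) t-test on
per-sample FPKM.  Welch is the safer choice at n = 2–4 per group; with
both groups at zero variance the statistic is undefined and the record is
assigned p = 1.0 with a warning, and groups of fewer than two samples get
an undefined p that fails every significance clause.  No multiple-testing
correction is applied — the tiered raw-p rule *is* the procedure; a BH
column can be added downstream but never gates selection.

Two genuinely ambiguous readings are resolved as follows and exposed as
configuration.  First, "at least `n_strict` of the datasets" is taken as
≥ 2 of 3 rather than all 3, because requiring all three at p < 0.1 would
make the p < 0.3 clause vacuous.  Second, the abundance filter removes a
gene only when it is weak in *all* datasets, the permissive reading; the
strict reading ("any") is one flag away.

Candidate ranking within each phenotype class is by descending mean
|log2fc| across datasets; the cross-dataset summary used for the
cross-tissue sign comparison is the mean of the per-dataset fold changes
re-oriented so that positive always means "toward contractile".  The
cross-tissue step calls a candidate *comparable* when the skeletal
dataset supports a reliable call — abundance, |log2fc| and `p_skeletal`
all passed with a valid denominator — which quantifies an otherwise
informal "reliable expression in both tissues" requirement.

## Promoter enrichment

The promoter is the window from 2,000 bp upstream to 500 bp downstream of
the TSS, measured along the transcription direction: `[tss−2000,
tss+500)` on `+`, and its exact mirror about the 5' base, `[tss−499,
tss+2001)`, on `−`; windows are clipped at chromosome boundaries and
candidate promoters are treated independently even if they overlap.
A TF hits a promoter when ≥ 1 peak overlaps it by ≥ 1 bp (binary
incidence; multiple peaks count once; no minimum overlap fraction).
Enrichment between the synthetic-up and contractile-up promoter sets is
the exact one-sided hypergeometric tail P(X ≥ a), computed for both
directions and reported with a 0.1 highlighting threshold, uncorrected.

## Cis-acting and ceRNA evidence

The nearest coding gene minimises the span-to-span gap (0 when spans
overlap), strand- and orientation-agnostic; ties break toward the smaller
start coordinate, then lexicographic gene id.  The cis-acting evidence is
the Pearson correlation of lncRNA and neighbour log2 fold changes across
≥ 3 conditions (the four datasets by default); zero-variance vectors give
an undefined correlation, reported as missing.

ceRNA nomination counts target-track intervals overlapping ≥ 1 bp of any
exon (an interval spanning two exons counts once; intronic intervals do
not count; a gene-span mode exists by flag since site predictions live on
transcripts).  A miRNA passes the inverse-expression filter for a lncRNA
that goes down upon differentiation when its fold ratio exceeds 1 at
*every* time point (mirror rule for up-lncRNAs); the all-time-points
requirement is the default because the evidence table carries exactly two
time points, and an any-time-point mode is a flag.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not real sequences.  Genes (300 lncRNAs, 100 coding by default) are laid
out in blocks ≥ 10 kb apart on three 4-Mb chromosomes; each planted
lncRNA shares its block with its designated coding neighbour at a
0.5–2 kb gap, which makes the neighbour the unique nearest coding gene by
construction.  Baseline FPKM is log-normal (ln-scale mean 3, sd 1, median
≈ 20 FPKM); each dataset applies an extra per-gene log-normal jitter
(sd 0.25) emulating cross-experiment variability; within-group sample
noise is multiplicative log-normal with CV 0.1 and 4 samples per group.
Planted candidates (15 synthetic-up, 10 contractile-up — the scale of a
realistic shortlist) receive a ±1 log2 effect with the sign pattern of
their class; their neighbours share the effect (cis-acting behaviour);
each planted gene is assigned a same-direction (probability 0.6) or
opposite-direction skeletal effect.  Planted genes and neighbours have
their baseline floored at 20 FPKM so that recovery measures the selection
rules rather than the baseline draw.  Nuisance genes exercise the
filters: 15 % of lncRNAs are kept below 5 FPKM everywhere, and 5 % are
zero-inflated — half of every smooth-muscle control group set to zero
*and* given a candidate-like effect, so only the zero-denominator rule
can exclude them.  Peaks: 20 TFs, 3 truly enriched (hit probability 0.9
on synthetic-up promoters vs 0.1 background, plus 20 random genomic peaks
per TF).  miRNAs: 30 families split into consistently-up,
consistently-down and mixed-ratio roles over two time points; planted
lncRNAs get 1–4 exonic sites for 2–4 truly inverse families and 1–3
mixed-role decoys.

Everything is drawn from one seeded NumPy generator, so a config is
byte-reproducible down to the serialized files.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: FPKM estimation noise and gene-length
biases, correlated expression between neighbouring null genes, realistic
peak width/occupancy distributions, annotation errors, and any sequence
content.  Recovery statistics on this design demonstrate the correctness
and calibration of the rules, not the biological yield of the thresholds
on a given GEO dataset.

## Numerical and design choices

- Abutting intervals do not overlap (half-open semantics throughout);
  overlap tests ignore strand.
- Fisher p-values use the exact hypergeometric survival function; the two
  one-sided directions share the point probability (p₁ + p₂ ≥ 1).
- Fold-change vectors containing non-finite values (a zero group mean
  with pseudocount 0) yield a missing correlation rather than an error.
- Gene identifiers are assumed unique across the merged annotation; an
  annotation mixing lncRNA and coding sources must be reconciled to a
  single GTF upstream of this package.
- Unknown biotypes ingest as `other` and are excluded from all stages
  rather than raising.
- Problem sizes in the test and acceptance suites (default-scale studies
  over 10–20 seeds) were chosen to keep a full run on one CPU in tens of
  seconds while leaving every rule with non-trivial work.

## Repository shape

The package under `src/lncswitch/` holds all computation; the numbered
scripts under `analysis/` are thin narrative drivers that run one study
end to end and write their tables under `results/`; the regenerable
synthetic bundle lives under `scratch/` (not versioned).  The
`lncswitch` console script exposes the same stages for use on real
manifests.

## Known limitations

- The selection is threshold-based by design (no count models, no
  dispersion estimation); it reproduces an FPKM-rule procedure and
  inherits its sensitivity to normalisation quality.
- With two samples per group (common in public datasets) the Welch test
  is underpowered and the tiered rule leans heavily on the fold-change
  concordance; the generator's four-samples-per-group default is the
  optimistic end of realistic.
- Promoter enrichment treats promoters as exchangeable units; shared or
  bidirectional promoters among candidates would violate the 2×2
  independence assumption.
- The ceRNA stage consumes a precomputed target track; it performs no
  seed-match prediction and no coding-potential assessment.
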