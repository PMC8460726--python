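# Methods

## Screen model

A pooled prime-editing screen couples each pegRNA to a surrogate target:
the lentivirally integrated amplicon carries, in order, a constant 5′
anchor, the 47-nt *wide target* (4 nt upstream flank, 20-nt protospacer,
NGG PAM, 20 nt downstream flank), a constant 3′ anchor, 4 nt of
pair-specific sequence, and the pair's unique 18-nt barcode.  The Cas9
H840A nickase cuts between protospacer positions 17 and 18; all edit and
window coordinates are expressed as offsets from that nick (offset 0 = the
first base 3′ of the nick; internal coordinates are 0-based half-open).

### Demultiplexing

Reads are assigned by scanning for an exact occurrence of the 22-nt key
(4-nt upstream sequence ++ barcode).  Exact match only — the key is the
only identifier the protocol defines, and tolerating mismatches would risk
crediting reads to the wrong pair's denominator.  A read containing two
distinct keys is ambiguous and discarded; `N` never matches a key
position.  The scan is position-independent, so prepending sequence never
changes an assignment.

### Outcome classification

The wide-target region is excised between exact matches of the 10-nt
flanking anchors; reads where either anchor is missing are discarded and
excluded from all denominators.  Classification precedence:

1. region == edited reference → **intended** (an intended insertion or
   deletion alone is intended, not an indel);
2. region == unedited reference → **wild type**;
3. length differs from both references, or the alignment against the
   closer reference (edlib, fewest edits; ties favor the unedited
   reference) contains an insertion/deletion → **indel** — so an intended
   edit accompanied by an extra indel is an indel;
4. otherwise → **unintended edit** (substitution-only mismatch).

Frequencies are read-count ratios × 100.  Pairs with fewer than 100
assigned reads are excluded (99 reads fail, 100 pass).  Per-position
substitution profiling covers nick offsets −10..+25 inclusive.  That
window is conventionally described as a "40-nt region", but the inclusive
integer span contains 36 positions; the stated offsets are implemented and
the endpoints are configurable.  Only indel-free reads contribute
substitution counts (avoiding double counting with the indel frequency),
and positions belonging to an intended substitution are skipped.  The
summary rate is the across-position mean of the counts divided by total
reads; averaging is over positions (the alternative reading — averaging
over replicates — would belong upstream of this package).

### Adjusted fold change

`(hyPE2 % + 0.1%) / (PE2 % + 0.1%)`.  The 0.1-percentage-point pseudocount
keeps the ratio defined at a 0% baseline and damps fold changes computed
from near-noise efficiencies.  It is strictly increasing in the hyPE2
efficiency, strictly decreasing in the PE2 efficiency, and converges to
the raw ratio once both efficiencies dominate the pseudocount.  Pairs with
PE2 < 1% are stratified out of fold-change statistics (boundary: 1.0% is
kept, since the exclusion is phrased as "lower than 1%"); within the
excluded stratum the subset with hyPE2 ≥ 1% is reported as rescued.

## Featurization (1,820 features)

The published total is 1,820; the per-group breakdown is not published, so
this package defines an explicit registry (serialized with every model,
checksummed in manifests) that reproduces the named ingredients and the
printed total:

| group | content | count |
|---|---|---|
| POSDEP_MONO_TARGET | one-hot nucleotides, 47-nt wide target | 188 |
| POSDEP_DI_TARGET | one-hot dinucleotides, 46 adjacent positions | 736 |
| POSDEP_MONO_EXT | one-hot nucleotides, 42-nt extension window | 168 |
| POSDEP_DI_EXT | one-hot dinucleotides, 41 positions | 656 |
| POSINDEP_COUNTS | mono+di counts for target, PBS, RT template | 60 |
| SCALARS | 4 Tm, 3 GC counts, 3 GC fractions, MFE, on-target score | 12 |

The pegRNA 3′ extension (RT template ++ PBS, 5′→3′) is right-aligned in
the 42-nt window and left-padded with all-zero columns, so the PBS always
occupies the same positions regardless of RT-template length.  An
alternative breakdown summing to 1,820 can be swapped in through the
registry without touching the learners.

**Melting temperatures** use `Bio.SeqUtils.MeltingTemp.Tm_NN` with its
default parameter set (Allawi & SantaLucia 1997 nearest-neighbor table,
50 mM Na⁺, 25 nM strands, entropy-based salt correction).  The scalar set
is: Tm of the PBS (the duplex it forms with the nicked target strand), Tm
of the RT template against the DNA strand it templates (RNA/DNA-hybrid
table, Sugimoto 1995), Tm of the full extension, and the PBS−RT
difference.

**Self-folding MFE** of the extension (as RNA) defaults to the ViennaRNA
MFE; a bundled minimal model is available as a fallback engine:
Watson-Crick pairs only, hairpin loops ≥ 3 nt, free energy = sum of
stacking energies of directly nested pairs (Turner-style values), solved
exactly by dynamic programming.  Under either engine the MFE is ≤ 0 (the
open chain has energy 0) and a sequence without a complementary stretch of
at least 2 nt cannot fold below 0.

**On-target score** is a plug-in: a callable on the spacer, or a
precomputed per-pair table; with neither, a constant column (default 0)
is emitted and a warning recorded in the manifest.  Bundling or training
the external deep on-target model is out of scope.

## Model selection

Data are split into train/test at the group level, where groups are
connected components over shared spacer or shared wide target — a
PAM-silent variant therefore always travels with its parent.  The default
test fraction is 0.15 (at the 665-pegRNA library scale this leaves ≈ 568
pegRNAs for training); sizes land within one group of the request.

Grids per learner: boosted trees (XGBoost and sklearn GBRT) —
{50, 100} estimators × {5, 10} depth × {1, 2} min-leaf × {0.1, 0.2}
learning rate = 16; random forest — the same minus learning rate, times
{all, sqrt, log2} max-features = 24 (the accompanying prose also says "16
models"; the full product is enumerated and the discrepancy is recorded in
the run manifest); L1/L2/L1L2 linear — 16 penalties log-evenly spaced in
[10⁻⁶, 10⁶]; RBF-SVM — 4 C × 4 γ log-evenly spaced in [10⁻³, 10³] = 16.

Selection is fivefold grouped CV on the training partition (group-aware
folds, for consistency with the split rule), scored by mean across-fold
Spearman ρ; constant-prediction folds score 0 with a warning; ties go to
the smallest grid index.  Linear and SVM learners are standardized with
training-fold statistics and fit on the log fold change (the target is a
ratio); tree learners take the raw fold change — Spearman scoring is
invariant either way, and predictions are back-transformed for export.
The test partition is touched exactly once per learner, after all
selection decisions; the audit log records the order and tests assert
zero spacer/target overlap across the split and across folds.

Attribution uses exact TreeSHAP as implemented inside XGBoost
(`pred_contribs`); per-pair attributions plus the bias term reproduce each
prediction, and the global ranking is by mean |attribution|.  The fold
increase is additionally summarized in PBS-Tm bins <20, [20,30), [30,40),
[40,50), ≥50 °C (left-closed) with n, median, quartiles and 10th/90th
percentiles.  Although the attribution model is sometimes labeled a
classifier in figure legends elsewhere, the task here is fold-increase
prediction, so the regressor is used.

## Synthetic screens

The generators exist so every stage runs and is tested without downloads;
all are seed-deterministic.

* **Library designer** — defaults mirror the screened library: 507 base
  pegRNAs in a 100:100:200 deletion:insertion:substitution mix, 158/507
  re-issued as PAM-silent variants (an extra synonymous G→C in the PAM,
  written into the RT template), three barcodes per pegRNA: 665 pegRNAs,
  1,995 oligos.  Barcodes are sampled with pairwise Hamming distance ≥ 3
  (rejection sampling with bounded retries).  PBS lengths are drawn
  uniformly from 7–17 nt and RT-template lengths from 10–23 nt — typical
  pegRNA design ranges.  PBS and RT template are reverse complements of
  the appropriate target strands, so PBS Tm tracks local target
  composition as it does in real designs.
* **Read simulator** — per pair, `depth` reads are drawn multinomially
  over {intended, unintended substitution, indel, wild type}; planted
  labels are emitted as ground truth.  Per-base substitution errors
  (default 10⁻³) are applied only outside the 22-nt key and outside the
  wide target: key errors would silently shrink assignment truth, and
  wide-target errors would relabel outcomes, whereas anchor errors only
  discard reads, which leaves every frequency unbiased.  An optional mode
  lets errors hit the key so assignment loss can be measured.  Spurious
  indels are redrawn if their length collides with the edited reference,
  keeping planted labels unambiguous.
* **Fold-change simulator** — `log F = intercept + slope · Tm(PBS) + ε`,
  ε ~ N(0, σ²), defaults intercept 1.0, slope −0.02 /°C, σ 0.15: folds
  around 1–2.5× across the realistic PBS-Tm range, decreasing as the PBS
  binds more tightly, at a noise level that leaves the effect clearly
  recoverable.  PE2 baselines come from a mixture with a 20% sub-1%
  stratum (uniform 0.01–0.99%) and a log-uniform 1–40% body; the hyPE2
  efficiency follows from the planted fold and is floored at 0 (with the
  default scales the floor is essentially never reached).

**What passing tests do and do not show.**  The simulators plant exactly
the structures the pipeline is designed to recover: error-free keys,
single clean edits, a single linear Tm effect.  Real screens add PCR and
recombination chimeras, position-dependent sequencing error, batch
effects, and fold-change structure far richer than one covariate.
Recovery on these fixtures therefore validates the arithmetic, the
bookkeeping and the leakage hygiene of the pipeline — not the biological
accuracy of any particular trained model.

## Problem sizes and numerical choices

Test and acceptance workloads use 100 pairs at depth 5,000 for end-to-end
rate recovery (mean absolute error < 1 pp; binomial sampling alone gives
≈ 0.4 pp at 12%) and 600 pairs for the full seven-learner selection —
sizes chosen to match the scale of the screened libraries while keeping a
complete run comfortable on a laptop.  Coordinate conventions are 0-based
half-open throughout.  Degenerate inputs: zero-read pairs report an
undefined efficiency and are excluded; empty substitution windows and
sub-3-point test sets are errors; constant predictions score ρ = 0 with a
warning rather than NaN.  Lasso/ElasticNet use `max_iter` = 5,000 and
convergence warnings are suppressed during grid search (tiny penalties on
1,820 correlated columns legitimately stop at the iteration cap; the
configuration then simply scores worse).

## Known limitations

* Exact-match demultiplexing discards reads with any key-region error;
  with an 18+4-nt key and typical error rates this loses a few percent of
  depth but never miscredits a pair.
* Wide-target localization needs both 10-nt anchors intact; amplicon
  designs without conserved anchors would need a different excision rule.
* The feature registry reproduces the named feature groups and the printed
  total, but the original per-group breakdown is unpublished, so trained
  models are not weight-compatible with the original web tool.
* Paired-end merging, quality trimming, genome alignment, off-target site
  discovery and between-condition hypothesis testing are out of scope.
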