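# Methods

## Copy-number model and calling

Array-CGH measures per-clone log2 tumor/reference ratios. Calls are pure
per-clone thresholds — no segmentation or smoothing — because the analysis
this package implements is defined at the clone level:

| state | rule | default |
|---|---|---|
| amplification | log2 > `amp_min` | 1.0 (linear ratio > 2); alternate preset 1.5 for pangenomic screens |
| gain | `gain_min` < log2 ≤ `amp_min` | 0.25 |
| loss | log2 ≤ `loss_max` | −0.25 |
| neutral | otherwise | — |

The amplification cutoffs are the analysis-defining constants; the ±0.25
loss/gain bounds are a conventional single-copy aCGH choice (the analysis
chain does not pin them) and are configurable. Masked (missing) clones
carry a fifth state and are excluded from numerators and denominators.

**Frequency maps.** "Occurrence" is tumor-level per bin: within each
fixed-width bin (default 2 Mb) a tumor counts at most once per state, the
denominator is the number of tumors with at least one informative clone in
the bin, and a clone contributes to every bin it overlaps. Bins without
informative tumors are reported as missing, never as zero. An amplified
clone also counts as gained (an amplification is a copy-number increase).
This convention is robust to uneven clone density and matches per-interval
tumor frequencies.

**Amplicon extraction and consensus.** Amplicons are maximal runs of
consecutive amp-state clones (runs separated by ≤ `max_gap_clones` non-amp
clones may be merged; default 0, intended for tiling data). The consensus
region is the strict intersection, across all amplicon-bearing tumors, of
each tumor's merged amplified footprint (`min_support` = all). If the
strict intersection is empty, the region of maximal support is returned
(widest first, leftmost on ties) with its support count — a documented
fallback, not the default interpretation. The returned region is always
contained in every supporting tumor's footprint.

Coordinates are 0-based half-open internally and in BED files; reports use
Mb. Gene queries use half-open overlap (a gene abutting the region end is
excluded) with an optional flank.

## Synthetic cohorts

Every generator is a pure function of (parameters, seed); noise is Gaussian
on the log2 scale for both aCGH and expression data (the standard two-color
array approximation — the underlying study conditions state thresholds, not
noise models, so these are free but fixed choices). Defaults (seed 17):

- **Chromosome-3 cohort**: 214 abutting-spaced 150 kb clones over 0–199 Mb;
  26 tumors, of which 5 carry a focal 3q26.33 amplicon containing the
  181.9–184.6 Mb consensus (mean log2 2.0–3.1, differing outer limits) on
  top of a broad 3q26–qter gain (176–196 Mb, mean 0.45), 11 more carry the
  broad gain only, and 16 (~60%) carry a 3p loss at 8–10 Mb (mean −0.5);
  clone noise sd 0.1. With amplicon means ≥ 2 and gain means ≤ 0.6 the
  amp/gain call margin exceeds 5 noise standard deviations, so the
  amplified-carrier count at the peak clone is effectively seed-independent.
- **Tiling cohort**: abutting clones (default 50 kb) over 177–186 Mb; five
  tumors whose amplicon boundaries are the same five outer-limit pairs used
  by the chromosome-3 design, all containing the consensus; amp mean 2.5,
  noise sd 0.1. Boundary recovery error is bounded by one clone spacing.
- **Expression dataset**: 2000 genes × (20 tumors + 20 normals); per-gene
  baseline means N(8, 1), within-group noise sd 0.5; 50+50 differential
  genes at ±2 log2 units (SOX2 among the up-regulated), a 40-gene stemness
  module at +1.5, and a target block (40 activated / 20 repressed) coupled
  to the SOX2 row with coefficients ±0.8 plus N(0, 0.5) noise.
- **qPCR fixture**: nine candidate genes × (5 amplified + 2 gained + 2
  reference tumors), raw quantities with log-normal technical noise
  (sd 0.08 on the log scale). Amplified-tumor means put SOX2/SOX2OT well
  above 5-fold, six further genes between 2.8- and 4.2-fold, and LAMP3
  near 0.5-fold, so the recurrence-rule outcome is deterministic.
- **IHC fixture**: 51 cases — 34 with nuclear H-score strictly above 90
  (five of them amplicon-carrier-like: intensity 3, 85–95% positive), 5
  with strong exclusively-cytoplasmic staining, 12 normal-like or weaker.
  The composition is fixed; the seed only shuffles case order and
  within-stratum percentages.

The fixture compositions deliberately mirror the cohort compositions the
analysis was designed around (5/26 amplified, 34/51 activated, nine genes,
345/97/142-gene lists), so recovery tests double as worked examples; this
circularity is intentional and means the tests validate the *machinery*,
not the biology. The generators do not model dye bias, spatial artifacts,
batch effects, probe cross-hybridization, or heavy-tailed expression noise;
passing tests therefore demonstrate correctness of the computations under
idealized Gaussian conditions, not performance on real arrays.

For the correlated-target fixture the 248 non-coupled target genes are
decorrelated from the SOX2 profile by construction (their noise is
residualized against it). Without this, Benjamini-Hochberg false positives
among 248 null genes sitting beside 97 strongly correlated ones would make
the recovered count fluctuate by a few genes across seeds; residualization
makes the truth partition unambiguous and the count deterministic. Real
data offer no such guarantee — on real cohorts the recovered list size
inherits ordinary multiple-testing variability.

## Fold changes and driver rules

Per-gene fold change = linear quantity / geometric mean of the reference
tumors (geometric, because qPCR fold changes are log-scale quantities; an
arithmetic option exists since the choice of reference averaging is not
pinned by the analysis). The recurrence rules are independent counts over
exactly n = 5 evaluated tumors: fold change > 2 in ≥ 4 (recurrent) and
> 5 in ≥ 4 (strong). Both thresholds, k and n are parameters.

## Signatures

Differential signatures use Welch's unequal-variance t per gene,
Benjamini-Hochberg adjustment, and membership iff adjusted p < 0.05 and
|log2FC| ≥ 1, directed by the sign of the mean difference. This is a
transparent stand-in for black-box microarray pipelines; all three knobs
are exposed. `top_markers` ranks by |t| with stable lexicographic
tie-breaking. A per-gene detection-fraction diagnostic (fraction of tumors
above fold 2 vs the mean normal) reports how broadly a gene such as SOX2 is
over-expressed.

## Enrichment statistics

The hypergeometric overlap test is exact (no normal approximation) and the
universe is always explicit — enrichment universes are the genes present on
the (synthetic) platform, passed by the caller, never implied.

The enrichment score walks the ranked list, adding
|score|^p / Σ_hits |score|^p at set members and subtracting 1/(N − |S|)
elsewhere; ES is the signed maximum deviation from zero (positive branch
preferred on exact magnitude ties; all-zero score vectors fall back to
equal hit weights). The default weight p = 1; p = 0 gives the classic
unweighted KS variant used by the brute-force oracle tests.

Rankings come from signal-to-noise (class labels; sample s.d. with ddof 1,
zero-variance genes score 0 and are flagged) or Pearson correlation
(continuous phenotype, e.g. SOX2 expression). Permutation schemes:
*phenotype* (permute labels or the continuous profile; preserves gene-gene
correlation) when each class has ≥ 7 samples, else *gene-set* (random
same-size sets on the observed ranking); `auto` switches at that boundary
and the scheme used is recorded in every result. NES = ES / mean same-sign
permutation |ES|; nominal p is the same-sign permutation tail; FDR q
compares the pooled sign-normalized permutation NES distribution with the
observed NES values (positive and negative tails separately, clipped to
[0, 1]). With a single set the q-value reduces to the normalized
permutation tail. All permutation draws flow from one seeded generator, so
results are bit-reproducible. A fast hit-rank evaluation (only running-sum
values adjacent to hits can be extrema) makes 10^6 permutation ES
evaluations cheap; it is verified against the full walk in the tests.

Correlated-target recovery applies per-gene Pearson correlation to the
driver profile with BH adjustment at α = 0.05 across all tested target
genes, plus a sign constraint (activated targets must correlate
positively, repressed negatively). The per-gene rule is a documented
choice; set-level FDR from enrichment is reported separately. Signature
consolidation intersects the driver-overexpression signature with the
union of cohort signatures and records per-gene direction concordance.

The packaged 16-gene candidate-mediator list is literature curation,
shipped as a static text file and excluded from all statistics.

## IHC scoring

H-score = nuclear intensity (0–3) × percent positive nuclei ∈ [0, 300].
The intensity scale is assumed four-level (0–3); the underlying scoring
scheme does not state the number of levels. Activation requires the
H-score to strictly exceed the reference of 90 — the normal bronchial
pattern (strong staining, intensity 3, in 30% of cells) — so a tumor
indistinguishable from normal is not called activated. Cases with strong
(intensity 3) cytoplasmic staining and no nuclear signal are reported as a
separate exclusively-cytoplasmic category. Percentages are rounded to the
nearest integer and may sum to 100 ± (categories − 1).

## Packaged annotation

The 3q26.33 gene annotation is a synthetic approximation
(`data/chr3q26_genes.synthetic.bed`): nine RefSeq genes inside the
181.9–184.6 Mb listing interval, laid out in the documented genomic order
(FXR1, DNAJC19, SOX2OT, SOX2, ATP11B, DCUN1D1, MCCC1, LAMP3, B3GNT5), plus
flanking genes outside the interval. Which gene is the ninth of the
interval is not enumerated by the source analysis; MCCC1 (a real 3q27 gene
adjacent to LAMP3) fills that slot, and SOX2OT is counted among the nine.
The genome build is carried as free-text metadata and never resolved. The
five-tumor amplicon fixture (`data/amplicon_segments.synthetic.bed`) is
likewise synthetic; its five outer-limit pairs intersect at exactly
181.9–184.6 Mb.

## Pipeline and reproducibility

`run_pipeline` composes the stages in cohort order on simulated inputs and
emits a JSON report plus a text digest; every numeric field is the output
of exactly one stage function, and re-running a stage with the same inputs
reproduces the field. Provenance records the seed, a SHA-256 hash of the
canonical config JSON, and the package version; timestamps are excluded
from anything hashed. Problem sizes used by the test-suite simulations
(2000-gene matrices, 1000 permutations, 100 boundary-recovery replicates,
20 null replicates) keep the full suite under a minute on one CPU while
leaving comfortable statistical margins.

## Known limitations

- No CBS/HMM segmentation, ploidy/purity correction, or allele-specific
  copy number; calls are per-clone thresholds by design.
- The signature derivation is a stand-in, not a reimplementation of any
  specific microarray pipeline; absolute gene lists from real data will
  differ even if the enrichment conclusions do not.
- File-based end-to-end orchestration is not wired into `run_pipeline`
  (stage functions accept real data individually); GEO/SOFT and CEL
  parsing, Excel I/O and live signature-database queries are out of scope.
- The empirical FDR and uniformity checks validate calibration under the
  Gaussian generative model only.
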