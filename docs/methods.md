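# Methods

## Scope and data model

repfeat analyzes UMI-annotated TCR-β clonotype tables. A clonotype is a
distinct rearrangement keyed by (CDR3 nucleotide sequence, TRBV, TRBJ);
its abundance is the number of distinct UMI-labeled cDNA molecules, which
is robust to PCR amplification bias. Upstream read processing and UMI
consensus building are out of scope: the library starts from exported
clonotype tables (MiXCR-style or AIRR Rearrangement TSV). V/J calls are
normalized to segment level (allele suffix after `*` stripped, composite
multi-hit strings truncated at the first comma) because every analysis
operates per V segment. Duplicate (CDR3 nt, V, J) rows are merged by
summing counts with a logged warning, tolerating exporter quirks.

Nonfunctional clonotypes (stop codon, frameshift, length not a multiple of
three) are removed before *all* downstream metrics and frequencies are
renormalized. Amino-acid-level analyses require translatable junctions;
applying the same filter before diversity estimation keeps all metrics on
one clonotype universe. Whether nucleotide-level diversity should instead
include nonfunctional clonotypes is a defensible alternative; we chose
uniformity and note that rerunning diversity without the filter is a
one-line change (skip `filter_functional`).

## Comparability across samples

Two mechanisms make per-segment values comparable:

1. **Everywhere-covered V selection.** Only TRBV segments whose summed UMI
   count reaches `min_umi` in *every* sample of a subset are analyzed,
   avoiding biases from individual V-usage differences.
2. **Rarefaction.** Diversity and convergence are computed on slices
   downsampled without replacement to a fixed UMI depth (multivariate
   hypergeometric over clonotypes; clonotypes reduced to zero are
   dropped). Samples below the depth raise an explicit
   insufficient-coverage signal and are excluded *with a logged reason*,
   never silently. Default depths follow the UMI-based study design this
   pipeline supports: 1,000 UMIs per segment for diversity; 1,524 (RTE),
   1,063 (mature naïve CD4), 953 (naïve Treg) for per-segment
   convergence; publicity on whole samples at 23,000–31,000 UMIs taking
   the top 13,000 clonotypes. All depths are configuration values; the
   bundled synthetic studies use desk-scale depths (100 UMIs per segment,
   1,500 for publicity with top 300) consistent with their 2,500-UMI
   samples.

Abundance-weighted CDR3 features (strength, volume, charge, length, added
nucleotides) are computed on full slices rather than rarefied ones: a
UMI-weighted mean is an unbiased functional of the frequency distribution
and does not need equal depth.

## Feature definitions

- **Central window.** Physicochemical features use the five residues in
  the middle of CDR3 — the positions most likely to contact the
  peptide–MHC complex — starting at offset `floor((L−5)/2)` (ties resolve
  toward the N terminus). CDR3s shorter than five residues are excluded
  from window features only; they still count toward length, insertions
  and diversity.
- **Strength** is the fraction of window residues in {F, I, L, M, V, W,
  Y} (hydrophobic/aromatic, strongly interacting). **Charge** is the
  fraction in {D, E, K, R}; histidine is excluded because it is largely
  uncharged at physiological pH. **Volume** is the mean residue volume
  over the window on the Zamyatnin (1972) scale (Å³), shipped in
  `features.RESIDUE_VOLUME`.
- **Added nucleotides** (non-templated N insertions at V–D and D–J).
  When junction annotations are present (always true for simulated data)
  the count is exact: `(j_start − v_end) − |d_span|`. Otherwise it is
  estimated by germline alignment: the V match is the longest common
  *prefix* of the CDR3 with the germline V tail — under 3′-V exonuclease
  trimming it is the tail's end that is removed, so prefix alignment is
  the correct orientation — the J match the longest common suffix with
  the J head, and the D match the longest D-gene substring (≥ 3 nt, since
  shorter matches arise by chance) in the remaining middle. Negative
  remainders from overlapping matches clamp to zero with a logged
  anomaly. On simulated ground truth at insertion means 4+4 the blind
  estimator's mean absolute error is ≈ 0.7 nt (tested bound: ≤ 1.5 nt).
- **Weighting.** Per-slice feature values are `Σ wᵢxᵢ / Σ wᵢ` with
  `wᵢ` the UMI count (each cDNA molecule counts once); an unweighted mode
  exists. UMI weighting within a slice is equivalent to weighting by
  clonotype frequency.

## Diversity, convergence, publicity

- **Chao1** uses the bias-corrected form `S_obs + f₁(f₁−1)/(2(f₂+1))`,
  defined even when no doubletons exist.
- **Normalized Shannon–Wiener** is Pielou evenness `H/ln S_obs`, the
  common repertoire-analysis convention; it requires at least two
  clonotypes.
- **Convergence** is (#distinct CDR3 nt)/(#distinct CDR3 aa) on an
  equal-depth slice; ≥ 1 always, with equality exactly when translation
  is injective. The equivalent formulation "mean number of nucleotide
  variants per amino-acid clonotype" is the same ratio.
- **Publicity** counts shared amino-acid CDR3s (not aa+V) between the
  top-N clonotypes of two samples at equal depth, as raw counts rather
  than frequency-weighted overlap. Per-sample downsampling seeds are
  derived from the master seed and the sample id, making the statistic
  symmetric in the pair and reproducible.

## Z-scoring and inference

Within each (subset, V segment, feature) stratum, values are Z-scored
across samples using the population standard deviation; degenerate strata
(sd = 0) map to all-zero scores and singleton strata are dropped with a
warning. This removes V-segment-specific baselines so segments can be
pooled.

Group testing treats each (sample, V segment) Z-score as one observation
(pooled-segments mode, mirroring per-segment figure panels); a
mean-over-segments mode (one value per sample) feeds the PCA and is
available for sensitivity analysis. Segments of one sample are not fully
independent, so pooled-mode p-values are mildly anti-conservative in
principle; the null-fixture calibration (below) shows the realized
false-positive rate stays well under control in the simulated regime.

Three-cohort comparisons use the Kruskal–Wallis test (midranks, tie
correction, chi-square tail with k−1 df) followed by Dunn's pairwise
z-tests with tie-corrected pooled-variance, adjusted by
Benjamini–Hochberg within each feature's family of three pairs
(study-wide adjustment is available via `adjust_scope`). Two-cohort
comparisons use the Wilcoxon rank-sum test: exact enumeration when
n₁+n₂ ≤ 12 without ties, else the normal approximation with tie-corrected
variance and continuity correction. All tests are two-sided. Tail
probabilities come from standard special-function routines
(`scipy.special.chdtrc`, `ndtr`). Under null simulations (10,000 runs)
both tests reject at 4.4–4.8% at α = 0.05.

PCA centers (and by default unit-scales) the samples × features matrix of
segment-averaged Z-scores, decomposes by SVD, and fixes signs so each
loading column's largest-magnitude entry is positive. Explained-variance
fractions sum to one over the returned components. Constant columns stay
at zero rather than dividing by zero.

## Synthetic repertoire generator

The generator emulates only the statistical structure the metrics
consume; it models no thymic selection, pMHC specificity or biological
Treg biology.

- **Germline.** A deterministic synthetic set (12 TRBV, 2 TRBD, 13 TRBJ)
  built from a seed; real IMGT references are deliberately not bundled or
  fetched. Every segment length is a multiple of three and translates
  stop-free, each V tail starts at a cysteine codon and each J head ends
  at a phenylalanine codon, so untrimmed junctions are automatically in
  frame.
- **Recombination.** V and J are drawn from usage vectors (uniform by
  default), D uniformly; ends are trimmed uniformly within configured
  bounds (defaults 4/3/4 nt); N-insertion lengths are geometric on
  {0,1,2,…} with configurable means (default 4+4 nt) — the simplest
  parametric forms consistent with random exonuclease trimming and
  non-templated addition, a deliberate simplification relative to
  full generative models of V(D)J recombination. Inserted nucleotides are
  drawn as codons whose logits are shifted by `strength_bias` on
  strong-residue codons. Out-of-frame or stop-containing junctions are
  rejected and resampled (bounded retries). Note the rejection step
  conditions the realized insertion-length distribution (the accepted
  total must satisfy the frame constraint), so the mean of accepted
  insertion totals sits slightly below the unconditional geometric mean
  (≈ 7.5 vs 8 at means 4+4); tests compare against an oracle that mirrors
  the acceptance sampling.
- **Convergence.** With probability `convergence_rate`, a new clonotype
  synonymously recodes an existing one (same amino acids and V/J,
  different nucleotides) — the literal mechanism behind a nucleotide-
  per-amino-acid ratio of approximately 1/(1−rate).
- **Clone sizes.** Lognormal (default σ = 1.2) or Pareto weights,
  converted to integer UMI counts ≥ 1 summing *exactly* to the configured
  depth by largest-remainder rounding.
- **Ground truth.** Every generated clonotype records its true junction
  boundaries and insertion total, enabling estimator-recovery tests.

### Fixture studies

`make_fixture_study` builds three-cohort studies (XLA / young / old, one
subset, default naïve Treg) at desk scale: 8 samples per cohort, 500
clonotypes, 2,500 UMIs per sample — sizes chosen so that a full study
simulates and analyzes in a few seconds while leaving ~200 UMIs per V
segment, consistent with the 100-UMI rarefaction depth. The `null` preset
gives all cohorts identical parameters. The `xla_like` preset alters the
XLA cohort in the directions reported for B-cell-deficient naïve Treg
repertoires: clonotypes halved to 250 (lower richness and evenness),
convergence rate 0 → 0.15, insertion means 4 → 2 nt per junction (shorter
CDR3s, fewer added nucleotides), and `strength_bias` 0 → 3.0. The bias
magnitude is chosen to near-saturate the inserted-codon distribution
(~93% strong-residue codons): because the bias acts only on inserted
nucleotides and the altered cohort simultaneously has *fewer* of them,
a mild bias would inject an effect too small to be a meaningful test
signal at 8 samples per cohort; the saturating value makes the injected
strength effect comparable in power to the other four.

What passing fixture tests show — and what they do not: recovery of all
injected effect directions demonstrates that the pipeline's weighting,
Z-scoring and rank tests are wired correctly and calibrated, under data
whose clone sizes, usage and junction statistics are idealized
(independent samples, no shared public backbone across donors, no
V/J-specific insertion profiles, no sequencing error). Real repertoires
violate all of these to some degree; effect sizes and p-values from the
fixtures say nothing quantitative about real cohorts.

## Determinism and numerical choices

Every stochastic step derives its seed from the master seed plus a string
context (sample id, cohort, analysis name) via SHA-256, so reruns are
byte-identical, per-sample seeds do not depend on iteration order, and
publicity is symmetric. Clonotype ordering is canonical (UMI count
descending, CDR3 nt lexicographic tie-break), making top-N selections
deterministic. Z-scores use population (not sample) SD so that a
two-sample stratum maps to ±1 rather than ±0.71, and degenerate strata
are defined. Insufficient coverage is always an exclusion signal with
bookkeeping (`report.json` lists every sample as included or excluded per
analysis), mirroring how donor exclusions are reported in practice.

## Known limitations

- The insertion estimator's germline alignment assumes the table's V/J
  names exist in the provided germline set; with real IMGT alleles a
  matching reference must be supplied.
- Publicity is amino-acid-identity sharing; it does not model
  near-matches or V-restricted sharing.
- The PCA consumes whichever features survive stratification; with many
  missing strata the feature set can shrink (columns with missing values
  are dropped and logged).
- Pooled-segment testing trades strict independence for the per-segment
  resolution of the figure-panel convention; see the calibration note
  above.
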