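# Methods notes

This note records the models, conventions and design choices behind
`methrevert`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates, levels and averaging

All internal coordinates are 0-based half-open; bismark-coverage input
(1-based inclusive) is converted on read. Promoter windows run from 2.2 kb
upstream to 0.5 kb downstream of the TSS. "Upstream" is read strand-aware
(5′ of the gene), so minus-strand windows are mirrored; windows are clipped
at coordinate 0.

Two averaging conventions coexist deliberately:

* **within a sample**, a region's level is the depth-weighted ratio
  Σmeth / Σtotal over CpGs with ≥ 4× coverage — the convention used when a
  region's reads are pooled;
* **across samples**, group means are unweighted — each animal contributes
  once, so the biological replicate is the animal, not the read.

Depth and missingness boundaries are strict in the directions stated by
the criteria: exactly 4 reads qualifies ("minimal 4×"), a missing fraction
of exactly 0.30 is retained (">30 % removed"), a methylation difference of
exactly 0.1 is rejected (">0.1"), and a DMR overlap of exactly half the
DMR fails (">50 %").

## DMR calling

The caller honors the four printed acceptance criteria — ≥ 5 CpGs,
adjacent-CpG gaps ≤ 300 bp, |Δm| > 0.1, Bonferroni-corrected Mann–Whitney
P < 0.05 — as the *contract*; the segmentation machinery between chaining
and testing is this package's own:

1. **Chaining.** Testable CpGs (post missingness filter) are chained into
   maximal runs with inter-cytosine gaps ≤ 300 bp; runs with < 5 CpGs are
   dropped.
2. **Segmentation.** Each window's per-CpG group-mean difference profile is
   refined by recursive binary splitting: every split leaving ≥ 5 CpGs on
   both sides is scored by max(|Δ̄ left|, |Δ̄ right|), and the best split is
   taken only when it beats the parent's |Δ̄| by more than `improve_eps`
   (default 0.02 methylation units — large enough that pure noise cannot
   drive endless refinement, small enough to find a 0.1 change point).
   This is a deliberate simplification of circular-binary-segmentation
   style DMR refiners; the printed criteria, not any particular refiner's
   internals, define a DMR here.
3. **Testing.** Each segment is summarised per sample by its depth-weighted
   region level and tested with the two-sided Mann–Whitney U test, so n per
   side equals the number of animals (7/10/12) — no per-CpG
   pseudoreplication. The exact null distribution is used for tie-free data
   when the smaller group has ≤ 8 observations; otherwise the normal
   approximation with midrank tie correction.
4. **Correction.** Bonferroni over the number of segments actually tested
   in that comparison (recorded as `n_tested` on the result). A
   per-comparison universe was chosen over a global one because each
   comparison filters its own site set; the choice is visible in the output
   metadata.

Emitted DMRs never overlap: segments partition their parent window and
windows are disjoint by construction.

## DMG calling

Overlap is computed as a fraction of the **DMR** (">50 % of [the DMR's]
sequences" overlapping the promoter). A DMR supporting two overlapping
promoters counts for both genes; no distance tie-break is applied because
no uniqueness rule is stated for the design. The promoter-level test
recomputes methylation over the *whole* promoter window, not only the DMR
CpGs — a gene qualifies because its promoter differs, not merely because it
contains a hotspot. Promoter P-values are used raw at 0.05 (as the
headline gene panels do); fold changes use the signed-ratio convention
(r if ≥ 1 else −1/r), which keeps |FC| ≥ 1 and matches how printed values
like "FC = −1.66" are read.

## RRHO

Elements are ranked by sign(Δm) · (−log₁₀ P) with lexicographic
tie-breaking for determinism; P is floored at 1e-300 so scores stay finite
after float underflow. The map scores *enrichment only* (upper-tail
hypergeometric); depletion between anti-correlated lists is not signed into
the map, since the analysis uses RRHO to find shared enrichment. The
default grid stride is n // 100 (full resolution available with step = 1).

Concordant sets default to **sign agreement** — an element counts when its
methylation difference points the same way in both comparisons — because
the workflow consumes concordant counts within supplied DMR lists, which is
what sign membership measures; map-quadrant extraction (`rrho_quadrant`)
is available when a map-driven set is wanted instead. Spearman correlation
of effect sizes confirms direction; its two-sided P is an exact full
permutation enumeration for tie-free n ≤ 9, else the t-approximation.

## Panels and reversibility

* **Core panel**: DMRs of FFC vs SD and FFC vs FFC/SD, each kept when
  concordant with the other comparison; the union is mapped to promoters
  and a gene enters the panel when its promoter differs in either
  comparison (P < 0.05) — the "merged" two gene sets.
* **Reversible vs retained**: a panel gene is reversible when FFC/SD and SD
  promoters are comparable (Mann–Whitney P > 0.05). This is an
  absence-of-evidence criterion, as the headline counts imply; a TOST-style
  equivalence margin could be swapped in but is not the default.
* **Persistence panel**: concordant DMR union of FFC vs SD and
  FFC/SD vs SD; genes qualify when differing from SD in either comparison
  while FFC and FFC/SD are equivalent (P ≥ 0.05).

A persistent gene's DMR appears only in the FFC-vs-SD list (its
FFC-vs-FFC/SD difference is null by definition), so its core-panel
membership hinges on a sign agreement that is a coin flip under the null —
persistent genes are therefore recovered reliably by the *persistence*
panel, and only at roughly half rate by the core panel. This is inherent
to the two-comparison concordance design, not an implementation artifact.

## Statistical kernels: build vs buy

Standard distributions and tests are delegated to established libraries —
`scipy.stats` (Mann–Whitney, hypergeometric tail, Spearman, Pearson,
chi-square, Welch t), `statsmodels` (Benjamini–Hochberg), `scikit-learn`
(PCA) — while everything the package contributes (chaining, segmentation,
concordance logic, panels, simulator) is authored here. The test suite
validates each delegated kernel against independent brute-force oracles
(exact rational combinatorics, full labeling/permutation enumeration)
rather than against the same library call.

PCA is centered but not scaled (all features are methylation ratios on one
scale) and uses a deterministic sign convention: the largest-|loading|
coordinate of each component is made positive. The chi-square variability
ranking pools read depths per group into a groups × {meth, unmeth} table —
the only construction that makes a count-based chi-square well-defined at
the promoter level; degenerate margins (all-methylated or all-unmethylated)
score 0 by convention.

The correlation-screen thresholds (P ≤ 0.01, |r| ≥ 0.4; P ≤ 0.001,
r ≥ 0.6) are combined **conjunctively**: at n = 29 either condition alone
would be nearly vacuous (|r| ≥ 0.4 implies P ≲ 0.03 already). A
disjunctive reading is available via `rule="or"`.

## qPCR model

Relative quantities use per-gene efficiency correction,
RQ = E^(Cq_min − Cq), with the per-gene minimum-Cq sample as reference
point; normalization divides by the geometric mean of the TBP/ACTB RQs.
Downstream fold changes and tests are invariant to the reference-point
choice and to per-sample global scaling — that invariance, not the
(undisclosed) preprocessing internals of commercial tools, is the testable
contract, and it is asserted in the suite. Tests run on log2 normalized
quantities (variance stabilization) as a two-sided Welch t-test with BH
adjustment across genes; BH was chosen because the adjustment method for
the expression panel is otherwise unspecified and BH is the field standard
for gene panels. Fold changes are reported on the linear scale with the
signed convention.

## The simulator

`simulate_methylome` emulates the structure the analysis assumes, at the
study's group sizes (SD = 7, FFC/SD = 12, FFC = 10):

* **Promoters**: 200 genes by default (a desk-scale stand-in for the
  ~29,000 captured promoters), 8–15 CpGs each, spaced 20–150 bp so chains
  never break inside a promoter.
* **Baselines**: cluster means from Beta(3, 2) (mean 0.6, matching the
  ~60 % promoter methylation the assay context implies), per-CpG scatter
  with concentration 50.
* **Counts**: depth ~ NegBin(mean 30, size 8) — deep enough that the 4×
  floor bites on a realistic minority of sites; per-sample per-CpG success
  probabilities from Beta(mν, (1−m)ν) with ν = 100 (per-CpG per-sample sd
  ≈ 0.05 at m = 0.5, a moderate overdispersion typical of targeted
  promoter bisulfite data); methylated reads binomial.
* **Effects**: reversible genes shift the FFC group only; persistent genes
  shift FFC and FFC/SD equally (so they are differential vs SD in both but
  mutually equivalent); |δ| = 0.25 on a run of ≥ 5 consecutive CpGs
  (~70 % of the promoter's CpGs), with planted baselines confined to
  [0.30, 0.65] so the shift never clips.
* **Missingness**: per-group zero-depth rate 0.05 applied after the depth
  draw.
* **Phenotypes**: per-group normal draws located at the study's group
  medians with IQR-matched scales (body weight, body fat, cholesterol,
  triglycerides, glucose, liver weight/glycogen/triglyceride/cholesterol);
  optional linear linkage plants recoverable methylation–phenotype
  correlations.
* **qPCR**: lognormal expression around planted group ratios (default: one
  4-fold knockdown in FFC, one 2-fold induction in FFC and FFC/SD, one
  null), flat reference genes, a per-sample global scale factor emulating
  input-amount variation, Cq = Cq₀ − log_E(expression).

Everything is drawn from a single seeded `numpy` generator, so outputs are
byte-identical across runs and platforms.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: read-level artifacts (bisulfite conversion
errors, capture bias, mapping bias), spatial correlation of methylation
beyond promoter-level block effects, cell-type heterogeneity (which
compresses real effect sizes into the 1.06–2.6-fold range), batch effects,
and covariate structure. The simulator certifies the *inferential
machinery* under its stated model, not the biology.

## Problem sizes in the test suite

The suite runs simulations at 200 promoters × 29 samples (single studies),
20-seed null sweeps, 10-dataset conformance sweeps, and 200-replicate
RRHO permutation checks at n = 1000 — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping every assertion
statistically meaningful. Exhaustive oracle checks cover all
hypergeometric parameter combinations to n = 12, all tie-free Mann–Whitney
group sizes to 6 per side, and all Spearman permutations to n = 5 (n = 7 in
unit tests).

## Known limitations

* The segmentation is not a reimplementation of any published DMR refiner;
  regions near the detection boundary may differ from other tools even
  when both honor the same printed criteria.
* Bonferroni over tested segments is conservative when segments within a
  window are correlated.
* "Reversible" rests on a non-significance criterion and inherits its
  asymmetry: low power in the FFC/SD-vs-SD comparison inflates apparent
  reversibility.
* Plus- and minus-strand cytosines of a CpG are treated as separate input
  sites; merging, if wanted, belongs to upstream tooling.
* The correlation screen applies no multiple-testing correction across the
  gene × phenotype grid (by design, matching the tiered-threshold
  reporting).
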