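# Methods

This note documents the models and procedures implemented in `gcx`, the
parameter choices that matter, and what the synthetic cohort generator
does and does not emulate.

## Copy-number curation and the GC score

Coordinates are 0-based half-open internally; SEG input is accepted as
1-based inclusive (`seg_1based`, the common SEG convention) and converted
on read, so sizes are always `end − start`. Chromosomes 1–22, X and Y are
accepted, with or without a `chr` prefix.

Curation proceeds per sample in a fixed order:

1. **CN-LOH exclusion.** Copy-number-neutral LOH segments carry allelic
   imbalance but no net copy change and are excluded from the count.
2. **Chromothripsis collapse.** Catastrophic shattering produces many
   oscillating copy-number states on one chromosome; such a pattern is one
   biological event, not dozens. No consensus operational definition
   exists at segment-table resolution, so two routes are provided: an
   explicit per-segment input flag (always honoured; flagged segments on a
   chromosome collapse to one cluster), and a heuristic — walking the
   chromosome's segments in genomic order, inserting an implied
   copy-neutral state into every gap, ≥ 10 adjacent state changes
   (configurable) collapse the chromosome to a single cluster of weight 1.
   The heuristic is deliberately conservative: isolated segments separated
   by gaps contribute two switches each, so ten switches require at least
   five to six alternating segments on one chromosome.
3. **Proximity merge.** Same-chromosome, same-direction events whose gap
   is ≤ 5 Mb (inclusive) merge into one event spanning the union,
   transitively. Losses merge only with losses and gains with gains —
   merging a gain into a loss has no biological reading. A merge that
   involves a biallelic loss yields a biallelic loss, so the double hit is
   never diluted by an adjacent monoallelic fragment.
4. **Size-or-region retention.** An event is kept iff it overlaps a
   catalog region by ≥ 1 bp or spans ≥ 5 Mb (inclusive). The ≥ 1 bp rule
   is deliberate: recurrent in-region CNAs down to a few kb are real and
   prognostically relevant. The bundled GRCh37 catalog covers the arms
   2p, 4p, 6q, 11q, 13q, 14q and 17p plus TP53, ATM, BIRC3, RB1 and the
   13q14 minimally deleted region; it is an editable BED because arm
   boundaries are a convention, not a measurement, and users on another
   build must replace it.
5. **Aneuploidy.** An event covering ≥ 90 % of its chromosome
   (configurable) is reclassified as a whole-chromosome gain or loss.
   The threshold is below 100 % because arrays and shallow WGS rarely
   cover telomeric and centromeric ends.

The CNA count is the sum of event weights — 2 for a biallelic loss, 1
otherwise — and classifies genomic complexity as LGC (0–2), IGC (3–4) or
HGC (≥ 5). 13q deletions are size-classed with the 2 Mb boundary closed on
Class I (a deletion of exactly 2 Mb is Class I, preserving "< 2 Mb" as the
closed-side definition of the small class); larger Class II deletions extend
into RB1 territory and track with complexity.

## Integration

Gene lesion states combine panel mutations with the curated deletion
flags: TP53 via del17p, ATM via del11q, BIRC3 via its own deletion flag.
Mutation + deletion (or a biallelic deletion) is a biallelic hit; TP53
aberration is any non-wildtype TP53 state. TL classes use the established
cut-offs with the interval "2.92–3.57 kb" treated as closed on
both ends (S strictly below, L strictly above). TMB is binned 0 / 1 / 2 /
≥ 3; the ≥ 3 bin is the high-TMB indicator used in survival models (the
cut is configurable). Missing IGHV, epitype or TL are kept as missing and
handled complete-case per analysis — denominators therefore vary between
analyses, and nothing is imputed. A clinical sample with no curated
segment row is a zero-CNA (LGC) patient, not a missing one: the segment
table is the profiling output, and absence of calls means absence of
detected CNAs.

## Association statistics

Test choice is a fixed rule, not per-case judgement: Fisher's exact for a
2×2 table with any expected cell below 5, chi-squared without continuity
correction otherwise; r×c tables always use chi-squared. Enrichment scans
test each feature one-vs-rest against each GC class and adjust by
Benjamini–Hochberg across the whole scan — the family is one `enrichment_scan`
call, recorded in its output, since no finer-grained family definition is
canonical. Correlations are Kendall's τ-b (tie-corrected; CNA counts are
heavily tied). Two-group comparisons are two-sided Wilcoxon rank-sum with
exact p-values at small n (scipy's automatic switch).

## Survival models

Kaplan–Meier curves are product-limit estimates; the median is the first
time survival reaches ≤ 0.5 (undefined if never); `survival_at` is a
right-continuous step lookup that warns when extrapolating beyond the last
observed time. Group differences use the log-rank test.

Cox models use the Efron approximation for ties (the standard modern
default). Backward elimination drops, at each step, the term with the
largest Wald p ≥ α (default 0.05) and refits until every remaining term is
significant; ties in p break by earliest position in the caller's
candidate order, so elimination is deterministic for a fixed dataset. The
trace of every drop is part of the result object. α = 1 returns the full
model and α → 0 an empty one. A binary covariate with zero events on one
side cannot be estimated (the partial likelihood diverges); univariate
screens report it with an infinite/zero hazard-ratio sentinel rather than
failing. Multivariate models use complete cases across all candidate
covariates, so their n shrinks with the candidate set. Cohorts with
different treatments and follow-up (e.g. the two trial arms) are modelled
separately; age enters per year, centred at 64.

## The synthetic cohort generator

The generator emulates the statistical structure of a chemoimmunotherapy-
era CLL trial cohort of ~495 patients:

* **Marginals.** U-CLL 60 %; epitype conditional on IGHV (n/i/m = 0.75/
  0.20/0.05 given U-CLL and 0.10/0.50/0.40 given M-CLL, giving marginals
  0.49/0.32/0.19); lesions del13q 47.4 % (21 % of them biallelic, Class II
  fraction 170/256), del11q 18 % (70 % extending into BIRC3 — BIRC3
  deletions never occur without the 11q deletion), tri12 12.5 %, del17p
  4.4 %; panel mutations SF3B1 22 %, NOTCH1 15 %, ATM ~11 %, TP53 ~9 %,
  BIRC3 3.2 %, plus minor genes. TP53 and ATM mutations are drawn
  conditionally on the corresponding deletion (P(TP53 mut | del17p) = 0.8
  vs 0.061 without), reproducing the observed concentration of biallelic
  hits.
* **Telomere length.** Log-normal with median 3.21 kb and log-sd 0.38
  (range ≈ 1.1–10 kb at n ≈ 500), shifted −0.15 on the log scale in U-CLL
  (centred so the overall median holds).
* **CNA count.** Canonical lesion weights plus a negative-binomial "extra
  event" count with log-mean 0.05 + log(1.5)·TP53-aberrant +
  log(1.8)·U-CLL and size 0.45, linked to the TL normal score through a
  Gaussian copula. The copula correlation (−0.2596) was calibrated by
  bisection with common random numbers (n = 200 000, bracket tolerance
  10⁻³) so the population Kendall τ-b of TL vs total count is −0.147;
  `calibrate_tl_cna_rho` re-runs the search after any change to the count
  or TL model. The count parameters were fitted by grid against the target
  marginals (mean 2.62 per patient, GC proportions 67/20/13, U-CLL vs
  M-CLL count means 2.86 vs 2.01); the NB family cannot satisfy all of
  these at once — the chosen setting reproduces the mean, the LGC fraction
  and the IGHV gap, at the price of an HGC fraction near 16 % rather than
  13 %. This is a known limitation of the count model, not a data
  statement.
* **Segments.** True lesions are rendered at their canonical GRCh37 loci;
  extra events are placed on chromosomes free of catalog regions, spaced
  > 5 Mb apart so they never merge. Curation traps are injected at
  configurable rates, all count-preserving by construction: events split
  into fragments ≤ 5 Mb apart (must re-merge), sub-5 Mb off-catalog
  fragments (must be filtered), CN-LOH decoys (must be excluded),
  biallelic 13q deletions (must count twice) and 12-segment oscillating
  clusters (must collapse to one). Consequently the curated count equals
  the latent count exactly for every patient, which is what makes the
  round-trip test sharp.
* **Survival.** Weibull proportional hazards: linear predictor
  Σ log(HR)·x, baseline scale solved by bisection so the cohort's marginal
  median matches the configured trial median (OS 6 y / PFS 2.4 y for the
  long-follow-up trial; 6.44 / 4.72 y for the newer pair), administrative
  censoring at the follow-up horizon (17 / 10 / 9 years). The baseline
  shape 1.2 was calibrated so that the overall-survival design yields
  ~167 events per 198 patients at the 17-year horizon, matching the
  multivariate model's reported denominators. Default hazard-ratio vector
  (overall survival, older trial): HGC 1.61, TP53 aberration 2.94, tri12
  1.79, TL-S 1.70, U-CLL 1.54, SF3B1 1.50, age 1.05 per year. An
  alternative "group-hazard" mode draws times from per-GC-class Weibulls
  calibrated to 5-year survival rates (61/50/42 % or 51/40/29 %; the
  intermediate class is a midpoint choice) for Kaplan–Meier checks.
* **FISH.** Locus calls are the true lesions flipped with 5 % probability,
  within the 71–99 % agreement band reported for genomic-vs-FISH
  concordance.
* **Missingness.** IGHV and epitype are masked at 11.3 % and 9.9 % to
  exercise complete-case handling.

Everything is driven by one `numpy` generator seeded from `SimConfig.seed`,
so a bundle is byte-identical across runs with the same seed.

**What the generator does not emulate:** probe-level array noise, breakpoint
uncertainty, clonal evolution, balanced translocations (invisible to CNA
data by construction), informative censoring, correlations among features
beyond those listed, and the within-patient dependence of mutation VAFs.
Passing tests therefore demonstrate that the pipeline's rules and models
are implemented correctly and recover planted structure at realistic sizes;
they do not validate the biological calibration against real cohorts.

## Numerical and reporting choices

* Problem sizes: marginal checks use n = 5 000; dependence checks
  n = 20 000; copula calibration n = 200 000; τ recovery runs 50 cohorts
  of n = 495 with full curation; Cox recovery 200 replicates of n = 198;
  KM recovery 50 cohorts of n = 251.
* The mean hazard ratio reported for a backward-eliminated term averages
  over the replicates in which the term is retained. For a term whose Wald
  z-statistic is near the retention threshold this is a truncated mean and
  sits above the generating value — the weaker the effect, the stronger
  the inflation. The strong TP53 effect is essentially unaffected; the
  moderate HGC effect is visibly inflated. This is a property of
  select-then-estimate reporting, not of the estimator.
* Odds ratios of divergent 2×2 tables are reported as +inf/0 sentinels;
  survival times are floored at 10⁻⁴ years to keep fitters defined;
  extra-event counts are capped at 25 per patient (the upper end of
  plausible burdens) so extreme copula quantiles remain placeable on the
  genome.
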