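# gcx — genomic complexity scoring and prognostic modelling for CLL

`gcx` implements, as a tested and reusable Python pipeline, the genomic-
complexity (GC) analysis used in chronic lymphocytic leukaemia (CLL)
prognostics: it curates raw copy-number segment calls into a per-patient
CNA count and GC class, integrates that score with telomere length (TL),
IGHV mutational status, DNA-methylation epitype and recurrent gene lesions,
and provides the downstream enrichment, survival and high-risk-feature
convergence analyses. A synthetic cohort generator with matched statistical
structure makes every stage testable end to end without patient data.

It is aimed at biostatisticians and cancer-genomics analysts working with
SEG-style copy-number tables from arrays or shallow WGS, clinical trial
survival data, and standard CLL biomarkers.

## The score and the models

**CNA curation.** Raw segments (loss / biallelic loss / gain / CN-LOH) are
curated per sample: copy-number-neutral LOH is excluded; same-direction
segments within ≤ 5 Mb merge into one event; oscillating chromothripsis-like
clusters collapse to a single event; events outside a catalog of recurrently
altered regions (2p, 4p, 6q, 11q, 13q, 14q, 17p plus the TP53, ATM, BIRC3,
RB1 and 13q14-MDR loci) must span ≥ 5 Mb to be retained, while any overlap
with a catalog region retains an event regardless of size; events covering
≥ 90 % of a chromosome become aneuploidies. The CNA count is

```
count = Σ_events weight,   weight = 2 for a biallelic loss, else 1
```

and stratifies patients into LGC (0–2), IGC (3–4) and HGC (≥ 5).

**Integration.** Gene lesion states (wildtype / mutated / deleted /
biallelic) combine mutation calls over a 9-gene panel with the curated
deletion flags (TP53↔del17p, ATM↔del11q, BIRC3); TP53 aberration is any
non-wildtype TP53 state; TL classes use the established 2.92 / 3.57 kb
cut-offs; tumour mutation burden (TMB) is the panel mutation count.

**Statistics.** Enrichment across GC groups uses Fisher's exact test (2×2
with any expected cell < 5) or chi-squared otherwise, with Benjamini–
Hochberg correction per scan; correlations use Kendall's τ-b; group
comparisons use the Wilcoxon rank-sum test. Survival uses Kaplan–Meier /
log-rank and Cox proportional hazards (Efron ties) with stepwise backward
elimination: the term with the largest Wald p ≥ α (default 0.05) is dropped
and the model refit until all remaining terms are significant.

## Worked example

Generate a synthetic 495-patient cohort, curate it, and run the survival
and convergence analyses:

```python
import gcx

bundle = gcx.generate_cohort(gcx.SimConfig(n_patients=495, seed=7))
events, summary = gcx.curate_cohort(bundle.segments,
                                    sample_ids=list(bundle.truth.sample_id))
print(summary["gc_class"].value_counts().to_dict())
# {'LGC': 339, 'IGC': 82, 'HGC': 74}

cohort = gcx.build_cohort_table(
    bundle.clinical, summary,
    [gcx.MutationCall(r.sample, r.gene, r.vaf) for r in bundle.mutations.itertuples()],
    bundle.tl.rename(columns={"sample": "sample_id"}),
    bundle.epitype.rename(columns={"sample": "sample_id"}),
)
print(gcx.kendall_tau(cohort["tl_kb"], cohort["cna_count"]))
# CorrelationResult(variables=('x', 'y'), tau_b=-0.201, p=6.5e-10, n=495)
```

Shorter telomeres accompany higher CNA counts (τ-b = −0.20 here; the
generator is calibrated to a population value of −0.147). A multivariate
Cox model of overall survival with backward elimination:

```python
cohort["hgc"] = cohort["gc_class"] == "HGC"
cohort["tl_s"] = cohort["tl_class"] == "S"
cohort["ucll"] = cohort["ighv"] == "U-CLL"
cohort["age_c"] = cohort["age"] - 64
cohort["sf3b1_mut"] = cohort["SF3B1_mut"]
res = gcx.cox_backward_eliminate(
    cohort.dropna(subset=["ighv"]),
    ["hgc", "tp53_aberrant", "tri12", "tl_s", "ucll", "sf3b1_mut", "age_c"],
    "os_time_years", "os_event", alpha=0.05)
print(res.summary().round(3))
#             term     HR  ci95_low  ci95_high      p
# 0            hgc  1.527     1.155      2.018  0.003
# 1  tp53_aberrant  3.470     2.413      4.989  0.000
# 2          tri12  1.818     1.321      2.502  0.000
# 3           tl_s  1.481     1.198      1.832  0.000
# 4           ucll  2.073     1.662      2.585  0.000
# 5          age_c  1.072     1.058      1.086  0.000
```

The hazard ratios are per-term multiplicative effects on the hazard; the
elimination trace (`res.elimination_trace`) records that `sf3b1_mut` was
dropped at p = 0.10. Finally, the convergence analysis of the HGC subgroup:

```python
s = gcx.convergence_summary(cohort)
print(s.n_hgc, s.n_tp53_aberrant, s.n_no_feature, round(s.proportion_any_feature, 1))
# 74 13 5 93.2
```

i.e. 93 % of this cohort's HGC cases carry at least one of TP53 aberration,
U-CLL, short TL or the n-CLL epitype — high genomic complexity largely
converges on already-measurable high-risk biology.

The same pipeline is scriptable from the shell (`gcx simulate`, `gcx
curate`, `gcx integrate`, `gcx associate`, `gcx survive`, `gcx converge`).

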