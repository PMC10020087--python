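# m6asplice

Toolkit for the computational arm of an m6A / alternative-splicing (AS)
study in cancer transcriptomics: derive AS events from a gene annotation,
quantify percent spliced-in (PSI) from transcript abundances, call
differential splicing between knockdown and control with an empirical test,
run negative-binomial differential expression, test whether intronic
m6A peaks (or premature termination codons) are enriched among
differentially skipped exons, profile motif density around peak summits,
and build a PSI-based Lasso–Cox survival risk signature.

Everything runs on a bundled synthetic-data generator with known ground
truth, so the full pipeline is testable without any external download.

## The statistics at the core

**PSI.** For an event with inclusion isoform set *I* and exclusion set *E*,
per sample: `PSI = Σ_{t∈I} TPM_t / Σ_{t∈I∪E} TPM_t`. Seven event classes
are derived from transcript structure: skipped exon (SE), retained intron
(RI), mutually exclusive exons (MX), alternative 5′/3′ splice sites
(A5/A3), and alternative first/last exons (AF/AL), with strand-mirrored
definitions.

**ΔPSI.** Between conditions, `ΔPSI = mean PSI(B) − mean PSI(A)`; its
significance is the empirical tail probability against a null pool of
between-replicate PSI fluctuations from events of similar abundance,
followed by Benjamini–Hochberg FDR. Two independent knockdowns (sh1/sh2)
are combined by intersection with sign concordance — the guard against
shRNA off-target effects.

**Differential expression.** An exact conditional test under a negative
binomial whose variance is linked to the mean via a locally-regressed
smooth function: per feature, condition sums are NB with moment-matched
parameters and the two-sided p-value sums the probabilities of all splits
of the conditional total no more likely than the observed one. Features
must have reads in at least half of the samples.

**m6A × splicing.** An SE event is m6A⁺ when a peak summit falls inside
either flanking intron of the cassette exon. Enrichment of m6A⁺ (or PTC⁺,
by the >50-nt rule: a stop codon more than 50 nt upstream of the last
exon–exon junction) among significant events is a two-sided Fisher exact
test computed in exact integer arithmetic.

**Motif density.** ±150 nt summit windows versus matched random intronic
windows; per-position motif-start density over −80..+80 nt with full IUPAC
degeneracy (DRACH = D{A,G,U} R{A,G} A C H{A,C,U}); center enrichment scored
by label permutation.

**Risk signature.** Lasso-penalized Cox partial likelihood on per-event
PSI; each patient's risk score is `Σᵢ βᵢ × PSIᵢ`, and patients are split
at the 75th percentile of scores (top quarter = high risk — for 1,207
patients, 302 high / 905 low). Kaplan–Meier curves and the log-rank test
compare the strata.

## Worked example

```python
from m6asplice import (SimConfig, make_annotation, simulate_knockdown_pair,
                       build_events, compute_psi, delta_psi,
                       combine_knockdowns, simulate_cohort, CoxLassoRisk)

cfg = SimConfig(n_genes=250, dse_fraction=0.2, psi_shift=0.3, seed=42)
ann = make_annotation(cfg)
events = build_events(ann)
q1, q2, truth = simulate_knockdown_pair(ann, cfg)
d1 = delta_psi(compute_psi(events, q1), "control", "knockdown")
d2 = delta_psi(compute_psi(events, q2), "control", "knockdown")
dse = combine_knockdowns(d1, d2, alpha=0.05)
print(f"{len(events)} events, {len(dse)} concordant DSE")

cohort, _ = simulate_cohort(
    ["e1", "e2", "e3"],
    SimConfig(n_patients=1207, true_betas=(1.5, -1.5, 0.0),
              censor_rate=0.2, seed=42),
)
print(CoxLassoRisk(cohort).fit(seed=0).summary())
```

prints

```
250 events, 49 concordant DSE
Lasso-Cox PSI risk signature
  patients: 1207 (977 events)
  penalty: 0.007514
  coefficients:
    e1: +1.2231
    e2: -1.4006
    e3: +0.0000
  risk cutoff (75% percentile): 0.3103
  groups: high=302, low=905
  log-rank: chi2=199.390, p=2.838e-45
```

All 49 concordant DSE here are planted events (49/49 recovered, no false
positives); the cross-validated Lasso recovers the signs of the two real
hazard coefficients, zeroes the null one, and the 75th-percentile rule
splits the 1,207 patients 302/905. The high-risk stratum has sharply worse
survival (log-rank p ≈ 3e-45) because the hazard truly follows the PSI
covariates.

A command-line interface mirrors each stage
(`m6asplice simulate | events | psi | dpsi | combine | diffexpr |
m6a-enrich | motif-density | survival | run-all`); see
`m6asplice --help`.

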