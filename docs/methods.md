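# Methods

This note documents the models and procedures implemented in `m6asplice`,
the assumptions behind them, the tunable parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Coordinates and gene models

All internal coordinates are 0-based half-open on the genomic plus strand;
GTF (1-based closed) and BED (0-based half-open) are converted exactly once
at the I/O boundary. A transcript is an ordered list of disjoint exons with
an optional CDS; introns are the gaps between consecutive exons. Minus-strand
transcripts reverse their exon order for all mRNA-coordinate computations.

## AS event calculus

Events are derived per gene by pairwise structural comparison of
transcripts, then de-duplicated on (class, defining coordinates):

- **SE** — one transcript shows junctions (C1end→Astart) and (Aend→C2start)
  around a cassette exon A, the other the direct junction (C1end→C2start).
  The two flanking introns are recorded; they are the unit of the m6A
  assignment.
- **RI** — one transcript retains, inside a single exon, an intron (d→a)
  that the other splices, with matching outer exon boundaries.
- **MX** — two internal exons, mutually absent across the pair,
  non-overlapping, sharing both flanking splice sites.
- **A5/A3** — two introns share one boundary and differ at the other; the
  variable region must be exonic in the longer-exon form. A donor-side
  difference is A5 on the plus strand and A3 on the minus strand (and
  conversely for acceptor-side differences).
- **AF/AL** — distinct, non-overlapping terminal exons joined to a shared
  internal splice site; genomic-first exons are AF on plus / AL on minus.

Inclusion/exclusion transcript sets contain *all* of a gene's transcripts
compatible with each form (presence of the defining junctions and exons),
not just the generating pair. The "inclusion" form is, by convention, the
form with more exonic sequence (SE: exon in; RI: retained; A5/A3: longer
exon) or the genomically left alternative exon (MX, AF, AL). Any fixed
convention works because PSI for one form is one minus PSI of the other;
the tests pin this one.

Partial-overlap configurations are deliberately not forced into MX, and
tandem starts inside one first exon are ignored — both would otherwise
create ambiguous duplicates of A5/A3 events.

**PTC flagging.** For transcripts with a CDS, the distance from the 3' end
of the stop codon to the last exon–exon junction is measured in mRNA
coordinates; a transcript is PTC+ (predicted NMD substrate) when that
distance strictly exceeds 50 nt and the stop is not in the last exon.
Both entry points exist: annotation-provided flags can be bypassed by
recomputing from the CDS, since source annotations differ in whether they
tag NMD transcripts.

## PSI and differential splicing

`PSI = ΣTPM(inclusion) / ΣTPM(inclusion ∪ exclusion)` per sample; undefined
when the denominator is zero. Differential testing drops events whose
condition-mean total TPM falls below 1 (an expression floor that avoids
0/0 PSI noise; configurable) or that are undefined in more than half the
replicates of either condition.

The significance of `ΔPSI = mean PSI(B) − mean PSI(A)` is empirical: the
null pool collects within-condition between-replicate |PSI differences|
from all events in the same abundance bin (about ten equal-occupancy bins
of log total TPM, reduced automatically so each bin keeps ≥ ~30 events).
Because a between-replicate difference has variance 2σ² while a difference
of condition means has σ²(1/nA + 1/nB), the pool is rescaled by
√((1/nA + 1/nB)/2); without this factor the null is overdispersed and
p-values are conservative rather than uniform. p = (1 + #{null ≥ |obs|}) /
(1 + #null); FDR is Benjamini–Hochberg. The add-one estimator bounds the
smallest attainable p by the bin pool size — at 250 events and 3+3
replicates the floor is ≈ 0.005, which is why the bundled power analyses
use a few hundred events.

Two knockdowns against the same control are combined by intersection:
an event survives iff FDR < 0.05 in both and the ΔPSI signs agree;
reported ΔPSI is the mean, reported p (and FDR) the maximum. Pooling the
samples instead would gain power but lose the off-target guard, so
intersection is the default and only mode.

## Negative-binomial differential expression

- **Detection filter**: keep features with nonzero counts in at least
  ⌈n/2⌉ samples.
- **Normalization**: median-of-ratios to the geometric-mean
  pseudo-reference over features with no zeros, rescaled to geometric
  mean 1.
- **Mean–variance fit**: per-feature, per-condition means and unbiased
  variances of normalized counts are pooled; the *moment dispersion*
  φᵢ = (s²ᵢ − μᵢ)/μᵢ² is smoothed against log μ by tricube-weighted
  local-linear regression (bandwidth 0.3 of the log-mean span, evaluated
  on a 256-point grid). Negative moment estimates stay in the fit — they
  carry the information that makes the Poisson case unbiased — and the
  fitted φ is floored at 0 on evaluation, so the predicted variance never
  drops below the Poisson bound. Fitting the raw variance (or its log)
  against log mean instead is badly biased at 2–4 degrees of freedom:
  the log transform has a large Jensen bias and the raw-scale local fit
  is convexity-biased; both break type-I calibration, which is why the
  dispersion scale was chosen.
  Features below 1 normalized count are excluded from the fit (their
  moment dispersions are uninformative noise).
- **Exact conditional test**: per feature, the condition sums K_A, K_B are
  modelled as NB with mean q̂·Σsⱼ and variance m + φ(q̂)·q̂²·Σsⱼ²; given the
  total K = K_A + K_B, the two-sided p sums P(a, K−a) over all splits with
  P ≤ P(observed)·(1+1e−7) (the epsilon guards float ties). Normalized
  values enter the NB only through moments, so the enumeration is exact
  over integer splits. All-zero features get p = 1.
- **FDR**: Benjamini–Hochberg. The cited FDR procedure could also be read
  as a q-value estimator; BH was chosen as the monotone, parameter-free
  default.

An exact conditional moment-based test (rather than a Wald/LRT on a GLM)
matches a variance "linked to the mean via a locally-regressed smooth
function" — the variance is estimated marginally, not fit per-feature.

## m6A association

SE events are flagged m6A⁺ when at least one peak **summit** lies inside a
flanking intron (summit containment, not any-overlap: summit assignment is
unambiguous for peaks straddling boundaries, and the motif analysis is
summit-centered anyway; any-overlap is available via `mode="overlap"`).
The 2×2 table (significant vs non-significant × flag⁺ vs flag⁻) is tested
with a two-sided Fisher exact test implemented with exact integer
hypergeometric weights C(r1,k)·C(r2,c1−k); the "no more likely than
observed" comparison is integer-exact, so there are no floating-point tie
artifacts, and zero margins give p = 1 by convention. The association is
event-level (the finer, testable unit; the gene-level collapse is a
one-liner on the flag maps), the universe is all *tested* events, and
non-SE events are excluded because flanking introns are only defined for
cassette exons. The PTC analogue reuses the identical machinery with the
event-level PTC flag (any event transcript PTC+).

## Motif density

±150 nt summit windows (301 nt, reverse-complemented on minus strands;
clipped windows dropped and logged) against the same number of random
windows drawn uniformly from the intronic space of peak-bearing genes
(length-weighted across introns that can host a full window). "Similar
properties" is operationalized as length + intronic location; GC matching
was considered and left off by default since the generator's background is
uniform. Densities count motif *start* offsets over −80..+80 with IUPAC
degeneracy; overlapping matches all count, which gives the exact
conservation law Σ_positions density × #windows = #matches. Center
enrichment is the ratio of mean densities within ±20 nt, with a seeded
permutation p over window group labels (1000 permutations by default).

## Survival risk signature

The Lasso-Cox fit uses cyclic coordinate descent on the penalized partial
likelihood (via scikit-survival's Coxnet path solver; lifelines provides
the unpenalized fit at penalty 0). When no penalty is supplied, it is
chosen by seeded 5-fold cross-validated held-out partial likelihood
(Breslow form) over the path, with the one-standard-error rule computed on
*paired per-fold differences* — fold-level likelihood magnitudes vary with
fold composition, and an unpaired SE would absorb that variation and
over-penalize. The CV-maximum rule is available (`cv_rule="min"`) when
minimal shrinkage bias matters more than sparsity; the 1-SE default
reliably zeroes null coefficients at the cost of shrinking real ones by
roughly 10–30% at n = 1000.

Risk score = Σβᵢ·PSIᵢ. Stratification takes the top ⌈(1−q)·n⌉ patients by
descending score as high-risk (q = 0.75), with boundary ties broken by
stable input order — this rank rule reproduces a 302/905 split of 1,207
patients exactly and is free of quantile-interpolation conventions.
Kaplan–Meier estimation and the two-group log-rank test come from
lifelines; tumor/normal PSI comparisons default to the two-sided rank-sum
test (exact for small untied samples, tie-corrected normal approximation
otherwise, Welch's t behind a flag) since PSI distributions are bounded
and often skewed; expression–PSI association is Pearson's R with the
t-based p, with missing pairs dropped and an explicit NaN sentinel for
constant inputs.

Missing PSI is handled complete-case per model: clinical PSI tables are
sparse and any imputation would be an unstated modelling choice.

## Synthetic-data generator

The generator emulates the statistical structure of the study's inputs —
not real genomes:

- **Annotation**: one gene per contig (independent contigs avoid overlap
  bookkeeping; downstream code needs only local coordinates), each gene
  realizing one event class with the canonical two-isoform pair. Defaults:
  150 nt exons, 1000 nt introns (long enough to host ±150 nt summit
  windows), 400 nt contig padding, 60 nt alternative splice-site
  extensions, strands assigned at random. Genes with more than two
  isoforms are rejected by config validation: extra isoforms would plant
  additional unintended events and break the one-event-per-gene ground
  truth. Every transcript gets a CDS; a configurable fraction of
  exclusion-form transcripts receives a premature stop 100 nt upstream of
  the last junction so the PTC machinery is exercisable.
- **Quantifications**: gene expression is log-normal (ln TPM ~ N(2.5, 1));
  isoform usage is the true PSI with logit-normal replicate noise
  (σ = 0.25 on the logit scale, ≈ 0.06 PSI at mid-range — keeps PSI in
  (0,1)); TPM = expression × usage, renormalized to 1e6 per sample;
  counts are gamma-Poisson around TPM × effective length × depth
  (variance μ + φ(μ)μ², default φ = 0.1, typical bulk-RNA-seq
  overdispersion; depth factor 1e−3 gives a few hundred counts for an
  average transcript). Planted differential events (default 20% of genes)
  shift usage by ΔPSI = 0.3 in a random direction; base PSI is drawn in
  [0.35, 0.65] so the shift never leaves [0, 1]. The planted truth
  depends only on the seed, so two "knockdowns" with independent noise
  share the same biology.
- **Peaks**: planted-DSE SE events receive a summit inside one flanking
  intron with probability `peak_enrichment_fraction`; background peaks
  fall as a Poisson process (0.1/kb) on all other introns, with planted
  events' introns excluded from the background so the planted flag
  probability equals the enrichment fraction exactly.
- **Sequences**: uniform random bases per contig, one concrete instance
  of the configured IUPAC motif written at each summit on the peak's
  strand, so a strand-aware window reads the motif starting at offset 0.
- **Cohort**: PSI ~ U(0,1) per patient and event; survival times are
  exponential with rate `baseline_hazard · exp(Σβᵢ PSIᵢ)`; censoring is
  independent exponential with its rate solved numerically so the expected
  censored fraction equals `censor_rate`.

What the generator does **not** emulate: realistic exon/intron length
distributions, splice-site sequences, GC structure, correlated events
within genes, isoform-specific effective-length effects, batch effects,
or clinical covariates. Passing tests therefore demonstrate correctness
of the algorithms under the stated statistical model, not performance on
real tissue data.

## Problem sizes and calibration checks

The bundled analyses use sizes at which the statistics are informative yet
quick: 250 events / 3+3 replicates for splicing recovery, 5,000 features
for NB type-I calibration, 500 SE events × 100 peak realizations for
enrichment power, 150 summit windows for motif profiling, and cohorts of
1,000–2,000 patients for coefficient recovery. The log-rank null
calibration uses 1,000 replicates of 100 + 100 uncensored patients — at
substantially smaller groups the asymptotic χ² reference is visibly
liberal (rejection ≈ 0.06–0.07 at 30 + 30), which is a property of the
test, not of the implementation.

## Known limitations

- The empirical ΔPSI p-value floor is set by the bin pool size; very small
  event sets cannot reach small FDRs.
- The exact NB test enumerates all splits of the conditional total, so
  features with totals in the many millions would be slow (vectorized, it
  is comfortable up to ~1e5 per feature).
- Event compatibility is junction-based; transcripts with exotic
  structures that contain an event's junctions but differ elsewhere are
  counted as compatible, as in annotation-based event quantification
  generally.
- Lasso coefficients under the 1-SE rule are biased toward zero by
  design; use `cv_rule="min"` or `penalty=0` for estimation rather than
  selection.
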