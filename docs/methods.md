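# Methods

## The analysis

`chcv` models the association of clonal hematopoiesis (CH) with
cardiovascular outcomes in a cancer cohort. Two forms of CH enter the
analysis: CHIP — a cancer-associated somatic point mutation in blood at
VAF ≥ 2% in one of eleven panel genes (ASXL1, CBL, DNMT3A, GNAS, GNB1,
JAK2, PPM1D, SF3B1, SRSF2, TET2, TP53) — and mosaic chromosomal
alterations (mCAs: loss/gain/copy-neutral-LOH events with a cell
fraction), categorized as any mCA, LOY (chrY loss, men), LOX (chrX loss,
women), autosomal, and expanded (cell fraction ≥ 10%). Five endpoints are
analyzed: incident CVD, incident CAD, CV death, CAD death, any death.

Prevalence questions (who carries CHIP/mCA, co-occurrence) use logistic
regression with Wald intervals. Outcome questions use Cox proportional
hazards with the four-category exposure {no CH, CHIP only, mCA only,
both}; additive interaction is summarized by RERI = h11 − h10 − h01 + 1
and AP = RERI/h11, multiplicative interaction by h11/(h10·h01). The
latter equals exp of the product-term coefficient; because the
four-category and product-term parameterizations span the same design
space, the package computes the product term as the exact linear contrast
b11 − b10 − b01 of the four-category fit (variance by the same contrast
of the covariance) rather than refitting. The classical Rothman synergy
index (h11−1)/((h10−1)+(h01−1)) is computed separately and labelled as
such, because the source tables use the name "SI" for the multiplicative
ratio; the package reproduces the reported quantity and keeps the
conventional one available.

## The CHIP filter cascade

Rules, in application order (each per-variant rule depends only on the
record, so verdicts commute and the audit lists all failed rules):

1. **Whitelist** — exact protein-change entries plus gene-level rules
   (any frameshift/nonsense/splice in the loss-of-function genes, any
   DNMT3A missense). The published prespecified list is not printed in
   the source; the packaged TSV is a documented stand-in assembled from
   well-known hotspots and is fully editable.
2. **Depth** — DP ≥ 20, alt AD ≥ 5, F1R2 ≥ 1 and F2R1 ≥ 1.
3. **Homopolymer** — if the position lies inside or immediately adjacent
   to a run of ≥ 5 identical reference bases (scanned in the ±5 bp
   context, from a `CONTEXT` INFO tag or an indexed FASTA), removed when
   AD < 10 or VAF < 0.08. "Adjacent" is included because slippage
   artifacts concentrate at run boundaries.
4. **Named artifacts** — TP53 p.P72R and ASXL1 p.P815L removed
   unconditionally; ASXL1 p.G646Wfs\*12 removed only at VAF < 0.1 (it is a
   genuine hotspot at larger clone sizes). The sentence defining this rule
   is grammatically ambiguous about the scope of the VAF clause; the
   alternative reading (VAF < 0.1 applies to all three) is available via
   `artifact_vaf_scope="all"`.
5. **Binomial somatic test** — non-exempt missense variants in
   CBL/TET2/DNMT3A/TP53 are removed when an exact binomial test of the
   alt count against VAF = 0.5 gives p ≥ 0.01, i.e. when read support is
   indistinguishable from a heterozygous germline variant. Sidedness is
   unstated in the source; the package uses the two-sided exact test
   (computed as twice the smaller tail, which is exact for the symmetric
   null), since "looks germline" is a two-sided notion. TET2 p.H1904R,
   p.I1873T and p.T1884A are exempt.
6. **Cohort recurrence** — variants carried by > 20 individuals are kept
   only if associated with age or with TERT rs7705526 dosage at p ≤ 0.1
   (univariate logistic Wald tests; Fisher's exact on a dichotomized
   covariate as the separation fallback). The combination rule is
   unstated in the source; the default keeps a variant if **either** test
   passes — a genuine CHIP variant needs only one signature of positive
   selection — with `recurrence_combine="both"` as the stricter option.
   Under this rule an age/TERT-independent artifact survives with
   probability ≈ 0.19 (two independent near-uniform p-values), so the
   null removal rate is ≈ 81%.

Expanded CHIP is max VAF ≥ 0.10. Coordinates are 1-based VCF convention
throughout.

## Cohort construction

Exclusions: hematologic cancer diagnosed within ±182 days of study entry;
genotypic–phenotypic sex discordance; one member of each first/second-
degree relative group. The relative choice is drawn from an RNG seeded by
the global seed and the group label over the canonically sorted members,
so the retained set does not depend on the order in which the three rules
are applied; groups larger than two are pruned to a single survivor.

Time origins: recruitment date for cancers diagnosed on or before
baseline, diagnosis date for later diagnoses. The delay covariate is
max(0, recruitment − diagnosis) in days. Follow-up for event-free
participants ends at the last registered death date in the dataset — a
single administrative censoring date with no per-person loss to
follow-up. This is unusual but implemented literally; with a common
recruitment era it behaves like administrative censoring and leaves the
partial likelihood unbiased, because no events exist beyond the horizon.
Participants whose recorded event predates their time origin are dropped
and logged. Multiple cancers per participant are resolved to the earliest
qualifying diagnosis. Unknown smoking status is kept in descriptive
tables and removed by complete-case deletion in models.

## Models and numerics

- Logistic fits: `statsmodels` Logit (Newton ML), Wald CIs on the log-OR
  scale. LOY/LOX models run on the sex-restricted subset without a sex
  covariate. Non-finite standard errors flag separation in the output.
- Cox fits: `statsmodels` PHReg with Breslow tie handling (ties are rare
  with day-resolution times; Breslow keeps the partial likelihood simple
  and is the assumption under which the test oracles are written). The
  coefficient covariance feeds the delta-method interaction CIs. Fits
  require ≥ 10 events; an exposure category with zero events raises a
  category-naming error that the report layer converts to a
  "not reportable" flag instead of a crash.
- Interaction CIs: the default delta method propagates the exposure-block
  covariance through each metric's gradient in coefficient space, on the
  natural scale (the source tables print symmetric intervals). A
  participant-resampling bootstrap (seeded, default 1000 replicates,
  percentile intervals) is available, and is the fallback when the
  covariance is singular.
- Rounding for display: percents half-up to 1 decimal, ratios/metrics
  half-up to 3 decimals.

## The synthetic cohort generator

The generator emulates the study conditions so that the cascade and the
models can be exercised and validated end-to-end:

- **Demographics**: age truncated-normal (mean 60, SD 7, range 40–71);
  54.2% women; smoking never/previous/current/unknown ≈ 48.8/39.5/11.1/
  0.6%; chemotherapy 23.3%, radiotherapy 6.3%, prevalent CVD 22.6%;
  TERT rs7705526 dosage Binomial(2, 0.3); ten standard-normal genetic
  PCs; cancer types at configurable frequencies with sex-specific types
  drawn conditionally.
- **CHIP carriage**: logistic in centered age (log-OR 0.077/year),
  current/previous smoking and chemotherapy; the intercept is calibrated
  numerically on the realized linear predictors so the marginal
  prevalence matches the configured 5.5% exactly up to binomial noise.
  Carriers receive 1/2/3+ mutations with probabilities 84.4/8.6/7.0%,
  genes at shares matching the reported carrier composition (DNMT3A 52%,
  TET2 22%, ASXL1 14%, …), split between a few high-frequency hotspots
  and long tails of unique variants. Tail variants stay below the
  20-carrier recurrence threshold at the default scales; hotspot variants
  carry enough age-enriched carriers that the recurrence filter retains
  them with probability ≈ 1.
- **Clone sizes**: VAF ~ Beta(1, 6) truncated at the 2% detection floor,
  giving P(VAF ≥ 0.10) = 0.60, near the reported 63.4% expanded-CHIP
  share. The source reports no VAF distribution; this is a stand-in.
  Read evidence is drawn as DP ~ 30 + Poisson(15) and AD ~ Binomial(DP,
  VAF), with DP escalated and AD redrawn until the record is
  rule-compliant (AD ≥ 5, realized VAF ≥ 2%, and — for missense variants
  subject to the binomial test — exact p < 0.01; such target VAFs are
  capped at 0.40, since clones nearer 0.5 are not separable from germline
  at realistic depth). Small clones therefore receive deeper coverage
  rather than inflated alt counts, standing in for the depth-dependence
  of real detection.
- **Decoys**: a configurable fraction of participants receive labelled
  decoy variants that each violate exactly the rule they exercise
  (sub-threshold DP/AD/orientation, homopolymer context with low
  AD and VAF, germline-like VAF ≈ 0.5 conditioned to p ≥ 0.05, the three
  named artifacts), plus a recurrent decoy site (GNAS p.R201C) assigned
  to ~0.4% of participants independently of age and TERT. Truth labels
  record every decoy's kind, so the cascade's confusion matrix can be
  checked exactly; recurrent decoys are stochastic by design (≈ 81%
  removal) and are evaluated separately from the exact check.
- **mCAs**: LOY among men (≈ 29% at the margin, log-OR −0.43 with CHIP),
  LOX among women (≈ 6.2%, log-OR +0.22 with CHIP), autosomal events
  (≈ 5.5%), all age-increasing, jointly targeting ≈ 20.7% any-mCA
  prevalence; cell fractions ~ Beta(0.4, 6.74), giving P(≥ 0.10) = 0.19
  to match the reported expanded-mCA share. Again a stand-in
  distribution.
- **Events**: exponential proportional hazards per endpoint from the
  participant's time origin, with configurable exposure log-HRs
  (defaults near the published four-category estimates, e.g. CHIP-only
  incident CVD HR 1.082) and covariate effects, administratively
  censored at a 15-year horizon. Exponential baselines were chosen over
  Weibull for closed-form sampling; Cox fits are baseline-agnostic, so
  recovery tests lose nothing. Endpoints are generated as independent
  processes (a CV-death event does not force an any-death event); the
  analysis treats endpoints marginally, so no test depends on
  cross-endpoint coherence.

What passing tests therefore show: the cascade implements its rules
exactly; the models recover known effects from data that satisfy their
assumptions; the interaction arithmetic and intervals are correct. What
they do not show: performance under real sequencing error profiles,
correlated endpoints, non-proportional hazards, informative censoring, or
linkage structure — none of which the generator attempts to emulate.

## Problem sizes used in the checks

The packaged checks use 50,000 participants for the cascade
confusion-matrix check (the scale at which the recurrence filter engages
its hotspots), 50 replicates of 20,000 for Cox parameter recovery, 500
replicates of 5,000 for the null RERI coverage check (with CHIP/mCA
prevalences raised to 30% so the joint-exposure cell carries enough
events for asymptotics), and 250 replicates for the recurrence-filter
null removal rate. These sizes give Monte-Carlo error small enough for
the stated bands while keeping a full run in minutes on one CPU.

## Known limitations

- The packaged whitelist is a stand-in; swap in a site-specific TSV for
  real analyses.
- The upstream callers are out of scope: somatic variant calling from
  reads, and mCA detection from LRR/BAF arrays, are consumed as inputs.
- No competing-risks or time-varying-exposure modelling; CH status is a
  one-time baseline measurement.
- The literal last-registered-death censoring rule assigns event-free
  participants a common calendar censoring date; if recruitment eras
  differed strongly this would need per-person censoring dates instead.
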