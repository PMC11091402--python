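# Methods

## The problem

External quality assessment (EQA, also called external proficiency
testing) programmes send identical blinded samples to many
histocompatibility and immunogenetics laboratories, collect their
results, decide what the *true* (assigned) value of every parameter is,
score each laboratory result against it, and publish success rates.
`immunoeqa` implements that evaluation chain for the thirteen scheme
types of a long-running national immunogenetics programme — serological
and molecular HLA typing (low and high resolution), HLA-B27 and
HLA-B\*57:01 detection, coeliac-disease-related HLA, KIR and HPA typing,
anti-HLA and anti-HPA antibodies, CDC and flow-cytometry crossmatches,
and chimerism — together with a seeded synthetic-report generator, so
that the whole pipeline is testable without access to the programme's
confidential per-laboratory data.

## Assigned values

Three assignment modes exist, chosen per parameter kind:

* **Reference** (DNA-based typing schemes): an organiser/reference
  genotype is taken as correct outright, regardless of what participants
  reported.
* **Consensus** (qualitative parameters): antibody specificities use a
  two-sided rule with thresholds `pos_threshold = 0.75` and
  `neg_threshold = 0.95` — POSITIVE when ≥ 75 % of laboratories report
  the specificity, NEGATIVE when ≥ 95 % omit it, a *non-assessable
  negative* (never penalised) when 75–95 % omit it, and NO_CONSENSUS
  otherwise. With the defaults the positive fraction *p* partitions as
  NEGATIVE (p ≤ 0.05) / NON_ASSESSABLE (0.05 < p ≤ 0.25) / NO_CONSENSUS
  (0.25 < p < 0.75) / POSITIVE (p ≥ 0.75); every boundary is inclusive
  ("at least"). Crossmatch, screening, presence and interpretation calls
  use the same 75 % threshold as a majority rule, and genotypes without
  a reference use it on concordance-equivalence classes of reports
  (members mutually concordant at their shared resolution; the modal
  class's highest-resolution member is assigned). The 75 % typing/
  qualitative threshold generalises the documented antibody threshold
  and is configurable.
* **Robust statistics** (chimerism, the only quantitative parameter):
  the ISO 13528 Annex C "Algorithm A" robust location x\* and scale s\*.
  Initialise x\* at the median and s\* at 1.483 × MAD; iterate —
  winsorise at x\* ± 1.5 s\*, set x\* to the mean and s\* to 1.134 × the
  sample standard deviation (n−1) of the winsorised values — until both
  move by less than `tol·max(s*, tol)` (`tol = 1e-6`, `max_iter = 100`).
  When at least half the values coincide the MAD is zero and the
  iteration stops immediately with s\* = 0 (the winsorisation band is
  empty; the estimates cannot move). When no value leaves the band the
  fixed point is exactly the arithmetic mean and 1.134 × sd.

A consensus needs at least `min_consensus_n = 3` quantitative returns;
this floor is a package convention, not a programme rule, and is
configurable.

## Scoring and the error taxonomy

Every result becomes exactly one of CORRECT, ERROR (with exactly one
category) or NOT_EVALUABLE (no assigned value; excluded from every
numerator and denominator). Typing reports walk a fixed decision order
so the taxonomy partitions the error space:

1. unparseable payload or wrong locus → NOMENCLATURE;
2. any reported ambiguity containing a null allele (expression suffix
   `N`) that the laboratory did not explicitly exclude, while the
   assigned genotype is fully expressed → NULL_ALLELE.  Exclusions must
   be listed per allele; a generic "every null allele excluded"
   annotation is not a concept the data model admits;
3. genotype concordance → CORRECT.  Concordance is judged at the
   reported resolution (a reported allele concordant when its fields
   are a numeric prefix of the truth's), so stopping short of allelic
   resolution is never penalised; expressed-versus-null conflicts are
   always discordant even on matching digits; a homozygous claim (one
   allele, written once or twice) matches only a homozygous truth;
4. a single distinct reported allele against a heterozygous assigned
   genotype, concordant with one copy → HOMOZYGOSITY;
5. anything else → ALLELE_MISMATCH (the "random" wrong-allele residual).

Antibody panels score per specificity (false positive / false negative
against the consensus map), screening calls carry the SCREENING
category, and the DQ/DP two-antigen-bead interpretation call is an
ordinary qualitative parameter. Whole-blood crossmatches are scored
against the whole-blood consensus only — never against OR(T-cell,
B-cell) — which is exactly how over-interpretation of separated
crossmatches becomes a scoreable error. Disease-association schemes add
a risk-interpretation item: the laboratory's risk label is compared with
an ordered, config-supplied genotype-pattern → category map applied to
the *assigned* genotypes (the packaged coeliac map grades DQ2.5/DQ8
dose; it is a literature-informed default, editable per scheme).

Chimerism results are accepted when |value − x\*| / s\* ≤ `z_limit`
(default 2.0); when s\* = 0 an absolute window of `abs_tol` = 5
percentage points applies. Both knobs are configurable; the programme
literature does not quantify its acceptance window, so these defaults
are package conventions.

The per-laboratory scheme-year outcome is PASS when at most
`max_error_samples = 1` samples contain an error (configurable; pass
criteria are cited by EQA standards but not quantified).

## Aggregation

Success rate = 100 × error-free results / valid results. Yearly scheme
rates average unweighted into scheme means; scheme means average
unweighted (over *unrounded* values) into analytical-family means — the
only reading that reproduces the programme's published family figures
from its published yearly table. Percentages are rounded half-up to one
decimal at presentation only. The published 12-year summary tables
(participation, result volumes, yearly success rates, scheme registry)
ship as package data and drive both the regression tests and the
simulator defaults. Two published inconsistencies are deliberately not
"fixed": the B57 printed 12-year mean is 0.1 above the mean of its
printed yearly values (likely computed on unrounded inputs), and the
quoted molecular-typing grand total exceeds the sum of the published
per-scheme volumes; the package always reports the recomputed values.

## The synthetic generator

`SimulationConfig` defines the study conditions. Defaults are a "mini
programme" sized to run in seconds: up to 20 laboratories per
scheme-year (published participation, capped), 8 samples per scheme-year
(16 for chimerism), years 2020–2022, per-scheme-year error rates equal
to one minus the published success rates, and per-scheme category mixes
equal to the published pooled shares — high-resolution typing 60.1 %
null-allele (remainder split mismatch/homozygosity), chimerism 62.2 %
quantification (remainder modelled as a qualitative interpretation
call), KIR 40.1 % allele-variant mismatch (remainder
homozygosity-reporting), antibodies 89.7 % specificity identification /
1.4–1.9 % screening / 5.4 % DQ/DP interpretation (midpoint taken for
screening; the three published shares sum to ~97 %, so they are
normalised to one). Coeliac-disease and serology mixes are unpublished
and default to package conventions (risk-interpretation–dominant and
mismatch-dominant respectively).

Design choices that make the generator a *calibration instrument*:

* **Item-type-aware injection.** A sample may carry items of several
  types (chimerism: one quantitative value + one interpretation call;
  antibodies: specificities + screening + DQ/DP). The per-item error
  probability is `rate · mix_mass(type) · n_items / n_type`, which
  matches the overall per-result error rate and the category mix
  simultaneously; probabilities saturate at 1 for extreme rates.
* **Exact recoverability.** Truth genotypes draw two *distinct*
  expressed alleles (sampling without replacement), so an injected
  homozygosity error is always realisable and the category mix is not
  distorted by unrealisable draws; nulls exist in every locus pool but
  only as injected ambiguity alternatives. Clean quantitative reports
  reproduce the true value exactly (`report_noise = 0` by default): the
  robust scale of the clean majority degenerates to zero and the 5-point
  absolute window takes over, so the expected recovered success rate
  equals 100 × (1 − rate) by construction. A nonzero bounded-uniform
  `report_noise` is available, but any within-window spread makes the
  sample-based |z| ≤ 2 rule fail a small fraction (≈ 0.2–3 %) of honest
  reports — an intrinsic property of robust z-scoring with ~20
  participants, not an implementation artefact, and the reason the
  calibration default removes it.
* **Stream independence.** Each (scheme, year) truth panel and each
  (scheme, year, laboratory) report stream has its own RNG derived from
  the master seed, so adding a scheme or laboratory never perturbs
  another's draws and equal seeds give byte-identical output files.
* **Laboratory heterogeneity.** An optional lognormal per-laboratory
  error-rate multiplier (`lab_error_sigma`, default 0) supports
  pass-all-schemes statistics; the programme publishes no
  per-laboratory model.

What the generator does **not** emulate: realistic HLA haplotype
frequencies or linkage (pools are small fictitious-but-valid allele
sets), assay physics (probe dropout, fluorescence), year-to-year drift
of category mixes (held constant per scheme), or honest-but-deviant
quantitative spread (see above). Passing recovery tests therefore
demonstrates that the pipeline measures what was injected — not that
real laboratories behave like the generator.

## Numerical conventions

Field tokens preserve leading zeros but compare numerically
("02" ≡ "2"); rendering is canonical uppercase with two-digit minimum
fields. Ambiguity alternatives and genotype copies sort canonically, so
parse → render is a fixed point after one normalisation. Genotype
consensus ties (two classes of equal modal size) are NOT_EVALUABLE.
Method-frequency ties break lexicographically and are flagged. Threshold
comparisons are inclusive throughout. Half-up decimal rounding is used
for all printed percentages (never banker's rounding).

## Problem sizes used in checks

The end-to-end recovery checks run the chimerism scheme at 20
laboratories × 16 samples × 200 seeds (≈ 128 000 scored results) against
the published 94.8 % mean success rate and 62.2 % quantification share,
and smaller replicate sets for the high-resolution-typing null-allele
share and the KIR allele-variant share. These sizes give Monte-Carlo
standard errors of ≈ 0.06 percentage points on the recovered success
rate and ≈ 1–3 points on category shares, and complete in well under a
minute on one core.
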