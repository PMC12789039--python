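# Methods

## The attributable-fraction model

For a categorical exposure with levels *i* = 0…k (level 0 the lowest-risk
reference), the population attributable fraction is computed from case
fractions and risk ratios:

    PAF_i = p_ci · (RR_i − 1) / RR_i,        PAF = Σ_{i≥1} PAF_i

with `p_ci` the fraction of all cases observed in level *i* and `RR_i` the
risk of level *i* relative to the reference. The form is exact under the
counterfactual "everyone experiences the reference risk": since the
expected counterfactual case count in level *i* is `cases_i / RR_i`, the
total PAF equals `(observed − Σ cases_i/RR_i) / observed`. Two consequences
are used as test oracles throughout:

- **Excess-case identity.** On any simulated cohort, the formula evaluated
  at empirical case fractions and the *generative* RRs equals brute-force
  excess-case counting exactly (to float precision).
- **Levin reduction.** With a single exposed level of prevalence `q_e`,
  the formula collapses to Levin's `q_e(RR−1)/(1+q_e(RR−1))` whenever case
  fraction and prevalence are mutually consistent.

Here the exposure is the *APOE* genotype with six levels, ε2/ε2 as the
reference: attributable fractions against ε3/ε3 (the common convention)
would understate the burden because ε3 itself raises risk relative to ε2.

### Confidence intervals

PAF CIs are plug-in: every per-level PAF is re-evaluated at the lower
(resp. upper) 95% bounds of the RRs and summed. Only RR uncertainty is
propagated; sampling error in the case fractions is ignored, which makes
the intervals anti-conservative. This is a deliberate design choice so the
reproduction paths match the published quantities' construction, and it is
flagged in the API docs. PAF intervals are asymmetric near 1 because the
transform plateaus as RR → ∞.

### OR→RR conversion

Case-control designs and logistic fits deliver odds ratios. They are
converted with `RR = OR / (1 − p0 + p0·OR)`, where `p0` is the assumed
outcome probability in the reference genotype (default 0.01 = a 1%
baseline probability of disease in ε2/ε2). The conversion is applied
identically to point estimates and both CI bounds. `RR` always lies
between 1 and `OR` and decreases in `p0` for OR > 1; a 1–5% sensitivity
sweep is built in (`sensitivity_p0`) and shows totals moving by only a few
percentage points on the embedded case-control table.

### Allele partition

The five risk genotypes split cleanly between alleles except ε3/ε4. Its
PAF is divided with weight `w4 = RR(ε2/ε4) / (RR(ε2/ε3) + RR(ε2/ε4))`
to ε4 — each allele weighted by the risk it confers when added to an ε2
background ("rr-proportional", the default) — or with RR−1 weights
("excess-rr-proportional"). Both rules satisfy exact closure:
ε3 share + ε4 share = five-genotype total. The rule identifier is recorded
in every output because the split is a modelling convention, not an
estimable quantity. Partition CIs are the same plug-in construction as
the totals and should be read with the same caution; the shares' bounds
are not independently validated against any external value.

## APOE coding

Unphased diplotypes at rs429358/rs7412 map to genotypes through the
haplotype definitions ε2 = (T,T), ε3 = (T,C), ε4 = (C,C). The double
heterozygote (C/T at both SNPs) is consistent with both ε2/ε4 and ε1/ε3;
the default policy assigns ε2/ε4 (ε1 is vanishingly rare), with
`ambiguity_policy="missing"` available to drop such individuals instead.
The three diplotypes only explicable with an ε1 haplotype return missing
rather than raising, mirroring how anomalous alleles are excluded in
practice. Hardy–Weinberg equilibrium is checked with a chi-square on the
six genotype classes against the triallelic HWE expansion, df = 3
(6 classes − 1 − 2 estimated allele frequencies); an exact test is out of
scope.

## Risk estimation

- **Crude estimators** operate on count tables: cohort-design risk ratios
  and case-control odds ratios, both with Wald CIs on the log scale.
  A Haldane–Anscombe 0.5 continuity correction is available but **off by
  default** — the embedded tables need none, and silent corrections change
  results. Zero cells raise errors naming the offending cell.
- **Re-orientation** of an OR set to a new reference is exact when the
  source counts are available (the 2×2 tables are simply rebuilt); from
  summary estimates alone, points and bounds are divided by the reference
  OR, an approximation (reference-OR sampling error ignored) recorded in
  the provenance string.
- **Log-binomial GLMs** (binomial family, log link; statsmodels IRLS)
  estimate RRs directly from individual-level tables. When fitted
  probabilities reach the boundary of the mean space — the canonical
  failure when high-risk strata approach certainty of disease — the fit
  raises a `ConvergenceError` that points at the logistic + conversion
  fallback. The switch is never made automatically: which model a dataset
  gets is an analyst decision, and a silent fallback would hide it.
- **Logistic GLMs** provide the OR path; with a genotype-only design the
  MLE reproduces the crude contingency ORs exactly (saturated categorical
  model), which the tests exploit as a cross-check.

## Synthetic cohorts

The generator emulates a biobank-style ageing cohort: six-genotype
multinomial draw (defaults: the genotype distribution of a ~171k-person
60+ cohort, ε3/ε3 ≈ 58.9%, ε3/ε4 ≈ 23.4%), risk multiplicative in the
genotype RR (defaults: the AD gradient 1.68 → 23.36 against ε2/ε2) and
optional log-scale age/sex effects around a Normal(64.1, 2.8²) age and
Bernoulli(0.5) sex. Baseline risk defaults to 0.01, the same 1% ε2/ε2
baseline used by the OR→RR conversion, so crude and adjusted quantities
coincide under the zero-covariate default. Parameter sets whose implied
maximum individual risk exceeds one are rejected at construction (the
covariate multiplier is bounded at ±4 SD of age); residual tail risks are
clipped at 1. Diplotypes are emitted by inverse coding, with ε2/ε4
individuals deliberately written as the ambiguous double heterozygote so
the coding policy is exercised downstream.

Sampling designs:

- **cohort** — n independent subjects;
- **case-control** — fixed case/control quotas filled by batched rejection
  sampling from the cohort model, so a case's genotype follows the exact
  conditional law `q_i·RR_i / Σ q_j·RR_j` (a distributional test target);
- **screened** — affected subjects are retained with a genotype-specific
  probability, unaffected subjects always. This models volunteer/screening
  selection in which people with established disease — disproportionately
  the high-risk genotypes — never enter the sample; retention falling with
  genotype risk biases the high-risk RR estimates toward the null, and a
  test asserts that direction. The mechanism is qualitative: no attempt is
  made to calibrate its strength to any real screening process.

The closed-form `true_paf` (case fractions `q_i·RR_i/Σ q_j·RR_j` pushed
through the PAF formula) is exact under zero covariate effects and is the
recovery target for the estimation pipeline: at n = 100,000 the
seed-averaged estimated total PAF sits within 3 Monte-Carlo standard
errors of it.

What the generator does **not** emulate: follow-up time and competing
mortality, relatedness and population structure, genotyping error,
covariate-confounded genotype distributions. Passing recovery tests
therefore demonstrate the estimators' correctness under the generative
model, not robustness to those real-data complications.

## Locus-level PAFs

For a biallelic GWAS locus, genotype frequencies follow HWE from the risk
allele frequency, per-genotype odds are (1, OR, OR²) under the default
multiplicative dosage model or (1, OR, OR) under dominant/carrier coding,
ORs are converted to RRs at `p0`, and case fractions are the HWE-implied
ones `q_i·RR_i/Σ q_j·RR_j` — real GWAS case fractions are not recoverable
from summary statistics, so outputs are labelled `hwe-implied`. Dominant
PAFs are bounded above by multiplicative PAFs at equal frequency and
OR > 1. Ranking is by PAF descending with a stable id tie-break. PAFs of
different loci may legitimately sum past 100%: attributable fractions of
non-exclusive causes overlap.

## Embedded published tables and reproduction scope

The fixtures carry the in-text tables of the source analyses: the
neuropathology case-control genotype counts (4018/989), the screening
sample's two-level positivity counts (1/25 vs 1202/4390; SUVr ≥ 1.15
defines positivity), the four cohorts' per-genotype RR sets, the FinnGen
per-genotype PAF points, and a 171k-cohort genotype distribution. A SHA-256
digest over all embedded values is checked before every reproduction run.

Two reproduction paths are kept deliberately separate: injecting the
published RRs into the PAF formula (matches the published totals to their
printed rounding), and recomputing from raw counts (crude ORs converted at
`p0 = 0.01`), which reproduces the published RRs to within ~1–3% relative
— the residual reflects that the published values derive from the source
study's covariate-adjusted ORs, while the counts path is crude. The
biobank-scale individual-level analyses and the specific GWAS locus values
cannot be reproduced from embedded data; their machinery is covered by the
property and simulation suites instead.

## Numerical conventions

- Reported percentages round to 1 decimal, RRs to 2, in the report layer
  only; JSON artifacts keep full precision.
- Wald CIs use z = 1.959963984540054 throughout.
- Genotype labels are canonicalised to ASCII (`e3/e4`), order-insensitive,
  with Unicode ε accepted on input.
- Problem sizes in the test suite (cohorts of 10⁴–4·10⁵, five seeds for
  recovery) keep each distributional test's false-alarm probability low at
  multinomial/binomial 99–99.9% bounds while the whole suite stays fast;
  all seeds are fixed in the tests.
- The staged runner logs every numeric default in force (p0, SUVr
  threshold, partition rule, ambiguity policy), the seed, the package
  version and input digests to `run_log.jsonl`; identical configs produce
  byte-identical artifacts.
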