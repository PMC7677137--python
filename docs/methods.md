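# Methods

This note documents the models implemented in `hlamatch`, the synthetic
data they are exercised on, the numerical choices, and what the package's
tests do and do not demonstrate about real registry data.

## Compatibility model

Allele names follow WHO HLA nomenclature restricted to the five classical
transplant loci (HLA-A, -B, -C, -DRB1, -DQB1): colon-separated numeric
fields, an optional G-group suffix, and NMDP-style multiple-allele codes
for ambiguously typed donors.  Two comparison resolutions are supported:

* **low** — equality of the first field (allele group);
* **medium** — equality of the first two fields after truncation; a
  G-suffixed name is truncated to its two-field prefix before comparison
  (full G-group equivalence tables are out of scope); a code on the donor
  side is compatible when the patient's two-field allele is a member of
  its expansion.

A per-locus mismatch count between two unordered genotypes is 2 minus the
best bijective pairing of compatible alleles; a search allows a total of
0 or 1 mismatches summed over the queried loci (so a 9/10 search means at
most one mismatched allele anywhere, not one whole locus — the allowance
is stated per allele).  Searches at 6/6 query HLA-A/-B/-DRB1, 8/8 adds
-C, 10/10 adds -DQB1.

Two conservative rules cover situations registries leave implicit:

* a donor typed at only one field can never be *confirmed* compatible in
  a medium-resolution search and is therefore treated as incompatible
  (this mirrors clinical confirmatory-typing practice; the alternative —
  treating one-field typings as wildcards — would overstate
  medium-resolution match rates);
* a donor untyped at a required locus is excluded from that search and
  counted, not treated as wildcard-compatible, which reflects that only
  the typed subset of a registry can be queried at 8/8 or 10/10.

The indexed engine hashes canonical truncated-genotype keys (donors with
codes are indexed under every expansion member; single-mismatch searches
consult per-locus relaxed indexes and verify the relaxed locus per
candidate).  It is checked for exact set equality against a naive scan
that applies the allele-level rules donor by donor.

## Synthetic population

The generator emulates, at desk scale, a registry-match study in a
three-way admixed population.  Its defaults are the study conditions;
they are not tuned per run.

**Haplotype pools.**  Two ancestry-specific pools of five-locus
haplotypes.  Allele universes are nested per locus: the African pool has
more allele groups (e.g. 26 vs 16 at HLA-B) and more two-field variants
per group (4 vs 2); 80% of the European groups are shared with the
African set, modeling worldwide allele sharing.  Haplotypes are sampled
from per-locus group frequencies (Dirichlet, concentration 0.8) and pool
frequencies are Dirichlet with concentration 1.0 over 500 haplotypes
(African) vs 0.8 over 120 (European).  This realizes the single premise
driving the analysis — higher African HLA diversity: the African pool has
strictly more distinct haplotypes, higher expected heterozygosity at
every locus, and a smaller collision probability Σp² (≈0.004 vs ≈0.02
for full haplotypes under the default seed).

**Admixture.**  Genome-wide African ancestry q_AFR is Beta-distributed
per cohort: mean 0.309 for the default merged-style cohort, 0.497 for the
high-admixture variant, 0.52 for the sickle-cell (SCD) sub-cohort —
matching the emulated cohorts' printed mean ancestries.  Native American
ancestry is drawn as q_NAT = (1 − q_AFR)·Beta(1.0, 10.3) (≈6% overall
mean); it participates in the simplex and in SNP generation but has no
dedicated haplotype pool — NAT-labelled MHC haplotypes draw from the
European pool, because the analysis contrasts African vs European
ancestry only.

**MHC segment.**  The MHC is modeled as the interval delimited by HLA-A
and HLA-DQB1 (2,724,220 bp), with loci at their physical offsets.  Each
of the two haplotypes is assigned African ancestry with probability
q_AFR.  By default the whole segment inherits one ancestry
(haplotype-block model, recombination off), because the analysis treats
MHC ancestry at segment level; a config switch enables within-segment
switches with probability 1 − exp(−g·d) per inter-locus interval
(d in Morgans at 1 cM/Mb, g = 8 generations since admixture), producing
fractional per-haplotype African fractions.  The African-MHC dosage class
(0/1/2) rounds each haplotype's fraction to the nearest integer and sums;
halves round up (toward African) — the rounding direction is a fixed
convention required for reproducibility, and rounding is per chromosome
(the class is a count of chromosomes with African MHC), not applied to
the summed dosage.

**Self-identification.**  Census-style labels are an ordered-threshold
readout of q_AFR: latent = q_AFR + σ·N(0,1), with thresholds 0.25/0.5
separating "White"/"Mixed"/"Black"; "Indigenous", "Yellow" and
"NonInformed" occur at small fixed rates (1%, 0.8%, 1.7%) and are
excluded from contrasts.  σ is calibrated by bisection (common random
numbers, 60 iterations) so that the three main categories explain a
target fraction of the variance in q_AFR — 0.64 for the merged-style
cohort, 0.31 in high-admixture mode.  The calibration sample defaults to
20,000 draws: the R² estimator's sampling sd is ≈0.01 at n = 4,000,
which would consume most of the ±0.02 calibration band, so a larger
sample is used purely for numerical accuracy.

**Registry.**  20,000 donors by default, drawn with the self-ID
composition 54.64% "White", 23.44% "Mixed", 7.17% "Black", 0.46%
"Indigenous", 3.31% "Yellow", 10.97% "NonInformed" (the printed
composition of the emulated registry; it sums to 0.9999 as printed and is
renormalized).  Donor ancestry is drawn from category-conditional Betas
(means ≈0.18/0.38/0.61 for White/Mixed/Black) and genotypes by the same
admixture mechanism as patients.  All donors are typed at HLA-A/-B/-DRB1;
HLA-C and -DQB1 are each typed with probability 0.35.  The real registry
types C/DQB1 for only ~2.6% of donors, but of 4.9 million — copying the
fraction at n = 20,000 would leave ~13 donors eligible for 10/10
searches, so the fraction is a desk-scale choice that keeps the extended
loci sets statistically usable while preserving the qualitative typing
heterogeneity.  Typing resolution is per donor (half low, half medium),
emulating decades of accumulated typing technologies with one knob; 15%
of medium donors have one allele replaced by a generated multiple-allele
code covering it (the code table is written beside the registry and can
be swapped for a real NMDP table with the same JSON schema).

**SNP panel.**  2,000 unlinked biallelic SNPs with Balding–Nichols
parental frequencies (ancestral frequency uniform on [0.05, 0.95],
divergence F = 0.2).  The panel stands in for an 800k-SNP array in a
supervised ancestry fit, so it is modeled as an ancestry-informative
subset rather than genome-average markers: at F = 0.15 the Fisher
information of 2,000 random SNPs caps the achievable q_AFR RMSE near
0.03 (measured by direct likelihood optimization on simulated data),
i.e. the panel would be information-poorer than the array-scale
inference it emulates.  Linkage, genotyping error and LD pruning are not
modeled.

**What passing tests show.**  The generator reproduces composition
percentages, mean ancestries and the qualitative diversity ordering; it
does not use real HLA frequency catalogs, realistic linkage, or
coalescent history.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that the ancestry-effect hierarchy
follows from the diversity premise — not that the synthetic match rates
equal real-registry rates (absolute rates scale with registry size and
pool diversity).

## Ancestry estimation

The supervised estimator maximizes ∏_j Binom(g_j | 2, Σ_k q_k f_kj) over
the K = 3 simplex by EM, parental frequencies fixed and clamped to
[1e−6, 1−1e−6].  Convergence is a log-likelihood gain below 1e−7, capped
at 1,000 iterations; EM is monotone (asserted per iteration in tests) but
converges sublinearly near the simplex boundary, so boundary-ancestry
individuals may legitimately end unconverged at the cap with accurate
estimates.  Missing dosages are skipped; a flat frequency matrix
(indistinguishable populations) returns the uniform vector flagged
unconverged.  A vectorized whole-cohort variant freezes individuals as
they converge.  Bootstrap uncertainty and LD handling are array-QC
machinery for real data and are not reproduced — the synthetic SNPs are
unlinked by construction.

Quartiles of African ancestry are rank-based with stable tie-breaking
(hence invariant to monotone transformations); degenerate boundaries are
flagged, not fatal.

## Reported statistics

* **Odds ratios**: 2×2 cross-product with Woolf (log-normal) 95% CI and a
  Wald p-value; a logistic fit cross-checks the closed form (agreement to
  1e−6).  A zero cell triggers the Haldane–Anscombe 0.5 correction,
  flagged, and skips the logistic cross-check (no MLE under separation).
  The CI method and the Wald (rather than likelihood-ratio) p-value are
  implementation choices; the source analyses report univariate ORs
  without naming either.
* **Percent decrease**: 100·(r_ref − r_cmp)/r_ref.  Because the groups
  compared differ in size, the size-matched variant repeatedly subsamples
  the larger group to the smaller group's n (200 seeded replicates,
  without replacement) and averages the rate before the ratio; a single
  subsample would inject avoidable Monte-Carlo noise, and the estimate
  converges to the plain rate when rates are size-independent (tested).
* **Donor composition**: per patient the category frequencies among that
  patient's matched donors; per group the unweighted mean of those
  per-patient vectors ("average of individual averages"), which weights
  patients equally rather than donors — distinct from pooling counts.
* **Mann–Whitney U** on donor counts among matched patients: normal
  approximation with tie correction at cohort scale, exact null for
  small untied fixtures.
* **Two-proportion z-test**: pooled variance, two-sided.
* **Rounding** of reported values: half away from zero; one decimal for
  rates, integer percents for decreases.  (With this convention the
  two-sibling probability 43.75% prints as 43.8.)

## Pipeline and reproducibility

Stages (`simulate`, `ancestry`, `match`, `analyze`, `report`) are pure
functions of (config, seed, artifact directory); each can be re-run from
the artifacts of its predecessors.  One global seed is expanded into
per-stage streams keyed by fixed constants, so adding a stage never
perturbs earlier stages' draws.  Every CSV carries a schema comment line;
the manifest records a config hash and SHA-256 checksums of all outputs,
and identical (config, seed) runs are byte-identical.  Counts that real
analyses handle silently — donors excluded for missing loci, zero-cell
corrections — are logged.

Default problem sizes (cohort 2,000 + 417 SCD, registry 20,000, 2,000
SNPs, all 12 search specs) were chosen so a full run completes in a few
minutes on one CPU; all group contrasts in the default run are separated
by many binomial standard errors, so the asserted orderings are stable
across seeds.

## Known limitations

* No real HLA allele/haplotype frequencies; allele names are synthetic
  labels with realistic structure.
* No donor availability, attrition or confirmatory-typing workflow; a
  "match" is a genotype query hit.
* Native American ancestry has no dedicated haplotype pool and no effect
  analyses.
* Serological equivalents, expression suffixes (N/L/S/Q), DRB3/4/5 and
  DPB1 are out of scope.
* The conservative one-field-donor rule makes medium-resolution match
  rates lower bounds.
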