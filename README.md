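# hlamatch

Ancestry-aware analysis of the chance of finding an HLA-compatible
unrelated donor in a volunteer registry, exercised end to end on a
synthetic admixed cohort and a synthetic registry.

## The problem

Allogeneic hematopoietic stem-cell transplantation requires the patient
and donor to match at the classical HLA loci (HLA-A, -B, -C, -DRB1,
-DQB1).  HLA is the most polymorphic region of the human genome, and its
variability is highest in populations of African origin, so two unrelated
individuals of African ancestry are less likely to share a multilocus HLA
genotype than two Europeans.  In admixed populations this creates a
layered question: how well do (i) census self-identification labels,
(ii) genome-wide genetic ancestry q = (q_AFR, q_EUR, q_NAT), and (iii)
the local ancestry of the MHC segment itself predict the chance of
finding a registry match?  `hlamatch` is for population and transplant
geneticists who want a tested, reusable implementation of that analysis:
a registry match engine with the standard search grid, a supervised
ancestry estimator, the full reporting statistics, and a seeded generator
that emulates the study conditions at desk scale.

## What it computes

* **Match searches.** Full matching at 3, 4 and 5 loci (6/6, 8/8, 10/10)
  and single-allele-mismatch searches (5/6, 7/8, 9/10), each at low
  resolution (one allele field: any variant of A\*34 is compatible with
  A\*34:02) and medium resolution (two fields: only variants of A\*34:02,
  or an NMDP-style multiple-allele code whose expansion contains 34:02).
  Donors untyped at a required locus are excluded and counted.  An
  indexed engine is verified against a naive scan.
* **Ancestry.** Supervised maximum-likelihood admixture proportions from
  SNP dosages: q maximizes ∏_j Binom(g_j | 2, Σ_k q_k f_kj) over the
  K = 3 simplex via EM with fixed parental frequencies f.  Individuals
  are grouped into quartiles of q_AFR and into MHC African-dosage classes
  0/1/2 (each chromosome's African fraction of the MHC segment rounded to
  the nearest integer).
* **Statistics.** Per-group match rates; odds ratios (2×2 cross-product
  with Woolf CIs, cross-checked by logistic regression); size-matched
  percent decreases 100·(r_ref − r_cmp)/r_ref; donor-composition tables
  (average of individual averages); Mann–Whitney U on donor counts; the
  two-proportion z-test for the sickle-cell-disease contrast; and the
  sibling match probability 1 − (3/4)^k.

## Worked example

```bash
hlamatch all --seed 1 --out runs/demo
```

simulates the default study (2,000-member admixed cohort plus a
417-member sickle-cell sub-cohort, 20,000-donor registry), estimates
ancestry from 2,000 SNPs, runs all 12 search specs and writes
`runs/demo/report.md`.  With seed 1 the headline tables read:

| Loci  | Resolution | % at least one match | Median matches | Max matches |
| ----- | ---------- | -------------------- | -------------- | ----------- |
| 6/6   | low        | 64.0                 | 6              | 133         |
| 8/8   | low        | 42.7                 | 2              | 25          |
| 10/10 | low        | 25.7                 | 1              | 9           |

Match rates fall with every layer of African ancestry — e.g. at 10/10
low resolution, 42.6% of quartile Q1 (least African) find a donor versus
8.8% of Q4, and 49.5% of individuals with no African-MHC chromosome
versus 0.7% of those with two.  The size-matched percent decreases show
the hierarchy of effects (self-identification < genome-wide ancestry <
MHC ancestry):

| Query (low resolution) | Black vs. White | Most vs. Least African (genome) | Most vs. Least African (MHC) |
| ---------------------- | --------------- | ------------------------------- | ---------------------------- |
| 6/6                    | 47%             | 58%                             | 85%                          |
| 10/10                  | 69%             | 79%                             | 99%                          |

SCD patients, whose mean African ancestry is elevated (52%), find a
10/10 match in 15.8% of cases versus 27.8% for the rest of the cohort
(z = −5.069, p = 4e-07), and self-identification explains R² = 0.634 of
the variance in estimated African ancestry.  Absolute rates depend on the
synthetic registry's size and diversity; the object of interest is the
ordering and the group contrasts, which are stable across seeds.

Single searches run directly from CSV files:

```bash
hlamatch match --cohort cohort.csv --registry registry.csv \
    --codes registry_codes.json --spec 10of10 --resolution low \
    --allow-mismatch 0 --out matches.csv
```

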