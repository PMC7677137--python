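"""Statistics for ancestry-stratified registry match results.

Covers the full reporting layer of the analysis: per-group match rates,
odds ratios for finding a match (closed-form 2x2 cross-product with Woolf
confidence intervals, cross-checked by a logistic fit), matched-size
percent decreases between groups, donor-composition "average of individual
averages" tables, Mann-Whitney tests on donor counts, the two-proportion
z-test used for the sickle-cell contrast, and the sibling HLA-identity
probability 1 - (3/4)^k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupedRates",
    "ORResult",
    "PercentDecrease",
    "grouped_match_rates",
    "odds_ratio",
    "percent_decrease",
    "donor_composition",
    "donor_count_test",
    "two_prop_ztest",
    "sibling_match_prob",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used for reported
    percentages; one decimal for rates, integers for percent decreases)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class GroupedRates:
    """Per-group proportion of patients with at least one match."""

    grouping: str
    table: pd.DataFrame  # columns: group, n, n_with_match, rate

    def rate(self, group) -> float:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(f"group {group!r} not present under {self.grouping}")
        return float(row["rate"].iloc[0])


def grouped_match_rates(
    match_table: pd.DataFrame,
    assignments: pd.Series,
    grouping: str,
    group_order: list | None = None,
) -> GroupedRates:
    """Proportion of individuals with >= 1 match, per group.

    ``match_table`` holds one row per patient (columns ``patient_id``,
    ``n_matches``) for a single search spec; ``assignments`` maps patient
    id to group label.  Patients without an assignment are an error.
    """
    ids = match_table["patient_id"]
    missing = ids[~ids.isin(assignments.index)]
    if len(missing):
        raise ValueError(
            f"no {grouping} assignment for patients {sorted(missing)[:5]}..."
        )
    groups = assignments.loc[ids].to_numpy()
    matched = (match_table["n_matches"].to_numpy() >= 1)
    df = pd.DataFrame({"group": groups, "matched": matched})
    agg = df.groupby("group", sort=True).agg(
        n=("matched", "size"), n_with_match=("matched", "sum")
    ).reset_index()
    agg["rate"] = agg["n_with_match"] / agg["n"]
    if group_order is not None:
        agg["__o"] = agg["group"].map({g: i for i, g in enumerate(group_order)})
        agg = agg.sort_values("__o").drop(columns="__o").reset_index(drop=True)
    return GroupedRates(grouping=grouping, table=agg)


@dataclass
class ORResult:
    """Odds ratio for a binary contrast, from the 2x2 table and a logistic fit."""

    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float
    logistic_or: float
    table: tuple[int, int, int, int]  # a, b, c, d
    corrected: bool  # Haldane-Anscombe 0.5 added to a zero cell


def odds_ratio(outcome: np.ndarray, group: np.ndarray) -> ORResult:
    """Odds ratio of the outcome for group=1 relative to group=0.

    Closed form OR = (a d)/(b c) with a Woolf (log-normal) 95% CI and a
    Wald p-value; an iteratively-reweighted logistic fit cross-checks the
    estimate.  A zero cell triggers the Haldane-Anscombe 0.5 correction,
    flagged in the result (the logistic cross-check is skipped then, since
    the MLE does not exist under separation).
    """
    outcome = np.asarray(outcome, dtype=int)
    group = np.asarray(group, dtype=int)
    if set(np.unique(outcome)) - {0, 1} or set(np.unique(group)) - {0, 1}:
        raise ValueError("outcome and group must be binary 0/1 vectors")
    if len(np.unique(outcome)) < 2:
        raise ValueError("both outcome levels must be present")
    a = int(np.sum((group == 1) & (outcome == 1)))
    b = int(np.sum((group == 1) & (outcome == 0)))
    c = int(np.sum((group == 0) & (outcome == 1)))
    d = int(np.sum((group == 0) & (outcome == 0)))
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_)
    ci = (math.exp(log_or - 1.959963984540054 * se),
          math.exp(log_or + 1.959963984540054 * se))
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    logistic_or = float("nan")
    if not corrected:
        x = sm.add_constant(group.astype(float))
        fit = sm.GLM(outcome, x, family=sm.families.Binomial()).fit()
        logistic_or = float(np.exp(fit.params[1]))
    return ORResult(
        oddsratio=float(or_), ci_low=ci[0], ci_high=ci[1], p_value=float(p),
        logistic_or=logistic_or, table=(a, b, c, d), corrected=corrected,
    )


@dataclass
class PercentDecrease:
    """Percent decrease in match rate of a group relative to a reference."""

    raw: float
    rounded: int
    rate_ref: float
    rate_cmp: float
    matched_sizes: bool


def percent_decrease(
    outcomes_ref: np.ndarray | None = None,
    outcomes_cmp: np.ndarray | None = None,
    *,
    rates: tuple[float, float] | None = None,
    matched_sizes: bool = False,
    subsample_reps: int = 200,
    rng: np.random.Generator | int | None = None,
) -> PercentDecrease:
    """100 x (r_ref - r_cmp) / r_ref, optionally on size-matched groups.

    Either pass the two match rates directly via ``rates=(r_ref, r_cmp)``,
    or pass the two groups' binary match outcomes.  With
    ``matched_sizes=True`` the larger group is repeatedly subsampled
    (without replacement) to the smaller group's size and its rate averaged
    over ``subsample_reps`` replicates before the ratio is taken, so the
    two rates enter on an equal footing.  The reported value is rounded
    half away from zero to an integer percent.
    """
    if rates is not None:
        r_ref, r_cmp = rates
        if matched_sizes:
            raise ValueError("matched_sizes requires the raw outcome vectors")
    else:
        if outcomes_ref is None or outcomes_cmp is None:
            raise ValueError("pass either rates= or both outcome vectors")
        ref = np.asarray(outcomes_ref, dtype=float)
        cmp_ = np.asarray(outcomes_cmp, dtype=float)
        if len(ref) == 0 or len(cmp_) == 0:
            raise ValueError("both outcome vectors must be non-empty")
        if matched_sizes:
            if isinstance(rng, (int, np.integer)) or rng is None:
                rng = np.random.default_rng(rng)
            n = min(len(ref), len(cmp_))

            def mean_rate(v: np.ndarray) -> float:
                if len(v) == n:
                    return float(v.mean())
                reps = [
                    float(rng.choice(v, size=n, replace=False).mean())
                    for _ in range(subsample_reps)
                ]
                return float(np.mean(reps))

            r_ref, r_cmp = mean_rate(ref), mean_rate(cmp_)
        else:
            r_ref, r_cmp = float(ref.mean()), float(cmp_.mean())
    if r_ref <= 0:
        raise ValueError("reference rate must be positive")
    raw = 100.0 * (r_ref - r_cmp) / r_ref
    return PercentDecrease(
        raw=raw, rounded=int(round_half_away(raw)), rate_ref=r_ref,
        rate_cmp=r_cmp, matched_sizes=matched_sizes,
    )


def donor_composition(
    donor_counts: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Group-level average of each patient's donor-category frequencies.

    ``donor_counts`` has one row per patient (index = patient id) and one
    column per donor category with the number of matched donors in that
    category.  Only patients with at least one match contribute; each such
    patient's counts are normalized to frequencies, and the group value is
    the unweighted mean of those per-patient frequency vectors (an
    "average of individual averages", not a pooled donor count), so every
    group row sums to one.
    """
    totals = donor_counts.sum(axis=1)
    contributing = donor_counts[totals > 0]
    if contributing.empty:
        return pd.DataFrame(columns=donor_counts.columns)
    freqs = contributing.div(totals[totals > 0], axis=0)
    grp = groups.loc[contributing.index]
    out = freqs.groupby(grp.to_numpy()).mean()
    out.index.name = "group"
    return out


def donor_count_test(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-patient donor counts.

    Uses the normal approximation with tie correction for the cohort-scale
    samples, and the exact null distribution for small fixtures (both
    samples below 20 and no ties).  Inputs should come from patients with
    at least one match.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    small = max(len(a), len(b)) < 20
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_prop_ztest(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (two-sided).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0,1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def sibling_match_prob(k: int) -> float:
    """Probability that at least one of k siblings is HLA-genoidentical.

    Each sibling inherits one of two haplotypes from each parent, so it is
    genoidentical to the patient with probability 1/4 and the chance of at
    least one identical sibling among k is 1 - (3/4)^k: 25% with one
    sibling, rising to 43.7%, 57.8% and 68.4% with two, three and four.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError("number of siblings must be an integer")
    if k < 0:
        raise ValueError("number of siblings must be >= 0")
    return 1.0 - 0.75**int(k)
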