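"""End-to-end pipeline: simulate -> estimate ancestry -> match -> analyze -> report.

Every stage is a pure function of (config, seed, artifact directory) and
can be re-run independently from prior artifacts.  A single global seed is
expanded into independent per-stage streams keyed by fixed stage
constants, so adding a stage never perturbs the draws of earlier stages.
A run manifest records the config hash, seed, package version and a
checksum for every data artifact; identical (config, seed) runs produce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import assign_quartiles, estimate_ancestry_batch, mhc_dosage, variance_explained
from .cohort import (
    CONTRAST_CATEGORIES,
    SELF_ID_CATEGORIES,
    Registry,
    cohort_from_csv,
    cohort_to_csv,
    parental_freqs_from_csv,
    parental_freqs_to_csv,
    snps_from_csv,
    snps_to_csv,
)
from .matching import all_search_specs, batch_match, summarize_matches
from .simulate import (
    GeneratorConfig,
    calibrate_self_id,
    generate_cohort,
    generate_pools,
    generate_registry,
    generate_scd_cohort,
    generate_snp_panel,
)
from .stats import (
    donor_composition,
    donor_count_test,
    odds_ratio,
    percent_decrease,
    round_half_away,
    sibling_match_prob,
    two_prop_ztest,
)

__all__ = ["STAGES", "run_pipeline", "render_report", "stage_simulate",
           "stage_ancestry", "stage_match", "stage_analyze", "stage_report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ancestry", "match", "analyze", "report")
# fixed per-stage entropy constants: adding a stage never shifts earlier streams
_STAGE_KEYS = {"simulate": 101, "ancestry": 102, "match": 103, "analyze": 104}

_FOCUS = {"resolution": "low", "max_mismatch": 0}  # reported contrasts use low-res full matching
_CONTRASTS = [
    # (grouping, comparison group, reference group, printed column name)
    ("self_id", "Black", "White", "Black vs. White"),
    ("quartile", "Q4", "Q1", "Most vs. Least African (genome)"),
    ("mhc_dosage", "2", "0", "Most vs. Least African (MHC)"),
]


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]]))


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required pipeline artifact not found: {path}")
    return path


def _write_table(df: pd.DataFrame, path: Path, schema: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# hlamatch/{schema} v1\n")
        df.to_csv(fh, index=False, float_format="%.10g")


# ===================================================================== stages

def stage_simulate(config: GeneratorConfig, outdir: Path, seed: int) -> list[Path]:
    rng = _stage_rng(seed, "simulate")
    cfg = config
    if cfg.self_id_sigma is None:
        cal = calibrate_self_id(
            cfg, cfg.self_id_target_r2,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        logger.info("simulate: calibrated self-ID sigma=%.4f (R2=%.3f)",
                    cal.sigma, cal.achieved_r2)
        cfg = dataclasses.replace(cfg, self_id_sigma=cal.sigma)
    pools = generate_pools(cfg, rng)
    snp_freqs = generate_snp_panel(cfg, rng)
    cohort = generate_cohort(
        cfg, pools, cfg.cohort_size, "merged", rng,
        sigma=cfg.self_id_sigma, snp_freqs=snp_freqs,
    )
    scd = generate_scd_cohort(
        cfg, pools, cfg.scd_size, rng, sigma=cfg.self_id_sigma, snp_freqs=snp_freqs,
    )
    registry = generate_registry(cfg, pools, rng)
    everyone = cohort + scd
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(outdir / "config.json")
    cohort_to_csv(everyone, outdir / "cohort.csv")
    snps_to_csv(
        [ind.id for ind in everyone],
        np.stack([ind.snps for ind in everyone]),
        outdir / "snps.csv",
    )
    parental_freqs_to_csv(snp_freqs, outdir / "parental_freqs.csv")
    registry.to_csv(outdir / "registry.csv", outdir / "registry_codes.json")
    logger.info("simulate: %d cohort members (%d SCD), %d donors",
                len(everyone), len(scd), len(registry))
    return [outdir / n for n in
            ("config.json", "cohort.csv", "snps.csv", "parental_freqs.csv",
             "registry.csv", "registry_codes.json")]


def stage_ancestry(config: GeneratorConfig, outdir: Path, seed: int) -> list[Path]:
    ids, dosages = snps_from_csv(_require(outdir / "snps.csv"))
    freqs = parental_freqs_from_csv(_require(outdir / "parental_freqs.csv"))
    cohort = cohort_from_csv(_require(outdir / "cohort.csv"))
    q_hat, _, _, converged = estimate_ancestry_batch(dosages, freqs)
    est = pd.DataFrame({
        "id": ids,
        "q_afr_hat": q_hat[:, 0],
        "q_eur_hat": q_hat[:, 1],
        "q_nat_hat": q_hat[:, 2],
        "converged": converged.astype(int),
    })
    _write_table(est, outdir / "estimates.csv", "ancestry-estimates")
    quartiles = assign_quartiles(q_hat[:, 0])
    if quartiles.degenerate:
        logger.warning("ancestry: degenerate quartile boundaries %s",
                       quartiles.boundaries)
    by_id = {ind.id: ind for ind in cohort}
    assignments = pd.DataFrame({
        "id": ids,
        "self_id": [by_id[i].self_id for i in ids],
        "scd": [int(by_id[i].scd) for i in ids],
        "q_afr_hat": q_hat[:, 0],
        "quartile": quartiles.labels,
        "mhc_dosage": [mhc_dosage(by_id[i].mhc_afr) for i in ids],
    })
    _write_table(assignments, outdir / "assignments.csv", "assignments")
    logger.info("ancestry: estimated %d individuals (%d converged); quartile "
                "boundaries %s", len(ids), int(converged.sum()),
                tuple(round(b, 4) for b in quartiles.boundaries))
    return [outdir / "estimates.csv", outdir / "assignments.csv"]


def stage_match(config: GeneratorConfig, outdir: Path, seed: int) -> list[Path]:
    cohort = cohort_from_csv(_require(outdir / "cohort.csv"))
    registry = Registry.from_csv(
        _require(outdir / "registry.csv"), _require(outdir / "registry_codes.json")
    )
    table = batch_match(cohort, registry, all_search_specs())
    _write_table(table, outdir / "matches.csv", "match-results")
    logger.info("match: %d patients x %d specs against %d donors",
                len(cohort), len(all_search_specs()), len(registry))
    return [outdir / "matches.csv"]


def _spec_slice(matches: pd.DataFrame, loci_set: str,
                resolution: str | None = None, mm: int | None = None) -> pd.DataFrame:
    resolution = resolution or _FOCUS["resolution"]
    mm = mm if mm is not None else _FOCUS["max_mismatch"]
    out = matches[(matches["loci_set"] == loci_set)
                  & (matches["resolution"] == resolution)
                  & (matches["max_mismatch"] == mm)]
    return out.set_index("patient_id")


def stage_analyze(config: GeneratorConfig, outdir: Path, seed: int) -> list[Path]:
    rng = _stage_rng(seed, "analyze")
    matches = pd.read_csv(_require(outdir / "matches.csv"), comment="#")
    assignments = pd.read_csv(
        _require(outdir / "assignments.csv"), comment="#",
        dtype={"mhc_dosage": str},
    ).set_index("id")

    summary = summarize_matches(matches)

    groupings = {
        "self_id": assignments["self_id"],
        "quartile": assignments["quartile"],
        "mhc_dosage": assignments["mhc_dosage"],
        "scd": assignments["scd"].map({0: "non-SCD", 1: "SCD"}),
    }
    group_orders = {
        "self_id": list(CONTRAST_CATEGORIES),
        "quartile": ["Q1", "Q2", "Q3", "Q4"],
        "mhc_dosage": ["0", "1", "2"],
        "scd": ["non-SCD", "SCD"],
    }

    rate_rows = []
    for loci_set in ("6/6", "8/8", "10/10"):
        for resolution in ("low", "medium"):
            sl = _spec_slice(matches, loci_set, resolution=resolution).reset_index()
            for grouping, assign in groupings.items():
                sub = sl
                if grouping == "self_id":
                    keep = assign.loc[sl["patient_id"]].isin(CONTRAST_CATEGORIES)
                    sub = sl[keep.to_numpy()]
                from .stats import grouped_match_rates
                gr = grouped_match_rates(sub, assign, grouping,
                                         group_order=group_orders[grouping])
                for row in gr.table.itertuples(index=False):
                    rate_rows.append({
                        "loci_set": loci_set, "resolution": resolution,
                        "max_mismatch": 0, "grouping": grouping,
                        "group": str(row.group), "n": int(row.n),
                        "n_with_match": int(row.n_with_match),
                        "rate_pct": round_half_away(100.0 * row.rate, 1),
                    })
    rates_df = pd.DataFrame(rate_rows)

    def _group_outcomes(loci_set: str, grouping: str, group: str) -> np.ndarray:
        sl = _spec_slice(matches, loci_set)
        assign = groupings[grouping].loc[sl.index]
        return (sl.loc[assign[assign == group].index, "n_matches"] >= 1).to_numpy()

    pct_rows, or_rows = [], []
    for loci_set in ("6/6", "8/8", "10/10"):
        for grouping, cmp_g, ref_g, label in _CONTRASTS:
            out_ref = _group_outcomes(loci_set, grouping, ref_g)
            out_cmp = _group_outcomes(loci_set, grouping, cmp_g)
            pd_rng = np.random.default_rng(rng.integers(2**31))
            try:
                pd_res = percent_decrease(
                    out_ref, out_cmp, matched_sizes=True,
                    subsample_reps=200, rng=pd_rng,
                )
            except ValueError as exc:
                logger.warning("analyze: percent decrease skipped for %s at %s: %s",
                               label, loci_set, exc)
            else:
                pct_rows.append({
                    "loci_set": loci_set, "contrast": label,
                    "percent_decrease": pd_res.rounded,
                    "percent_decrease_raw": pd_res.raw,
                    "rate_ref": pd_res.rate_ref, "rate_cmp": pd_res.rate_cmp,
                })
            outcome = np.concatenate([out_cmp, out_ref]).astype(int)
            group = np.concatenate(
                [np.ones(len(out_cmp), int), np.zeros(len(out_ref), int)]
            )
            try:
                orr = odds_ratio(outcome, group)
                or_rows.append({
                    "loci_set": loci_set, "contrast": label,
                    "oddsratio": orr.oddsratio, "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high, "p_value": orr.p_value,
                    "corrected": int(orr.corrected),
                })
            except ValueError as exc:
                logger.warning("analyze: OR skipped for %s at %s: %s",
                               label, loci_set, exc)
    pct_df = pd.DataFrame(pct_rows)
    or_df = pd.DataFrame(or_rows)

    # donor composition (average of individual averages) at 6/6 low, mm0
    comp_slice = _spec_slice(matches, "6/6")
    donor_cols = [f"n_donor_{c}" for c in SELF_ID_CATEGORIES]
    counts = comp_slice[donor_cols].rename(
        columns=dict(zip(donor_cols, SELF_ID_CATEGORIES))
    )
    comp_rows = []
    for grouping in ("self_id", "quartile", "mhc_dosage"):
        comp = donor_composition(counts, groupings[grouping])
        for group, row in comp.iterrows():
            entry = {"grouping": grouping, "group": str(group)}
            entry.update({c: float(row[c]) for c in SELF_ID_CATEGORIES})
            comp_rows.append(entry)
    comp_df = pd.DataFrame(comp_rows)

    # Mann-Whitney on donor counts among matched patients, 6/6 low mm0
    mw_rows = []
    sl66 = _spec_slice(matches, "6/6")
    for grouping, cmp_g, ref_g, label in _CONTRASTS:
        assign = groupings[grouping].loc[sl66.index]
        cnt_ref = sl66.loc[assign[assign == ref_g].index, "n_matches"]
        cnt_cmp = sl66.loc[assign[assign == cmp_g].index, "n_matches"]
        cnt_ref = cnt_ref[cnt_ref >= 1].to_numpy()
        cnt_cmp = cnt_cmp[cnt_cmp >= 1].to_numpy()
        if len(cnt_ref) and len(cnt_cmp):
            u, p = donor_count_test(cnt_cmp, cnt_ref)
            mw_rows.append({"loci_set": "6/6", "contrast": label,
                            "U": u, "p_value": p})

    # SCD contrast: 10/10 low-resolution match rate, SCD vs the rest
    sl1010 = _spec_slice(matches, "10/10")
    scd_mask = assignments.loc[sl1010.index, "scd"] == 1
    scd_out = (sl1010.loc[scd_mask.to_numpy(), "n_matches"] >= 1)
    rest_out = (sl1010.loc[(~scd_mask).to_numpy(), "n_matches"] >= 1)
    z, p = two_prop_ztest(
        float(scd_out.mean()), int(len(scd_out)),
        float(rest_out.mean()), int(len(rest_out)),
    )
    scd_test = {
        "rate_scd_pct": round_half_away(100.0 * scd_out.mean(), 1),
        "n_scd": int(len(scd_out)),
        "rate_non_scd_pct": round_half_away(100.0 * rest_out.mean(), 1),
        "n_non_scd": int(len(rest_out)),
        "z": z, "p_value": p,
    }

    # self-ID informativeness about estimated ancestry
    main = assignments[assignments["self_id"].isin(CONTRAST_CATEGORIES)]
    r2 = variance_explained(main["self_id"].to_numpy(),
                            main["q_afr_hat"].to_numpy())

    stats_payload = {
        "schema": "hlamatch/stats v1",
        "config_hash": config_hash(config),
        "seed": int(seed),
        "summary": summary.to_dict(orient="records"),
        "grouped_rates": rates_df.to_dict(orient="records"),
        "percent_decreases": pct_df.to_dict(orient="records"),
        "odds_ratios": or_df.to_dict(orient="records"),
        "donor_composition": comp_df.to_dict(orient="records"),
        "donor_count_tests": mw_rows,
        "scd_ztest": scd_test,
        "self_id_r2_of_estimated_ancestry": r2,
        "sibling_match_prob_pct": {
            str(k): round_half_away(100.0 * sibling_match_prob(k), 1)
            for k in (1, 2, 3, 4)
        },
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_table(summary, outdir / "summary_table.csv", "match-summary")
    _write_table(rates_df, outdir / "grouped_rates.csv", "grouped-rates")
    _write_table(pct_df, outdir / "percent_decreases.csv", "percent-decreases")
    _write_table(or_df, outdir / "odds_ratios.csv", "odds-ratios")
    _write_table(comp_df, outdir / "donor_composition.csv", "donor-composition")
    return [outdir / n for n in
            ("stats.json", "summary_table.csv", "grouped_rates.csv",
             "percent_decreases.csv", "odds_ratios.csv", "donor_composition.csv")]


# ===================================================================== report

def _md_table(headers: list[str], rows: list[list[str]]) -> str:
    if not rows:
        rows = [["(no data)"] + [""] * (len(headers) - 1)]
    widths = [max(len(str(h)), *(len(str(r[i])) for r in rows))
              for i, h in enumerate(headers)]
    def fmt(row):
        return "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
    lines = [fmt(headers), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines)


def render_report(stats: dict) -> str:
    """Render the stats JSON as a deterministic markdown report."""
    parts = ["# hlamatch run report", "",
             f"config hash `{stats.get('config_hash', '?')}`, "
             f"seed {stats.get('seed', '?')}", ""]

    parts += ["## Match summary", ""]
    rows = []
    for rec in stats.get("summary", []):
        if rec.get("max_mismatch") != 0:
            continue
        rows.append([
            rec["loci_set"], rec["resolution"],
            f"{rec['pct_at_least_one_match']:.1f}",
            f"{rec['median_matches']:g}" if rec["median_matches"] == rec["median_matches"] else "-",
            rec["max_matches"],
        ])
    parts.append(_md_table(
        ["Loci", "Resolution", "% at least one match",
         "Median number of matches", "Maximum number of matches"], rows))

    parts += ["", "## Match rate by group (low resolution, full match)", ""]
    rows = [
        [rec["grouping"], rec["group"], rec["loci_set"], rec["n"],
         f"{rec['rate_pct']:.1f}"]
        for rec in stats.get("grouped_rates", [])
        if rec.get("resolution") == "low"
    ]
    parts.append(_md_table(["Grouping", "Group", "Loci", "n", "% with match"], rows))

    parts += ["", "## Percent decrease in chances of finding a match "
              "(size-matched groups, low resolution)", ""]
    by_set: dict[str, dict[str, str]] = {}
    for rec in stats.get("percent_decreases", []):
        by_set.setdefault(rec["loci_set"], {})[rec["contrast"]] = f"{rec['percent_decrease']}%"
    contrast_cols = [c[3] for c in _CONTRASTS]
    rows = [[ls] + [by_set[ls].get(c, "-") for c in contrast_cols]
            for ls in ("6/6", "8/8", "10/10") if ls in by_set]
    parts.append(_md_table(["Query (low resolution)"] + contrast_cols, rows))

    parts += ["", "## Donor self-identification composition of matches "
              "(6/6 low, average of individual averages)", ""]
    rows = [
        [rec["grouping"], rec["group"]] + [f"{rec[c]:.3f}" for c in SELF_ID_CATEGORIES]
        for rec in stats.get("donor_composition", [])
    ]
    parts.append(_md_table(["Grouping", "Group"] + list(SELF_ID_CATEGORIES), rows))

    scd = stats.get("scd_ztest")
    if scd:
        parts += ["", "## Sickle-cell disease contrast (10/10 low resolution)", "",
                  f"{scd['rate_scd_pct']}% of {scd['n_scd']} SCD patients find a "
                  f"match, vs {scd['rate_non_scd_pct']}% of {scd['n_non_scd']} "
                  f"others (z = {scd['z']:.3f}, p = {scd['p_value']:.2g})."]

    sib = stats.get("sibling_match_prob_pct", {})
    if sib:
        parts += ["", "## Sibling match probability", ""]
        parts.append(_md_table(
            ["Siblings", "P(at least one HLA-identical) %"],
            [[k, sib[k]] for k in sorted(sib, key=int)]))
    r2 = stats.get("self_id_r2_of_estimated_ancestry")
    if r2 is not None:
        parts += ["", f"Self-identification explains R² = {r2:.3f} of the "
                  "variance in estimated African ancestry.", ""]
    return "\n".join(parts) + "\n"


def stage_report(config: GeneratorConfig, outdir: Path, seed: int) -> list[Path]:
    with open(_require(outdir / "stats.json")) as fh:
        stats = json.load(fh)
    text = render_report(stats)
    with open(outdir / "report.md", "w") as fh:
        fh.write(text)
    return [outdir / "report.md"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ancestry": stage_ancestry,
    "match": stage_match,
    "analyze": stage_analyze,
    "report": stage_report,
}


def run_pipeline(
    config: GeneratorConfig,
    outdir: str | Path,
    seed: int = 1,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages and return the run manifest (also written
    to ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    produced: list[Path] = []
    timestamps: dict[str, str] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        produced += _STAGE_FUNCS[stage](config, outdir, seed)
        timestamps[stage] = datetime.now(timezone.utc).isoformat()
    manifest = {
        "schema": "hlamatch/manifest v1",
        "config_hash": config_hash(config),
        "seed": int(seed),
        "version": __version__,
        "stages": list(stages),
        "checksums": {p.name: _sha256(p) for p in sorted(set(produced))},
        "timestamps": timestamps,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
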