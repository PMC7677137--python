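"""Registry search for HLA-compatible donors.

Searches are parameterized by a loci set (6/6 = HLA-A/-B/-DRB1, 8/8 adds
-C, 10/10 adds -DQB1), a resolution (low = one allele field, medium =
two), and a mismatch allowance (0, or 1 allele summed over all loci, i.e.
5/6, 7/8, 9/10 searches).  Donors not typed at every required locus are
excluded from that search and counted, rather than treated as wildcards.

Two routes are provided: an indexed engine (:class:`MatchEngine`) built on
canonical truncated-genotype keys, with donors carrying multiple-allele
codes indexed under every expansion member, and a naive full scan
(:func:`naive_find_matches`) driven by the allele-level compatibility
rules, used to verify the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Donor, Registry, SELF_ID_CATEGORIES, TypedIndividual
from .nomenclature import (
    AlleleCode,
    HLAAllele,
    LocusGenotype,
    Resolution,
    locus_mismatch_count,
    truncate,
)

__all__ = [
    "LOCI_SETS",
    "SearchSpec",
    "MatchResult",
    "MatchEngine",
    "find_matches",
    "naive_find_matches",
    "batch_match",
    "summarize_matches",
    "all_search_specs",
]

logger = logging.getLogger(__name__)

LOCI_SETS: dict[str, tuple[str, ...]] = {
    "6/6": ("A", "B", "DRB1"),
    "8/8": ("A", "B", "C", "DRB1"),
    "10/10": ("A", "B", "C", "DRB1", "DQB1"),
}
_ALIASES = {"6of6": "6/6", "8of8": "8/8", "10of10": "10/10",
            "6/6": "6/6", "8/8": "8/8", "10/10": "10/10"}


@dataclass(frozen=True)
class SearchSpec:
    """One registry search: loci set, resolution, mismatch allowance."""

    loci_set: str
    resolution: Resolution
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        canon = _ALIASES.get(str(self.loci_set))
        if canon is None:
            raise ValueError(f"unknown loci set {self.loci_set!r}")
        object.__setattr__(self, "loci_set", canon)
        object.__setattr__(self, "resolution", Resolution.coerce(self.resolution))
        if self.max_mismatch not in (0, 1):
            raise ValueError("mismatch allowance must be 0 or 1")

    @property
    def loci(self) -> tuple[str, ...]:
        return LOCI_SETS[self.loci_set]

    @property
    def label(self) -> str:
        return f"{self.loci_set} {self.resolution.value} mm{self.max_mismatch}"


def all_search_specs() -> list[SearchSpec]:
    """The full 3 x 2 x 2 grid of loci sets, resolutions and allowances."""
    return [
        SearchSpec(ls, res, mm)
        for ls in LOCI_SETS
        for res in (Resolution.LOW, Resolution.MEDIUM)
        for mm in (0, 1)
    ]


@dataclass
class MatchResult:
    patient_id: str
    spec: SearchSpec
    donor_ids: tuple[str, ...]
    excluded_untyped: int

    @property
    def n_matches(self) -> int:
        return len(self.donor_ids)


# --------------------------------------------------------------- repr layer
#
# For speed, donor genotypes are reduced per resolution to per-locus pairs
# of lightweight representations: a truncated allele name string, a
# frozenset of such strings (code expansion), or None for an entry that can
# never be confirmed compatible at this resolution (one-field typing in a
# medium search).


def _entry_repr(entry, res: Resolution):
    if isinstance(entry, AlleleCode):
        if res is Resolution.LOW:
            return HLAAllele(locus=entry.locus, field1=entry.field1).name
        return frozenset(truncate(a, res).name for a in entry.expansion)
    if res is Resolution.MEDIUM and entry.field2 is None:
        return None
    return truncate(entry, res).name


def _compat_repr(patient_name: str, donor_repr) -> bool:
    if donor_repr is None:
        return False
    if isinstance(donor_repr, frozenset):
        return patient_name in donor_repr
    return patient_name == donor_repr


def _mismatch_repr(p_pair: tuple[str, str], d_pair) -> int:
    p1, p2 = p_pair
    d1, d2 = d_pair
    straight = int(_compat_repr(p1, d1)) + int(_compat_repr(p2, d2))
    crossed = int(_compat_repr(p1, d2)) + int(_compat_repr(p2, d1))
    return 2 - max(straight, crossed)


def _patient_pairs(
    patient: TypedIndividual, loci: Iterable[str], res: Resolution
) -> dict[str, tuple[str, str]]:
    pairs = {}
    for locus in loci:
        g = patient.genotypes[locus]
        if not g.typed:
            raise ValueError(
                f"patient {patient.id} untyped at required locus {locus}"
            )
        a1, a2 = (truncate(a, res).name for a in g.alleles)
        pairs[locus] = (a1, a2)
    return pairs


def _donor_options(d_pair) -> list[tuple[str, str]] | None:
    """Concrete sorted allele-name pairs a donor genotype can stand for."""
    r1, r2 = d_pair
    if r1 is None or r2 is None:
        return None
    o1 = sorted(r1) if isinstance(r1, frozenset) else [r1]
    o2 = sorted(r2) if isinstance(r2, frozenset) else [r2]
    opts = {tuple(sorted((a, b))) for a in o1 for b in o2}
    return sorted(opts)


class MatchEngine:
    """Indexed donor lookup for a fixed registry.

    Exact (0-mismatch) searches resolve through a hash of canonical
    truncated genotype keys over the required loci; single-mismatch
    searches additionally consult, for each locus, an index keyed on the
    remaining loci and verify the relaxed locus per candidate.  Index
    construction is idempotent and cached per (loci set, resolution).
    """

    def __init__(self, registry: Registry):
        self.registry = registry
        self._reprs: dict[Resolution, list[dict]] = {}
        self._exact: dict = {}
        self._relaxed: dict = {}
        self._untyped: dict[str, int] = {}

    # ------------------------------------------------------------- caches

    def _donor_reprs(self, res: Resolution) -> list[dict]:
        if res not in self._reprs:
            reprs = []
            for d in self.registry.donors:
                dr = {}
                for locus, g in d.genotypes.items():
                    if g.typed:
                        dr[locus] = (
                            _entry_repr(g.alleles[0], res),
                            _entry_repr(g.alleles[1], res),
                        )
                reprs.append(dr)
            self._reprs[res] = reprs
        return self._reprs[res]

    def excluded_untyped(self, loci_set: str) -> int:
        if loci_set not in self._untyped:
            loci = LOCI_SETS[loci_set]
            self._untyped[loci_set] = sum(
                0 if d.typed_at(loci) else 1 for d in self.registry.donors
            )
        return self._untyped[loci_set]

    def _exact_index(self, loci: tuple[str, ...], res: Resolution) -> dict:
        key = (loci, res)
        if key not in self._exact:
            index: dict[tuple, list[int]] = {}
            reprs = self._donor_reprs(res)
            for i, dr in enumerate(reprs):
                if any(l not in dr for l in loci):
                    continue
                per_locus = []
                ok = True
                for l in loci:
                    opts = _donor_options(dr[l])
                    if opts is None:
                        ok = False
                        break
                    per_locus.append(opts)
                if not ok:
                    continue
                for combo in product(*per_locus):
                    index.setdefault(combo, []).append(i)
            self._exact[key] = index
        return self._exact[key]

    def _relaxed_index(
        self, loci: tuple[str, ...], res: Resolution, skip: str
    ) -> dict:
        key = (loci, res, skip)
        if key not in self._relaxed:
            others = tuple(l for l in loci if l != skip)
            index: dict[tuple, list[int]] = {}
            reprs = self._donor_reprs(res)
            for i, dr in enumerate(reprs):
                if any(l not in dr for l in loci):
                    continue
                per_locus = []
                ok = True
                for l in others:
                    opts = _donor_options(dr[l])
                    if opts is None:
                        ok = False
                        break
                    per_locus.append(opts)
                if not ok:
                    continue
                for combo in product(*per_locus):
                    index.setdefault(combo, []).append(i)
            self._relaxed[key] = index
        return self._relaxed[key]

    # -------------------------------------------------------------- search

    def find(self, patient: TypedIndividual, spec: SearchSpec) -> MatchResult:
        loci = spec.loci
        res = spec.resolution
        pairs = _patient_pairs(patient, loci, res)
        pkey = tuple(tuple(sorted(pairs[l])) for l in loci)
        hits: set[int] = set(self._exact_index(loci, res).get(pkey, ()))
        if spec.max_mismatch == 1:
            reprs = self._donor_reprs(res)
            for skip in loci:
                others = tuple(l for l in loci if l != skip)
                rkey = tuple(tuple(sorted(pairs[l])) for l in others)
                for i in self._relaxed_index(loci, res, skip).get(rkey, ()):
                    if i in hits:
                        continue
                    if _mismatch_repr(pairs[skip], reprs[i][skip]) <= 1:
                        hits.add(i)
        ids = tuple(sorted(self.registry.donors[i].id for i in hits))
        return MatchResult(
            patient_id=patient.id,
            spec=spec,
            donor_ids=ids,
            excluded_untyped=self.excluded_untyped(spec.loci_set),
        )


def find_matches(
    patient: TypedIndividual, registry: Registry, spec: SearchSpec
) -> MatchResult:
    """Search the registry for donors matching the patient under ``spec``.

    Uses an index cached on the registry; equivalent to
    :func:`naive_find_matches` but fast for repeated queries.
    """
    if registry._engine is None:
        registry._engine = MatchEngine(registry)
    return registry._engine.find(patient, spec)


def naive_find_matches(
    patient: TypedIndividual, registry: Registry, spec: SearchSpec
) -> MatchResult:
    """Reference implementation: full scan with allele-level mismatch counts."""
    loci = spec.loci
    res = spec.resolution
    for locus in loci:
        if not patient.genotypes[locus].typed:
            raise ValueError(f"patient {patient.id} untyped at required locus {locus}")
    matched = []
    excluded = 0
    for donor in registry.donors:
        if not donor.typed_at(loci):
            excluded += 1
            continue
        mm = 0
        for locus in loci:
            mm += locus_mismatch_count(
                patient.genotypes[locus], donor.genotypes[locus], res
            )
            if mm > spec.max_mismatch:
                break
        if mm <= spec.max_mismatch:
            matched.append(donor.id)
    return MatchResult(
        patient_id=patient.id,
        spec=spec,
        donor_ids=tuple(sorted(matched)),
        excluded_untyped=excluded,
    )


def batch_match(
    cohort: Sequence[TypedIndividual],
    registry: Registry,
    specs: Sequence[SearchSpec] | None = None,
    include_donor_ids: bool = False,
) -> pd.DataFrame:
    """Run every (patient, spec) search and tabulate the results.

    One row per patient and spec with the match count, the number of
    donors excluded for missing required loci, and the self-identification
    composition of the matched donors (needed for donor-composition
    statistics).  Per-patient errors are logged and skipped, not fatal.
    """
    specs = list(specs) if specs is not None else all_search_specs()
    if registry._engine is None:
        registry._engine = MatchEngine(registry)
    engine: MatchEngine = registry._engine
    donor_cat = {d.id: d.self_id for d in registry.donors}
    rows = []
    for patient in cohort:
        for spec in specs:
            try:
                result = engine.find(patient, spec)
            except ValueError as exc:
                logger.warning("skipping %s at %s: %s", patient.id, spec.label, exc)
                continue
            row = {
                "patient_id": patient.id,
                "loci_set": spec.loci_set,
                "resolution": spec.resolution.value,
                "max_mismatch": spec.max_mismatch,
                "n_matches": result.n_matches,
                "excluded_untyped": result.excluded_untyped,
            }
            counts = {c: 0 for c in SELF_ID_CATEGORIES}
            for did in result.donor_ids:
                counts[donor_cat[did]] += 1
            for c in SELF_ID_CATEGORIES:
                row[f"n_donor_{c}"] = counts[c]
            if include_donor_ids:
                row["donor_ids"] = ";".join(result.donor_ids)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_matches(match_table: pd.DataFrame) -> pd.DataFrame:
    """Per-spec summary: % with at least one match, median and maximum
    number of matches among patients with at least one match."""
    rows = []
    for (ls, res, mm), grp in match_table.groupby(
        ["loci_set", "resolution", "max_mismatch"], sort=False
    ):
        with_match = grp[grp["n_matches"] >= 1]["n_matches"]
        rows.append({
            "loci_set": ls,
            "resolution": res,
            "max_mismatch": mm,
            "pct_at_least_one_match": 100.0 * len(with_match) / len(grp) if len(grp) else float("nan"),
            "median_matches": float(with_match.median()) if len(with_match) else float("nan"),
            "max_matches": int(with_match.max()) if len(with_match) else 0,
        })
    return pd.DataFrame(rows)
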