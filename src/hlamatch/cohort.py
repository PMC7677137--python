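"""In-memory containers and CSV I/O for patient cohorts and donor registries.

A cohort member (:class:`TypedIndividual`) carries five-locus two-field HLA
genotypes, genome-wide ancestry proportions q = (q_AFR, q_EUR, q_NAT), the
African fraction of each of the two MHC haplotypes, a census
self-identification label, and optionally a SNP dosage vector for ancestry
estimation.  A registry donor carries per-locus typings with heterogeneous
completeness (HLA-A/-B/-DRB1 always typed, -C and -DQB1 only for subsets)
and a per-donor typing resolution; medium-resolution donors may report
multiple-allele codes.

All tables are plain CSV with a leading ``#`` schema comment line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    LOCI,
    AlleleCode,
    GenotypeEntry,
    HLAAllele,
    LocusGenotype,
    load_allele_codes,
    dump_allele_codes,
    parse_typing,
)

__all__ = [
    "SELF_ID_CATEGORIES",
    "CONTRAST_CATEGORIES",
    "TypedIndividual",
    "Donor",
    "Registry",
    "cohort_to_csv",
    "cohort_from_csv",
    "snps_to_csv",
    "snps_from_csv",
    "parental_freqs_to_csv",
    "parental_freqs_from_csv",
]

#: Census self-identification labels, plus the registry's non-response label.
SELF_ID_CATEGORIES = ("Black", "Mixed", "White", "Indigenous", "Yellow", "NonInformed")
#: Labels used in group contrasts (the minor categories are excluded).
CONTRAST_CATEGORIES = ("Black", "Mixed", "White")

_COHORT_SCHEMA = "# hlamatch/cohort v1"
_REGISTRY_SCHEMA = "# hlamatch/registry v1"
_SNP_SCHEMA = "# hlamatch/snp-dosages v1"
_FREQ_SCHEMA = "# hlamatch/parental-freqs v1"

_GENO_COLS = [f"{locus}_{i}" for locus in LOCI for i in (1, 2)]


@dataclass
class TypedIndividual:
    """A fully typed cohort member with ancestry annotations."""

    id: str
    cohort: str
    q: np.ndarray  # (q_AFR, q_EUR, q_NAT), sums to 1
    mhc_afr: tuple[float, float]
    genotypes: dict[str, LocusGenotype]
    self_id: str
    scd: bool = False
    snps: np.ndarray | None = None
    #: per-haplotype locus-level ancestry tracks (True = African), in
    #: chromosomal order; kept for auditing the MHC mosaic, not serialized.
    mhc_tracks: tuple[tuple[bool, ...], tuple[bool, ...]] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (3,) or not np.isclose(self.q.sum(), 1.0, atol=1e-9):
            raise ValueError(f"ancestry vector of {self.id} must be a 3-simplex point")
        if not all(0.0 <= a <= 1.0 for a in self.mhc_afr):
            raise ValueError(f"MHC African fractions of {self.id} must lie in [0,1]")
        missing = [l for l in LOCI if l not in self.genotypes or not self.genotypes[l].typed]
        if missing:
            raise ValueError(f"cohort member {self.id} untyped at {missing}")


@dataclass
class Donor:
    """A registry donor with possibly incomplete, possibly low-resolution typing."""

    id: str
    self_id: str
    typing_resolution: str  # "low" | "medium"
    genotypes: dict[str, LocusGenotype]

    def __post_init__(self) -> None:
        if self.typing_resolution not in ("low", "medium"):
            raise ValueError(f"donor {self.id}: bad resolution {self.typing_resolution!r}")
        for locus in LOCI:
            if locus not in self.genotypes:
                self.genotypes[locus] = LocusGenotype.untyped(locus)

    def typed_at(self, loci: Iterable[str]) -> bool:
        return all(self.genotypes[l].typed for l in loci)


class Registry:
    """A collection of donors plus the code table their typings refer to."""

    def __init__(self, donors: Sequence[Donor], codes: Mapping[str, AlleleCode] | None = None):
        self.donors: list[Donor] = list(donors)
        self.codes: dict[str, AlleleCode] = dict(codes or {})
        self._engine = None  # lazily built match index, see matching.MatchEngine

    def __len__(self) -> int:
        return len(self.donors)

    def __iter__(self):
        return iter(self.donors)

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.donors]

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path, codes_path: str | Path | None = None) -> None:
        rows = []
        for d in self.donors:
            row = {"donor_id": d.id, "self_id": d.self_id,
                   "typing_resolution": d.typing_resolution}
            for locus in LOCI:
                g = d.genotypes[locus]
                for i in (1, 2):
                    row[f"{locus}_{i}"] = g.alleles[i - 1].name if g.typed else ""
            rows.append(row)
        df = pd.DataFrame(rows, columns=["donor_id", "self_id", "typing_resolution"] + _GENO_COLS)
        with open(path, "w", newline="") as fh:
            fh.write(_REGISTRY_SCHEMA + "\n")
            df.to_csv(fh, index=False)
        if codes_path is not None:
            dump_allele_codes(self.codes, codes_path)

    @classmethod
    def from_csv(cls, path: str | Path, codes_path: str | Path | None = None) -> "Registry":
        codes = load_allele_codes(codes_path) if codes_path else {}
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
        donors = []
        for row in df.itertuples(index=False):
            genotypes: dict[str, LocusGenotype] = {}
            for locus in LOCI:
                a1 = getattr(row, f"{locus}_1")
                a2 = getattr(row, f"{locus}_2")
                if a1 == "" and a2 == "":
                    genotypes[locus] = LocusGenotype.untyped(locus)
                else:
                    genotypes[locus] = LocusGenotype(
                        locus=locus,
                        alleles=(parse_typing(a1, codes), parse_typing(a2, codes)),
                    )
            donors.append(
                Donor(
                    id=row.donor_id,
                    self_id=row.self_id,
                    typing_resolution=row.typing_resolution,
                    genotypes=genotypes,
                )
            )
        return cls(donors, codes)


# ------------------------------------------------------------------ cohort I/O

def cohort_to_csv(individuals: Sequence[TypedIndividual], path: str | Path) -> None:
    rows = []
    for ind in individuals:
        row = {
            "id": ind.id,
            "cohort": ind.cohort,
            "self_id": ind.self_id,
            "scd": int(ind.scd),
            "q_afr": f"{ind.q[0]:.8f}",
            "q_eur": f"{ind.q[1]:.8f}",
            "q_nat": f"{ind.q[2]:.8f}",
            "mhc_afr_1": f"{ind.mhc_afr[0]:.6f}",
            "mhc_afr_2": f"{ind.mhc_afr[1]:.6f}",
        }
        for locus in LOCI:
            g = ind.genotypes[locus]
            row[f"{locus}_1"] = g.alleles[0].name
            row[f"{locus}_2"] = g.alleles[1].name
        rows.append(row)
    cols = ["id", "cohort", "self_id", "scd", "q_afr", "q_eur", "q_nat",
            "mhc_afr_1", "mhc_afr_2"] + _GENO_COLS
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", newline="") as fh:
        fh.write(_COHORT_SCHEMA + "\n")
        df.to_csv(fh, index=False)


def cohort_from_csv(path: str | Path) -> list[TypedIndividual]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        genotypes = {
            locus: LocusGenotype(
                locus=locus,
                alleles=(
                    parse_typing(getattr(row, f"{locus}_1")),
                    parse_typing(getattr(row, f"{locus}_2")),
                ),
            )
            for locus in LOCI
        }
        q = np.array([float(row.q_afr), float(row.q_eur), float(row.q_nat)])
        q = q / q.sum()  # guard against rounding in the serialized decimals
        out.append(
            TypedIndividual(
                id=row.id,
                cohort=row.cohort,
                q=q,
                mhc_afr=(float(row.mhc_afr_1), float(row.mhc_afr_2)),
                genotypes=genotypes,
                self_id=row.self_id,
                scd=bool(int(row.scd)),
            )
        )
    return out


# ------------------------------------------------------------------- SNP I/O

def snps_to_csv(ids: Sequence[str], dosages: np.ndarray, path: str | Path) -> None:
    """Write a dosage matrix (rows = individuals, values in {0,1,2})."""
    n, j = dosages.shape
    if len(ids) != n:
        raise ValueError("id list and dosage matrix disagree on sample size")
    with open(path, "w", newline="") as fh:
        fh.write(_SNP_SCHEMA + "\n")
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"snp{k:05d}" for k in range(j)])
        for i, ind_id in enumerate(ids):
            writer.writerow([ind_id] + [str(int(x)) for x in dosages[i]])


def snps_from_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, comment="#")
    ids = df["id"].astype(str).tolist()
    dosages = df.drop(columns=["id"]).to_numpy(dtype=float)
    return ids, dosages


def parental_freqs_to_csv(freqs: np.ndarray, path: str | Path) -> None:
    """Write per-SNP parental allele frequencies (columns AFR, EUR, NAT)."""
    df = pd.DataFrame(freqs, columns=["AFR", "EUR", "NAT"])
    df.insert(0, "snp", [f"snp{k:05d}" for k in range(len(df))])
    with open(path, "w", newline="") as fh:
        fh.write(_FREQ_SCHEMA + "\n")
        df.to_csv(fh, index=False, float_format="%.8f")


def parental_freqs_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    return df[["AFR", "EUR", "NAT"]].to_numpy(dtype=float)
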