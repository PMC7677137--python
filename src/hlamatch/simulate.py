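"""Seeded synthetic admixed cohorts, haplotype pools and donor registries.

The generator emulates the study design of an ancestry-aware registry
match analysis in an admixed population with African, European and Native
American components:

* two ancestry-specific five-locus HLA haplotype pools, with the African
  pool larger and flatter (African populations carry more HLA variability
  than non-Africans, which is the mechanism depressing match chances);
* admixed individuals whose genome-wide African proportion q_AFR follows a
  cohort-specific Beta distribution, whose two MHC haplotypes are assigned
  a continental ancestry (African with probability q_AFR) and then drawn
  from the corresponding pool, and whose census self-identification label
  is an imperfect, noise-calibrated readout of q_AFR;
* a donor registry with configurable self-identification composition,
  partial HLA-C/-DQB1 typing, per-donor low/medium typing resolution, and
  multiple-allele codes on a fraction of medium-resolution donors;
* an unlinked biallelic SNP panel (Balding-Nichols parental frequencies)
  from which genome-wide ancestry can be re-estimated.

Native American ancestry is generated as a third simplex component but has
no dedicated haplotype pool: NAT-labelled MHC haplotypes draw from the
European pool, since the analysis contrasts African vs European ancestry
only.

Every draw flows through an explicit :class:`numpy.random.Generator`, so
all outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ancestry import variance_explained
from .cohort import (
    CONTRAST_CATEGORIES,
    SELF_ID_CATEGORIES,
    Donor,
    Registry,
    TypedIndividual,
)
from .nomenclature import (
    LOCI,
    AlleleCode,
    HLAAllele,
    LocusGenotype,
    parse_allele,
)

__all__ = [
    "GeneratorConfig",
    "HaplotypePool",
    "CalibrationError",
    "CalibrationResult",
    "generate_pools",
    "generate_snp_panel",
    "generate_individual",
    "generate_cohort",
    "generate_registry",
    "generate_scd_cohort",
    "calibrate_self_id",
    "self_id_labels",
]

#: Physical positions (bp) of the classical loci within the modeled MHC
#: segment, which is delimited by HLA-A and HLA-DQB1 and spans 2,724,220 bp.
MHC_POSITIONS_BP: dict[str, int] = {
    "A": 0,
    "C": 1_330_000,
    "B": 1_385_000,
    "DRB1": 2_640_000,
    "DQB1": 2_724_220,
}
#: Loci ordered along the chromosome (differs from alphabetical order).
CHROM_ORDER = tuple(sorted(MHC_POSITIONS_BP, key=MHC_POSITIONS_BP.get))


class CalibrationError(RuntimeError):
    """Raised when the self-identification noise cannot reach the target R²."""


def _segment_weights() -> np.ndarray:
    """Fraction of the MHC segment attributed to each locus (chromosomal order).

    The segment is partitioned at midpoints between adjacent loci; the
    weight of a locus is the length of its sub-interval over the total.
    """
    pos = np.array([MHC_POSITIONS_BP[l] for l in CHROM_ORDER], dtype=float)
    bounds = np.concatenate([[pos[0]], (pos[:-1] + pos[1:]) / 2.0, [pos[-1]]])
    return np.diff(bounds) / (pos[-1] - pos[0])


SEGMENT_WEIGHTS = _segment_weights()


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults matching the study
    conditions being emulated (registry composition, cohort admixture
    means, time since admixture) or chosen once as realistic desk-scale
    values (pool sizes, typing fractions, SNP panel)."""

    seed: int = 0

    # --- haplotype pools -------------------------------------------------
    afr_pool_size: int = 500
    eur_pool_size: int = 120
    afr_hap_concentration: float = 1.0
    eur_hap_concentration: float = 0.8
    group_concentration: float = 0.8
    afr_groups_per_locus: dict[str, int] = field(
        default_factory=lambda: {"A": 18, "B": 26, "C": 14, "DRB1": 14, "DQB1": 9}
    )
    eur_groups_per_locus: dict[str, int] = field(
        default_factory=lambda: {"A": 11, "B": 16, "C": 9, "DRB1": 9, "DQB1": 6}
    )
    afr_variants_per_group: int = 4
    eur_variants_per_group: int = 2
    shared_group_fraction: float = 0.8

    # --- admixture -------------------------------------------------------
    # Beta(a, b) of q_AFR per cohort: "merged" matches a merged-sample mean
    # African proportion of 0.309; "high_admixture" a mean of 0.497
    # (sickle-cell source cohort); "scd" the transplant-eligible subset
    # mean of 0.52.
    cohort_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "merged": (0.85, 1.9),
            "high_admixture": (3.5, 3.542),
            "scd": (4.16, 3.84),
        }
    )
    # q_NAT = (1 - q_AFR) * Beta(a, b); default gives ~6% mean NAT ancestry
    nat_beta: tuple[float, float] = (1.0, 10.3)
    generations_since_admixture: int = 8
    mhc_recombination: bool = False

    # --- self-identification --------------------------------------------
    self_id_thresholds: tuple[float, float] = (0.25, 0.5)
    self_id_sigma: float | None = None  # calibrated when None
    self_id_target_r2: float = 0.64
    calibration_size: int = 20000
    minor_category_rates: dict[str, float] = field(
        default_factory=lambda: {"Indigenous": 0.01, "Yellow": 0.008, "NonInformed": 0.017}
    )

    # --- registry --------------------------------------------------------
    registry_size: int = 20000
    # printed registry composition (normalized in __post_init__)
    registry_composition: dict[str, float] = field(
        default_factory=lambda: {
            "White": 0.5464,
            "Mixed": 0.2344,
            "Black": 0.0717,
            "Indigenous": 0.0046,
            "Yellow": 0.0331,
            "NonInformed": 0.1097,
        }
    )
    donor_ancestry_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "White": (1.3, 6.0),
            "Mixed": (2.6, 4.2),
            "Black": (4.5, 2.9),
            "Indigenous": (1.0, 6.0),
            "Yellow": (0.8, 7.0),
            "NonInformed": (1.0, 2.6),
        }
    )
    c_typed_fraction: float = 0.35
    dqb1_typed_fraction: float = 0.35
    medium_resolution_fraction: float = 0.5
    allele_code_fraction: float = 0.15

    # --- SNP panel -------------------------------------------------------
    n_snps: int = 2000
    snp_fst: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)

    # --- cohort sizes ----------------------------------------------------
    cohort_size: int = 2000
    scd_size: int = 417

    def __post_init__(self) -> None:
        for name in ("afr_pool_size", "eur_pool_size", "registry_size",
                     "n_snps", "cohort_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.afr_pool_size < 2 or self.eur_pool_size < 2:
            raise ValueError("haplotype pools need at least 2 haplotypes")
        total = sum(self.registry_composition.values())
        if not math.isclose(total, 1.0, abs_tol=0.005):
            raise ValueError(
                f"registry composition sums to {total:.4f}, expected ~1"
            )
        self.registry_composition = {
            k: v / total for k, v in self.registry_composition.items()
        }
        for name in ("c_typed_fraction", "dqb1_typed_fraction",
                     "medium_resolution_fraction", "allele_code_fraction",
                     "shared_group_fraction", "snp_fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        t1, t2 = self.self_id_thresholds
        if not 0.0 < t1 < t2 < 1.0:
            raise ValueError("self-ID thresholds must satisfy 0 < t1 < t2 < 1")

    # ---------------------------------------------------------------- JSON

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("nat_beta", "self_id_thresholds", "ancestral_maf_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("cohort_beta", "donor_ancestry_beta"):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema": "hlamatch/config v1", "generator": self.to_dict()},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw, dict) and "generator" in raw:
            raw = raw["generator"]
        return cls.from_dict(raw)


@dataclass
class HaplotypePool:
    """An ancestry-specific pool of five-locus HLA haplotypes.

    Haplotypes are tuples of two-field allele names ordered as
    :data:`hlamatch.nomenclature.LOCI`; ``frequencies`` sum to one.
    """

    ancestry: str  # "AFR" | "EUR"
    haplotypes: list[tuple[str, ...]]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies disagree in length")
        if np.any(self.frequencies <= 0):
            raise ValueError("haplotype frequencies must be positive")
        if not math.isclose(self.frequencies.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("haplotype frequencies must sum to 1")
        self._cum = np.cumsum(self.frequencies)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def sample(self, rng: np.random.Generator) -> tuple[str, ...]:
        idx = int(np.searchsorted(self._cum, rng.random(), side="right"))
        return self.haplotypes[min(idx, len(self.haplotypes) - 1)]

    def marginal_allele_freqs(self, locus: str) -> dict[str, float]:
        i = LOCI.index(locus)
        out: dict[str, float] = {}
        for hap, p in zip(self.haplotypes, self.frequencies):
            out[hap[i]] = out.get(hap[i], 0.0) + p
        return out

    def expected_heterozygosity(self, locus: str) -> float:
        """1 - sum p_a^2 over the pool's marginal allele frequencies."""
        freqs = np.array(list(self.marginal_allele_freqs(locus).values()))
        return float(1.0 - np.sum(freqs**2))


# ===================================================================== pools

def _allele_name(locus: str, group: int, variant: int) -> str:
    return f"{locus}*{group:02d}:{variant:02d}"


def _build_group_sets(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """Per-locus allele-group index sets for each ancestry.

    African groups are 1..G_afr; a configured fraction of the (smaller)
    European group set is drawn from the African groups (worldwide allele
    sharing), the rest are Europe-specific groups numbered beyond G_afr.
    """
    groups: dict[str, dict[str, list[int]]] = {}
    for locus in LOCI:
        n_afr = config.afr_groups_per_locus[locus]
        n_eur = config.eur_groups_per_locus[locus]
        afr = list(range(1, n_afr + 1))
        n_shared = int(round(config.shared_group_fraction * n_eur))
        n_shared = min(n_shared, n_afr)
        shared = sorted(rng.choice(afr, size=n_shared, replace=False).tolist()) if n_shared else []
        novel = list(range(n_afr + 1, n_afr + 1 + (n_eur - n_shared)))
        groups[locus] = {"AFR": afr, "EUR": shared + novel}
    return groups


def _sample_pool(
    ancestry: str,
    group_sets: dict,
    pool_size: int,
    hap_concentration: float,
    group_concentration: float,
    variants_per_group: int,
    rng: np.random.Generator,
) -> HaplotypePool:
    group_freqs = {
        locus: rng.dirichlet([group_concentration] * len(group_sets[locus][ancestry]))
        for locus in LOCI
    }
    haps: list[tuple[str, ...]] = []
    for _ in range(pool_size):
        alleles = []
        for locus in LOCI:
            gs = group_sets[locus][ancestry]
            g = gs[int(rng.choice(len(gs), p=group_freqs[locus]))]
            v = int(rng.integers(1, variants_per_group + 1))
            alleles.append(_allele_name(locus, g, v))
        haps.append(tuple(alleles))
    freqs = rng.dirichlet([hap_concentration] * pool_size)
    # merge duplicate haplotypes, keep deterministic (sorted) order
    merged: dict[tuple[str, ...], float] = {}
    for h, p in zip(haps, freqs):
        merged[h] = merged.get(h, 0.0) + p
    items = sorted(merged.items())
    haplotypes = [h for h, _ in items]
    frequencies = np.array([p for _, p in items])
    frequencies = frequencies / frequencies.sum()
    return HaplotypePool(ancestry=ancestry, haplotypes=haplotypes, frequencies=frequencies)


def generate_pools(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypePool, HaplotypePool]:
    """Generate the (African, European) haplotype pools.

    The African pool is larger and has flatter Dirichlet frequencies, so it
    carries more distinct haplotypes and higher per-locus expected
    heterozygosity than the European pool under the default configuration.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    group_sets = _build_group_sets(config, rng)
    afr = _sample_pool(
        "AFR", group_sets, config.afr_pool_size, config.afr_hap_concentration,
        config.group_concentration, config.afr_variants_per_group, rng,
    )
    eur = _sample_pool(
        "EUR", group_sets, config.eur_pool_size, config.eur_hap_concentration,
        config.group_concentration, config.eur_variants_per_group, rng,
    )
    return afr, eur


# ================================================================== SNP panel

def generate_snp_panel(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Parental allele frequencies, shape (n_snps, 3), columns AFR/EUR/NAT.

    Balding-Nichols model: each population's frequency is a Beta draw
    around a shared ancestral frequency, with divergence set by an
    F_ST-like parameter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    fst = config.snp_fst
    c = (1.0 - fst) / fst
    freqs = np.empty((config.n_snps, 3))
    for k in range(3):
        freqs[:, k] = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    return np.clip(freqs, 0.01, 0.99)


# ============================================================== individuals

def _draw_mhc_track(
    config: GeneratorConfig, q_afr: float, rng: np.random.Generator
) -> tuple[bool, ...]:
    """Locus-level ancestry of one MHC haplotype, in chromosomal order.

    With recombination off the whole segment inherits a single ancestry
    (haplotype-block model).  With recombination on, ancestry may switch
    between adjacent loci with probability 1 - exp(-g * d), where d is the
    inter-locus distance in Morgans (1 cM/Mb) and g the number of
    generations since admixture; a switch redraws ancestry from the
    individual's admixture proportion.
    """
    first = rng.random() < q_afr
    if not config.mhc_recombination:
        return (first,) * len(CHROM_ORDER)
    g = config.generations_since_admixture
    track = [first]
    for a, b in itertools.pairwise(CHROM_ORDER):
        d_morgan = (MHC_POSITIONS_BP[b] - MHC_POSITIONS_BP[a]) / 1e8
        if rng.random() < 1.0 - math.exp(-g * d_morgan):
            track.append(rng.random() < q_afr)
        else:
            track.append(track[-1])
    return tuple(track)


def _haplotype_from_track(
    track: tuple[bool, ...],
    afr_pool: HaplotypePool,
    eur_pool: HaplotypePool,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Allele per locus for one haplotype given its ancestry track."""
    afr_hap = afr_pool.sample(rng) if any(track) else None
    eur_hap = eur_pool.sample(rng) if not all(track) else None
    anc_by_locus = dict(zip(CHROM_ORDER, track))
    out = {}
    for i, locus in enumerate(LOCI):
        source = afr_hap if anc_by_locus[locus] else eur_hap
        out[locus] = source[i]
    return out


def self_id_labels(
    q_afr: np.ndarray,
    sigma: float,
    thresholds: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ordered-threshold self-identification model on q_AFR + Gaussian noise.

    Latent = q_AFR + sigma * N(0,1); below t1 -> "White", below t2 ->
    "Mixed", else "Black".  Minor categories are handled by the caller.
    """
    latent = np.asarray(q_afr, dtype=float) + sigma * rng.standard_normal(len(q_afr))
    t1, t2 = thresholds
    labels = np.where(latent < t1, "White", np.where(latent < t2, "Mixed", "Black"))
    return labels


@dataclass
class CalibrationResult:
    sigma: float
    achieved_r2: float
    target_r2: float
    bracket: tuple[float, float]  # (R² at max noise, R² at zero noise)


def calibrate_self_id(
    config: GeneratorConfig,
    target_r2: float,
    rng: np.random.Generator | None = None,
    cohort: str = "merged",
    tol: float = 0.02,
    sigma_max: float = 3.0,
) -> CalibrationResult:
    """Tune the self-ID noise scale so the three main categories explain the
    target fraction of variance in q_AFR.

    Uses bisection on a fixed calibration sample with common random
    numbers, so the achieved R² is a deterministic, (near-)monotone
    decreasing function of the noise scale.  Raises
    :class:`CalibrationError`, reporting the achievable bracket, when the
    target lies outside it.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target R² must lie in (0,1)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a, b = config.cohort_beta[cohort]
    n = config.calibration_size
    q = rng.beta(a, b, size=n)
    eps = rng.standard_normal(n)

    def achieved(sigma: float) -> float:
        latent = q + sigma * eps
        t1, t2 = config.self_id_thresholds
        labels = np.where(latent < t1, "White", np.where(latent < t2, "Mixed", "Black"))
        if len(np.unique(labels)) < 2:
            return 0.0
        return variance_explained(labels, q)

    r_zero = achieved(0.0)
    r_max = achieved(sigma_max)
    if not (r_max - tol <= target_r2 <= r_zero + tol):
        raise CalibrationError(
            f"target R²={target_r2:.3f} outside achievable bracket "
            f"[{r_max:.3f}, {r_zero:.3f}] for cohort {cohort!r}"
        )
    lo, hi = 0.0, sigma_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if achieved(mid) > target_r2:
            lo = mid
        else:
            hi = mid
    sigma = 0.5 * (lo + hi)
    got = achieved(sigma)
    if abs(got - target_r2) > tol:
        raise CalibrationError(
            f"bisection stalled at R²={got:.3f} for target {target_r2:.3f} "
            f"(bracket [{r_max:.3f}, {r_zero:.3f}])"
        )
    return CalibrationResult(sigma=sigma, achieved_r2=got, target_r2=target_r2,
                             bracket=(r_max, r_zero))


def _resolve_sigma(config: GeneratorConfig, rng: np.random.Generator) -> float:
    if config.self_id_sigma is not None:
        return config.self_id_sigma
    return calibrate_self_id(
        config, config.self_id_target_r2,
        rng=np.random.default_rng(rng.integers(2**31)),
    ).sigma


def _draw_self_id(
    q_afr: float,
    sigma: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> str:
    u = rng.random()
    acc = 0.0
    for cat, rate in config.minor_category_rates.items():
        acc += rate
        if u < acc:
            return cat
    latent = q_afr + sigma * rng.standard_normal()
    t1, t2 = config.self_id_thresholds
    return "White" if latent < t1 else ("Mixed" if latent < t2 else "Black")


def generate_individual(
    config: GeneratorConfig,
    pools: tuple[HaplotypePool, HaplotypePool],
    cohort: str,
    rng: np.random.Generator,
    index: int = 0,
    sigma: float | None = None,
    snp_freqs: np.ndarray | None = None,
    scd: bool = False,
    id_prefix: str = "P",
) -> TypedIndividual:
    """Draw one admixed, fully typed individual from the given cohort."""
    afr_pool, eur_pool = pools
    a, b = config.cohort_beta[cohort]
    q_afr = float(rng.beta(a, b))
    q_nat = float((1.0 - q_afr) * rng.beta(*config.nat_beta))
    q = np.array([q_afr, 1.0 - q_afr - q_nat, q_nat])

    tracks = (
        _draw_mhc_track(config, q_afr, rng),
        _draw_mhc_track(config, q_afr, rng),
    )
    mhc_afr = tuple(
        float(np.dot(SEGMENT_WEIGHTS, np.asarray(t, dtype=float))) for t in tracks
    )
    hap_alleles = [
        _haplotype_from_track(t, afr_pool, eur_pool, rng) for t in tracks
    ]
    genotypes = {
        locus: LocusGenotype(
            locus=locus,
            alleles=(
                parse_allele(hap_alleles[0][locus]),
                parse_allele(hap_alleles[1][locus]),
            ),
        )
        for locus in LOCI
    }
    if sigma is None:
        sigma = _resolve_sigma(config, rng)
    self_id = _draw_self_id(q_afr, sigma, config, rng)
    snps = None
    if snp_freqs is not None:
        p_ind = snp_freqs @ q
        snps = rng.binomial(2, p_ind).astype(np.int8)
    return TypedIndividual(
        id=f"{id_prefix}{index:06d}",
        cohort=cohort,
        q=q,
        mhc_afr=mhc_afr,  # type: ignore[arg-type]
        genotypes=genotypes,
        self_id=self_id,
        scd=scd,
        snps=snps,
        mhc_tracks=tracks,
    )


def generate_cohort(
    config: GeneratorConfig,
    pools: tuple[HaplotypePool, HaplotypePool],
    n: int,
    cohort: str,
    rng: np.random.Generator,
    sigma: float | None = None,
    snp_freqs: np.ndarray | None = None,
    scd: bool = False,
    id_prefix: str = "P",
) -> list[TypedIndividual]:
    if sigma is None:
        sigma = _resolve_sigma(config, rng)
    return [
        generate_individual(
            config, pools, cohort, rng, index=i, sigma=sigma,
            snp_freqs=snp_freqs, scd=scd, id_prefix=id_prefix,
        )
        for i in range(n)
    ]


def generate_scd_cohort(
    config: GeneratorConfig,
    pools: tuple[HaplotypePool, HaplotypePool],
    n: int | None = None,
    rng: np.random.Generator | None = None,
    sigma: float | None = None,
    snp_freqs: np.ndarray | None = None,
) -> list[TypedIndividual]:
    """A sickle-cell-disease sub-cohort with elevated African ancestry."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.scd_size
    if n < 1:
        raise ValueError("SCD cohort size must be >= 1")
    return generate_cohort(
        config, pools, n, "scd", rng, sigma=sigma, snp_freqs=snp_freqs,
        scd=True, id_prefix="S",
    )


# ================================================================== registry

_LABEL_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _code_label(counter: int) -> str:
    """Two-letter labels AB, AC, ... (skipping AA to stay unambiguous)."""
    first, second = divmod(counter + 1, 26)
    return _LABEL_ALPHABET[first % 26] + _LABEL_ALPHABET[second]


def _variants_by_group(
    pools: tuple[HaplotypePool, HaplotypePool]
) -> dict[tuple[str, int], list[str]]:
    """All two-field allele names present in either pool, per (locus, group)."""
    out: dict[tuple[str, int], set[str]] = {}
    for pool in pools:
        for hap in pool.haplotypes:
            for name in hap:
                a = parse_allele(name)
                out.setdefault((a.locus, a.field1), set()).add(name)
    return {k: sorted(v) for k, v in out.items()}


def generate_registry(
    config: GeneratorConfig,
    pools: tuple[HaplotypePool, HaplotypePool],
    rng: np.random.Generator | None = None,
) -> Registry:
    """Generate the donor registry.

    Donors are drawn with the configured self-identification composition;
    each donor's ancestry is drawn from a category-conditional Beta and
    their HLA genotypes from the same admixture mechanism as cohort
    members.  All donors are typed at HLA-A/-B/-DRB1; HLA-C and -DQB1 are
    typed with the configured fractions.  A per-donor typing resolution is
    drawn (low-resolution donors report one-field alleles), and a fraction
    of medium-resolution donors have one allele replaced by a
    multiple-allele code covering it.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    comp = config.registry_composition
    cats = sorted(comp)
    probs = np.array([comp[c] for c in cats])
    variants = _variants_by_group(pools)
    codes: dict[str, AlleleCode] = {}
    code_by_key: dict[tuple[str, int, frozenset], str] = {}
    counter = 0
    donors: list[Donor] = []
    n = config.registry_size
    categories = rng.choice(cats, size=n, p=probs)
    for i in range(n):
        cat = str(categories[i])
        a, b = config.donor_ancestry_beta[cat]
        q_afr = float(rng.beta(a, b))
        tracks = (
            _draw_mhc_track(config, q_afr, rng),
            _draw_mhc_track(config, q_afr, rng),
        )
        hap_alleles = [_haplotype_from_track(t, *pools, rng) for t in tracks]
        resolution = "medium" if rng.random() < config.medium_resolution_fraction else "low"
        typed = {"A": True, "B": True, "DRB1": True,
                 "C": rng.random() < config.c_typed_fraction,
                 "DQB1": rng.random() < config.dqb1_typed_fraction}
        genotypes: dict[str, LocusGenotype] = {}
        for locus in LOCI:
            if not typed[locus]:
                genotypes[locus] = LocusGenotype.untyped(locus)
                continue
            alleles = [parse_allele(hap_alleles[0][locus]),
                       parse_allele(hap_alleles[1][locus])]
            if resolution == "low":
                alleles = [HLAAllele(locus=a_.locus, field1=a_.field1) for a_ in alleles]
            genotypes[locus] = LocusGenotype(locus=locus, alleles=tuple(alleles))
        if resolution == "medium" and rng.random() < config.allele_code_fraction:
            locus = str(rng.choice([l for l in LOCI if typed[l]]))
            slot = int(rng.integers(2))
            true_allele = genotypes[locus].alleles[slot]
            pool_variants = variants.get((locus, true_allele.field1), [true_allele.name])
            others = [v for v in pool_variants if v != true_allele.name]
            k = min(len(others), int(rng.integers(1, 4)))
            extra = (
                [str(x) for x in rng.choice(others, size=k, replace=False)]
                if k else []
            )
            members = frozenset(
                [parse_allele(true_allele.name)] + [parse_allele(x) for x in extra]
            )
            key = (locus, true_allele.field1, frozenset(a_.name for a_ in members))
            if key in code_by_key:
                token = code_by_key[key]
            else:
                label = _code_label(counter)
                counter += 1
                code = AlleleCode(
                    locus=locus, field1=true_allele.field1,
                    code_label=label, expansion=members,
                )
                token = code.name
                codes[token] = code
                code_by_key[key] = token
            new_alleles = list(genotypes[locus].alleles)
            new_alleles[slot] = codes[token]
            genotypes[locus] = LocusGenotype(locus=locus, alleles=tuple(new_alleles))
        donors.append(
            Donor(
                id=f"D{i:06d}",
                self_id=cat,
                typing_resolution=resolution,
                genotypes=genotypes,
            )
        )
    return Registry(donors, codes)
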