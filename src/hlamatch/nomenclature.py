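"""HLA allele nomenclature: parsing, truncation and compatibility.

Implements the subset of WHO HLA nomenclature needed for unrelated-donor
registry searches at the five classical loci (HLA-A, -B, -C, -DRB1,
-DQB1): colon-separated numeric fields, G-group suffixes, and NMDP-style
multiple-allele codes used to report ambiguously typed donors.

Two search resolutions are supported.  At *low* resolution only the first
field (the allele group) is compared, so ``A*34:02`` is compatible with any
variant of ``A*34``.  At *medium* resolution the first two fields (protein
level) must agree, so only variants of ``A*34:02`` (e.g. ``A*34:02:01G``)
are compatible, as well as any multiple-allele code whose expansion
contains ``A*34:02``.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "LOCI",
    "Resolution",
    "HLAAllele",
    "AlleleCode",
    "LocusGenotype",
    "HLAParseError",
    "CrossLocusError",
    "UntypedLocusError",
    "InsufficientResolutionError",
    "parse_allele",
    "parse_typing",
    "truncate",
    "compatible",
    "locus_mismatch_count",
    "load_allele_codes",
    "dump_allele_codes",
]

#: Classical loci in scope, in conventional (alphabetical) order.
LOCI = ("A", "B", "C", "DRB1", "DQB1")


class HLAParseError(ValueError):
    """Raised for malformed allele names or unknown loci."""


class CrossLocusError(ValueError):
    """Raised when alleles from different loci are compared."""


class UntypedLocusError(ValueError):
    """Raised when a mismatch count is requested for an untyped locus."""


class InsufficientResolutionError(ValueError):
    """Raised when an operation needs a second field that is absent."""


class Resolution(enum.Enum):
    """Typing/search resolution: one field (low) or two fields (medium)."""

    LOW = "low"
    MEDIUM = "medium"

    @classmethod
    def coerce(cls, value: Union[str, "Resolution"]) -> "Resolution":
        if isinstance(value, Resolution):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(f"unknown resolution {value!r}; expected 'low' or 'medium'")


_NAME_RE = re.compile(r"^([A-Za-z0-9]+)\*(\d+(?::\d+)*)(G?)$")
# token whose second field is a letter-bearing label, e.g. "A*34:AB" -> NMDP code
_CODE_RE = re.compile(r"^([A-Za-z0-9]+)\*(\d+):([A-Z][A-Z0-9]*)$")


@dataclass(frozen=True)
class HLAAllele:
    """A parsed HLA allele name such as ``A*34:02:01G``.

    ``field1`` is the allele group (always present); ``field2`` the
    protein-level field (absent for one-field, low-resolution typings);
    ``extra_fields`` any further synonymous/intron-level fields;
    ``g_group`` is set for names carrying the G-group suffix.
    """

    locus: str
    field1: int
    field2: int | None = None
    extra_fields: tuple[int, ...] = ()
    g_group: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise HLAParseError(f"unknown or unsupported locus {self.locus!r}")
        if self.field1 <= 0:
            raise HLAParseError(f"allele group must be positive, got {self.field1}")
        if self.field2 is None and (self.extra_fields or self.g_group):
            raise HLAParseError(
                "extra fields or a G suffix require a two-field allele name"
            )

    @property
    def name(self) -> str:
        """Canonical name with zero-padded two-digit fields."""
        parts = [f"{self.locus}*{self.field1:02d}"]
        if self.field2 is not None:
            parts.append(f"{self.field2:02d}")
        parts.extend(f"{x:02d}" for x in self.extra_fields)
        return ":".join(parts) + ("G" if self.g_group else "")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class AlleleCode:
    """An NMDP-style multiple-allele code.

    Denotes a set of possible two-field alleles for an ambiguously typed
    donor, e.g. a code ``A*34:AB`` expanding to {A*34:01, A*34:02}.  All
    expansion members share the code's locus and allele group.
    """

    locus: str
    field1: int
    code_label: str
    expansion: frozenset[HLAAllele]

    def __post_init__(self) -> None:
        if not self.expansion:
            raise ValueError(f"allele code {self.name} has an empty expansion")
        for a in self.expansion:
            if a.locus != self.locus or a.field1 != self.field1:
                raise ValueError(
                    f"expansion member {a.name} does not share locus/group "
                    f"with code {self.name}"
                )
            if a.field2 is None:
                raise ValueError(
                    f"expansion member {a.name} of code {self.name} must be two-field"
                )
        # two-field keys for fast membership tests
        object.__setattr__(
            self,
            "_keys",
            frozenset((a.field1, a.field2) for a in self.expansion),
        )

    @property
    def name(self) -> str:
        return f"{self.locus}*{self.field1:02d}:{self.code_label}"

    def contains(self, allele: HLAAllele) -> bool:
        """Whether the code's expansion contains the allele (two-field)."""
        if allele.field2 is None:
            raise InsufficientResolutionError(
                f"cannot test one-field allele {allele.name} against code {self.name}"
            )
        return (allele.field1, allele.field2) in self._keys  # type: ignore[attr-defined]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


GenotypeEntry = Union[HLAAllele, AlleleCode]


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered pair of alleles (or codes) at one locus; possibly untyped."""

    locus: str
    alleles: tuple[GenotypeEntry, ...] = ()
    typed: bool = True

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise HLAParseError(f"unknown or unsupported locus {self.locus!r}")
        if self.typed and len(self.alleles) != 2:
            raise ValueError(
                f"typed locus {self.locus} needs exactly 2 alleles, got "
                f"{len(self.alleles)}"
            )
        if not self.typed and self.alleles:
            raise ValueError(f"untyped locus {self.locus} must carry no alleles")
        for a in self.alleles:
            if a.locus != self.locus:
                raise CrossLocusError(
                    f"allele {a.name} placed in genotype at locus {self.locus}"
                )

    @classmethod
    def untyped(cls, locus: str) -> "LocusGenotype":
        return cls(locus=locus, alleles=(), typed=False)


@lru_cache(maxsize=None)
def parse_allele(name: str) -> HLAAllele:
    """Parse a WHO-nomenclature allele name, e.g. ``A*34:02:01G``.

    Raises :class:`HLAParseError` naming the offending token for malformed
    strings or loci outside the five classical loci in scope.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise HLAParseError(f"malformed HLA allele name: {name!r}")
    locus, fields_s, g = m.groups()
    if locus not in LOCI:
        raise HLAParseError(f"unknown or unsupported locus {locus!r} in {name!r}")
    fields = [int(x) for x in fields_s.split(":")]
    if g and len(fields) < 2:
        raise HLAParseError(f"G suffix requires at least two fields: {name!r}")
    return HLAAllele(
        locus=locus,
        field1=fields[0],
        field2=fields[1] if len(fields) > 1 else None,
        extra_fields=tuple(fields[2:]),
        g_group=bool(g),
    )


def parse_typing(
    token: str, codes: Mapping[str, AlleleCode] | None = None
) -> GenotypeEntry:
    """Parse a typing-table token: either an allele name or a code token.

    A token whose second field starts with a letter (e.g. ``A*34:AB``) is an
    NMDP-style multiple-allele code and is resolved through ``codes``.
    """
    cm = _CODE_RE.match(token.strip())
    if cm is not None:
        if codes is None or token.strip() not in codes:
            raise HLAParseError(
                f"allele code {token!r} has no expansion in the supplied code table"
            )
        return codes[token.strip()]
    return parse_allele(token)


def truncate(allele: HLAAllele, res: Resolution | str) -> HLAAllele:
    """Truncate an allele to the requested resolution.

    Low keeps the allele group only; medium keeps the first two fields and
    drops any extra fields and the G suffix.  Truncating an allele already
    at (or below) the target resolution is the identity; truncating a
    one-field allele to medium raises
    :class:`InsufficientResolutionError`.
    """
    res = Resolution.coerce(res)
    if res is Resolution.LOW:
        if allele.field2 is None and not allele.g_group:
            return allele
        return HLAAllele(locus=allele.locus, field1=allele.field1)
    if allele.field2 is None:
        raise InsufficientResolutionError(
            f"cannot truncate one-field allele {allele.name} to medium resolution"
        )
    if not allele.extra_fields and not allele.g_group:
        return allele
    return HLAAllele(locus=allele.locus, field1=allele.field1, field2=allele.field2)


def compatible(
    patient: HLAAllele, donor: GenotypeEntry, res: Resolution | str
) -> bool:
    """Whether a donor allele (or code) is compatible with a patient allele.

    Low resolution compares allele groups; medium compares the first two
    fields, or, for a code on the donor side, tests membership of the
    patient's two-field name in the code's expansion.  A one-field donor
    typing can never be confirmed compatible at medium resolution and
    returns False (conservative handling of insufficiently resolved
    donors).  Symmetric in its allele arguments when both sides are plain
    alleles.
    """
    res = Resolution.coerce(res)
    if patient.locus != donor.locus:
        raise CrossLocusError(
            f"cannot compare {patient.name} with {donor.name}: different loci"
        )
    if res is Resolution.LOW:
        return patient.field1 == donor.field1
    if patient.field2 is None:
        raise InsufficientResolutionError(
            f"patient allele {patient.name} is one-field; medium-resolution "
            "comparison requires two fields"
        )
    if isinstance(donor, AlleleCode):
        return donor.contains(patient)
    if donor.field2 is None:
        # insufficient resolution on the donor side: cannot be confirmed
        return False
    return patient.field1 == donor.field1 and patient.field2 == donor.field2


def locus_mismatch_count(
    patient: LocusGenotype, donor: LocusGenotype, res: Resolution | str
) -> int:
    """Allele mismatches (0, 1 or 2) between two genotypes at one locus.

    Equals 2 minus the maximum number of compatible patient-to-donor allele
    pairings over the two possible bijections between the unordered pairs.
    Raises :class:`UntypedLocusError` if either side is untyped; the caller
    decides whether to exclude the donor.
    """
    res = Resolution.coerce(res)
    if not patient.typed or not donor.typed:
        raise UntypedLocusError(
            f"mismatch count at locus {patient.locus} requires both sides typed"
        )
    if patient.locus != donor.locus:
        raise CrossLocusError(
            f"cannot compare genotypes at {patient.locus} and {donor.locus}"
        )
    p1, p2 = patient.alleles
    d1, d2 = donor.alleles
    if not isinstance(p1, HLAAllele) or not isinstance(p2, HLAAllele):
        raise TypeError("patient genotypes must contain plain alleles, not codes")
    c11 = compatible(p1, d1, res)
    c22 = compatible(p2, d2, res)
    c12 = compatible(p1, d2, res)
    c21 = compatible(p2, d1, res)
    best = max(int(c11) + int(c22), int(c12) + int(c21))
    return 2 - best


def load_allele_codes(source: str | Path | Mapping[str, Iterable[str]]) -> dict[str, AlleleCode]:
    """Load a multiple-allele code table.

    Accepts a JSON file path or an in-memory mapping of code token to a
    list of two-field allele names, e.g. ``{"A*34:AB": ["A*34:01",
    "A*34:02"]}``.  JSON files may wrap the mapping under a ``"codes"``
    key (the format written by :func:`dump_allele_codes`).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = json.load(fh)
        if isinstance(raw, dict) and "codes" in raw:
            raw = raw["codes"]
    else:
        raw = dict(source)
    codes: dict[str, AlleleCode] = {}
    for token, names in raw.items():
        cm = _CODE_RE.match(token)
        if cm is None:
            raise HLAParseError(f"malformed allele-code token: {token!r}")
        locus, f1, label = cm.group(1), int(cm.group(2)), cm.group(3)
        if locus not in LOCI:
            raise HLAParseError(f"unknown or unsupported locus {locus!r} in {token!r}")
        expansion = frozenset(truncate(parse_allele(n), Resolution.MEDIUM) for n in names)
        codes[token] = AlleleCode(
            locus=locus, field1=f1, code_label=label, expansion=expansion
        )
    return codes


def dump_allele_codes(codes: Mapping[str, AlleleCode], path: str | Path) -> None:
    """Write a code table as JSON (schema: ``{"codes": {token: [names]}}``)."""
    payload = {
        "schema": "hlamatch/allele-codes v1",
        "codes": {
            token: sorted(a.name for a in code.expansion)
            for token, code in sorted(codes.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
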