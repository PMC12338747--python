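"""Core data model for trio de novo mutation (DNM) analysis.

Conventions used throughout the package:

* VCF and read-evidence coordinates are 1-based; BED/feature intervals are
  0-based half-open.  Conversions happen only at the IO boundary
  (:mod:`trioscope.io`).
* Genotypes are tuples of allele indices after biallelic splitting:
  ``(0, 0)`` hom-ref, ``(0, 1)`` het, ``(1,)`` haploid alt.  The sentinel
  allele ``2`` marks "some other alternate allele" on a split record and
  ``None`` marks a missing call.
* A deletion-spanning read observation carries the allele ``"*"``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Platform(str, enum.Enum):
    HIFI = "HIFI"
    ONT = "ONT"
    ILLUMINA = "ILLUMINA"


class Tissue(str, enum.Enum):
    BLOOD = "BLOOD"
    CELL_LINE = "CELL_LINE"


class Role(str, enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    PROBAND = "proband"
    SIBLING = "sibling"


class QualityTier(str, enum.Enum):
    """Base-quality tier of a read at the variant site.

    HIGH: base quality > 20; LOW: 10 <= base quality <= 20; DISCARD: < 10.
    """

    HIGH = "HIGH"
    LOW = "LOW"
    DISCARD = "DISCARD"

    @staticmethod
    def of(base_qual: float) -> "QualityTier":
        if base_qual > 20:
            return QualityTier.HIGH
        if base_qual >= 10:
            return QualityTier.LOW
        return QualityTier.DISCARD


class Verdict(str, enum.Enum):
    """Per-platform read-support verdict for a candidate variant."""

    DENOVO = "DENOVO"
    INHERITED = "INHERITED"
    NODATA = "NODATA"
    #: parents clean but zero child reads carry the de novo allele even
    #: though usable child reads exist; counts toward neither support nor
    #: inheritance.
    NO_SUPPORT = "NO_SUPPORT"


class Phase(str, enum.Enum):
    PATERNAL = "PATERNAL"
    MATERNAL = "MATERNAL"
    UNPHASED = "UNPHASED"
    CONFLICT = "CONFLICT"


class Origin(str, enum.Enum):
    GERMLINE = "GERMLINE"
    POSTZYGOTIC = "POSTZYGOTIC"
    NA = "NA"


class TrueClass(str, enum.Enum):
    """Ground-truth label of a simulated variant."""

    GERMLINE = "GERMLINE"
    PZM = "PZM"
    INHERITED_ARTIFACT = "INHERITED_ARTIFACT"
    RECURRENT_ERROR = "RECURRENT_ERROR"
    HOMOPOLYMER_ERROR = "HOMOPOLYMER_ERROR"


@dataclass
class Person:
    sample_id: str
    family_id: str
    role: Role
    sex: str  # "M" | "F"
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    father_age_at_birth: Optional[float] = None
    mother_age_at_birth: Optional[float] = None

    @property
    def is_child(self) -> bool:
        return self.role in (Role.PROBAND, Role.SIBLING)


@dataclass
class Family:
    family_id: str
    father: Person
    mother: Person
    children: list[Person]

    @property
    def members(self) -> list[Person]:
        return [self.father, self.mother, *self.children]


class Pedigree:
    """A cohort of families, indexed by sample and by family."""

    def __init__(self, families: Sequence[Family]):
        self.families: dict[str, Family] = {}
        self._by_sample: dict[str, Person] = {}
        for fam in families:
            if fam.family_id in self.families:
                raise ValueError(f"duplicate family_id {fam.family_id!r}")
            self.families[fam.family_id] = fam
            for person in fam.members:
                if person.sample_id in self._by_sample:
                    raise ValueError(f"duplicate sample_id {person.sample_id!r}")
                self._by_sample[person.sample_id] = person

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_sample

    def __len__(self) -> int:
        return len(self._by_sample)

    def person(self, sample_id: str) -> Person:
        return self._by_sample[sample_id]

    def family_of(self, sample_id: str) -> Family:
        return self.families[self._by_sample[sample_id].family_id]

    def parents_of(self, child_id: str) -> tuple[Person, Person]:
        """(father, mother) of a child sample."""
        fam = self.family_of(child_id)
        return fam.father, fam.mother

    def siblings_of(self, child_id: str) -> list[Person]:
        fam = self.family_of(child_id)
        return [c for c in fam.children if c.sample_id != child_id]

    @property
    def children(self) -> list[Person]:
        return [p for p in self._by_sample.values() if p.is_child]

    @property
    def samples(self) -> list[str]:
        return list(self._by_sample)

    def related_samples(self, sample_id: str) -> set[str]:
        """Members of the same family (including the sample itself)."""
        return {p.sample_id for p in self.family_of(sample_id).members}


@dataclass(slots=True)
class VariantCall:
    """One biallelic site in a single family's callset."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, Optional[tuple]]  # sample -> allele-index tuple
    gq: dict[str, int] = field(default_factory=dict)
    caller_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt) and abs(len(self.ref) - len(self.alt)) < 50

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PlatformAlleleCounts:
    platform: str
    n_ref: int = 0
    n_alt: int = 0

    @property
    def ab(self) -> Optional[float]:
        total = self.n_ref + self.n_alt
        if total == 0:
            return None
        return self.n_alt / total


@dataclass
class DnmRecord:
    """A candidate/validated de novo variant with full provenance."""

    chrom: str
    pos: int
    ref: str
    alt: str
    child_id: str
    variant_type: str  # SNV | INS | DEL
    validation_status: str = "CANDIDATE"
    phase: Phase = Phase.UNPHASED
    origin: Origin = Origin.NA
    platform_counts: dict[str, PlatformAlleleCounts] = field(default_factory=dict)
    hap_counts: dict[str, tuple] = field(default_factory=dict)  # platform -> (n_ref, n_alt) on origin hap
    category: str = ""  # SNV | INDEL_TR | INDEL_NONTR

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.child_id)

    @property
    def is_snv(self) -> bool:
        return self.variant_type == "SNV"

    def mean_ab(self) -> Optional[float]:
        """Unweighted mean allele balance over platforms with >= 1 child read."""
        abs_ = [c.ab for c in self.platform_counts.values() if c.ab is not None]
        if not abs_:
            return None
        return sum(abs_) / len(abs_)


@dataclass
class CallableMask:
    """Per-child intervals (0-based half-open) where discovery was possible."""

    child_id: str
    intervals: dict[str, list[tuple[int, int]]]  # chrom -> [(start, end), ...]

    def normalized(self) -> "CallableMask":
        out = {}
        for chrom, ivs in self.intervals.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = [(s, e) for s, e in merged]
        return CallableMask(self.child_id, out)

    def total_bp(self, chroms: Optional[Sequence[str]] = None) -> int:
        total = 0
        for chrom, ivs in self.intervals.items():
            if chroms is not None and chrom not in chroms:
                continue
            total += sum(e - s for s, e in ivs)
        return total

    def contains(self, chrom: str, pos_1based: int) -> bool:
        import bisect

        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        p = pos_1based - 1
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, p) - 1
        return i >= 0 and ivs[i][0] <= p < ivs[i][1]


@dataclass
class RateEstimate:
    n_mutations: int
    callable_bp: int
    ploidy_factor: int
    rate: float
    ci_low: float
    ci_high: float
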