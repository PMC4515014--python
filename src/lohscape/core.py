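"""Domain types and genotype semantics shared by every pipeline stage.

The model is oriented on the reference genome: at any position the allele
matching the reference base is the major allele M, any differing base is a
minor allele m.  Genotypes are therefore MM (homozygous reference), Mm
(heterozygous) or mm (homozygous non-reference); sites failing the dialect
filters are UNCALLABLE and enter no denominator.  Only biallelic single-base
substitutions are modelled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

BASES = ("A", "C", "G", "T")

#: Unordered base pairs that constitute a transition (purine<->purine or
#: pyrimidine<->pyrimidine).
_TRANSITION_PAIRS = frozenset({frozenset({"A", "G"}), frozenset({"C", "T"})})


class GenotypeClass(str, enum.Enum):
    MM = "MM"
    Mm = "Mm"
    mm = "mm"
    UNCALLABLE = "UNCALLABLE"


class EventKind(str, enum.Enum):
    LOH_TO_MM = "LOH_to_MM"
    LOH_TO_mm = "LOH_to_mm"
    GOH_M = "GOH_M"
    GOH_m = "GOH_m"
    HET_SWITCH = "HET_SWITCH"
    HOM_SWITCH = "HOM_SWITCH"


#: Event kinds that are losses of heterozygosity.
LOH_KINDS = (EventKind.LOH_TO_MM, EventKind.LOH_TO_mm)


class ChangeClass(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


class InvalidAlleleError(ValueError):
    """Raised for non-ACGT or identical ref/alt alleles."""


@dataclass(frozen=True)
class Locus:
    """A 1-based genomic position with its reference (M) base and optional alt."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in BASES:
            raise InvalidAlleleError(f"invalid ref base {self.ref_base!r}")
        if self.alt_base is not None:
            if self.alt_base not in BASES:
                raise InvalidAlleleError(f"invalid alt base {self.alt_base!r}")
            if self.alt_base == self.ref_base:
                raise InvalidAlleleError("ref and alt bases must differ")


@dataclass(frozen=True)
class SiteObservation:
    """One sample's read evidence at a locus.

    ``sb`` is the signed strand-bias score used by the inter-Alu capture
    dialect (pass when sb < sb_max); ``fs`` is the Phred-scaled Fisher strand
    p-value used by the whole-genome dialect (pass when fs <= fs_max).
    Whichever annotation the active dialect does not use is ignored; a
    missing annotation that the dialect requires makes the site UNCALLABLE.
    """

    locus: Locus
    depth: int
    ad_ref: int
    ad_alt: int
    qd: Optional[float] = None
    sb: Optional[float] = None
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise ValueError("allele depths must be >= 0")
        if self.ad_ref + self.ad_alt > self.depth:
            raise ValueError("ad_ref + ad_alt exceeds depth")


@dataclass(frozen=True)
class GenotypeCall:
    gclass: GenotypeClass
    m_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gclass is GenotypeClass.MM and self.m_base is not None:
            raise ValueError("MM call cannot carry a minor allele")
        if self.gclass in (GenotypeClass.Mm, GenotypeClass.mm) and self.m_base is None:
            raise ValueError(f"{self.gclass.value} call requires a minor allele")

    @property
    def callable(self) -> bool:
        return self.gclass is not GenotypeClass.UNCALLABLE


UNCALLABLE_CALL = GenotypeCall(GenotypeClass.UNCALLABLE)


@dataclass(frozen=True)
class FilterDialect:
    """Per-platform genotype filter thresholds.

    The two shipped dialects mirror the filtering regimes of inter-Alu
    capture sequencing (``aluscan``) and whole-genome sequencing (``wgs``):
    a minimum read depth in *both* members of a pair, a heterozygous
    allele-fraction band, quality-by-depth floors per genotype class, and a
    strand-bias cutoff (signed SB for aluscan, Phred-scaled FS for wgs).
    """

    name: str
    min_depth: int
    het_af_lo: float
    het_af_hi: float
    qd_het: float
    qd_hom_nonref: float
    qd_hom_ref: Optional[float] = None
    sb_max: Optional[float] = None
    fs_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.het_af_lo < self.het_af_hi < 1.0):
            raise ValueError("het band must satisfy 0 < lo < hi < 1")
        if (self.sb_max is None) == (self.fs_max is None):
            raise ValueError("exactly one of sb_max / fs_max must be set")


ALUSCAN = FilterDialect(
    name="aluscan",
    min_depth=8,
    het_af_lo=0.35,
    het_af_hi=0.65,
    qd_het=4.0,
    qd_hom_nonref=20.0,
    sb_max=-0.01,
)

WGS = FilterDialect(
    name="wgs",
    min_depth=15,
    het_af_lo=0.25,
    het_af_hi=0.75,
    qd_het=4.0,
    qd_hom_nonref=20.0,
    qd_hom_ref=1.0,
    fs_max=12.0,
)

DIALECTS = {"aluscan": ALUSCAN, "wgs": WGS}


@dataclass
class MutationEvent:
    """A classified control->tumor genotype change at one locus."""

    locus: Locus
    sample_id: str
    kind: EventKind
    control_call: GenotypeCall
    tumor_call: GenotypeCall
    mm_context: str
    change_class: ChangeClass
    copy_neutral: bool = field(default=True)


def mm_context_label(ref_base: str, alt_base: str) -> str:
    """Ordered heterozygote label: uppercase reference, lowercase minor.

    There are exactly 12 labels ("Ac", "Ag", "At", "Ca", ...); e.g. a site
    with reference A and minor allele G is labelled ``"Ag"``.
    """
    if ref_base not in BASES or alt_base not in BASES:
        raise InvalidAlleleError(f"bases must be in {BASES}: {ref_base!r}, {alt_base!r}")
    if ref_base == alt_base:
        raise InvalidAlleleError("ref and alt bases must differ")
    return ref_base.upper() + alt_base.lower()


def classify_change(ref_base: str, alt_base: str) -> ChangeClass:
    """Transition iff the unordered pair is {A,G} or {C,T}; else transversion."""
    if ref_base not in BASES or alt_base not in BASES:
        raise InvalidAlleleError(f"bases must be in {BASES}: {ref_base!r}, {alt_base!r}")
    if ref_base == alt_base:
        raise InvalidAlleleError("ref and alt bases must differ")
    if frozenset({ref_base, alt_base}) in _TRANSITION_PAIRS:
        return ChangeClass.TRANSITION
    return ChangeClass.TRANSVERSION


#: Transition partner of each base (A<->G, C<->T).
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def all_contexts() -> list[str]:
    """The 12 ordered heterozygote context labels in a fixed order."""
    return [mm_context_label(r, a) for r in BASES for a in BASES if a != r]
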