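"""Core domain types for trio phasing and construction of the joint trio site table.

The trio site table is the central data structure of the pipeline: one row per
child variant site, carrying the child's genotype together with both parents'
genotypes resolved at the same position (from an explicit record, from a gVCF
reference block, or missing when the position is uncovered).  Parental allele
indices are remapped onto the child site's allele list so that all downstream
transmission logic operates in a single allele coordinate system per site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .vcf_io import GvcfIndex, VariantRecord

logger = logging.getLogger(__name__)

#: Chromosomes retained in the trio table (normalized labels, no "chr" prefix).
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Default minimum Phred-scaled site quality for a child variant to be phased.
DEFAULT_MIN_QUAL: float = 30.0


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosomes first in natural order."""
    if chrom.isdigit():
        return (0, int(chrom), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype as a pair of allele indices.

    Allele indices refer to a site's allele list (0 = REF, 1.. = ALT).
    Negative indices denote *foreign* alleles: parental alleles that do not
    occur in the child site's allele list (they can never match a child
    allele, which is all the transmission logic needs to know about them).
    ``alleles is None`` means the genotype is missing; half-calls are
    normalized to missing.

    When ``phased`` is true the pair is ordered; with ``paternal_first``
    (the convention used throughout this package) the first allele is the
    paternally inherited one.
    """

    alleles: Optional[tuple[int, int]] = None
    phased: bool = False
    paternal_first: bool = True

    def __post_init__(self) -> None:
        if self.alleles is not None and any(a is None for a in self.alleles):
            object.__setattr__(self, "alleles", None)
            object.__setattr__(self, "phased", False)

    @classmethod
    def missing(cls) -> "Genotype":
        return cls(None)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    @property
    def has_alt(self) -> bool:
        """True when any called allele is non-reference (including foreign)."""
        return self.alleles is not None and any(a != 0 for a in self.alleles)

    def allele_set(self) -> frozenset[int]:
        return frozenset(self.alleles) if self.alleles is not None else frozenset()

    def multiset(self) -> Counter:
        return Counter(self.alleles) if self.alleles is not None else Counter()

    def __contains__(self, allele: int) -> bool:
        return self.alleles is not None and allele in self.alleles

    def gt_string(self) -> str:
        if self.alleles is None:
            return "./."
        sep = "|" if self.phased else "/"
        return f"{self.alleles[0]}{sep}{self.alleles[1]}"


class PhaseStatus(Enum):
    """Mendelian classification of a trio site."""

    MENDELIAN_PHASED = "mendelian_phased"
    UNPHASEABLE = "unphaseable"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class PhaseCall:
    """Outcome of Mendelian transmission analysis at one site.

    ``paternal``/``maternal`` are set only for MENDELIAN_PHASED calls and
    together carry exactly the child's allele multiset.  ``novel_allele``
    marks a child allele observed in neither parent's (non-missing)
    genotype — a de novo candidate or genotyping error — and implies
    INCONSISTENT status.
    """

    status: PhaseStatus
    paternal: Optional[int] = None
    maternal: Optional[int] = None
    novel_allele: bool = False


@dataclass(frozen=True)
class TrioSite:
    """One child variant site with all three members' genotypes.

    ``alts`` is the child's alternate allele list; parental genotypes are
    expressed in the child's allele index space (foreign parental alleles
    get negative indices).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    child_gt: Genotype
    father_gt: Genotype
    mother_gt: Genotype
    qual: Optional[float] = None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def allele_name(self, index: int) -> str:
        """Base string for an allele index; foreign indices get a tag."""
        if index < 0:
            return f"<FOREIGN{-index}>"
        return self.alleles[index]


@dataclass
class TableBuildStats:
    """Bookkeeping from trio-table construction.

    ``child_variant_records`` counts child records with a called non-reference
    genotype; every one of them lands in exactly one bucket:
    table row, quality-excluded, off-autosome, or duplicate-position drop.
    """

    child_variant_records: int = 0
    quality_excluded: int = 0
    off_autosome: int = 0
    duplicates_dropped: int = 0
    parental_ref_mismatch: int = 0

    @property
    def table_rows(self) -> int:
        return (
            self.child_variant_records
            - self.quality_excluded
            - self.off_autosome
            - self.duplicates_dropped
        )


def _trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-normalization of one REF/ALT pair.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``), always keeping at least one base on each side.
    Enough to reconcile padding differences between a child and a parent
    record at the same position; full reference-aware normalization is
    out of scope.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (pos, ref, alt)


def _refs_compatible(child_ref: str, parent_ref: str) -> bool:
    return child_ref.startswith(parent_ref) or parent_ref.startswith(child_ref)


def remap_parent_genotype(
    parent_record: Optional["VariantRecord"],
    child_pos: int,
    child_ref: str,
    child_alts: tuple[str, ...],
    foreign: dict[str, int],
) -> tuple[Genotype, bool]:
    """Express a parent's genotype in the child site's allele index space.

    Returns ``(genotype, ref_mismatch)``.  ``parent_record`` is whatever
    record covers the child position in the parent's gVCF: a reference
    block yields homozygous-reference, no record yields missing.  Alleles
    of an explicit parent record are matched against the child's alleles
    after minimal normalization; parent alleles absent from the child's
    list are assigned fresh negative ("foreign") indices.  A parent REF
    irreconcilable with the child REF makes the whole parental genotype
    missing — a silent mismatch would corrupt phasing.
    """
    if parent_record is None:
        return Genotype.missing(), False
    if not parent_record.alts:  # reference block or invariant record
        return Genotype((0, 0)), False
    gt = parent_record.genotype
    if gt.is_missing:
        return Genotype.missing(), False
    if parent_record.pos != child_pos or not _refs_compatible(
        child_ref, parent_record.ref
    ):
        return Genotype.missing(), True

    child_keys = {
        _trim_allele(child_pos, child_ref, alt): i + 1
        for i, alt in enumerate(child_alts)
    }

    def map_allele(idx: int) -> int:
        if idx == 0:
            return 0
        alt = parent_record.alts[idx - 1]
        key = _trim_allele(parent_record.pos, parent_record.ref, alt)
        if key in child_keys:
            return child_keys[key]
        if alt not in foreign:
            foreign[alt] = -(len(foreign) + 1)
        return foreign[alt]

    a, b = gt.alleles  # type: ignore[misc]
    return Genotype((map_allele(a), map_allele(b))), False


def build_trio_table(
    child: "GvcfIndex",
    father: "GvcfIndex",
    mother: "GvcfIndex",
    min_qual: float = DEFAULT_MIN_QUAL,
) -> tuple[list[TrioSite], TableBuildStats]:
    """Assemble the joint trio site table from three single-sample gVCF indexes.

    One :class:`TrioSite` is produced per child variant record (called
    genotype containing a non-reference allele) on autosomes 1-22 whose site
    QUAL passes ``min_qual``; a missing QUAL counts as 0.  Parental genotypes
    are resolved position-wise through each parent's index and remapped onto
    the child's allele list.  Filtered records are counted, never errors.
    """
    table: list[TrioSite] = []
    stats = TableBuildStats()

    for chrom in sorted(child.chroms, key=chrom_sort_key):
        last_pos = None
        for rec in child.records_for(chrom):
            gt = rec.genotype
            if not rec.alts or gt.is_missing or not gt.has_alt:
                continue
            stats.child_variant_records += 1
            if chrom not in AUTOSOMES:
                stats.off_autosome += 1
                continue
            qual = rec.qual if rec.qual is not None else 0.0
            if qual < min_qual:
                stats.quality_excluded += 1
                continue
            if rec.pos == last_pos:
                stats.duplicates_dropped += 1
                continue
            last_pos = rec.pos

            foreign: dict[str, int] = {}
            father_gt, f_mm = remap_parent_genotype(
                father.record_at(chrom, rec.pos), rec.pos, rec.ref, rec.alts, foreign
            )
            mother_gt, m_mm = remap_parent_genotype(
                mother.record_at(chrom, rec.pos), rec.pos, rec.ref, rec.alts, foreign
            )
            stats.parental_ref_mismatch += int(f_mm) + int(m_mm)

            table.append(
                TrioSite(
                    chrom=chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=rec.alts,
                    child_gt=gt,
                    father_gt=father_gt,
                    mother_gt=mother_gt,
                    qual=rec.qual,
                )
            )

    logger.info(
        "trio table: %d sites (%d child variant records; %d below QUAL %g, "
        "%d off-autosome, %d duplicate positions)",
        len(table),
        stats.child_variant_records,
        stats.quality_excluded,
        min_qual,
        stats.off_autosome,
        stats.duplicates_dropped,
    )
    return table, stats
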