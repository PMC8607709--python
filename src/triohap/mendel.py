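"""Mendelian-inheritance phasing: transmission enumeration, site classification,
scaffold construction and de-novo-candidate reporting.

The engine rests on one constraint: a child receives exactly one allele from
each parent.  At a site, each ordered pair (paternal allele, maternal allele)
whose multiset equals the child's genotype and whose members are present in
the respective parent's genotype is a *consistent transmission*.  A unique
consistent transmission phases the site; several leave it unphaseable (the
classic case being all three members heterozygous for the same two alleles);
none at all marks a Mendelian inconsistency — genotyping error or de novo
mutation.  A parent with a missing genotype constrains nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .trio_core import (
    Genotype,
    PhaseCall,
    PhaseStatus,
    TrioSite,
    chrom_sort_key,
)

if TYPE_CHECKING:  # pragma: no cover
    from .merge_phase import MergedRecord

logger = logging.getLogger(__name__)


def enumerate_transmissions(site: TrioSite) -> frozenset[tuple[int, int]]:
    """All ordered (paternal, maternal) allele pairs consistent with the trio.

    A pair qualifies when its multiset equals the child's allele multiset and
    each member is carried by the corresponding parent; a missing parental
    genotype admits any child allele from that side.
    """
    child = site.child_gt.alleles
    if child is None:
        raise ValueError(f"{site.chrom}:{site.pos}: child genotype is missing")
    a, b = child
    out = set()
    for p, m in {(a, b), (b, a)}:
        if not site.father_gt.is_missing and p not in site.father_gt:
            continue
        if not site.mother_gt.is_missing and m not in site.mother_gt:
            continue
        out.add((p, m))
    return frozenset(out)


def phase_site(site: TrioSite) -> PhaseCall:
    """Classify one trio site by Mendelian transmission logic.

    Exactly one consistent transmission -> MENDELIAN_PHASED with that
    paternal|maternal order (a homozygous child with any consistent
    transmission lands here, its two orderings coinciding); two -> UNPHASEABLE;
    none -> INCONSISTENT.  ``novel_allele`` is raised only when both parents
    are genotyped and some child allele occurs in neither — missing parental
    data is absence of evidence, never Mendelian conflict.
    """
    transmissions = enumerate_transmissions(site)
    novel = False
    if not site.father_gt.is_missing and not site.mother_gt.is_missing:
        parental = site.father_gt.allele_set() | site.mother_gt.allele_set()
        novel = any(a not in parental for a in site.child_gt.alleles)  # type: ignore[union-attr]
    if len(transmissions) == 1:
        paternal, maternal = next(iter(transmissions))
        return PhaseCall(PhaseStatus.MENDELIAN_PHASED, paternal, maternal)
    if not transmissions:
        return PhaseCall(PhaseStatus.INCONSISTENT, novel_allele=novel)
    return PhaseCall(PhaseStatus.UNPHASEABLE)


@dataclass
class MendelCounts:
    """Aggregate Mendelian classification counts over a trio table."""

    phased: int = 0
    unphaseable: int = 0
    inconsistent: int = 0
    novel_allele: int = 0

    @property
    def total(self) -> int:
        return self.phased + self.unphaseable + self.inconsistent


@dataclass(frozen=True)
class ScaffoldEntry:
    """One Mendelian-phased site: the a priori haplotype handed to the
    statistical phaser and kept for the final merge."""

    site: TrioSite
    paternal: int
    maternal: int


class Scaffold:
    """Per-chromosome collection of Mendelian-phased sites."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, dict[int, ScaffoldEntry]] = {}

    def add(self, entry: ScaffoldEntry) -> None:
        self._by_chrom.setdefault(entry.site.chrom, {})[entry.site.pos] = entry

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom, key=chrom_sort_key)

    def entries(self, chrom: str) -> list[ScaffoldEntry]:
        chrom_map = self._by_chrom.get(chrom, {})
        return [chrom_map[pos] for pos in sorted(chrom_map)]

    def by_pos(self, chrom: str) -> Mapping[int, ScaffoldEntry]:
        return self._by_chrom.get(chrom, {})

    def get(self, chrom: str, pos: int) -> Optional[ScaffoldEntry]:
        return self._by_chrom.get(chrom, {}).get(pos)

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        return pos in self._by_chrom.get(chrom, {})

    def __len__(self) -> int:
        return sum(len(m) for m in self._by_chrom.values())


class PhaseLedger:
    """Per-site record of every PhaseCall made over a trio table."""

    def __init__(self) -> None:
        self.calls: list[tuple[TrioSite, PhaseCall]] = []
        self._by_key: dict[tuple[str, int], PhaseCall] = {}
        self.counts = MendelCounts()

    def record(self, site: TrioSite, call: PhaseCall) -> None:
        self.calls.append((site, call))
        self._by_key[(site.chrom, site.pos)] = call
        if call.status is PhaseStatus.MENDELIAN_PHASED:
            self.counts.phased += 1
        elif call.status is PhaseStatus.UNPHASEABLE:
            self.counts.unphaseable += 1
        else:
            self.counts.inconsistent += 1
        if call.novel_allele:
            self.counts.novel_allele += 1

    def call_at(self, chrom: str, pos: int) -> Optional[PhaseCall]:
        return self._by_key.get((chrom, pos))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, call in self.calls:
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alts": ",".join(site.alts),
                    "child_gt": site.child_gt.gt_string(),
                    "father_gt": site.father_gt.gt_string(),
                    "mother_gt": site.mother_gt.gt_string(),
                    "status": call.status.value,
                    "paternal": "" if call.paternal is None else call.paternal,
                    "maternal": "" if call.maternal is None else call.maternal,
                    "novel_allele": int(call.novel_allele),
                }
            )
        columns = [
            "chrom", "pos", "ref", "alts", "child_gt", "father_gt",
            "mother_gt", "status", "paternal", "maternal", "novel_allele",
        ]
        return pd.DataFrame(rows, columns=columns)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def build_scaffold(table: Sequence[TrioSite]) -> tuple[Scaffold, PhaseLedger]:
    """Run :func:`phase_site` over a trio table.

    The scaffold holds exactly the MENDELIAN_PHASED sites (homozygous child
    sites included — their phase is trivially determined and they anchor the
    statistical phaser just as well); UNPHASEABLE and INCONSISTENT sites are
    left for the statistical phaser.  The ledger records every call.
    """
    scaffold = Scaffold()
    ledger = PhaseLedger()
    for site in table:
        call = phase_site(site)
        ledger.record(site, call)
        if call.status is PhaseStatus.MENDELIAN_PHASED:
            scaffold.add(ScaffoldEntry(site, call.paternal, call.maternal))  # type: ignore[arg-type]
    logger.info(
        "Mendelian classification: %d phased, %d unphaseable, %d inconsistent "
        "(%d novel-allele)",
        ledger.counts.phased,
        ledger.counts.unphaseable,
        ledger.counts.inconsistent,
        ledger.counts.novel_allele,
    )
    return scaffold, ledger


def denovo_report(
    merged: Iterable["MergedRecord"], ledger: PhaseLedger
) -> list["MergedRecord"]:
    """De-novo-candidate subset of the final merged output.

    Returns exactly the *phased* final records whose site carries a child
    allele seen in neither parent (``novel_allele``).  Such sites may reflect
    genotyping error or true de novo mutation; Mendelian logic cannot have
    phased them, so any phase they carry came from the statistical phaser.
    """
    out = []
    for rec in merged:
        if not rec.phased:
            continue
        call = ledger.call_at(rec.site.chrom, rec.site.pos)
        if call is not None and call.novel_allele:
            out.append(rec)
    return out
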