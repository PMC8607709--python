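"""Scaffold-constrained statistical phasing (adapter layer) and the final
merge of Mendelian and statistical phase sets.

A statistical phaser (SHAPEIT4 in production) consumes a chromosome's
unphased genotypes, the Mendelian scaffold as a priori haplotypes, and a
haplotype reference panel.  Its output is restricted to biallelic sites
present in the panel, so the merge step restores scaffold sites the phaser
dropped (multi-allelic or off-panel) and leaves the remainder unphased.
The bundled mock adapter reproduces exactly this contract without any
external process or panel, which is what the test-bed runs against.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import zlib
from abc import ABC, abstractmethod
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .mendel import Scaffold, ScaffoldEntry
from .trio_core import Genotype, TrioSite, chrom_sort_key

logger = logging.getLogger(__name__)


class AdapterContractError(RuntimeError):
    """A phaser adapter produced output violating its contract."""


class PhaserError(RuntimeError):
    """The external phasing process failed; carries captured diagnostics."""


@dataclass(frozen=True)
class PhasedSite:
    """One site phased by the statistical phaser, in the child's allele
    index space, ordered paternal|maternal."""

    chrom: str
    pos: int
    paternal: int
    maternal: int


class PhaserAdapter(ABC):
    """Contract for statistical phasers.

    An adapter may only *order* genotypes: its output sites must be a subset
    of the sites it was given, each with the same allele content, and it is
    expected to honor the scaffold orientation at scaffold sites.
    """

    name: str = "abstract"

    @abstractmethod
    def phase_chromosome(
        self,
        chrom: str,
        sites: Sequence[TrioSite],
        scaffold: Mapping[int, ScaffoldEntry],
        panel_dir: Optional[str],
        seed: int,
    ) -> list[PhasedSite]:
        """Phase one chromosome; return phased sites in position order."""


def _orientation_bit(seed: int, chrom: str, pos: int) -> int:
    # process-independent deterministic pseudo-random bit per site
    return zlib.crc32(f"{seed}:{chrom}:{pos}".encode()) & 1


class MockPanelPhaser(PhaserAdapter):
    """Deterministic stand-in emulating a panel-based statistical phaser.

    Phases every biallelic site it is given: scaffold sites keep their
    scaffold orientation, non-scaffold heterozygotes get a seeded
    pseudo-random orientation, homozygotes are trivial.  Multi-allelic sites
    are dropped, emulating the reference-panel/biallelic restriction of the
    real tool.  No notion of linkage: orientations at non-scaffold sites are
    independent, so only set arithmetic — not phasing accuracy — is
    meaningful for them.
    """

    name = "mock"

    def phase_chromosome(
        self,
        chrom: str,
        sites: Sequence[TrioSite],
        scaffold: Mapping[int, ScaffoldEntry],
        panel_dir: Optional[str],
        seed: int,
    ) -> list[PhasedSite]:
        out: list[PhasedSite] = []
        for site in sites:
            if len(site.alts) != 1:
                continue  # panel restriction: biallelic only
            entry = scaffold.get(site.pos)
            if entry is not None:
                out.append(PhasedSite(chrom, site.pos, entry.paternal, entry.maternal))
                continue
            a, b = site.child_gt.alleles  # type: ignore[misc]
            if a == b:
                out.append(PhasedSite(chrom, site.pos, a, b))
                continue
            lo, hi = sorted((a, b))
            if _orientation_bit(seed, chrom, site.pos):
                lo, hi = hi, lo
            out.append(PhasedSite(chrom, site.pos, lo, hi))
        return out


class Shapeit4Adapter(PhaserAdapter):
    """Subprocess adapter for a real SHAPEIT4 installation.

    Integration path for production use: writes the chromosome VCF and
    scaffold to disk, invokes ``shapeit4`` with ``--scaffold`` and the
    reference panel found under ``panel_dir``, and reads the phased output
    back.  Requires the executable and per-chromosome panel files; the
    bundled mock adapter is the supported test surface.
    """

    name = "shapeit4"

    def __init__(self, executable: str = "shapeit4") -> None:
        self.executable = executable

    def phase_chromosome(
        self,
        chrom: str,
        sites: Sequence[TrioSite],
        scaffold: Mapping[int, ScaffoldEntry],
        panel_dir: Optional[str],
        seed: int,
    ) -> list[PhasedSite]:
        import tempfile
        from pathlib import Path

        from . import vcf_io

        if shutil.which(self.executable) is None:
            raise PhaserError(f"{self.executable!r} not found on PATH")
        if panel_dir is None:
            raise PhaserError("shapeit4 adapter requires a reference panel directory")
        panel = Path(panel_dir) / f"chr{chrom}.bcf"
        with tempfile.TemporaryDirectory(prefix="triohap_shapeit4_") as tmp:
            tmp = Path(tmp)
            unphased = tmp / f"{chrom}.vcf"
            scaff = tmp / f"{chrom}.scaffold.vcf"
            phased = tmp / f"{chrom}.phased.vcf"
            vcf_io.write_phased_vcf(
                [_site_record(s, Genotype(s.child_gt.alleles)) for s in sites],
                unphased,
            )
            vcf_io.write_phased_vcf(
                [
                    _site_record(
                        e.site, Genotype((e.paternal, e.maternal), phased=True)
                    )
                    for e in scaffold.values()
                ],
                scaff,
            )
            cmd = [
                self.executable,
                "--input", str(unphased),
                "--scaffold", str(scaff),
                "--reference", str(panel),
                "--region", chrom,
                "--seed", str(seed),
                "--output", str(phased),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise PhaserError(
                    f"shapeit4 failed on chromosome {chrom} "
                    f"(exit {proc.returncode}):\n{proc.stderr}"
                )
            out = []
            for rec in vcf_io.read_gvcf(phased):
                gt = rec.genotype
                if gt.alleles is None or not gt.phased:
                    continue
                out.append(PhasedSite(rec.chrom, rec.pos, gt.alleles[0], gt.alleles[1]))
            return out


def _site_record(site: TrioSite, genotype: Genotype):
    from .vcf_io import VariantRecord

    return VariantRecord(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alts=site.alts,
        genotype=genotype,
        qual=site.qual,
    )


ADAPTERS: dict[str, type[PhaserAdapter]] = {
    MockPanelPhaser.name: MockPanelPhaser,
    Shapeit4Adapter.name: Shapeit4Adapter,
}


def get_adapter(name: str) -> PhaserAdapter:
    try:
        return ADAPTERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown phaser adapter {name!r}; available: {sorted(ADAPTERS)}"
        ) from None


def validate_adapter_output(
    sites: Sequence[TrioSite], output: Sequence[PhasedSite]
) -> None:
    """Enforce the adapter contract: output ⊆ input, allele content intact."""
    by_pos = {s.pos: s for s in sites}
    for ps in output:
        site = by_pos.get(ps.pos)
        if site is None:
            raise AdapterContractError(
                f"{ps.chrom}:{ps.pos}: adapter emitted a site it was not given"
            )
        if sorted((ps.paternal, ps.maternal)) != sorted(site.child_gt.alleles):  # type: ignore[arg-type]
            raise AdapterContractError(
                f"{ps.chrom}:{ps.pos}: adapter altered genotype allele content"
            )


def check_scaffold_conformance(
    scaffold: Mapping[int, ScaffoldEntry], output: Sequence[PhasedSite]
) -> list[int]:
    """Positions where the adapter flipped a scaffold orientation (should be
    empty for a conforming adapter)."""
    flipped = []
    for ps in output:
        entry = scaffold.get(ps.pos)
        if entry is not None and (ps.paternal, ps.maternal) != (
            entry.paternal,
            entry.maternal,
        ):
            flipped.append(ps.pos)
    return flipped


def run_statistical_phaser(
    adapter: PhaserAdapter,
    table: Sequence[TrioSite],
    scaffold: Scaffold,
    panel_dir: Optional[str] = None,
    seed: int = 0,
    cores: int = 1,
) -> dict[str, list[PhasedSite]]:
    """Phase every chromosome of the trio table through an adapter.

    Chromosomes are independent work units (``cores`` of them in flight at a
    time); results are assembled in chromosome order so the degree of
    parallelism never changes the output.
    """
    by_chrom: dict[str, list[TrioSite]] = {}
    for site in table:
        by_chrom.setdefault(site.chrom, []).append(site)
    chroms = sorted(by_chrom, key=chrom_sort_key)

    def run_one(chrom: str) -> list[PhasedSite]:
        out = adapter.phase_chromosome(
            chrom, by_chrom[chrom], scaffold.by_pos(chrom), panel_dir, seed
        )
        validate_adapter_output(by_chrom[chrom], out)
        return out

    if cores <= 1 or len(chroms) <= 1:
        results = {chrom: run_one(chrom) for chrom in chroms}
    else:
        with ThreadPoolExecutor(max_workers=cores) as pool:
            futures = {chrom: pool.submit(run_one, chrom) for chrom in chroms}
            results = {chrom: futures[chrom].result() for chrom in chroms}
    logger.info(
        "statistical phaser %s: %d sites phased over %d chromosomes",
        adapter.name,
        sum(len(v) for v in results.values()),
        len(chroms),
    )
    return results


@dataclass
class PhaseStats:
    """Phase-source accounting over one trio run.

    ``mendelian_exclusive`` counts scaffold sites absent from the statistical
    output (multi-allelic or off-panel); ``statistical_exclusive`` counts
    phased sites that were not in the scaffold; jointly phased sites complete
    the partition, so the three always sum to ``total_phased``.
    """

    total_genotyped: int = 0
    total_phased: int = 0
    jointly_phased: int = 0
    mendelian_exclusive: int = 0
    statistical_exclusive: int = 0
    unphased: int = 0
    scaffold_discordant: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total_genotyped": self.total_genotyped,
            "total_phased": self.total_phased,
            "jointly_phased": self.jointly_phased,
            "mendelian_exclusive": self.mendelian_exclusive,
            "statistical_exclusive": self.statistical_exclusive,
            "unphased": self.unphased,
            "scaffold_discordant": self.scaffold_discordant,
        }


@dataclass(frozen=True)
class MergedRecord:
    """Final per-site result: the child's genotype with its phase source."""

    site: TrioSite
    gt: tuple[int, int]
    phased: bool
    source: str  # "statistical" | "mendelian" | "unphased"


def merge_outputs(
    statistical: Mapping[str, Sequence[PhasedSite]],
    scaffold: Scaffold,
    table: Sequence[TrioSite],
) -> tuple[list[MergedRecord], PhaseStats]:
    """Merge statistical and Mendelian phase sets into the final record set.

    Per site: the statistical phaser's phase wins where present (the adapter
    contract already forces scaffold agreement; a discordant orientation is
    counted as a warning, statistical kept); a scaffold site the phaser
    dropped keeps its Mendelian phase; anything else is emitted unphased.
    """
    stat_by_key: dict[tuple[str, int], PhasedSite] = {}
    for chrom, sites in statistical.items():
        for ps in sites:
            stat_by_key[(chrom, ps.pos)] = ps

    merged: list[MergedRecord] = []
    stats = PhaseStats(total_genotyped=len(table))
    for site in table:
        key = (site.chrom, site.pos)
        in_scaffold = key in scaffold
        ps = stat_by_key.get(key)
        if ps is not None:
            merged.append(
                MergedRecord(site, (ps.paternal, ps.maternal), True, "statistical")
            )
            if in_scaffold:
                stats.jointly_phased += 1
                entry = scaffold.get(site.chrom, site.pos)
                if (ps.paternal, ps.maternal) != (entry.paternal, entry.maternal):  # type: ignore[union-attr]
                    stats.scaffold_discordant += 1
            else:
                stats.statistical_exclusive += 1
        elif in_scaffold:
            entry = scaffold.get(site.chrom, site.pos)
            merged.append(
                MergedRecord(site, (entry.paternal, entry.maternal), True, "mendelian")  # type: ignore[union-attr]
            )
            stats.mendelian_exclusive += 1
        else:
            merged.append(
                MergedRecord(site, site.child_gt.alleles, False, "unphased")  # type: ignore[arg-type]
            )
            stats.unphased += 1
    stats.total_phased = (
        stats.jointly_phased + stats.mendelian_exclusive + stats.statistical_exclusive
    )
    if stats.scaffold_discordant:
        logger.warning(
            "%d scaffold sites were re-oriented by the statistical phaser "
            "(statistical phase kept)",
            stats.scaffold_discordant,
        )
    logger.info(
        "merge: %d/%d phased (%d joint, %d Mendelian-exclusive, "
        "%d statistical-exclusive)",
        stats.total_phased,
        stats.total_genotyped,
        stats.jointly_phased,
        stats.mendelian_exclusive,
        stats.statistical_exclusive,
    )
    return merged, stats
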