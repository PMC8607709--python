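"""End-to-end trio phasing: gVCFs in, phased VCF + de novo VCF + reports out.

The pipeline chains the library modules: read the three gVCFs, build the
joint trio site table, derive the Mendelian scaffold, hand unphased
chromosomes plus scaffold to the statistical-phaser adapter, merge the two
phase sets, and write the outputs.  Output genotypes are ordered
paternal|maternal.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import mendel, merge_phase, trio_core, vcf_io
from .mendel import MendelCounts, PhaseLedger
from .merge_phase import MergedRecord, PhaseStats
from .trio_core import Genotype, TableBuildStats

logger = logging.getLogger(__name__)

SUPPORTED_BUILDS = ("GRCh38", "GRCh37")


class PipelineError(RuntimeError):
    """Unrecoverable pipeline failure for one trio."""


@dataclass
class PipelineResult:
    """Everything one trio run produced."""

    phased_vcf: Path
    denovo_vcf: Path
    ledger_tsv: Path
    stats_json: Path
    stats: PhaseStats
    counts: MendelCounts
    table_stats: TableBuildStats


def _output_paths(out: Path) -> tuple[Path, Path, Path]:
    base = out.with_suffix("") if out.suffix == ".vcf" else out
    return (
        base.with_name(base.name + ".denovo.vcf"),
        base.with_name(base.name + ".mendel.tsv"),
        base.with_name(base.name + ".stats.json"),
    )


def _merged_to_records(
    merged: Sequence[MergedRecord],
) -> list[vcf_io.VariantRecord]:
    return [
        vcf_io.VariantRecord(
            chrom=m.site.chrom,
            pos=m.site.pos,
            ref=m.site.ref,
            alts=m.site.alts,
            genotype=Genotype(m.gt, phased=m.phased),
            qual=m.site.qual,
        )
        for m in merged
    ]


def run_single(
    child: str | Path,
    father: str | Path,
    mother: str | Path,
    out: str | Path,
    panel_dir: Optional[str | Path] = None,
    cores: int = 2,
    build: str = "GRCh38",
    min_qual: float = trio_core.DEFAULT_MIN_QUAL,
    phaser: str = "mock",
    seed: int = 0,
) -> PipelineResult:
    """Phase one trio.

    ``build`` selects coordinate labeling only (passed through to real
    adapters for panel selection; the mock adapter is build-agnostic).
    ``cores`` chromosomes are phased concurrently; the outputs are identical
    for any core count.
    """
    if build not in SUPPORTED_BUILDS:
        raise PipelineError(
            f"unsupported genome build {build!r}; choose from {SUPPORTED_BUILDS}"
        )
    if cores < 1:
        raise PipelineError("cores must be >= 1")
    for path in (child, father, mother):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    adapter = merge_phase.get_adapter(phaser)
    out = Path(out)
    denovo_path, ledger_path, stats_path = _output_paths(out)

    t0 = time.perf_counter()
    child_idx = vcf_io.read_gvcf(child)
    father_idx = vcf_io.read_gvcf(father)
    mother_idx = vcf_io.read_gvcf(mother)
    logger.info("read inputs in %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    table, table_stats = trio_core.build_trio_table(
        child_idx, father_idx, mother_idx, min_qual=min_qual
    )
    scaffold, ledger = mendel.build_scaffold(table)
    logger.info("Mendelian phasing in %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    statistical = merge_phase.run_statistical_phaser(
        adapter,
        table,
        scaffold,
        panel_dir=None if panel_dir is None else str(panel_dir),
        seed=seed,
        cores=cores,
    )
    merged, stats = merge_phase.merge_outputs(statistical, scaffold, table)
    logger.info("statistical phasing + merge in %.1fs", time.perf_counter() - t0)

    out.parent.mkdir(parents=True, exist_ok=True)
    vcf_io.write_phased_vcf(
        _merged_to_records(merged),
        out,
        dialect=child_idx.dialect,
        sample=child_idx.sample,
        contigs=child_idx.contigs,
    )
    denovo = mendel.denovo_report(merged, ledger)
    vcf_io.write_phased_vcf(
        _merged_to_records(denovo),
        denovo_path,
        dialect=child_idx.dialect,
        sample=child_idx.sample,
        contigs=child_idx.contigs,
    )
    ledger.write_tsv(ledger_path)
    payload = {
        "inputs": {
            "child": str(child),
            "father": str(father),
            "mother": str(mother),
            "min_qual": min_qual,
            "build": build,
            "phaser": adapter.name,
            "seed": seed,
        },
        "table": {
            "child_variant_records": table_stats.child_variant_records,
            "quality_excluded": table_stats.quality_excluded,
            "off_autosome": table_stats.off_autosome,
            "duplicates_dropped": table_stats.duplicates_dropped,
        },
        "mendelian": {
            "phased": ledger.counts.phased,
            "unphaseable": ledger.counts.unphaseable,
            "inconsistent": ledger.counts.inconsistent,
            "novel_allele": ledger.counts.novel_allele,
        },
        "phase": stats.as_dict(),
        "denovo_candidates_reported": len(denovo),
    }
    stats_path.write_text(json.dumps(payload, indent=2) + "\n")
    logger.info("wrote %s (+ de novo, ledger, stats)", out)
    return PipelineResult(
        phased_vcf=out,
        denovo_vcf=denovo_path,
        ledger_tsv=ledger_path,
        stats_json=stats_path,
        stats=stats,
        counts=ledger.counts,
        table_stats=table_stats,
    )


@dataclass
class TrioStatus:
    """Per-trio outcome of a batch run."""

    line: int
    child: str
    out: str
    ok: bool
    message: str = ""


def parse_manifest(manifest: str | Path) -> tuple[list[tuple[int, list[str]]], list[TrioStatus]]:
    """Read a 4-column (child, father, mother, output) TSV manifest.

    Returns ``(rows, errors)`` where malformed lines become error statuses
    rather than aborting the batch."""
    rows: list[tuple[int, list[str]]] = []
    errors: list[TrioStatus] = []
    for lineno, raw in enumerate(Path(manifest).read_text().splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 4 or any(not f.strip() for f in fields):
            errors.append(
                TrioStatus(
                    line=lineno,
                    child=fields[0] if fields else "",
                    out="",
                    ok=False,
                    message=f"line {lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}",
                )
            )
            continue
        rows.append((lineno, [f.strip() for f in fields]))
    return rows, errors


def run_batch(
    manifest: str | Path,
    panel_dir: Optional[str | Path] = None,
    cores: int = 2,
    build: str = "GRCh38",
    min_qual: float = trio_core.DEFAULT_MIN_QUAL,
    phaser: str = "mock",
    seed: int = 0,
) -> list[TrioStatus]:
    """Phase every trio of a manifest; one failure never aborts the rest."""
    rows, statuses = parse_manifest(manifest)
    for lineno, (child, father, mother, out) in ((ln, f) for ln, f in rows):
        try:
            run_single(
                child,
                father,
                mother,
                out,
                panel_dir=panel_dir,
                cores=cores,
                build=build,
                min_qual=min_qual,
                phaser=phaser,
                seed=seed,
            )
            statuses.append(TrioStatus(lineno, child, out, True, "ok"))
        except Exception as exc:  # noqa: BLE001 - batch isolation by design
            logger.error("trio at line %d failed: %s", lineno, exc)
            statuses.append(TrioStatus(lineno, child, out, False, str(exc)))
    statuses.sort(key=lambda s: s.line)
    done = sum(s.ok for s in statuses)
    logger.info("batch: %d/%d trios phased", done, len(statuses))
    return statuses
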