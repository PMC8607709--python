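"""Single-sample VCF/gVCF reading and writing on top of pysam.

A gVCF differs from a plain VCF in that invariant stretches of the genome are
represented as *reference blocks*: records with no real ALT allele and an
INFO ``END`` giving the last position the block covers.  This module exposes
both kinds of record through one container, :class:`GvcfIndex`, which answers
the question the trio logic keeps asking: "what is this sample's genotype at
position X?" — an explicit record, homozygous-reference inside a block, or
missing.

Conventions: coordinates are 1-based inclusive (VCF); ``END`` is inclusive;
chromosome labels are normalized internally by stripping a leading ``chr``
and the original dialect is remembered so output files match their inputs;
symbolic gVCF alleles (``<NON_REF>``, ``<*>``) are dropped from allele lists
after block processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

from .trio_core import Genotype, chrom_sort_key

logger = logging.getLogger(__name__)

SYMBOLIC_ALTS = frozenset({"<NON_REF>", "<*>"})

#: Value of ``GvcfIndex.dialect`` for inputs using "chr1"-style labels.
DIALECT_CHR = "chr"
DIALECT_PLAIN = "plain"


class VcfParseError(ValueError):
    """A malformed VCF/gVCF header or record."""


class VcfInputError(ValueError):
    """An input that is structurally valid VCF but unusable (e.g. multi-sample)."""


class VcfOutputError(ValueError):
    """A record set that cannot be written as a valid VCF."""


def normalize_chrom(label: str) -> str:
    return label[3:] if label.lower().startswith("chr") else label


def apply_dialect(chrom: str, dialect: str) -> str:
    return f"chr{chrom}" if dialect == DIALECT_CHR else chrom


@dataclass(frozen=True)
class VariantRecord:
    """One VCF/gVCF record for a single sample, reduced to the modelled fields.

    ``end`` equals ``pos`` for any record with real ALT alleles; only
    reference blocks span further.  ``format_extras`` carries unmodelled
    per-sample fields opaquely.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: Genotype
    qual: Optional[float] = None
    end: Optional[int] = None
    id: Optional[str] = None
    format_extras: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"{self.chrom}:{self.pos}: POS must be >= 1")
        if not self.ref or any(b not in "ACGTN" for b in self.ref.upper()):
            raise VcfParseError(f"{self.chrom}:{self.pos}: bad REF {self.ref!r}")
        end = self.end
        if end is None:
            end = self.pos
            object.__setattr__(self, "end", end)
        if self.alts and end != self.pos:
            object.__setattr__(self, "end", self.pos)
            end = self.pos
        if end < self.pos:
            raise VcfParseError(
                f"{self.chrom}:{self.pos}: END {end} is smaller than POS"
            )

    @property
    def is_reference_block(self) -> bool:
        return not self.alts


class GvcfIndex:
    """Per-chromosome ordered, non-overlapping records of one sample's gVCF."""

    def __init__(
        self,
        records: Iterable[VariantRecord],
        dialect: str = DIALECT_PLAIN,
        sample: str = "SAMPLE",
        contigs: Optional[Mapping[str, Optional[int]]] = None,
    ):
        self.dialect = dialect
        self.sample = sample
        self.contigs: dict[str, Optional[int]] = dict(contigs or {})
        self._by_chrom: dict[str, list[VariantRecord]] = {}
        for rec in records:
            self._by_chrom.setdefault(rec.chrom, []).append(rec)
        self._starts: dict[str, list[int]] = {}
        for chrom, recs in self._by_chrom.items():
            prev_end = 0
            for rec in recs:
                if rec.pos <= prev_end:
                    raise VcfParseError(
                        f"{chrom}:{rec.pos}: records out of order or overlapping "
                        f"(previous block ends at {prev_end})"
                    )
                prev_end = rec.end  # type: ignore[assignment]
            self._starts[chrom] = [r.pos for r in recs]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom, key=chrom_sort_key)

    def records_for(self, chrom: str) -> Sequence[VariantRecord]:
        return self._by_chrom.get(chrom, ())

    def __iter__(self) -> Iterator[VariantRecord]:
        for chrom in self.chroms:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def record_at(self, chrom: str, pos: int) -> Optional[VariantRecord]:
        """The record whose [pos, end] interval covers ``pos``, if any."""
        import bisect

        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        rec = self._by_chrom[chrom][i]
        return rec if pos <= rec.end else None  # type: ignore[operator]

    def genotype_at(self, chrom: str, pos: int) -> Optional[Genotype]:
        """Genotype at a position: explicit call, block homozygous-reference,
        or ``None`` when no record covers the position."""
        rec = self.record_at(chrom, pos)
        if rec is None:
            return None
        if rec.is_reference_block:
            return Genotype((0, 0))
        return rec.genotype


def _convert_pysam_record(rec: "pysam.VariantRecord", ordinal: int) -> VariantRecord:
    raw_alts = tuple(rec.alts or ())
    keep = [i for i, a in enumerate(raw_alts) if a not in SYMBOLIC_ALTS]
    alts = tuple(raw_alts[i] for i in keep)
    # old 1-based allele index -> new, dropped symbolic alleles map to None
    remap = {0: 0}
    for new_i, old_i in enumerate(keep):
        remap[old_i + 1] = new_i + 1

    sample = rec.samples[0]
    raw_gt = sample.get("GT")
    alleles: Optional[tuple[int, int]] = None
    phased = False
    if raw_gt is not None and len(raw_gt) == 2:
        mapped = tuple(remap.get(a) if a is not None else None for a in raw_gt)
        if all(m is not None for m in mapped):
            alleles = mapped  # type: ignore[assignment]
            phased = sample.phased
    extras = tuple((k, v) for k, v in sample.items() if k != "GT")

    end = rec.pos if alts else rec.stop
    if end < rec.pos:
        raise VcfParseError(
            f"record {ordinal} at {rec.chrom}:{rec.pos}: END {end} < POS"
        )
    return VariantRecord(
        chrom=normalize_chrom(rec.chrom),
        pos=rec.pos,
        ref=rec.ref,
        alts=alts,
        genotype=Genotype(alleles, phased=phased),
        qual=rec.qual,
        end=end,
        id=rec.id,
        format_extras=extras,
    )


def _validate_end_fields(path: Path) -> None:
    """Reject records whose INFO END precedes POS.

    htslib silently drops such END fields with a warning, which would turn a
    corrupt reference block into a single-position one; scan the raw text so
    the error surfaces with its line number instead.
    """
    import gzip

    with open(path, "rb") as probe:
        magic = probe.read(2)
    opener = gzip.open if magic == b"\x1f\x8b" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or "END=" not in fields[7]:
                continue
            for item in fields[7].split(";"):
                if item.startswith("END="):
                    try:
                        end = int(item[4:])
                        pos = int(fields[1])
                    except ValueError:
                        raise VcfParseError(
                            f"{path}: line {lineno}: unparseable POS/END"
                        ) from None
                    if end < pos:
                        raise VcfParseError(
                            f"{path}: line {lineno}: END {end} is smaller "
                            f"than POS {pos}"
                        )


def read_gvcf(path: str | Path) -> GvcfIndex:
    """Read a single-sample gVCF (or plain VCF), plain text or bgzipped.

    Chromosome labels are normalized (leading ``chr`` stripped) and the
    original dialect is retained on the returned index for output.
    Reference blocks keep their inclusive ``END``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_end_fields(path)
    records: list[VariantRecord] = []
    dialect = DIALECT_PLAIN
    contigs: dict[str, Optional[int]] = {}
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise VcfInputError(
                f"{path}: expected a single-sample file, found {len(samples)} samples"
            )
        for name, contig in vf.header.contigs.items():
            if name.lower().startswith("chr"):
                dialect = DIALECT_CHR
            contigs[normalize_chrom(name)] = contig.length
        ordinal = 0
        try:
            for rec in vf:
                ordinal += 1
                if rec.chrom.lower().startswith("chr"):
                    dialect = DIALECT_CHR
                records.append(_convert_pysam_record(rec, ordinal))
        except VcfParseError:
            raise
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"{path}: malformed record (record {ordinal + 1} after header): {exc}"
            ) from exc
    logger.info("%s: read %d records (%s)", path.name, len(records), samples[0])
    return GvcfIndex(records, dialect=dialect, sample=samples[0], contigs=contigs)


def _sorted_checked(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    out = sorted(records, key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    seen: set[tuple[str, int, str, tuple[str, ...]]] = set()
    for rec in out:
        key = (rec.chrom, rec.pos, rec.ref, rec.alts)
        if key in seen:
            raise VcfOutputError(
                f"duplicate record {rec.chrom}:{rec.pos} {rec.ref}->{rec.alts}"
            )
        seen.add(key)
    return out


def _build_header(
    records: Sequence[VariantRecord],
    dialect: str,
    sample: str,
    contigs: Optional[Mapping[str, Optional[int]]],
    gvcf: bool,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if gvcf:
        header.add_line(
            '##INFO=<ID=END,Number=1,Type=Integer,'
            'Description="Stop position of the interval">'
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if not gvcf:
        header.add_line(
            '##phasing=trio; phased genotypes are ordered paternal|maternal'
        )
    names: dict[str, Optional[int]] = {}
    for rec in records:
        names.setdefault(rec.chrom, None)
    if contigs:
        for name, length in contigs.items():
            names[normalize_chrom(name)] = length
    for name in sorted(names, key=chrom_sort_key):
        length = names[name]
        label = apply_dialect(name, dialect)
        if length:
            header.add_line(f"##contig=<ID={label},length={length}>")
        else:
            header.add_line(f"##contig=<ID={label}>")
    header.add_sample(sample)
    return header


def _emit(
    vf: pysam.VariantFile,
    rec: VariantRecord,
    dialect: str,
    gvcf: bool,
) -> None:
    alleles: tuple[str, ...] = (rec.ref,) + rec.alts
    if gvcf:
        alleles = alleles + ("<NON_REF>",)
    if len(alleles) < 2:
        raise VcfOutputError(
            f"{rec.chrom}:{rec.pos}: cannot write a record without ALT alleles "
            "to a plain VCF"
        )
    stop = rec.end if (gvcf and rec.is_reference_block) else rec.pos
    out = vf.new_record(
        contig=apply_dialect(rec.chrom, dialect),
        start=rec.pos - 1,
        stop=stop,  # INFO END (inclusive, 1-based) for reference blocks
        alleles=alleles,
        qual=rec.qual,
        id=rec.id,
    )
    gt = rec.genotype
    out.samples[0]["GT"] = gt.alleles if gt.alleles is not None else (None, None)
    out.samples[0].phased = gt.phased
    vf.write(out)


def write_phased_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    dialect: str = DIALECT_PLAIN,
    sample: str = "SAMPLE",
    contigs: Optional[Mapping[str, Optional[int]]] = None,
) -> Path:
    """Write a plain VCF 4.2 of (possibly) phased genotypes.

    Phased genotypes are written with ``|`` in paternal|maternal order (the
    header documents the convention); records are sorted by (chrom, pos) and
    chromosome labels restored to the requested dialect.  Duplicate
    (chrom, pos, ref, alts) records are an error.
    """
    path = Path(path)
    out = _sorted_checked(records)
    header = _build_header(out, dialect, sample, contigs, gvcf=False)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in out:
            _emit(vf, rec, dialect, gvcf=False)
    return path


def write_gvcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    dialect: str = DIALECT_PLAIN,
    sample: str = "SAMPLE",
    contigs: Optional[Mapping[str, Optional[int]]] = None,
) -> Path:
    """Write a single-sample gVCF: variant records plus reference blocks.

    Every record carries a trailing symbolic ``<NON_REF>`` allele and
    reference blocks carry INFO ``END``, matching what standard gVCF
    callers emit (and what :func:`read_gvcf` strips back off).
    """
    path = Path(path)
    out = _sorted_checked(records)
    header = _build_header(out, dialect, sample, contigs, gvcf=True)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in out:
            _emit(vf, rec, dialect, gvcf=True)
    return path
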