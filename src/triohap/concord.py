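"""Concordance between two phased VCFs of the same sample.

Two phased call sets are compared on *congruent* sites — same chromosome,
position, reference allele and alternate-allele set — and, among those, the
fraction phased identically.  Because the haplotype labeling of a phased VCF
is a convention (paternal-first here, arbitrary elsewhere), agreement is
reported both in the raw orientation and under the whole-comparison
haplotype swap that maximizes agreement; the two coincide when both files
anchor haplotypes the same way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import vcf_io
from .trio_core import Genotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceReport:
    """Comparison summary.

    ``congruent`` counts comparable sites (matching site keys, both phased,
    both heterozygous when ``het_only``); ``identical_raw`` matches ordered
    genotypes as written; ``identical`` takes the better of raw and
    whole-set-swapped orientation; ``excluded_unphased`` counts congruent
    site keys dropped because a genotype was unphased.
    """

    congruent: int
    identical_raw: int
    identical: int
    orientation: str  # "same" | "swapped"
    excluded_unphased: int
    excluded_not_het: int

    @property
    def fraction_raw(self) -> float:
        return self.identical_raw / self.congruent if self.congruent else 0.0

    @property
    def fraction(self) -> float:
        return self.identical / self.congruent if self.congruent else 0.0

    def as_dict(self) -> dict:
        return {
            "congruent": self.congruent,
            "identical_raw": self.identical_raw,
            "identical": self.identical,
            "fraction_raw": self.fraction_raw,
            "fraction": self.fraction,
            "orientation": self.orientation,
            "excluded_unphased": self.excluded_unphased,
            "excluded_not_het": self.excluded_not_het,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n")
        return path


def _site_map(path: str | Path) -> dict[tuple, Genotype]:
    out: dict[tuple, Genotype] = {}
    for rec in vcf_io.read_gvcf(path):
        if rec.is_reference_block or rec.genotype.is_missing:
            continue
        out[(rec.chrom, rec.pos, rec.ref, frozenset(rec.alts))] = rec.genotype
    return out


def compare_phased(
    a: str | Path, b: str | Path, het_only: bool = False
) -> ConcordanceReport:
    """Compare two phased VCFs of one sample.

    Symmetric in its arguments.  With ``het_only`` only sites heterozygous
    in both call sets are compared (the convention when one of the inputs,
    like a read-backed phaser, reports heterozygous positions only).
    """
    map_a = _site_map(a)
    map_b = _site_map(b)
    keys = set(map_a) & set(map_b)

    congruent = 0
    same = 0
    swapped = 0
    excluded_unphased = 0
    excluded_not_het = 0
    for key in keys:
        ga, gb = map_a[key], map_b[key]
        if not (ga.phased and gb.phased):
            excluded_unphased += 1
            continue
        if het_only and not (ga.is_het and gb.is_het):
            excluded_not_het += 1
            continue
        congruent += 1
        if ga.alleles == gb.alleles:
            same += 1
        if ga.alleles == gb.alleles[::-1]:  # type: ignore[index]
            swapped += 1
    identical = max(same, swapped)
    report = ConcordanceReport(
        congruent=congruent,
        identical_raw=same,
        identical=identical,
        orientation="same" if same >= swapped else "swapped",
        excluded_unphased=excluded_unphased,
        excluded_not_het=excluded_not_het,
    )
    logger.info(
        "concordance: %d congruent, %d identical (%.4f, orientation %s)",
        report.congruent,
        report.identical,
        report.fraction,
        report.orientation,
    )
    return report
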