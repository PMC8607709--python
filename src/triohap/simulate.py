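"""Synthetic trio generator: gVCF triples with a known transmission truth.

The generator emulates the statistical structure the Mendelian engine
assumes: at each variant site an alternate-allele frequency ``p`` is drawn
from a configurable model (uniform on (0,1) by default), parental genotypes
are drawn under Hardy-Weinberg equilibrium at that frequency, and the child
receives one uniformly chosen allele from each parent.  On top of that clean
signal two kinds of noise can be injected:

* **genotype errors** — an *observed* genotype (never the truth) has one
  allele swapped for a uniformly chosen other allele of the site;
* **de novo events** — the site is made monomorphic in the parents
  (homozygous reference) and one of the child's alleles is replaced by a
  base absent from the site's allele list, the way a fresh germline mutation
  appears against an invariant background.

Sites are independent: there is no linkage disequilibrium or haplotype-block
structure, which is adequate because the statistical phaser the pipeline is
tested against is a deterministic mock, not an LD model.

The truth table records, per site, the parental haplotypes, the transmitted
(paternal, maternal) allele pair and every injected perturbation, as allele
*base strings* so it stays valid in any downstream allele indexing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import vcf_io
from .trio_core import Genotype, TrioSite
from .vcf_io import VariantRecord

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: alt-frequency model signature: (rng, size) -> array of frequencies in (0,1)
FreqModel = Callable[[np.random.Generator, int], np.ndarray]


def uniform_freq(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=size)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated trio.

    Defaults describe a clean trio: uniform allele-frequency spectrum, a
    small multi-allelic fraction (roughly what joint genotyping reports
    genome-wide), no genotyping error, no de novo events, reference blocks
    filling the space between variants.
    """

    n_sites: int = 10_000
    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000}
    )
    alt_freq_model: Optional[FreqModel] = None  # None -> Uniform(0,1)
    multiallelic_fraction: float = 0.02
    genotype_error_rate: float = 0.0
    denovo_rate: float = 0.0
    block_fill: bool = True
    qual_range: tuple[float, float] = (50.0, 99.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise SimConfigError("n_sites must be >= 0")
        for name in ("multiallelic_fraction", "genotype_error_rate", "denovo_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1], got {v}")
        if not self.chromosomes:
            raise SimConfigError("at least one chromosome is required")
        if sum(self.chromosomes.values()) < self.n_sites:
            raise SimConfigError("chromosome lengths cannot hold n_sites positions")
        if self.qual_range[0] > self.qual_range[1]:
            raise SimConfigError("qual_range must be (low, high)")


@dataclass(frozen=True)
class SimSite:
    """One simulated site: truth and observed genotypes in site allele space
    (indices into ``(ref,) + alts``)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    father_true: tuple[int, int]
    mother_true: tuple[int, int]
    transmitted: tuple[int, int]  # (paternal, maternal)
    child_obs: tuple[int, int]
    father_obs: tuple[int, int]
    mother_obs: tuple[int, int]
    denovo: bool
    child_error: bool
    father_error: bool
    mother_error: bool
    qual: float

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


def _allocate_sites(n: int, chromosomes: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of sites across chromosome lengths."""
    total = sum(chromosomes.values())
    exact = {c: n * length / total for c, length in chromosomes.items()}
    counts = {c: math.floor(v) for c, v in exact.items()}
    short = n - sum(counts.values())
    for c in sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _distinct_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    out = np.unique(rng.integers(1, length + 1, size=n + n // 4 + 16))
    while out.size < n:
        out = np.unique(
            np.concatenate([out, rng.integers(1, length + 1, size=n)])
        )
    if out.size > n:
        keep = rng.choice(out.size, size=n, replace=False)
        out = np.sort(out[keep])
    return out


def _draw_allele(u: float, cum: Sequence[float]) -> int:
    for i, edge in enumerate(cum):
        if u < edge:
            return i
    return len(cum)


def simulate_sites(config: SimConfig) -> list[SimSite]:
    """Generate the in-memory site list (no file IO)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    counts = _allocate_sites(n, config.chromosomes)
    chrom_pos: list[tuple[str, int]] = []
    for chrom in config.chromosomes:
        for pos in _distinct_positions(rng, counts[chrom], config.chromosomes[chrom]):
            chrom_pos.append((chrom, int(pos)))

    freq_model = config.alt_freq_model or uniform_freq
    p = freq_model(rng, n)
    if n and (np.min(p) < 0 or np.max(p) > 1):
        raise SimConfigError("alt_freq_model produced frequencies outside [0, 1]")
    is_multi = rng.random(n) < config.multiallelic_fraction
    is_denovo = rng.random(n) < config.denovo_rate
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    alt2_pick = rng.integers(0, 2, size=n)
    novel_pick = rng.integers(0, 3, size=n)
    split = rng.random(n)
    hap_u = rng.random((4, n))  # father hap1/hap2, mother hap1/hap2
    transmit = rng.integers(0, 2, size=(2, n))
    denovo_slot = rng.integers(0, 2, size=n)
    err_u = rng.random((3, n))  # child, father, mother
    err_slot = rng.integers(0, 2, size=(3, n))
    err_repl = rng.random((3, n))
    quals = np.round(rng.uniform(*config.qual_range, size=n), 2)

    sites: list[SimSite] = []
    for i, (chrom, pos) in enumerate(chrom_pos):
        ref = BASES[ref_idx[i]]
        if is_denovo[i]:
            others = [b for b in BASES if b != ref]
            alts = (others[novel_pick[i]],)
            father_true = mother_true = (0, 0)
            transmitted = (0, 0)
            child = [0, 0]
            child[denovo_slot[i]] = 1
            child_obs = tuple(child)
        else:
            offsets = [1, 2, 3]
            offsets.remove(int(alt_off[i]))
            alt1 = BASES[(ref_idx[i] + alt_off[i]) % 4]
            if is_multi[i]:
                alt2 = BASES[(ref_idx[i] + offsets[alt2_pick[i]]) % 4]
                alts = (alt1, alt2)
                p1 = p[i] * split[i]
                cum = (1.0 - p[i], 1.0 - p[i] + p1)
            else:
                alts = (alt1,)
                cum = (1.0 - p[i],)
            father_true = (
                _draw_allele(hap_u[0, i], cum),
                _draw_allele(hap_u[1, i], cum),
            )
            mother_true = (
                _draw_allele(hap_u[2, i], cum),
                _draw_allele(hap_u[3, i], cum),
            )
            transmitted = (
                father_true[transmit[0, i]],
                mother_true[transmit[1, i]],
            )
            child_obs = transmitted

        n_alleles = 1 + len(alts)
        observed = [list(child_obs), list(father_true), list(mother_true)]
        errored = [False, False, False]
        if config.genotype_error_rate > 0:
            for m in range(3):
                if err_u[m, i] < config.genotype_error_rate and n_alleles > 1:
                    slot = err_slot[m, i]
                    cur = observed[m][slot]
                    j = int(err_repl[m, i] * (n_alleles - 1))
                    if j >= cur:
                        j += 1
                    observed[m][slot] = j
                    errored[m] = True

        sites.append(
            SimSite(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                father_true=father_true,
                mother_true=mother_true,
                transmitted=transmitted,
                child_obs=tuple(observed[0]),
                father_obs=tuple(observed[1]),
                mother_obs=tuple(observed[2]),
                denovo=bool(is_denovo[i]),
                child_error=errored[0],
                father_error=errored[1],
                mother_error=errored[2],
                qual=float(quals[i]),
            )
        )
    return sites


def trio_sites(sites: Sequence[SimSite]) -> list[TrioSite]:
    """Observed genotypes of every simulated site as TrioSite rows, in the
    site's own allele space (the shortcut used when file IO is not under
    test; includes child homozygous-reference sites, which a real trio
    table would not contain)."""
    out = []
    for s in sites:
        out.append(
            TrioSite(
                chrom=s.chrom,
                pos=s.pos,
                ref=s.ref,
                alts=s.alts,
                child_gt=Genotype(tuple(sorted(s.child_obs))),
                father_gt=Genotype(tuple(sorted(s.father_obs))),
                mother_gt=Genotype(tuple(sorted(s.mother_obs))),
                qual=s.qual,
            )
        )
    return out


def truth_frame(sites: Sequence[SimSite]) -> pd.DataFrame:
    """Truth table with alleles spelled as base strings."""
    rows = []
    for s in sites:
        al = s.alleles

        def gt(pair: tuple[int, int]) -> str:
            return "/".join(al[a] for a in pair)

        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alts": ",".join(s.alts),
                "father_hap1": al[s.father_true[0]],
                "father_hap2": al[s.father_true[1]],
                "mother_hap1": al[s.mother_true[0]],
                "mother_hap2": al[s.mother_true[1]],
                "transmitted_paternal": al[s.transmitted[0]],
                "transmitted_maternal": al[s.transmitted[1]],
                "child_obs": gt(s.child_obs),
                "father_obs": gt(s.father_obs),
                "mother_obs": gt(s.mother_obs),
                "denovo": int(s.denovo),
                "child_error": int(s.child_error),
                "father_error": int(s.father_error),
                "mother_error": int(s.mother_error),
            }
        )
    columns = [
        "chrom", "pos", "ref", "alts", "father_hap1", "father_hap2",
        "mother_hap1", "mother_hap2", "transmitted_paternal",
        "transmitted_maternal", "child_obs", "father_obs", "mother_obs",
        "denovo", "child_error", "father_error", "mother_error",
    ]
    return pd.DataFrame(rows, columns=columns)


def member_records(
    sites: Sequence[SimSite],
    member: str,
    chromosomes: Mapping[str, int],
    block_fill: bool = True,
) -> list[VariantRecord]:
    """gVCF records of one trio member.

    A member's variant record lists only the alternate alleles its own
    observed genotype carries (plus the symbolic ``<NON_REF>`` the writer
    appends), the way per-sample gVCFs come out of a caller.  Homozygous-
    reference sites are covered by the surrounding reference blocks when
    ``block_fill`` is on, otherwise emitted as explicit invariant records.
    """
    obs_attr = {"child": "child_obs", "father": "father_obs", "mother": "mother_obs"}[
        member
    ]
    by_chrom: dict[str, list[SimSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    records: list[VariantRecord] = []
    for chrom, length in chromosomes.items():
        variant_positions: list[int] = []
        for s in sorted(by_chrom.get(chrom, []), key=lambda s: s.pos):
            obs: tuple[int, int] = getattr(s, obs_attr)
            if max(obs) == 0:
                if not block_fill:
                    records.append(
                        VariantRecord(
                            chrom=chrom,
                            pos=s.pos,
                            ref=s.ref,
                            alts=(),
                            genotype=Genotype((0, 0)),
                            end=s.pos,
                        )
                    )
                    variant_positions.append(s.pos)
                continue
            own = sorted({a for a in obs if a > 0})
            remap = {0: 0, **{site_idx: k + 1 for k, site_idx in enumerate(own)}}
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=s.pos,
                    ref=s.ref,
                    alts=tuple(s.alleles[a] for a in own),
                    genotype=Genotype(tuple(sorted(remap[a] for a in obs))),
                    qual=s.qual,
                )
            )
            variant_positions.append(s.pos)
        if block_fill:
            prev = 0
            for pos in variant_positions + [length + 1]:
                if pos - 1 >= prev + 1:
                    records.append(
                        VariantRecord(
                            chrom=chrom,
                            pos=prev + 1,
                            ref="N",
                            alts=(),
                            genotype=Genotype((0, 0)),
                            end=pos - 1,
                        )
                    )
                prev = pos
    return records


@dataclass(frozen=True)
class SimulatedTrio:
    """File paths and in-memory truth of one simulated trio."""

    child: Path
    father: Path
    mother: Path
    truth_path: Path
    truth: pd.DataFrame
    sites: tuple[SimSite, ...]
    config: SimConfig


def simulate_trio(config: SimConfig, out_dir: str | Path) -> SimulatedTrio:
    """Simulate a trio and write child/father/mother gVCFs plus a truth TSV.

    Output is byte-identical for a fixed config (including seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sites = simulate_sites(config)
    paths = {}
    for member in ("child", "father", "mother"):
        recs = member_records(sites, member, config.chromosomes, config.block_fill)
        paths[member] = vcf_io.write_gvcf(
            recs,
            out_dir / f"{member}.g.vcf",
            sample=member,
            contigs=config.chromosomes,
        )
    truth = truth_frame(sites)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    logger.info(
        "simulated trio: %d sites on %d chromosome(s) -> %s",
        len(sites),
        len(config.chromosomes),
        out_dir,
    )
    return SimulatedTrio(
        child=paths["child"],
        father=paths["father"],
        mother=paths["mother"],
        truth_path=truth_path,
        truth=truth,
        sites=tuple(sites),
        config=config,
    )
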