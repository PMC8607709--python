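# Methods

## Transmission model

A trio site carries an allele list `(REF, ALT1, …)` taken from the child's
record; parental genotypes are expressed in that index space. The child
inherits exactly one allele from each parent, so the candidate orderings of a
child genotype `{a, b}` are `(a, b)` and `(b, a)` (coinciding when the child
is homozygous). An ordering `(p, m)` is a *consistent transmission* when `p`
is an element of the father's genotype and `m` of the mother's; a missing
parental genotype imposes no constraint on its side. Classification is by
the number of consistent transmissions:

| transmissions | status | action |
|---|---|---|
| 1 | `MENDELIAN_PHASED` | written to the scaffold as paternal\|maternal |
| 2 | `UNPHASEABLE` | left to the statistical phaser |
| 0 | `INCONSISTENT` | left to the statistical phaser; flagged |

`novel_allele` is set when both parents are genotyped and some child allele
occurs in neither — the de novo candidate condition. It implies
`INCONSISTENT` (an allele no parent carries admits no transmission), and it
is deliberately never raised when a parent is missing: absence of evidence
is not Mendelian conflict. By the same principle, dropping a parent can only
weaken constraints — it never creates an inconsistency that full data would
not show.

Homozygous child sites with a consistent transmission are Mendelian-phased
(their order is trivially determined) and are *included* in the scaffold:
they anchor the statistical phaser at no cost. Homozygous sites conflicting
with both parents (child `G/G`, parents `A/A` × `A/A`) are classified
inconsistent with `novel_allele`, not silently phased `G|G` — conservative,
so the user sees the flag.

## Trio site table

Joint genotyping of the three gVCFs is replaced by a deterministic
position-wise lookup: one table row per child variant record (called
genotype containing a non-reference allele) on autosomes 1–22 with site
QUAL ≥ `min_qual` (default 30, the conventional confident-call threshold;
missing QUAL counts as 0). The filter applies to the child only — a parental
genotype is evidence about transmission, not a call being published — and
no likelihoods are recomputed. The parental genotype at each child position
is resolved through the parent's own gVCF: an explicit record, homozygous
reference inside a `[POS, END]` reference block, or missing in a coverage
gap.

Parental allele indices are remapped onto the child's allele list after a
minimal normalization (shared suffix then prefix trimming of each REF/ALT
pair), which reconciles padding-base differences in indel representation.
Parent alleles absent from the child's list get negative "foreign" indices —
they participate in the logic only by never matching. A parent REF that
cannot be reconciled with the child REF at the same position makes that
parental genotype missing and is counted, never silently matched.
Multi-allelic child records are kept whole (transmission logic handles any
allele count); half-calls are normalized to missing.

## Statistical phaser adapter and merge

The statistical phaser is behind an adapter contract: it may *order*
genotypes but not change them — output sites must be a subset of its input
sites with allele content intact — and it must honor the scaffold
orientation. The production adapter shells out to SHAPEIT4 with the scaffold
as pre-phased input and a reference panel directory. The bundled mock
adapter implements the same contract deterministically: every biallelic site
it receives is phased (scaffold sites in scaffold orientation, other
heterozygotes by a CRC32-derived bit of `(seed, chrom, pos)` so the result
is independent of process and execution order), and multi-allelic sites are
dropped, emulating the biallelic/panel restriction of the real tool. The
mock has no linkage model, so the *orientation* of non-scaffold sites is
meaningless; only the set arithmetic and plumbing are exercised.

The merge takes, per table site: the statistical phase where present
(discordance with the scaffold is counted as a warning and the statistical
phase kept, since conforming adapters cannot produce it); otherwise the
scaffold phase (these are the "Mendelian-exclusive" sites — multi-allelic or
off-panel); otherwise the site is emitted unphased. The three phased classes
partition the phased set, so `jointly + mendelian_exclusive +
statistical_exclusive = total_phased` holds by construction and is asserted
in tests. Chromosomes are independent work units (`--cores`, default 2);
results are assembled in chromosome order, so parallelism never changes an
output byte.

The de novo report is built *after* the merge: exactly the phased final
records whose site was flagged `novel_allele`. Mendelian logic cannot phase
such a site, so any phase it carries came from the statistical phaser; the
same records remain in the main output, the side file being informative.

## Synthetic trio generator

Per site: alternate-allele frequency `p` drawn from the configured model
(Uniform(0,1) by default — a flat spectrum that exercises the whole
frequency range rather than mimicking a site-frequency spectrum), parental
genotypes drawn independently under Hardy–Weinberg(p), the child receiving
one uniformly chosen allele from each parent. A configurable fraction of
sites (default 2%, roughly the genome-wide multi-allelic share in joint
call sets) gets a second alternate allele, with `p` split randomly between
the two. Site QUAL is uniform on 50–99, so the default quality filter is
neutral unless a test raises it deliberately.

Noise is injected only into *observed* genotypes; the truth table keeps the
generating haplotypes and the transmitted (paternal, maternal) pair as base
strings. A genotype error (probability `genotype_error_rate` per member per
site) swaps one allele for a uniformly chosen other allele of the site — the
simplest perturbation that produces both unphaseable and inconsistent
downstream cases. A de novo event (probability `denovo_rate` per site) makes
the site monomorphic in the parents (both homozygous reference) and gives
the child one novel allele absent from the site's allele list — the way a
fresh germline mutation appears against an invariant background, and making
every candidate site biallelic `REF/novel` in the child's record.

Each member's gVCF lists only the alternate alleles that member's observed
genotype carries (plus a symbolic `<NON_REF>`, as real callers emit), and
reference blocks fill all positions between a member's variant records, so
homozygous-reference parents are resolved through block queries exactly as
in real data. With `block_fill` off, explicit single-position invariant
records are written instead and coverage gaps appear between sites.

What the generator does **not** model: linkage disequilibrium or haplotype
blocks (unneeded — the statistical phaser under test is the mock),
read-level artifacts, indel alleles, sex chromosomes, population structure,
or a realistic site-frequency spectrum. Passing tests therefore demonstrate
the correctness of the transmission logic, the gVCF plumbing and the merge
accounting — not statistical phasing accuracy on real genomes.

Under the uniform frequency model the expected phaseable share of child
heterozygous sites has closed form: hets arise at rate `E[2pq] = 1/3`,
triple-het (unphaseable) configurations at `E[2pq · 2pq · ½] = E[2p²q²] =
1/15`, giving `1 − (1/15)/(1/3) = 4/5`. The simulation-based acceptance
check reproduces ~80% at n = 100,000 sites, inside the 67–83% range reported
for real trios.

## Numerical and format choices

- Coordinates 1-based inclusive throughout; `END` inclusive. Records with
  real ALT alleles always have `end == pos` (indel spans are not modelled).
- Chromosome labels are normalized internally (leading `chr` stripped);
  the input dialect is remembered per file and restored on output; the
  three inputs may mix dialects.
- Only GT, site QUAL and INFO `END` are modelled; other per-sample fields
  pass through opaquely on read. Symbolic ALTs (`<NON_REF>`, `<*>`) are
  dropped after block processing; a GT pointing at a dropped symbolic
  allele becomes missing.
- htslib silently discards an `END` smaller than `POS`; the reader re-scans
  the raw text for this case and fails with the line number instead of
  truncating a corrupt block.
- Duplicate child positions are dropped (first record kept) and counted.
- The per-site ledger is emitted as TSV next to the output VCF so the
  phased/unphaseable/inconsistent accounting is reproducible by users.
- `--build` (GRCh38 default, GRCh37 supported) selects coordinate labeling
  and panel pass-through only; no liftover is performed.

## Problem sizes

Unit tests run on simulated trios of 100–5,000 sites; the acceptance-style
checks use 10,000 sites through full gVCF round trips and 100,000 sites
in memory for the phaseable-fraction estimate — sizes at which every
distributional statement tested has comfortably small Monte Carlo error.

## Known limitations

- The real SHAPEIT4 adapter is an untested integration path (it requires
  the external binary and panel files); the mock adapter is the supported
  test surface.
- Indel handling is limited to padding-base normalization; full
  left-alignment against a reference sequence is out of scope.
- Genotype-likelihood information (GQ/PL) is not consulted; classification
  is purely on called genotypes, so systematically erroneous confident
  calls surface as inconsistencies rather than being re-genotyped.
- Sites where both parents are uncovered reduce to child-only information:
  heterozygous ones become unphaseable, and de novo events there are
  undetectable.
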