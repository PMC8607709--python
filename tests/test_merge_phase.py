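"""Mock phaser contract, adapter validation, and the final merge arithmetic."""

import pytest

from conftest import make_site
from triohap.mendel import Scaffold, ScaffoldEntry, build_scaffold
from triohap.merge_phase import (
    AdapterContractError,
    MockPanelPhaser,
    PhasedSite,
    PhaserAdapter,
    check_scaffold_conformance,
    get_adapter,
    merge_outputs,
    run_statistical_phaser,
    validate_adapter_output,
)
from triohap.trio_core import build_trio_table
from triohap.vcf_io import read_gvcf


def _scaffold_of(entries):
    scaffold = Scaffold()
    for site, p, m in entries:
        scaffold.add(ScaffoldEntry(site, p, m))
    return scaffold


class TestMockPhaser:
    def test_panel_restriction_and_scaffold_orientation(self):
        # 10 sites: 8 biallelic (5 in the scaffold), 2 multi-allelic
        biallelic = [
            make_site((0, 1), (0, 1), (0, 0), pos=10 * (i + 1), alts=("G",))
            for i in range(8)
        ]
        multi = [
            make_site((1, 2), (0, 1), (0, 2), pos=1000 + i, alts=("G", "T"))
            for i in range(2)
        ]
        sites = biallelic + multi
        scaffold = _scaffold_of([(s, 1, 0) for s in biallelic[:5]])
        out = MockPanelPhaser().phase_chromosome(
            "1", sites, scaffold.by_pos("1"), None, seed=0
        )
        assert len(out) == 8
        by_pos = {ps.pos: ps for ps in out}
        assert all(s.pos not in by_pos for s in multi)
        scaffold_matches = [
            ps for ps in out
            if ps.pos in scaffold.by_pos("1")
            and (ps.paternal, ps.maternal) == (1, 0)
        ]
        assert len(scaffold_matches) == 5

    def test_empty_chromosome(self):
        assert MockPanelPhaser().phase_chromosome("1", [], {}, None, 0) == []

    def test_orientation_is_seed_deterministic(self):
        sites = [make_site((0, 1), None, None, pos=p, alts=("G",)) for p in range(10, 200, 10)]
        mock = MockPanelPhaser()
        a = mock.phase_chromosome("1", sites, {}, None, seed=5)
        b = mock.phase_chromosome("1", sites, {}, None, seed=5)
        c = mock.phase_chromosome("1", sites, {}, None, seed=6)
        assert a == b
        assert a != c  # 19 coin flips: different seed realizes differently

    def test_unknown_adapter_name(self):
        with pytest.raises(ValueError, match="unknown phaser"):
            get_adapter("imaginary")


class TestAdapterContract:
    def test_extra_site_rejected(self):
        sites = [make_site((0, 1), (0, 1), (0, 0), pos=10, alts=("G",))]
        with pytest.raises(AdapterContractError, match="not given"):
            validate_adapter_output(sites, [PhasedSite("1", 99, 0, 1)])

    def test_allele_content_change_rejected(self):
        sites = [make_site((0, 1), (0, 1), (0, 0), pos=10, alts=("G",))]
        with pytest.raises(AdapterContractError, match="allele content"):
            validate_adapter_output(sites, [PhasedSite("1", 10, 1, 1)])

    def test_scaffold_flip_fails_conformance(self):
        site = make_site((0, 1), (0, 1), (0, 0), pos=10, alts=("G",))
        scaffold = _scaffold_of([(site, 1, 0)])

        class FlippingPhaser(PhaserAdapter):
            name = "flipper"

            def phase_chromosome(self, chrom, sites, scaffold, panel_dir, seed):
                return [PhasedSite(chrom, s.pos, 0, 1) for s in sites]

        out = FlippingPhaser().phase_chromosome("1", [site], scaffold.by_pos("1"), None, 0)
        assert check_scaffold_conformance(scaffold.by_pos("1"), out) == [10]
        assert check_scaffold_conformance(
            scaffold.by_pos("1"),
            MockPanelPhaser().phase_chromosome("1", [site], scaffold.by_pos("1"), None, 0),
        ) == []


class TestMergeOutputs:
    def _fixture(self, n=100, n_scaffold=70, n_stat_scaffold=60, n_stat_only=20):
        table = [
            make_site((0, 1), (0, 1), (0, 1), pos=i + 1, alts=("G",))
            for i in range(n)
        ]
        scaffold = _scaffold_of([(s, 1, 0) for s in table[:n_scaffold]])
        statistical = {
            "1": [PhasedSite("1", s.pos, 1, 0) for s in table[:n_stat_scaffold]]
            + [
                PhasedSite("1", s.pos, 0, 1)
                for s in table[n_scaffold : n_scaffold + n_stat_only]
            ]
        }
        return table, scaffold, statistical

    def test_set_arithmetic(self):
        table, scaffold, statistical = self._fixture()
        merged, stats = merge_outputs(statistical, scaffold, table)
        assert stats.total_genotyped == 100
        assert stats.total_phased == 90
        assert stats.mendelian_exclusive == 10
        assert stats.statistical_exclusive == 20
        assert stats.jointly_phased == 60
        assert stats.total_phased == (
            stats.jointly_phased
            + stats.mendelian_exclusive
            + stats.statistical_exclusive
        )
        assert stats.unphased == 10
        assert sum(m.phased for m in merged) == stats.total_phased

    def test_statistical_output_empty_falls_back_to_scaffold(self):
        table, scaffold, _ = self._fixture()
        merged, stats = merge_outputs({}, scaffold, table)
        assert stats.total_phased == stats.mendelian_exclusive == 70
        phased = {m.site.pos for m in merged if m.phased}
        assert phased == {s.pos for s in table[:70]}

    def test_empty_scaffold_passes_statistical_through(self):
        table, _, statistical = self._fixture()
        merged, stats = merge_outputs(statistical, Scaffold(), table)
        assert stats.total_phased == stats.statistical_exclusive == 80
        assert stats.mendelian_exclusive == 0

    def test_discordant_orientation_counted_statistical_wins(self):
        site = make_site((0, 1), (0, 1), (0, 0), pos=10, alts=("G",))
        scaffold = _scaffold_of([(site, 1, 0)])
        merged, stats = merge_outputs({"1": [PhasedSite("1", 10, 0, 1)]}, scaffold, [site])
        assert stats.scaffold_discordant == 1
        assert merged[0].gt == (0, 1)

    def test_no_genotype_mutation(self):
        table, scaffold, statistical = self._fixture()
        merged, _ = merge_outputs(statistical, scaffold, table)
        for m in merged:
            assert sorted(m.gt) == sorted(m.site.child_gt.alleles)


class TestConcurrencyNeutrality:
    def test_core_count_never_changes_output(self, clean_trio):
        child = read_gvcf(clean_trio.child)
        father = read_gvcf(clean_trio.father)
        mother = read_gvcf(clean_trio.mother)
        table, _ = build_trio_table(child, father, mother)
        scaffold, _ = build_scaffold(table)
        adapter = get_adapter("mock")
        runs = [
            run_statistical_phaser(adapter, table, scaffold, seed=1, cores=cores)
            for cores in (1, 2, 4)
        ]
        assert runs[0] == runs[1] == runs[2]
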