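"""Mendelian transmission engine: enumeration, classification, scaffold."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_site
from mendel_oracle import brute_force_phase
from triohap.mendel import build_scaffold, enumerate_transmissions, phase_site
from triohap.trio_core import PhaseStatus

# allele letters at the canonical test site: 0=A(ref), 1=G, 2=T


class TestEnumerateTransmissions:
    @pytest.mark.parametrize(
        "child, father, mother, expected",
        [
            # het child, het father, hom-ref mother: unique, alt is paternal
            ((0, 1), (0, 1), (0, 0), {(1, 0)}),
            # triple heterozygous: both orders survive
            ((0, 1), (0, 1), (0, 1), {(0, 1), (1, 0)}),
            # multi-allelic G/T child resolved uniquely by A/G + A/T parents
            ((1, 2), (0, 1), (0, 2), {(1, 2)}),
            # father homozygous for an allele the child lacks: impossible
            ((0, 1), (2, 2), (0, 0), set()),
            # missing father constrains nothing; hom mother still decides
            ((0, 1), None, (0, 0), {(1, 0)}),
            ((0, 1), None, None, {(0, 1), (1, 0)}),
        ],
    )
    def test_against_hand_worked_cases(self, child, father, mother, expected):
        site = make_site(child, father, mother)
        assert set(enumerate_transmissions(site)) == expected

    def test_missing_child_is_an_error(self):
        with pytest.raises(ValueError):
            enumerate_transmissions(make_site(None, (0, 0), (0, 0)))


class TestPhaseSite:
    @pytest.mark.parametrize(
        "child, father, mother, status, phase, novel",
        [
            ((0, 1), (0, 1), (0, 0), PhaseStatus.MENDELIAN_PHASED, (1, 0), False),
            ((0, 1), (0, 1), (0, 1), PhaseStatus.UNPHASEABLE, None, False),
            ((1, 1), (0, 1), (1, 1), PhaseStatus.MENDELIAN_PHASED, (1, 1), False),
            # child allele in neither parent: de novo candidate
            ((0, 1), (0, 0), (0, 0), PhaseStatus.INCONSISTENT, None, True),
            # allele present in mother only, but father cannot transmit it
            ((1, 1), (0, 0), (0, 1), PhaseStatus.INCONSISTENT, None, False),
            # homozygous conflict with both parents: inconsistent, novel
            ((1, 1), (0, 0), (0, 0), PhaseStatus.INCONSISTENT, None, True),
            # missing parent never creates inconsistency
            ((0, 1), None, (0, 0), PhaseStatus.MENDELIAN_PHASED, (1, 0), False),
            ((1, 1), None, (0, 1), PhaseStatus.MENDELIAN_PHASED, (1, 1), False),
        ],
    )
    def test_classification(self, child, father, mother, status, phase, novel):
        call = phase_site(make_site(child, father, mother))
        assert call.status is status
        assert call.novel_allele is novel
        if phase is not None:
            assert (call.paternal, call.maternal) == phase

    def test_exhaustive_three_allele_oracle(self):
        genotypes = [(a, b) for a in range(3) for b in range(a, 3)]
        parent_options = genotypes + [None]
        checked = 0
        for child in genotypes:
            for father in parent_options:
                for mother in parent_options:
                    call = phase_site(make_site(child, father, mother))
                    status, phase, novel = brute_force_phase(child, father, mother)
                    assert call.status.value.replace("mendelian_", "") == status, (
                        child, father, mother,
                    )
                    if status == "phased":
                        assert (call.paternal, call.maternal) == phase
                    assert call.novel_allele == novel
                    checked += 1
        assert checked == 6 * 7 * 7


GT = st.tuples(st.integers(0, 3), st.integers(0, 3))
OPT_GT = st.one_of(st.none(), GT)


class TestProperties:
    @settings(max_examples=500, derandomize=True)
    @given(child=GT, father=OPT_GT, mother=OPT_GT)
    def test_parent_swap_antisymmetry(self, child, father, mother):
        call = phase_site(make_site(child, father, mother))
        swapped = phase_site(make_site(child, mother, father))
        assert call.status is swapped.status
        assert call.novel_allele == swapped.novel_allele
        if call.status is PhaseStatus.MENDELIAN_PHASED:
            assert (swapped.paternal, swapped.maternal) == (call.maternal, call.paternal)

    @settings(max_examples=500, derandomize=True)
    @given(child=GT, father=OPT_GT, mother=OPT_GT)
    def test_allele_conservation(self, child, father, mother):
        call = phase_site(make_site(child, father, mother))
        if call.status is PhaseStatus.MENDELIAN_PHASED:
            assert sorted((call.paternal, call.maternal)) == sorted(child)

    @settings(max_examples=500, derandomize=True)
    @given(child=GT, father=GT, mother=GT, drop_father=st.booleans())
    def test_missing_parent_never_creates_inconsistency(
        self, child, father, mother, drop_father
    ):
        full = phase_site(make_site(child, father, mother))
        degraded = phase_site(
            make_site(child, None if drop_father else father,
                      mother if drop_father else None)
        )
        if degraded.status is PhaseStatus.INCONSISTENT:
            assert full.status is PhaseStatus.INCONSISTENT
        assert not degraded.novel_allele


class TestBuildScaffold:
    def test_mixed_table_counts(self):
        table = [
            make_site((0, 1), (0, 1), (0, 0), pos=10),
            make_site((1, 1), (0, 1), (1, 1), pos=20),
            make_site((0, 1), (0, 0), (1, 1), pos=30),
            make_site((0, 1), (0, 1), (0, 1), pos=40),  # triple het
            make_site((0, 1), (0, 0), (0, 0), pos=50),  # novel allele
        ]
        scaffold, ledger = build_scaffold(table)
        assert len(scaffold) == 3
        assert [e.site.pos for e in scaffold.entries("1")] == [10, 20, 30]
        assert (ledger.counts.phased, ledger.counts.unphaseable,
                ledger.counts.inconsistent) == (3, 1, 1)
        assert ledger.counts.novel_allele == 1

    def test_empty_table(self):
        scaffold, ledger = build_scaffold([])
        assert len(scaffold) == 0 and ledger.counts.total == 0

    def test_all_consistent_homozygotes_fill_the_scaffold(self):
        table = [make_site((1, 1), (0, 1), (0, 1), pos=p) for p in (10, 20, 30)]
        scaffold, ledger = build_scaffold(table)
        assert len(scaffold) == len(table) == ledger.counts.phased

    def test_ledger_frame_has_one_row_per_site(self):
        table = [make_site((0, 1), (0, 1), (0, 0), pos=p) for p in (10, 20)]
        _, ledger = build_scaffold(table)
        frame = ledger.to_frame()
        assert list(frame["pos"]) == [10, 20]
        assert set(frame["status"]) == {"mendelian_phased"}
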