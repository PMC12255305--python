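"""Nuclease digestion: site rules, blocking, tiling, partials, nucleosides."""

import pytest
from hypothesis import given, settings, strategies as st

from modseek.digestion import (
    DigestOptions,
    RNASE_A,
    RNASE_T1,
    cleavage_sites,
    digest,
    nucleoside_digest,
    read_fragment_table,
    write_fragment_table,
)
from modseek.masscalc import METHYL_DELTA_DA, fragment_mass
from modseek.rna import ModifiedRnaSequence, Residue

from _oracles import digest_oracle

_RIBOSE_CODE = {"A": "Am", "C": "Cm", "G": "Gm", "U": "Um"}


def make_rna(text, name="rna", **kw):
    return ModifiedRnaSequence.from_string(name, text, **kw)


def random_modified_rna(rng, n, name="rand"):
    residues = []
    for _ in range(n):
        base = rng.choice(list("ACGU"))
        if rng.random() < 0.15:
            residues.append(Residue(base, _RIBOSE_CODE[base]))
        elif base == "C" and rng.random() < 0.1:
            residues.append(Residue(base, "m5C"))
        else:
            residues.append(Residue(base))
    return ModifiedRnaSequence(name, tuple(residues))


class TestCleavageSites:
    def test_rnase_t1_cuts_after_every_guanosine(self):
        assert cleavage_sites(make_rna("GAGGU"), RNASE_T1) == [1, 3, 4]

    def test_ribose_methyl_blocks_the_site(self):
        assert cleavage_sites(make_rna("GAG{Gm}GU"), RNASE_T1) == [1, 4]

    def test_cm_before_g_is_not_cleaved_by_rnase_a(self):
        # the diagnostic missed cleavage: Cm at the pyrimidine position
        sites = cleavage_sites(make_rna("GGGGGC{Cm}GU"), RNASE_A)
        assert 6 not in sites
        assert 8 not in sites  # terminal residue is never a site
        assert sites == []

    def test_base_methylation_does_not_block(self):
        assert cleavage_sites(make_rna("AC{m5C}GUA"), RNASE_A) == [2, 4]

    def test_last_residue_is_never_a_site(self):
        assert cleavage_sites(make_rna("AG"), RNASE_T1) == []


class TestDigest:
    def test_complete_t1_digest_termini(self):
        frags = digest(make_rna("GAGGU"), RNASE_T1)
        assert [(f.start, f.end) for f in frags] == [(1, 1), (2, 3), (4, 4), (5, 5)]
        assert [f.three_prime for f in frags] == ["linear_phosphate"] * 3 + ["OH"]
        assert [f.five_prime for f in frags] == ["OH"] * 4

    def test_missed_cleavage_fragment_of_the_modified_acceptor_stem(self, cm6_trna):
        seq, _ = cm6_trna
        frags = digest(seq, RNASE_A, DigestOptions(phosphatase=True))
        first = frags[0]
        assert (first.start, first.end) == (1, 8)
        assert first.to_string() == "GGGGGC{Cm}GU"
        assert first.five_prime == "OH" and first.three_prime == "OH"

    def test_fragments_tile_the_parent(self, rng):
        for _ in range(30):
            rna = random_modified_rna(rng, int(rng.integers(1, 60)))
            frags = digest(rna, RNASE_A if rng.random() < 0.5 else RNASE_T1)
            assert frags[0].start == 1 and frags[-1].end == len(rna)
            for f1, f2 in zip(frags, frags[1:]):
                assert f2.start == f1.end + 1
            rebuilt = tuple(r for f in frags for r in f.residues)
            assert rebuilt == rna.residues

    def test_matches_naive_scan_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            rna = random_modified_rna(rng, int(rng.integers(1, 50)))
            enzyme = RNASE_T1 if rng.random() < 0.5 else RNASE_A
            expected = digest_oracle(
                rna.bases,
                [r.ribose_methyl for r in rna.residues],
                enzyme.cleaves_after_bases,
            )
            got = [(f.start, f.end) for f in digest(rna, enzyme)]
            assert got == expected

    def test_no_internal_unblocked_site_at_partial_level_zero(self, rng):
        for _ in range(20):
            rna = random_modified_rna(rng, 40)
            for f in digest(rna, RNASE_T1):
                internal = f.residues[:-1]
                assert not any(
                    r.base == "G" and not r.ribose_methyl for r in internal
                )

    def test_partial_digest_emits_flagged_spanning_fragments(self):
        frags = digest(make_rna("GAGGU"), RNASE_T1, DigestOptions(partial_missed_cleavages=1))
        partials = [f for f in frags if f.missed_cleavages == 1]
        assert [(f.start, f.end) for f in partials] == [(1, 3), (2, 4), (4, 5)]
        completes = [f for f in frags if f.missed_cleavages == 0]
        assert len(completes) == 4

    def test_phosphatase_strips_all_terminal_phosphates(self):
        rna = make_rna("GAGGU", five_prime="triphosphate")
        frags = digest(rna, RNASE_T1, DigestOptions(phosphatase=True))
        assert all(f.five_prime == "OH" and f.three_prime == "OH" for f in frags)

    def test_parent_termini_preserved_without_phosphatase(self):
        rna = make_rna("GAGGU", five_prime="triphosphate", three_prime="cyclic_phosphate")
        frags = digest(rna, RNASE_T1)
        assert frags[0].five_prime == "triphosphate"
        assert frags[-1].three_prime == "cyclic_phosphate"

    def test_blocking_merges_exactly_the_flanking_fragments(self, rng):
        # methylating a cleavable residue removes that one site and fuses
        # its two flanking fragments; the fused mass gains one methyl
        # over the sum-minus-condensation bookkeeping
        rna = random_modified_rna(rng, 40, name="parent")
        sites = cleavage_sites(rna, RNASE_T1)
        if not sites:
            pytest.skip("no cleavable site in this draw")
        target = sites[len(sites) // 2]
        residues = list(rna.residues)
        residues[target - 1] = Residue("G", "Gm")
        blocked = ModifiedRnaSequence("parent", tuple(residues))

        before = digest(rna, RNASE_T1)
        after = digest(blocked, RNASE_T1)
        assert len(after) == len(before) - 1
        f1 = next(f for f in before if f.end == target)
        f2 = next(f for f in before if f.start == target + 1)
        merged = next(f for f in after if (f.start, f.end) == (f1.start, f2.end))
        water = 18.0105646
        expected = fragment_mass(f1) + fragment_mass(f2) - water + METHYL_DELTA_DA
        assert fragment_mass(merged) == pytest.approx(expected, abs=1e-6)


class TestNucleosideDigest:
    def test_counts_preserve_modified_codes(self):
        counts = nucleoside_digest(make_rna("GGGGGC{Cm}GU"))
        assert counts == {"G": 6, "Cm": 1, "U": 1}

    def test_modified_and_unmodified_parents_differ_by_one_code(self, wt_trna, cm6_trna):
        a = nucleoside_digest(wt_trna[0])
        b = nucleoside_digest(cm6_trna[0])
        assert a["C"] - b["C"] == 1
        assert b["Cm"] - a["Cm"] == 1

    def test_path_independence_of_pooling(self, rng):
        # digesting with a nuclease first and pooling the fragments gives
        # the same nucleoside census as digesting the parent directly
        for _ in range(25):
            rna = random_modified_rna(rng, int(rng.integers(1, 50)))
            direct = nucleoside_digest(rna)
            pooled = sum(
                (nucleoside_digest(ModifiedRnaSequence("f", f.residues))
                 for f in digest(rna, RNASE_A)),
                start=type(direct)(),
            )
            assert pooled == direct
            assert sum(direct.values()) == len(rna)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.sampled_from("ACGU"), min_size=1, max_size=40),
    st.sampled_from([RNASE_T1, RNASE_A]),
)
def test_tiling_invariant_holds_for_any_sequence(bases, enzyme):
    rna = ModifiedRnaSequence("h", tuple(Residue(b) for b in bases))
    frags = digest(rna, enzyme)
    covered = [p for f in frags for p in range(f.start, f.end + 1)]
    assert covered == list(range(1, len(rna) + 1))


def test_fragment_table_round_trip(cm6_trna, tmp_path):
    seq, _ = cm6_trna
    frags = digest(seq, RNASE_A, DigestOptions(phosphatase=True))
    path = tmp_path / "frags.tsv"
    write_fragment_table(frags, path)
    assert read_fragment_table(path) == frags
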