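"""Formulas, monoisotopic masses, m/z, peak matching, localization,
relative quantification."""

import numpy as np
import pytest

from modseek.digestion import DigestOptions, Fragment, RNASE_A, RNASE_T1, digest
from modseek.masscalc import (
    ElementalFormula,
    METHYL_DELTA_DA,
    PROTON_MASS,
    PeakList,
    fragment_formula,
    fragment_mass,
    localize_ribose_methyl,
    match_peaks,
    monoisotopic_mass,
    mz_negative,
    read_peaklist,
    relative_mod_level,
    theoretical_ions,
    write_peaklist,
)
from modseek.rna import ModifiedRnaSequence, Residue, RnaValidationError

from _oracles import formula_oracle
from test_digestion import random_modified_rna


def make_rna(text, name="rna", **kw):
    return ModifiedRnaSequence.from_string(name, text, **kw)


class TestFormulas:
    def test_single_cytidine_is_the_bare_nucleoside(self):
        f = fragment_formula(make_rna("C"))
        assert f == ElementalFormula(C=9, H=13, N=3, O=5)

    def test_two_o_methyl_adds_exactly_ch2(self):
        plain = fragment_formula(make_rna("ACGU"))
        methylated = fragment_formula(make_rna("AC{Cm}GU"))
        assert methylated - plain == ElementalFormula(C=1, H=2)

    def test_matches_atom_enumeration_oracle_on_random_fragments(self, rng):
        five = ["OH", "monophosphate", "triphosphate"]
        three = ["OH", "linear_phosphate", "cyclic_phosphate"]
        for _ in range(20):
            rna = random_modified_rna(rng, int(rng.integers(1, 25)))
            fp = five[rng.integers(3)]
            tp = three[rng.integers(3)]
            frag = Fragment("p", 1, len(rna), rna.residues, fp, tp)
            n_methyl = sum(1 for r in rna.residues if r.mod_code)
            expected = formula_oracle(rna.bases, n_methyl, fp, tp)
            assert fragment_formula(frag).as_dict() == expected

    def test_formula_arithmetic_never_goes_negative(self):
        with pytest.raises(RnaValidationError):
            ElementalFormula(C=1) - ElementalFormula(C=2)


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass(ElementalFormula(H=2, O=1)) == pytest.approx(
            18.010565, abs=1e-6
        )

    def test_uridine_monophosphate(self):
        ump = ElementalFormula(C=9, H=13, N=2, O=9, P=1)
        assert monoisotopic_mass(ump) == pytest.approx(324.03587, abs=1e-5)

    def test_mass_is_additive(self, rng):
        f1 = ElementalFormula(C=3, H=7, N=1, O=2)
        f2 = ElementalFormula(C=10, H=12, N=5, O=4, P=1)
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-12
        )

    def test_every_methyl_code_shifts_by_ch2(self):
        for text_plain, text_mod in [
            ("ACGU", "A{Am}CGU"),
            ("ACGU", "AC{Cm}GU"),
            ("ACGU", "ACG{Gm}U"),
            ("ACGU", "ACGU{Um}"),
            ("ACGU", "AC{m5C}GU"),
        ]:
            delta = fragment_mass(make_rna(text_mod)) - fragment_mass(make_rna(text_plain))
            assert delta == pytest.approx(14.015650, abs=1e-6)


class TestMz:
    def test_singly_deprotonated_ion(self):
        assert mz_negative(1000.0, 1) == pytest.approx(1000.0 - 1.0072765, abs=1e-9)

    def test_strictly_decreasing_in_charge(self):
        mzs = [mz_negative(3000.0, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))

    def test_rnase_a_missed_cleavage_octamer_ion(self):
        # dephosphorylated 8-mer spanning the blocked C6-G7 bond
        frag = make_rna("GGGGGC{Cm}GU")
        assert mz_negative(fragment_mass(frag), 3) == pytest.approx(876.79, abs=0.05)

    def test_rnase_t1_trinucleotide_ion(self):
        frag = make_rna("CC{Cm}G", three_prime="linear_phosphate")
        assert mz_negative(fragment_mass(frag), 1) == pytest.approx(986.13, abs=0.05)

    def test_digest_mass_conservation(self, rng):
        # linear 3'-phosphate products: each cleavage consumes one water
        for _ in range(20):
            rna = random_modified_rna(rng, int(rng.integers(2, 40)))
            frags = digest(rna, RNASE_T1)
            water = monoisotopic_mass(ElementalFormula(H=2, O=1))
            total = sum(fragment_mass(f) for f in frags)
            expected = fragment_mass(rna) + (len(frags) - 1) * water
            assert total == pytest.approx(expected, abs=1e-6)


class TestMatchPeaks:
    def _fixture(self, rng, n_decoys=20):
        rna = random_modified_rna(rng, 60, name="p")
        frags = digest(rna, RNASE_T1)
        ions = theoretical_ions(frags, range(1, 6))[:10]
        decoys = []
        true_mz = np.array([i.mz for i in ions])
        while len(decoys) < n_decoys:
            cand = rng.uniform(600.0, 2000.0)
            if np.min(np.abs(cand - true_mz) / true_mz) * 1e6 >= 50.0:
                decoys.append(cand)
        mz = np.concatenate([true_mz, decoys])
        peaks = PeakList(mz, np.ones_like(mz))
        return rna, frags, ions, peaks

    def test_all_true_ions_matched_and_no_decoys(self, rng):
        rna, frags, ions, peaks = self._fixture(rng)
        matches = match_peaks(peaks, frags, range(1, 6), tolerance_ppm=20.0)
        matched_mz = {round(m.observed_mz, 6) for m in matches}
        assert matched_mz == {round(i.mz, 6) for i in ions}

    def test_exact_peak_has_zero_error(self, rng):
        rna, frags, ions, peaks = self._fixture(rng, n_decoys=0)
        matches = match_peaks(peaks, frags, range(1, 6))
        assert all(abs(m.error_ppm) < 1e-9 for m in matches)

    def test_ion_outside_scan_window_is_never_matched(self):
        frag = make_rna("CG", three_prime="linear_phosphate")  # ~ 648 Da, 1- ion
        mass = fragment_mass(frag)
        mz1 = mz_negative(mass, 1)
        peaks = PeakList(np.array([mz1]), np.array([1.0]), scan_window=(600.0, 2000.0))
        # narrow the window to exclude the ion
        narrow = PeakList(np.array([1500.0]), np.array([1.0]), scan_window=(1000.0, 2000.0))
        assert match_peaks(narrow, [Fragment("p", 1, 2, frag.residues,
                                             "OH", "linear_phosphate")], range(1, 2)) == []
        assert len(match_peaks(peaks, [Fragment("p", 1, 2, frag.residues,
                                                "OH", "linear_phosphate")], range(1, 2))) == 1

    def test_empty_peak_list_gives_empty_result(self, rng):
        rna = random_modified_rna(rng, 30)
        peaks = PeakList(np.array([]), np.array([]))
        assert match_peaks(peaks, digest(rna, RNASE_T1)) == []


class TestLocalization:
    def test_blocking_evidence_calls_the_exact_position(self, wt_trna, cm6_trna):
        opts = DigestOptions(phosphatase=True)
        ctrl = digest(wt_trna[0].__class__("x", wt_trna[0].residues), RNASE_A, opts)
        mod = digest(cm6_trna[0].__class__("x", cm6_trna[0].residues), RNASE_A, opts)
        calls = localize_ribose_methyl(ctrl, mod)
        assert [(c.position, c.evidence) for c in calls] == [(6, "blocking")]

    def test_mass_shift_evidence_reports_the_fragment_range(self, wt_trna, cm6_trna):
        ctrl = digest(wt_trna[0].__class__("x", wt_trna[0].residues), RNASE_T1)
        mod = digest(cm6_trna[0].__class__("x", cm6_trna[0].residues), RNASE_T1)
        calls = localize_ribose_methyl(ctrl, mod)
        assert [(c.position, c.fragment_range, c.evidence) for c in calls] == [
            (None, (6, 7), "mass_shift")
        ]

    def test_identical_digests_give_no_calls(self, wt_trna):
        frags = digest(wt_trna[0], RNASE_A)
        assert localize_ribose_methyl(frags, frags) == []

    def test_mismatched_parents_rejected(self, wt_trna, cm6_trna):
        with pytest.raises(RnaValidationError, match="different parents"):
            localize_ribose_methyl(
                digest(wt_trna[0], RNASE_A), digest(cm6_trna[0], RNASE_A)
            )

    def test_soundness_on_random_parents_with_planted_methylations(self, rng):
        hits = total = called = 0
        for _ in range(100):
            rna = random_modified_rna(rng, 50, name="p")
            # strip existing ribose methyls, then plant 1-3 at cleavable sites
            from modseek.digestion import cleavage_sites
            residues = [Residue(r.base, r.mod_code if r.mod_code == "m5C" else None)
                        for r in rna.residues]
            clean = ModifiedRnaSequence("p", tuple(residues))
            sites = [
                p for p in cleavage_sites(clean, RNASE_A)
                if clean.residues[p - 1].mod_code is None
            ]
            if len(sites) < 2:
                continue
            k = int(rng.integers(1, min(3, len(sites) - 1) + 1))
            chosen = sorted(rng.choice(sites, size=k, replace=False).tolist())
            planted = list(clean.residues)
            code = {"C": "Cm", "U": "Um"}
            for p in chosen:
                planted[p - 1] = Residue(planted[p - 1].base, code[planted[p - 1].base])
            mod = ModifiedRnaSequence("p", tuple(planted))
            calls = localize_ribose_methyl(
                digest(clean, RNASE_A), digest(mod, RNASE_A)
            )
            positions = [c.position for c in calls if c.evidence == "blocking"]
            total += len(chosen)
            called += len(positions)
            hits += len(set(positions) & set(chosen))
        assert total > 50
        assert hits == total  # recall 1.0
        assert called == hits  # precision 1.0


class TestRelativeQuantification:
    def test_identity_is_100_percent(self):
        areas = {"Cm": 4.0, "G": 20.0}
        assert relative_mod_level(areas, areas) == pytest.approx(100.0)

    def test_loss_of_one_of_four_cm_gives_75_percent(self):
        reference = {"Cm": 4.0, "G": 20.0}
        sample = {"Cm": 3.0, "G": 20.0}
        assert relative_mod_level(sample, reference) == pytest.approx(75.0)

    def test_scaling_the_sample_run_cancels(self):
        reference = {"Cm": 4.0, "G": 20.0}
        sample = {"Cm": 3.0 * 7.3, "G": 20.0 * 7.3}
        assert relative_mod_level(sample, reference) == pytest.approx(75.0)

    def test_zero_normalizer_is_a_domain_error(self):
        with pytest.raises(RnaValidationError, match="normalizer"):
            relative_mod_level({"Cm": 1.0, "G": 0.0}, {"Cm": 1.0, "G": 1.0})


def test_average_mass_exceeds_monoisotopic_for_real_molecules():
    from modseek.masscalc import average_mass

    ump = ElementalFormula(C=9, H=13, N=2, O=9, P=1)
    assert average_mass(ump) > monoisotopic_mass(ump)
    assert average_mass(ump) == pytest.approx(324.18, abs=0.05)


def test_out_of_window_peaks_are_dropped_with_a_warning(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "# polarity=negative scan_window=600,2000\n"
        "mz\tintensity\n500.0\t1.0\n900.0\t2.0\n"
    )
    with pytest.warns(UserWarning, match="outside the scan window"):
        peaks = read_peaklist(path)
    assert len(peaks) == 1 and peaks.mz[0] == 900.0


def test_peaklist_file_round_trip(tmp_path, rng):
    mz = np.sort(rng.uniform(600, 2000, size=15))
    peaks = PeakList(mz, rng.uniform(0, 1e6, size=15))
    path = tmp_path / "peaks.tsv"
    write_peaklist(peaks, path)
    again = read_peaklist(path)
    np.testing.assert_allclose(again.mz, peaks.mz, atol=1e-6)
    assert again.scan_window == peaks.scan_window
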