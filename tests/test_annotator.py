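"""RN/effector calling, the conserved-residue screen, and Cas10 motifs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import blosum62_lookup, gotoh_global_score, tally_conserved_columns
from ringscan.annotator import (
    align_to_consensus,
    annotate_cas10,
    build_conservation_profile,
    classify_rn,
    infer_signals,
    resolve_gene_roles,
    screen_candidate,
)
from ringscan.core_model import DomainHit, EffectorAnnotation, default_signal_mapping

AA = "ACDEFGHIKLMNPQRSTVWY"


def _hit(pid, family, evalue=1e-30, score=100.0):
    return DomainHit(pid, family, bitscore=score, evalue=evalue)


class TestClassifyRN:
    def test_length_cutoff_excludes_251_aa(self, make_gene, catalogue):
        g = make_gene(length_aa=251)
        assert classify_rn(g, [_hit("g1", "Crn1")], catalogue) is None

    def test_small_protein_with_csx16_hit(self, make_gene, catalogue):
        g = make_gene(length_aa=180)
        rn = classify_rn(g, [_hit("g1", "Csx16", 1e-20)], catalogue)
        assert rn is not None and rn.family == "Csx16"

    def test_best_bitscore_wins(self, make_gene, catalogue):
        g = make_gene(length_aa=200)
        rn = classify_rn(
            g,
            [_hit("g1", "Csx16", score=80.0), _hit("g1", "Csx20", score=40.0)],
            catalogue,
        )
        assert rn.family == "Csx16"

    def test_csx14_profile_maps_to_crn1(self, make_gene, catalogue):
        g = make_gene(length_aa=150)
        rn = classify_rn(g, [_hit("g1", "Csx14")], catalogue)
        assert rn.family == "Crn1"

    def test_tie_breaks_by_evalue_then_family(self, make_gene, catalogue):
        g = make_gene(length_aa=150)
        rn = classify_rn(
            g,
            [
                _hit("g1", "Csx20", evalue=1e-10, score=50.0),
                _hit("g1", "Csx16", evalue=1e-20, score=50.0),
            ],
            catalogue,
        )
        assert rn.family == "Csx16"  # same score, smaller e-value

    def test_lowering_ceiling_never_adds_annotations(self, make_gene, catalogue):
        g = make_gene(length_aa=150)
        hits = [_hit("g1", "Crn1", evalue=1e-6)]
        assert classify_rn(g, hits, catalogue, evalue_ceiling=1e-4) is not None
        assert classify_rn(g, hits, catalogue, evalue_ceiling=1e-8) is None


class TestConservationProfile:
    def test_uniform_column_is_conserved(self):
        msa = [("a", "HKA"), ("b", "HKC"), ("c", "HKD")]
        prof = build_conservation_profile(msa, t_cons=1.0)
        assert (0, "H") in prof.conserved_columns
        assert (1, "K") in prof.conserved_columns
        assert all(c != 2 for c, _ in prof.conserved_columns)

    def test_nine_of_ten_not_absolutely_conserved(self):
        msa = [(f"s{i}", "H") for i in range(9)] + [("s9", "A")]
        prof = build_conservation_profile(msa, t_cons=1.0)
        assert prof.conserved_columns == ()

    def test_ragged_alignment_aborts(self):
        with pytest.raises(ValueError, match="ragged"):
            build_conservation_profile([("a", "HK"), ("b", "HKA")])

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            n, length = int(rng.integers(3, 12)), int(rng.integers(5, 40))
            rows = [
                "".join(
                    rng.choice(list(AA + "--"), size=length)
                )
                for _ in range(n)
            ]
            # guard: oracle and implementation both skip all-gap columns
            rows = [r if set(r) != {"-"} else "A" * length for r in rows]
            prof = build_conservation_profile(
                [(f"s{i}", r) for i, r in enumerate(rows)], t_cons=1.0, g_max=0.2
            )
            assert list(prof.conserved_columns) == tally_conserved_columns(rows)

    def test_raising_t_cons_never_grows_conserved_set(self, rng):
        for _ in range(10):
            rows = [
                "".join(rng.choice(list(AA), size=30)) for _ in range(6)
            ]
            msa = [(f"s{i}", r) for i, r in enumerate(rows)]
            loose = set(build_conservation_profile(msa, t_cons=0.5).conserved_columns)
            strict = set(build_conservation_profile(msa, t_cons=1.0).conserved_columns)
            assert strict <= loose


class TestScreenCandidate:
    @pytest.fixture()
    def profile(self, noiseless_dataset, profiles_for):
        return profiles_for(noiseless_dataset)["Crn1"]

    def test_consensus_passes_its_own_screen(self, profile):
        status, missing = screen_candidate(profile.consensus, profile)
        assert status == "pass" and missing == ()

    def test_single_conserved_substitution_fails(self, profile):
        col, expected = profile.conserved_columns[2]
        seq = list(profile.consensus)
        seq[col] = "A" if expected != "A" else "G"
        status, missing = screen_candidate("".join(seq), profile)
        assert status == "fail"
        assert missing == ((col, expected),)

    def test_every_conserved_position_is_load_bearing(
        self, noiseless_dataset, profiles_for
    ):
        # mutating any single conserved residue flips pass -> fail
        for fam, prof in profiles_for(noiseless_dataset).items():
            for col, expected in prof.conserved_columns:
                seq = list(prof.consensus)
                seq[col] = "W" if expected != "W" else "F"
                status, missing = screen_candidate("".join(seq), prof)
                assert status == "fail", (fam, col)
                assert (col, expected) in missing

    def test_deletion_of_conserved_region_fails(self, profile):
        col, expected = profile.conserved_columns[0]
        seq = profile.consensus[:col] + profile.consensus[col + 1 :]
        status, missing = screen_candidate(seq, profile)
        assert status == "fail"
        assert (col, expected) in missing

    def test_empty_conserved_set_aborts(self, profile):
        from dataclasses import replace

        bare = replace(profile, conserved_columns=())
        with pytest.raises(ValueError, match="conserved"):
            screen_candidate("MKV", bare)


class TestAlignmentScores:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet=AA, min_size=1, max_size=10),
        b=st.text(alphabet=AA, min_size=1, max_size=10),
    )
    def test_short_sequences_match_dp_enumeration(self, a, b):
        from biotite.sequence import ProteinSequence
        from biotite.sequence.align import SubstitutionMatrix, align_optimal

        ali = align_optimal(
            ProteinSequence(a),
            ProteinSequence(b),
            SubstitutionMatrix.std_protein_matrix(),
            gap_penalty=(-10, -1),
            terminal_penalty=True,
        )[0]
        expected = gotoh_global_score(a, b, blosum62_lookup())
        assert ali.score == expected

    def test_trace_maps_identity_alignment(self):
        trace = align_to_consensus("MKVH", "MKVH")
        assert [(int(p), int(c)) for p, c in trace] == [(i, i) for i in range(4)]


class TestCrossAnnotation:
    def test_long_carf_effector_not_called_rn(self, make_gene, catalogue):
        g = make_gene(length_aa=600)
        hits = [_hit("g1", "Csx1", score=150.0), _hit("g1", "Crn1", score=120.0)]
        eff, rn = resolve_gene_roles(g, hits, catalogue)
        assert rn is None
        assert eff is not None and eff.family == "Csx1"

    def test_small_gene_rn_wins_on_higher_bitscore(self, make_gene, catalogue):
        g = make_gene(length_aa=200)
        hits = [_hit("g1", "Csx1", score=60.0), _hit("g1", "Csx20", score=90.0)]
        eff, rn = resolve_gene_roles(g, hits, catalogue)
        assert eff is None
        assert rn is not None and rn.family == "Csx20"

    def test_small_gene_effector_wins_on_equal_bitscore(self, make_gene, catalogue):
        g = make_gene(length_aa=200)
        hits = [_hit("g1", "Csx1", score=90.0), _hit("g1", "Csx20", score=90.0)]
        eff, rn = resolve_gene_roles(g, hits, catalogue)
        assert rn is None and eff.family == "Csx1"

    def test_plain_effector_hit(self, make_gene, catalogue):
        g = make_gene(length_aa=400)
        eff, rn = resolve_gene_roles(g, [_hit("g1", "Can1")], catalogue)
        assert eff.family == "Can1" and rn is None


class TestCas10Motifs:
    def test_ggdd_flags_cyclase(self, make_gene):
        g = make_gene(protein_seq="M" * 50 + "GGDD" + "M" * 50)
        assert annotate_cas10(g).has_cyclase

    def test_neither_motif_gives_both_false(self, make_gene):
        g = make_gene(protein_seq="MKVLAKEG" * 30)
        ann = annotate_cas10(g)
        assert not ann.has_cyclase and not ann.has_hd

    def test_hd_only_in_n_terminal_third(self, make_gene):
        n_term = make_gene(protein_seq="MKHSD" + "MKVLGE" * 40)
        c_term = make_gene(protein_seq="MKVLGE" * 40 + "HSD" + "MK")
        assert annotate_cas10(n_term).has_hd
        assert not annotate_cas10(c_term).has_hd

    def test_planted_cyclase_negatives_recovered(self, noiseless_dataset, noiseless_result):
        # cyclase-negative Cas10s in the generator carry no GGDD-type motif
        motifs = ("GGDD", "GGDE", "SGDD")
        for loc in noiseless_result.loci:
            seq = loc.cas10.gene.protein_seq
            assert loc.cas10.has_cyclase == any(m in seq for m in motifs)


class TestSignals:
    @pytest.mark.parametrize(
        "family,signal",
        [("Csx1", "cA4"), ("Csm6", "cA6"), ("NucC", "cA3"), ("CorA", "SAM-AMP")],
    )
    def test_family_to_signal(self, make_gene, family, signal):
        eff = EffectorAnnotation(family, make_gene(), 50.0, 1e-20)
        assert infer_signals([eff], default_signal_mapping()) == {signal}

    def test_no_effectors_empty_set(self):
        assert infer_signals([], default_signal_mapping()) == set()

    def test_unmapped_family_reports_unknown(self, make_gene):
        eff = EffectorAnnotation("Mystery9", make_gene(), 50.0, 1e-20)
        assert infer_signals([eff], default_signal_mapping()) == {"unknown"}


def test_no_gene_carries_both_annotations(noiseless_result):
    for loc in noiseless_result.loci:
        rn_genes = {r.gene.gene_id for r in loc.rns}
        eff_genes = {e.gene.gene_id for e in loc.effectors}
        assert not rn_genes & eff_genes
        for r in loc.rns:
            assert r.gene.length_aa <= 250
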