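"""Digestion, hydrophobicity, selection rules and candidate ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iomrm import peptide_selection as ps
from iomrm._ssrcalc_data import NT_WEIGHTS, RC, RC_NT


class TestDigest:
    def test_kp_rp_rule(self):
        peps = ps.digest_tryptic("MAKRPSTKGLR", "prot")
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("MAK", 1, 3),
            ("RPSTK", 4, 8),
            ("GLR", 9, 11),
        ]
        assert peps[0].is_n_terminal_peptide and not peps[0].is_c_terminal_peptide
        assert peps[2].is_c_terminal_peptide
        # K3 followed directly by R4: ragged boundary
        assert peps[0].has_ragged_end

    def test_no_cut_sites_yields_whole_protein(self):
        peps = ps.digest_tryptic("AAAA")
        assert len(peps) == 1
        assert peps[0].sequence == "AAAA"
        assert peps[0].is_n_terminal_peptide and peps[0].is_c_terminal_peptide

    def test_empty_sequence(self):
        assert ps.digest_tryptic("") == []

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    @settings(deadline=None, max_examples=200)
    def test_digest_is_a_partition(self, protein):
        peps = ps.digest_tryptic(protein)
        assert "".join(p.sequence for p in peps) == protein
        pos = 1
        for p in peps:
            assert p.start == pos
            pos = p.end + 1
        # every internal peptide ends in K/R
        for p in peps[:-1]:
            assert p.sequence[-1] in "KR"


class TestHydrophobicity:
    def test_matches_coefficient_table_recomputation(self):
        # independent spreadsheet-style recomputation over the packaged table
        seq = "LLLLLLLL"
        total = sum(RC[a] for a in seq)
        for w, a in zip(NT_WEIGHTS, seq[:3]):
            total += w * (RC_NT[a] - RC[a])
        kl = 1.0 - 0.055 * (10 - len(seq))
        expected = kl * total
        expected -= 0.3 * (expected - 38.0)  # above-scale damping
        assert ps.ssrcalc_hydrophobicity(seq) == pytest.approx(expected, abs=0.01)

    def test_hydrophobic_residue_increases_index(self):
        assert ps.ssrcalc_hydrophobicity("GGGGW") > ps.ssrcalc_hydrophobicity("GGGGG")

    def test_nonstandard_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            ps.ssrcalc_hydrophobicity("AABAA")


def _peptide(seq, protein="prot", start=10, **kw):
    return ps.DigestPeptide(
        protein_id=protein, sequence=seq, start=start, end=start + len(seq) - 1, **kw
    )


class TestRules:
    def test_reference_peptide_selectable_with_met_deprioritized(self):
        flags = ps.evaluate_candidate(_peptide("MGQQVLDNFFR"))
        assert flags.selectable
        assert flags.deprioritizations == {"contains_M"}
        assert 10 <= flags.hydrophobicity <= 40

    @pytest.mark.parametrize(
        "seq,rule",
        [
            ("LNGTK", "has_NG"),
            ("ALNPGK", "has_NP"),
            ("QAVLDK", "n_terminal_Q"),
            ("AGK", "length_out_of_range"),  # length 3 < 5
            ("A" * 31 + "K", "length_out_of_range"),  # length 32 > 30
            ("LLLLLLLLWWK", "hydrophobicity_out_of_range"),  # index > 40
            ("GSSGK", "hydrophobicity_out_of_range"),  # index < 10
        ],
    )
    def test_hard_exclusions_forced(self, seq, rule):
        flags = ps.evaluate_candidate(_peptide(seq))
        assert rule in flags.hard_exclusions

    def test_length_window_boundaries_inclusive(self):
        ok5 = ps.evaluate_candidate(_peptide("LLLLK"))
        ok30 = ps.evaluate_candidate(_peptide("ALLV" * 7 + "FK"))  # 30 residues
        assert "length_out_of_range" not in ok5.hard_exclusions
        assert "length_out_of_range" not in ok30.hard_exclusions

    def test_protein_terminal_rules(self):
        nterm = ps.evaluate_candidate(_peptide("AVLDLLK", start=1, is_n_terminal_peptide=True))
        assert "protein_n_terminal" in nterm.hard_exclusions
        cterm = ps.evaluate_candidate(_peptide("AVLDLLK", is_c_terminal_peptide=True))
        assert "protein_c_terminal" in cterm.deprioritizations

    def test_variant_maf_threshold_at_one_percent(self):
        pep = _peptide("AVLDLLK", start=10)  # covers residues 10..16
        common = [ps.VariantAnnotation("prot", 12, 0.05)]
        rare = [ps.VariantAnnotation("prot", 12, 0.005)]
        outside = [ps.VariantAnnotation("prot", 99, 0.5)]
        assert "common_variant" in ps.evaluate_candidate(pep, variants=common).hard_exclusions
        assert "common_variant" not in ps.evaluate_candidate(pep, variants=rare).hard_exclusions
        assert "common_variant" not in ps.evaluate_candidate(pep, variants=outside).hard_exclusions

    def test_uniqueness_without_ile_leu_equivalence(self):
        proteome = ps.ProteomeIndex(
            {"prot": "XXXAVLDLLKXXX", "other": "YYYAVIDLLKYYY"}
        )
        # exact sequence occurs only in prot; the I/L variant does not collide
        flags = ps.evaluate_candidate(_peptide("AVLDLLK", start=4), proteome)
        assert "not_unique" not in flags.hard_exclusions
        shared = ps.ProteomeIndex({"prot": "XAVLDLLKX", "other": "ZAVLDLLKZ"})
        flags = ps.evaluate_candidate(_peptide("AVLDLLK", start=2), shared)
        assert "not_unique" in flags.hard_exclusions

    def test_ptm_annotation_excludes(self):
        pep = _peptide("AVLDLLK", start=10)
        flags = ps.evaluate_candidate(pep, ptm_annotations=[("prot", 11)])
        assert "frequent_ptm" in flags.hard_exclusions


class TestRanking:
    def test_observation_count_dominates(self):
        a, b = _peptide("AVLDLLK"), _peptide("TVLDLLK")
        flags = [ps.evaluate_candidate(a), ps.evaluate_candidate(b)]
        ev = [
            ps.ObservationEvidence("AVLDLLK", 5, 1e6),
            ps.ObservationEvidence("TVLDLLK", 30, 1e3),
        ]
        ranked = ps.rank_candidates(flags, ev)
        assert ranked[0].peptide.sequence == "TVLDLLK"

    def test_deprioritization_breaks_ties(self):
        a, b = _peptide("MVLDLLK"), _peptide("TVLDLLK")  # Met vs no Met
        flags = [ps.evaluate_candidate(a), ps.evaluate_candidate(b)]
        ev = [
            ps.ObservationEvidence("MVLDLLK", 10, 100.0),
            ps.ObservationEvidence("TVLDLLK", 10, 100.0),
        ]
        ranked = ps.rank_candidates(flags, ev)
        assert ranked[0].peptide.sequence == "TVLDLLK"

    def test_matches_brute_force_sort_on_toy_proteome(self):
        proteome = {
            "p1": "MKAVLDLLKSSLLFVKR",
            "p2": "MKTVLDLLKWWLLAVKR",
            "p3": "MKEFLLDVKTLLSDFKR",
        }
        index = ps.ProteomeIndex(proteome)
        ev = [
            ps.ObservationEvidence("AVLDLLK", 12, 500.0),
            ps.ObservationEvidence("SSLLFVK", 3, 900.0),
            ps.ObservationEvidence("WWLLAVK", 5, 100.0),
            ps.ObservationEvidence("EFLLDVK", 5, 100.0),
            ps.ObservationEvidence("TLLSDFK", 5, 200.0),
        ]
        for pid, seq in proteome.items():
            flags = [
                ps.evaluate_candidate(p, index, [], [])
                for p in ps.digest_tryptic(seq, pid)
            ]
            ranked = ps.rank_candidates(flags, ev)
            # independent brute-force ordering
            ev_map = {e.sequence: e for e in ev}
            expected = sorted(
                [f for f in flags if f.selectable],
                key=lambda f: (
                    -(ev_map[f.peptide.sequence].observation_count if f.peptide.sequence in ev_map else 0),
                    -(ev_map[f.peptide.sequence].median_intensity if f.peptide.sequence in ev_map else 0.0),
                    len(f.deprioritizations),
                    f.peptide.sequence,
                ),
            )
            assert [f.peptide.sequence for f in ranked] == [
                f.peptide.sequence for f in expected
            ]


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=60))
@settings(deadline=None, max_examples=100)
def test_no_selected_peptide_violates_a_hard_rule(protein):
    table = ps.select_peptides({"prot": protein})
    selected = table[table["selectable"]]
    for row in selected.itertuples(index=False):
        seq = row.sequence
        assert "NG" not in seq and "NP" not in seq
        assert not seq.startswith("Q")
        assert 5 <= len(seq) <= 30
        assert 10.0 <= row.hydrophobicity <= 40.0
        assert row.start > 1  # never the protein N-terminal peptide
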