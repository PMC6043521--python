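"""In-silico PICS: digestion rules, model cleavage, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytkit.logo import AA_INDEX, BackgroundFrequencies
from phytkit.pics import (
    DigestionRules,
    SpecificityModel,
    digest,
    reconstruct_sites,
    simulate_cleavage,
    specificity_profile,
)
from phytkit.synthetic import BackgroundSpec, make_background_proteome
from phytkit.types import AMINO_ACIDS, ProteinRecord, WINDOW_POSITIONS


def wide_rules(enzyme):
    return DigestionRules.for_enzyme(enzyme, min_len=1, max_len=50)


class TestDigest:
    def test_chymotrypsin_blocks_proline(self):
        library = digest(
            [ProteinRecord(id="p", sequence="AAFPAAYK")],
            wide_rules("chymotrypsin"),
        )
        assert [p.sequence for p in library.peptides] == ["AAFPAAY", "K"]
        assert [p.source_offset for p in library.peptides] == [0, 7]

    def test_trypsin_basic(self):
        library = digest([ProteinRecord(id="p", sequence="MKRA")],
                         wide_rules("trypsin"))
        assert [p.sequence for p in library.peptides] == ["MK", "R", "A"]

    def test_length_bounds_drop_fragments(self):
        rules = DigestionRules.for_enzyme("trypsin", min_len=2, max_len=2)
        library = digest([ProteinRecord(id="p", sequence="MKRA")], rules)
        assert [p.sequence for p in library.peptides] == ["MK"]

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError):
            DigestionRules.for_enzyme("pepsin")

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25)
    def test_reassembly_oracle(self, seed):
        """Concatenating each protein's fragments (no length filter)
        reproduces the protein."""
        proteome = make_background_proteome(BackgroundSpec(
            n_proteins=4, length_range=(200, 200), seed=seed,
        ))
        for enzyme in ("trypsin", "chymotrypsin"):
            library = digest(proteome, wide_rules(enzyme),
                             apply_length_filter=False)
            by_source = {}
            for pep in library.peptides:
                by_source.setdefault(pep.source_protein_id, []).append(pep)
            for record in proteome:
                frags = sorted(by_source[record.id], key=lambda p: p.source_offset)
                assert "".join(p.sequence for p in frags) == record.sequence
                for p in frags:
                    start = p.source_offset
                    assert record.sequence[start:start + len(p.sequence)] == p.sequence


class TestSimulateCleavage:
    def test_strict_model_forced_cut(self):
        library = digest([ProteinRecord(id="p", sequence="AAADGGGGK")],
                         wide_rules("trypsin"))
        events = simulate_cleavage(library, SpecificityModel.asp_p1(), seed=0)
        assert len(events) == 1
        event = events[0]
        assert event.prime_fragment == "GGGGK"
        assert event.true_window.p1 == "D"

    def test_no_asp_no_event(self):
        library = digest([ProteinRecord(id="p", sequence="AAAGGGGGK")],
                         wide_rules("trypsin"))
        assert simulate_cleavage(library, SpecificityModel.asp_p1(), seed=0) == []

    def test_short_prime_fragment_dropped(self):
        library = digest([ProteinRecord(id="p", sequence="AAADGGK")],
                         wide_rules("trypsin"))
        assert simulate_cleavage(library, SpecificityModel.asp_p1(), seed=0) == []

    def test_one_cut_per_peptide_highest_score_leftmost(self):
        model = SpecificityModel.asp_p1(extra={("P4", "I"): 2.0})
        seq = "AADGGGGIAADGGGG"  # second D scores higher via P4-Ile
        library = digest([ProteinRecord(id="p", sequence=seq + "K")],
                         wide_rules("trypsin"))
        events = simulate_cleavage(library, model, seed=0)
        assert len(events) == 1
        assert events[0].cut_index == seq.index("D", 4) + 1

    def test_bernoulli_rate_binomial_oracle(self):
        """Event fraction matches the logistic cleavage probability."""
        model = SpecificityModel.asp_p1(mode="bernoulli", tau=10.0,
                                        steepness=1.0)
        # single D bond scores 10; logistic(1*(10-10.8473)) ~= 0.30
        model = SpecificityModel(weights=model.weights, mode="bernoulli",
                                 tau=10.0 + np.log(0.7 / 0.3), steepness=1.0)
        target = 0.3
        from phytkit.pics import Peptide, PeptideLibrary

        library = PeptideLibrary(peptides=[
            Peptide("AAAADGGGG", f"p{i}", 0) for i in range(10_000)
        ])
        events = simulate_cleavage(library, model, seed=123)
        rate = len(events) / 10_000
        sd = np.sqrt(target * (1 - target) / 10_000)
        assert abs(rate - target) < 3 * sd


class TestReconstruct:
    def test_unique_suffix_rebuilds_window(self):
        from phytkit.pics import Peptide, PeptideLibrary

        library = PeptideLibrary(peptides=[Peptide("AVNLDSTKGW", "p", 0)])
        result = reconstruct_sites(["STKGW"], library)
        assert result.n_retained == 1
        assert result.windows[0].residues == "-AVNLD" + "STKGW-"

    def test_ambiguous_fragment_discarded(self):
        from phytkit.pics import Peptide, PeptideLibrary

        library = PeptideLibrary(peptides=[
            Peptide("AVNLDSTKGW", "p1", 0),
            Peptide("CCCCCSTKGW", "p2", 0),
        ])
        result = reconstruct_sites(["STKGW"], library)
        assert result.n_retained == 0
        assert result.n_ambiguous == 1

    def test_unmatched_fragment_counted(self):
        from phytkit.pics import Peptide, PeptideLibrary

        library = PeptideLibrary(peptides=[Peptide("AVNLDSTKGW", "p", 0)])
        result = reconstruct_sites(["WWWWW"], library)
        assert result.n_unmatched == 1

    def test_round_trip_identity(self):
        """simulate -> reconstruct recovers every unambiguous true window."""
        proteome = make_background_proteome(BackgroundSpec(
            n_proteins=400, length_range=(150, 300), seed=202,
        ))
        library = digest(proteome, DigestionRules.for_enzyme("trypsin"))
        events = simulate_cleavage(library, SpecificityModel.asp_p1(), seed=0)
        assert len(events) > 200
        result = reconstruct_sites([e.prime_fragment for e in events], library)
        truth = {e.prime_fragment: e.true_window.residues for e in events}
        assert result.n_retained + result.n_ambiguous == len(events)
        recovered = [w.residues for w in result.windows]
        # all retained windows carry D at P1 and equal their true window
        unambiguous = [
            e.true_window.residues for e in events
            if len(library.lookup(e.prime_fragment)) == 1
        ]
        assert sorted(recovered) == sorted(unambiguous)
        assert all(w[5] == "D" for w in recovered)


class TestSpecificityProfile:
    def test_planted_model_recovery(self):
        proteome = make_background_proteome(BackgroundSpec(
            n_proteins=400, length_range=(150, 300), seed=77,
        ))
        library = digest(proteome, DigestionRules.for_enzyme("trypsin"))
        events = simulate_cleavage(library, SpecificityModel.asp_p1(), seed=0)
        result = reconstruct_sites([e.prime_fragment for e in events], library)
        bg = BackgroundFrequencies(freq=tuple([0.05] * 20), n_residues_used=10_000)
        profile = specificity_profile(result.windows, bg)
        heights = profile.percent_difference * profile.significant
        i, j = np.unravel_index(np.argmax(heights), heights.shape)
        assert WINDOW_POSITIONS[i] == "P1"
        assert AMINO_ACIDS[j] == "D"

    def test_empty_windows_error(self):
        bg = BackgroundFrequencies(freq=tuple([0.05] * 20), n_residues_used=10)
        with pytest.raises(ValueError):
            specificity_profile([], bg)
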