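"""Alignment identity, hit ranking, tie rule, replicate consensus, estimator."""

import random

import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from brute_force import brute_force_score
from coiauth.species_assignment import (
    AlignmentScoring,
    AssignmentHit,
    PanelIdentityClassifier,
    ReadAssignment,
    ReferencePanel,
    ReferenceRecord,
    build_panel,
    call_species_for_read,
    consensus_by_product,
    consensus_product_call,
    global_identity,
    rank_hits,
    round_half_up,
)
from coiauth.synthetic_data import SimulationConfig, mutate_to_identity, simulate_panel


class TestGlobalIdentity:
    def test_identical_sequences_are_100(self):
        seq = "ACGTACGTAC" * 65
        stats = global_identity(seq, seq)
        assert stats.identity_pct == 100.00
        assert stats.coverage_pct == 100.00
        assert stats.matches == stats.aligned_columns == len(seq)

    def test_two_substitutions_in_650(self):
        rng = random.Random(0)
        ref = "".join(rng.choice("ACGT") for _ in range(650))
        query = list(ref)
        query[100] = {"A": "C"}.get(query[100], "A")
        query[500] = {"G": "T"}.get(query[500], "G")
        stats = global_identity("".join(query), ref)
        assert stats.identity_pct == round_half_up(100 * 648 / 650, 2) == 99.69

    def test_symmetry_under_symmetric_scoring(self):
        rng = random.Random(1)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60)))
            assert global_identity(a, b).score == global_identity(b, a).score

    def test_n_occupies_a_column_but_never_matches(self):
        ref = "ACGTACGTAC"
        query = "ACGTNCGTAC"
        stats = global_identity(query, ref)
        assert stats.aligned_columns == 10
        assert stats.matches == 9
        assert stats.identity_pct == 90.00

    def test_non_iupac_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            global_identity("ACGR", "ACGT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")

    @given(
        a=st.text(alphabet="ACGT", min_size=0, max_size=8),
        b=st.text(alphabet="ACGT", min_size=0, max_size=8),
    )
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_dp_score_equals_enumeration_oracle(self, a, b):
        if not a or not b:
            return  # the aligner requires non-empty input; oracle covers the rest
        expected = brute_force_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0)
        assert global_identity(a, b).score == pytest.approx(expected)

    def test_alternative_scoring_scheme_against_oracle(self):
        rng = random.Random(99)
        scoring = AlignmentScoring(match=2.0, mismatch=-3.0, gap_open=-4.0, gap_extend=-4.0)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            expected = brute_force_score(a, b, match=2.0, mismatch=-3.0, gap=-4.0)
            assert global_identity(a, b, scoring).score == pytest.approx(expected)


class TestRankHits:
    def test_self_hit_ranks_first_at_100(self, small_panel):
        query = small_panel.records[1].sequence
        hits = rank_hits(query, small_panel, min_identity_pct=80.0)
        assert hits[0].accession == small_panel.records[1].accession
        assert hits[0].identity_pct == 100.00

    def test_threshold_excludes_all_when_no_exact_match(self, small_panel):
        query = mutate_to_identity(small_panel.records[0].sequence, 0.99, seed=5)
        assert rank_hits(query, small_panel, min_identity_pct=100.0) == []

    def test_mutated_query_ranks_source_species_first(self, small_panel):
        for i, rec in enumerate(small_panel.records):
            query = mutate_to_identity(rec.sequence, 0.99, seed=i)
            hits = rank_hits(query, small_panel, min_identity_pct=90.0)
            assert hits[0].species == rec.species

    def test_repeated_invocation_is_deterministic(self, small_panel):
        query = mutate_to_identity(small_panel.records[2].sequence, 0.985, seed=3)
        first = rank_hits(query, small_panel, min_identity_pct=0.0)
        second = rank_hits(query, small_panel, min_identity_pct=0.0)
        assert first == second

    def test_prefilter_agrees_with_exhaustive_alignment(self, small_panel, monkeypatch):
        import coiauth.species_assignment as sa

        query = mutate_to_identity(small_panel.records[0].sequence, 0.98, seed=11)
        with_filter = rank_hits(query, small_panel, min_identity_pct=97.0)
        monkeypatch.setattr(sa, "_HAVE_EDLIB", False)
        without_filter = rank_hits(query, small_panel, min_identity_pct=97.0)
        assert with_filter == without_filter


def _hit(accession, species, identity):
    return AssignmentHit(accession, species, identity, 100.0, 650, 0)


class TestTieRule:
    def test_unique_maximum_assigns(self):
        hits = [_hit("X1", "Thunnus albacares", 99.54), _hit("X2", "Thunnus albacares", 99.50)]
        call = call_species_for_read(hits)
        assert call.status == "assigned"
        assert call.species == "Thunnus albacares"
        assert call.best_identity_pct == 99.54

    def test_cross_species_tie_is_ambiguous(self):
        hits = [_hit("X1", "Sparus aurata", 99.54), _hit("X2", "Dicentrarchus labrax", 99.54)]
        call = call_species_for_read(hits)
        assert call.status == "ambiguous"
        assert call.tied_species == ("Dicentrarchus labrax", "Sparus aurata")

    def test_same_species_tie_still_assigns(self):
        hits = [_hit("X1", "Sparus aurata", 99.54), _hit("X2", "Sparus aurata", 99.54)]
        assert call_species_for_read(hits).status == "assigned"

    def test_no_hits_is_unassigned(self):
        assert call_species_for_read([]).status == "unassigned"

    def test_tolerance_widens_the_tied_set(self):
        hits = [_hit("X1", "Sparus aurata", 99.54), _hit("X2", "Dicentrarchus labrax", 99.50)]
        assert call_species_for_read(hits, tie_tolerance=0.0).status == "assigned"
        assert call_species_for_read(hits, tie_tolerance=0.05).status == "ambiguous"


def _read_call(code, rep, status, species=None, identity=None):
    tied = (species,) if species else ()
    return ReadAssignment(code, rep, status, species, identity, tied)


class TestConsensus:
    def test_unanimous_replicates_assign_with_max_identity(self):
        calls = [
            _read_call("MIL1T", 1, "assigned", "Thunnus albacares", 99.54),
            _read_call("MIL1T", 2, "assigned", "Thunnus albacares", 99.39),
            _read_call("MIL1T", 3, "assigned", "Thunnus albacares", 99.08),
        ]
        result = consensus_product_call(calls)
        assert result.status == "assigned"
        assert result.species == "Thunnus albacares"
        assert result.best_identity_pct == 99.54

    def test_single_replicate_assigns(self):
        result = consensus_product_call(
            [_read_call("MIL2B", 1, "assigned", "Dicentrarchus labrax", 99.37)]
        )
        assert result.status == "assigned"
        assert result.species == "Dicentrarchus labrax"

    def test_disagreeing_replicates_flag_multi_species(self):
        calls = [
            _read_call("X1", 1, "assigned", "Sparus aurata", 99.0),
            _read_call("X1", 2, "assigned", "Dicentrarchus labrax", 99.2),
        ]
        assert consensus_product_call(calls).status == "multi_species"

    def test_ambiguous_replicate_does_not_overrule_unanimity(self):
        calls = [
            _read_call("X1", 1, "assigned", "Sparus aurata", 99.0),
            ReadAssignment("X1", 2, "ambiguous", None, 98.9, ("Sparus aurata", "Pagrus major")),
        ]
        result = consensus_product_call(calls)
        assert result.status == "assigned"
        assert result.species == "Sparus aurata"

    def test_all_unassigned_is_unassigned(self):
        calls = [_read_call("X1", 1, "unassigned"), _read_call("X1", 2, "unassigned")]
        assert consensus_product_call(calls).status == "unassigned"

    def test_mixed_sample_codes_rejected(self):
        calls = [_read_call("X1", 1, "assigned", "Sparus aurata", 99.0),
                 _read_call("X2", 1, "assigned", "Sparus aurata", 99.0)]
        with pytest.raises(ValueError, match="sample codes"):
            consensus_product_call(calls)

    def test_grouping_by_product(self):
        calls = [
            _read_call("A", 1, "assigned", "Sparus aurata", 99.0),
            _read_call("B", 1, "assigned", "Thunnus thynnus", 98.5),
            _read_call("A", 2, "assigned", "Sparus aurata", 99.3),
        ]
        grouped = consensus_by_product(calls)
        assert set(grouped) == {"A", "B"}
        assert grouped["A"].best_identity_pct == 99.3


class TestBuildPanel:
    def _write(self, tmp_path, records, tax_rows):
        fasta = tmp_path / "panel.fasta"
        fasta.write_text("".join(f">{acc}\n{seq}\n" for acc, seq in records))
        tax = tmp_path / "tax.tsv"
        tax.write_text(
            "accession\tspecies\tgenus\tfamily\n"
            + "".join("\t".join(row) + "\n" for row in tax_rows)
        )
        return fasta, tax

    def test_panel_counts_and_species_index(self, tmp_path):
        seq = "ACGT" * 120
        fasta, tax = self._write(
            tmp_path,
            [("A1", seq), ("A2", seq), ("B1", seq)],
            [
                ("A1", "Sparus aurata", "Sparus", "Sparidae"),
                ("A2", "Sparus aurata", "Sparus", "Sparidae"),
                ("B1", "Thunnus thynnus", "Thunnus", "Scombridae"),
            ],
        )
        panel = build_panel(fasta, tax)
        assert len(panel) == 3
        assert panel.species_index["Sparus aurata"] == ["A1", "A2"]
        assert panel.family_of("Thunnus thynnus") == "Scombridae"

    def test_missing_taxonomy_entry_is_an_error(self, tmp_path):
        fasta, tax = self._write(
            tmp_path,
            [("A1", "ACGT" * 120)],
            [("ZZ", "Sparus aurata", "Sparus", "Sparidae")],
        )
        with pytest.raises(ValueError, match="A1"):
            build_panel(fasta, tax)

    def test_duplicate_accessions_rejected(self, tmp_path):
        fasta, tax = self._write(
            tmp_path,
            [("A1", "ACGT" * 120)],
            [("A1", "Sparus aurata", "Sparus", "Sparidae"),
             ("A1", "Sparus aurata", "Sparus", "Sparidae")],
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_panel(fasta, tax)


class TestPanelIdentityClassifier:
    def test_fit_predict_recovers_generating_species(self, small_panel):
        clf = PanelIdentityClassifier(min_identity_pct=90.0)
        clf.fit(small_panel)
        queries = [
            mutate_to_identity(rec.sequence, 0.985, seed=i)
            for i, rec in enumerate(small_panel.records)
        ]
        assert list(clf.predict(queries)) == [r.species for r in small_panel.records]

    def test_unassigned_below_threshold(self, small_panel):
        clf = PanelIdentityClassifier(min_identity_pct=99.9).fit(small_panel)
        query = mutate_to_identity(small_panel.records[0].sequence, 0.98, seed=1)
        assert clf.predict([query])[0] == "unassigned"

    def test_fit_from_sequences_and_labels(self):
        panel, _ = simulate_panel(SimulationConfig(seed=5, n_species=2))
        X = [r.sequence for r in panel.records]
        y = [r.species for r in panel.records]
        clf = PanelIdentityClassifier(min_identity_pct=90.0).fit(X, y)
        assert sorted(clf.classes_) == sorted(y)
        assert clf.predict([X[0]])[0] == y[0]

    def test_sklearn_param_interface_and_clone(self):
        clf = PanelIdentityClassifier(min_identity_pct=95.0, tie_tolerance=0.01)
        cloned = clone(clf)
        assert cloned.get_params()["min_identity_pct"] == 95.0
        cloned.set_params(min_identity_pct=98.0)
        assert cloned.min_identity_pct == 98.0
        with pytest.raises(ValueError, match="not fitted"):
            clf.predict(["ACGT"])
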