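"""Collapsed-proteome construction, digestion, and peptide assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heterosol.orthoproteome import (
    OrthogroupCatalog,
    assign_peptides,
    build_collapsed_proteome,
    digest,
    filter_cross_matches,
)
from helpers import brute_force_digest, naive_assignment, random_catalog

AA = "ACDEFGHIKLMNPQRSTVWY"
residue_text = st.text(alphabet=AA, min_size=1, max_size=60)


class TestCollapse:
    def test_two_members_joined_by_triple_lysine(self):
        catalog = OrthogroupCatalog([("og1", "A", "parent1"), ("og1", "B", "parent2")])
        proteome = build_collapsed_proteome(catalog, {"A": "AR", "B": "CDE"})
        entry = proteome["og1"]
        assert entry.sequence == "ARKKKCDE"
        assert [(b.protein_id, b.start, b.end) for b in entry.boundaries] == [
            ("A", 0, 2),
            ("B", 5, 8),
        ]

    def test_single_member_has_no_separator(self):
        catalog = OrthogroupCatalog([("og1", "A", "parent1")])
        entry = build_collapsed_proteome(catalog, {"A": "MKR"})["og1"]
        assert entry.sequence == "MKR"
        assert len(entry.boundaries) == 1

    def test_three_members_two_separators(self):
        catalog = OrthogroupCatalog(
            [("og1", x, "none") for x in ("A", "B", "C")]
        )
        entry = build_collapsed_proteome(
            catalog, {"A": "AA", "B": "CC", "C": "DD"}
        )["og1"]
        assert entry.sequence == "AAKKKCCKKKDD"
        assert len(entry.sequence) == 6 + 2 * 3

    def test_missing_sequence_names_protein(self):
        catalog = OrthogroupCatalog([("og1", "A", "none")])
        with pytest.raises(KeyError, match="A"):
            build_collapsed_proteome(catalog, {})

    def test_empty_sequence_rejected(self):
        catalog = OrthogroupCatalog([("og1", "A", "none")])
        with pytest.raises(ValueError):
            build_collapsed_proteome(catalog, {"A": ""})

    def test_members_recoverable_from_boundaries(self, rng):
        for _ in range(20):
            catalog, sequences = random_catalog(rng)
            proteome = build_collapsed_proteome(catalog, sequences)
            recovered = {}
            for entry in proteome.values():
                recovered.update(entry.member_sequences())
            assert recovered == sequences

    def test_duplicate_protein_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OrthogroupCatalog([("og1", "A", "none"), ("og2", "A", "none")])


class TestDigest:
    @pytest.mark.parametrize(
        "seq, max_missed, expected",
        [
            ("MKRADE", 0, {"MK", "R", "ADE"}),
            ("MKPR", 0, {"MKPR"}),  # no cleavage before proline
        ],
    )
    def test_worked_examples(self, seq, max_missed, expected):
        peps = {p.sequence for p in digest(seq, max_missed, min_len=1, max_len=60)}
        assert peps == expected

    def test_missed_cleavage_ladder(self):
        peps = {p.sequence for p in digest("AKBKCK", 2, min_len=1, max_len=60)}
        assert {"AK", "AKBK", "AKBKCK"} <= peps
        # nothing may carry three internal missed sites
        for p in digest("AKBKCKDK", 2, min_len=1, max_len=60):
            assert p.missed_cleavages <= 2

    def test_non_residue_characters_rejected(self):
        with pytest.raises(ValueError):
            digest("MK1R")

    def test_proline_rule_configurable(self):
        assert {p.sequence for p in digest("MKPR", 0, 1, 60, proline_rule=False)} == {
            "MK",
            "PR",
        }

    @given(seq=residue_text, max_missed=st.integers(0, 2))
    def test_matches_bruteforce_enumeration(self, seq, max_missed):
        got = {(p.sequence, p.start, p.missed_cleavages)
               for p in digest(seq, max_missed, min_len=1, max_len=60)}
        assert got == brute_force_digest(seq, max_missed)

    @given(seq=residue_text)
    def test_length_bounds_respected(self, seq):
        for p in digest(seq, 2, min_len=4, max_len=8):
            assert 4 <= len(p.sequence) <= 8


class TestAssign:
    @pytest.fixture()
    def toy(self):
        catalog = OrthogroupCatalog(
            [
                ("og1", "A", "parent1"),
                ("og1", "B", "parent2"),
                ("og2", "C", "parent1"),
            ]
        )
        sequences = {"A": "MAADER", "B": "MAVDER", "C": "MWWWTR"}
        return catalog, build_collapsed_proteome(catalog, sequences)

    def test_flags_from_single_and_cross_og_occurrences(self, toy):
        catalog, proteome = toy
        recs = {
            r.sequence: r
            for r in assign_peptides(
                ["MAADER", "DER", "MWWWTR", "QQQQ", "KKK"], proteome, catalog
            )
        }
        assert recs["MAADER"].unique_to_orthogroup
        assert recs["MAADER"].subgenome_specific == "parent1"
        # DER occurs in both homoeologs of og1 -> unique, shared
        assert recs["DER"].unique_to_orthogroup
        assert recs["DER"].subgenome_specific == "shared"
        assert recs["MWWWTR"].subgenome_specific == "parent1"
        assert recs["QQQQ"].hits == []
        assert recs["QQQQ"].subgenome_specific == "none"
        # separator-only lysines map to no member
        assert recs["KKK"].hits == []

    def test_peptide_in_two_orthogroups_not_unique(self):
        catalog = OrthogroupCatalog([("og1", "A", "none"), ("og2", "B", "none")])
        proteome = build_collapsed_proteome(
            catalog, {"A": "MSSSSER", "B": "MSSSSEK"}
        )
        (rec,) = assign_peptides(["SSSSE"], proteome, catalog)
        assert not rec.unique_to_orthogroup

    def test_equate_il_mode(self):
        catalog = OrthogroupCatalog([("og1", "A", "none")])
        proteome = build_collapsed_proteome(catalog, {"A": "MILLER"})
        (strict,) = assign_peptides(["MLLLER"], proteome, catalog)
        (loose,) = assign_peptides(["MLLLER"], proteome, catalog, equate_il=True)
        assert strict.hits == [] and len(loose.hits) == 1

    def test_matches_naive_scan_on_random_catalogs(self, rng):
        for _ in range(10):
            catalog, sequences = random_catalog(rng, n_orthogroups=4)
            proteome = build_collapsed_proteome(catalog, sequences)
            peptides = sorted(
                {p.sequence for e in proteome.values()
                 for p in digest(e.sequence, 2, min_len=1, max_len=30)}
            )[:80]
            for rec in assign_peptides(peptides, proteome, catalog):
                oracle = naive_assignment(rec.sequence, proteome, catalog)
                assert sorted(rec.hits) == oracle["hits"]
                assert rec.unique_to_orthogroup == oracle["unique_to_orthogroup"]
                assert rec.subgenome_specific == oracle["subgenome_specific"]
                assert rec.within_member == oracle["within_member"]


class TestChimeraSafety:
    def test_digest_peptides_never_bridge_members(self, rng):
        for _ in range(25):
            catalog, sequences = random_catalog(rng, n_orthogroups=2, members=(2, 3))
            proteome = build_collapsed_proteome(catalog, sequences)
            for entry in proteome.values():
                for pep in digest(entry.sequence, 2, min_len=1, max_len=10**9):
                    span = range(pep.start, pep.start + len(pep.sequence))
                    touched = {
                        b.protein_id
                        for b in entry.boundaries
                        for i in span
                        if b.start <= i < b.end
                    }
                    assert len(touched) <= 1, (pep, entry.orthogroup_id)


class TestCrossMatchFilter:
    def _records(self, sim_dataset):
        return [
            r
            for r in sim_dataset["records"]
            if r.unique_to_orthogroup
        ]

    def test_simulated_data_has_no_cross_matches(self, sim_dataset):
        kept, discarded = filter_cross_matches(
            self._records(sim_dataset),
            sim_dataset["features"],
            sim_dataset["design"],
            {"parent1": "parent1", "parent2": "parent2"},
        )
        assert discarded == set()
        assert kept == set(sim_dataset["features"]["orthogroup_id"])

    def test_wrong_parent_observation_discards_orthogroup(self, sim_dataset):
        features = sim_dataset["features"]
        design = sim_dataset["design"]
        p2_runs = design.loc[design["genotype"] == "parent2", "run_id"]
        spec1 = features[
            (features["subgenome_specific"] == "parent1")
        ].iloc[0]
        contaminated = features.copy()
        contaminated.loc[len(contaminated)] = {
            "peptide": spec1["peptide"],
            "orthogroup_id": spec1["orthogroup_id"],
            "subgenome_specific": "parent1",
            "run_id": p2_runs.iloc[0],
            "intensity": 1e6,
        }
        kept, discarded = filter_cross_matches(
            self._records(sim_dataset),
            contaminated,
            design,
            {"parent1": "parent1", "parent2": "parent2"},
        )
        assert spec1["orthogroup_id"] in discarded

    def test_missing_parent_genotype_is_config_error(self, sim_dataset):
        with pytest.raises(ValueError, match="parent"):
            filter_cross_matches(
                self._records(sim_dataset),
                sim_dataset["features"],
                sim_dataset["design"],
                {"nonexistent": "parent1"},
            )
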