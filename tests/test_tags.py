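"""Tag database construction, cleaning, and 1-mismatch mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cottondge import simulate as sim
from cottondge.simulate import ReferenceTranscript
from cottondge.tags import (
    build_tag_database,
    clean_tags,
    map_tags,
    process_library,
    summarize_library,
)
from oracles import map_tags_oracle


def _scan_tags(sequence: str) -> list[tuple[str, int]]:
    """Independent substring scan for all CATG offsets with >=17 trailing nt."""
    return [
        (sequence[i : i + 21], i)
        for i in range(len(sequence) - 3)
        if sequence[i : i + 4] == "CATG" and i + 21 <= len(sequence)
    ]


class TestBuildTagDatabase:
    def test_boundary_transcript_single_tag(self):
        seq = "CATG" + "A" * 17
        db = build_tag_database([ReferenceTranscript("g1", seq)])
        assert list(db.entries) == [seq]
        assert db.entries[seq] == [("g1", 0)]

    def test_no_anchor_gene_is_tagless(self):
        db = build_tag_database([ReferenceTranscript("g1", "ACGT" * 20)])
        assert len(db.entries) == 0
        assert db.tagless_genes == {"g1"}

    def test_two_anchors_two_positions(self):
        seq = "CATG" + "A" * 17 + "CATG" + "C" * 17
        db = build_tag_database([ReferenceTranscript("g1", seq)])
        expected = _scan_tags(seq)
        assert sorted((t, p) for t, hits in db.entries.items() for _, p in hits) == sorted(
            expected
        )
        assert {p for hits in db.entries.values() for _, p in hits} == {0, 21}

    def test_tag_count_equals_independent_scan(self, small_reference, small_db):
        for rec in small_reference:
            expected = _scan_tags(rec.sequence)
            got = [
                (tag, pos)
                for tag, hits in small_db.entries.items()
                for g, pos in hits
                if g == rec.gene_id
            ]
            assert sorted(got) == sorted(expected)

    def test_shared_tag_flagged_ambiguous(self):
        seq = "CATG" + "A" * 17
        db = build_tag_database(
            [ReferenceTranscript("g1", seq), ReferenceTranscript("g2", seq + "T")]
        )
        assert seq in db.ambiguous_tags

    def test_non_acgt_record_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="non-ACGT"):
            db = build_tag_database(
                [
                    ReferenceTranscript("bad", "CATGNNN" + "A" * 20),
                    ReferenceTranscript("ok", "CATG" + "A" * 17),
                ]
            )
        assert db.genes_for("CATG" + "A" * 17) == {"ok"}
        assert "bad" in db.tagless_genes

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            build_tag_database([])

    def test_antisense_indexes_reverse_complement(self):
        # CATG on the reverse complement only
        seq = ("CATG" + "A" * 17)  # revcomp is T*17 + CATG
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        db_sense = build_tag_database([ReferenceTranscript("g1", rc)])
        db_both = build_tag_database([ReferenceTranscript("g1", rc)], antisense=True)
        assert len(db_sense.entries) == 0
        assert seq in db_both.entries


class TestCleanTags:
    def test_short_tag_removed(self):
        clean, stats = clean_tags({"CATG" + "A" * 17: 5, "CATG" + "A" * 16: 100})
        assert list(clean) == ["CATG" + "A" * 17]
        assert stats["n_short_removed"] == 100

    def test_singleton_removed(self):
        clean, stats = clean_tags({"A" * 21: 1, "C" * 21: 2})
        assert list(clean) == ["C" * 21]
        assert stats["n_singletons_removed"] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        raw: dict[str, int] = {}
        for _ in range(int(rng.integers(1, 30))):
            length = int(rng.choice([15, 18, 20, 21, 21, 21]))
            tag = "".join(rng.choice(list("ACGT"), size=length))
            if tag not in raw:
                raw[tag] = int(rng.integers(1, 5))
        clean, stats = clean_tags(raw)
        expected = {
            t: c for t, c in raw.items() if len(t) >= 21 and c > 1
        }
        assert clean == expected
        assert stats["n_short_removed"] == sum(
            c for t, c in raw.items() if len(t) < 21
        )
        assert stats["n_singletons_removed"] == sum(
            1 for t, c in raw.items() if len(t) >= 21 and c == 1
        )


class TestMapTags:
    def test_exact_unique_hit(self, small_db):
        tag = next(
            t for t in small_db.entries
            if t not in small_db.ambiguous_tags
        )
        gene = next(iter(small_db.genes_for(tag)))
        counts, tallies = map_tags({tag: 7}, small_db)
        assert counts == {gene: 7}
        assert tallies["n_mapped"] == 7

    def test_multi_gene_tag_excluded(self):
        seq = "CATG" + "A" * 17
        db = build_tag_database(
            [ReferenceTranscript("g1", seq), ReferenceTranscript("g2", seq + "T")]
        )
        counts, tallies = map_tags({seq: 10}, db)
        assert counts == {}
        assert tallies["n_ambiguous_excluded"] == 10

    def test_one_mismatch_unique_rescue(self):
        seq_a = "CATG" + "A" * 17
        seq_b = "CATG" + "C" * 17
        db = build_tag_database(
            [ReferenceTranscript("gA", seq_a), ReferenceTranscript("gB", seq_b)]
        )
        query = "CATG" + "A" * 16 + "T"  # distance 1 from gA's tag, 17 from gB's
        counts, tallies = map_tags({query: 3}, db)
        assert counts == {"gA": 3}
        assert tallies["n_mapped"] == 3

    def test_positions_within_gene_sum(self):
        seq = "CATG" + "A" * 17 + "CATG" + "C" * 17
        db = build_tag_database([ReferenceTranscript("g1", seq)])
        clean = {tag: 5 for tag in db.entries}
        counts, _ = map_tags(clean, db)
        assert counts == {"g1": 10}

    def test_short_clean_tag_is_contract_violation(self, small_db):
        with pytest.raises(ValueError, match="cleaning contract"):
            map_tags({"CATGAAA": 2}, small_db)

    def test_agrees_with_brute_force_hamming_oracle(self, design):
        """Indexed matcher vs all-pairs Hamming scan on a database <= 500 tags,
        over queries at distances 0, 1 and 2 including ambiguous cases."""
        ref = sim.generate_reference(
            60, (100, 300), no_catg_fraction=0.0, paralog_fraction=0.3, seed=17
        )
        db = build_tag_database(ref)
        assert len(db.entries) <= 500
        rng = np.random.default_rng(17)
        queries: dict[str, int] = {}
        tags_list = sorted(db.entries)
        for i in range(300):
            tag = list(tags_list[rng.integers(0, len(tags_list))])
            for _ in range(rng.integers(0, 3)):  # mutate 0-2 positions
                pos = int(rng.integers(0, 21))
                tag[pos] = "ACGT"[rng.integers(0, 4)]
            queries["".join(tag)] = queries.get("".join(tag), 0) + int(
                rng.integers(1, 6)
            )
        counts, tallies = map_tags(queries, db)
        o_counts, o_mapped, o_ambig, o_unmapped = map_tags_oracle(
            queries, db.entries
        )
        assert counts == o_counts
        assert tallies["n_mapped"] == o_mapped
        assert tallies["n_ambiguous_excluded"] == o_ambig
        assert tallies["n_unmapped"] == o_unmapped


class TestLibraryProcessing:
    def test_partition_invariant(self, small_reference, small_db, design):
        truth = sim.simulate_true_expression(small_reference, design, seed=5)
        for lib_id in design.library_ids[:3]:
            raw = sim.simulate_tag_library(
                small_reference, truth, lib_id, depth=5000, seed=5
            )
            lib = process_library(lib_id, raw, small_db)
            s = lib.stats
            assert (
                s["n_mapped"] + s["n_ambiguous_excluded"] + s["n_unmapped"]
                == lib.clean_total
            )
            assert (
                lib.clean_total
                == lib.raw_total - s["n_short_removed"] - s["n_singletons_removed"]
            )

    def test_error_free_unique_tags_map_to_source(self, design):
        """With no errors and a paralog-free reference, every unambiguous tag
        maps back to its true source gene."""
        ref = sim.generate_reference(
            80, (100, 300), no_catg_fraction=0.0, paralog_fraction=0.0, seed=19
        )
        db = build_tag_database(ref)
        truth = sim.simulate_true_expression(ref, design, seed=19)
        lib_id = design.library_ids[0]
        raw = sim.simulate_tag_library(
            ref, truth, lib_id, depth=20_000, error_rate=0.0,
            short_frac=0.0, singleton_boost=0.0, seed=19,
        )
        lib = process_library(lib_id, raw, db)
        assert lib.stats["n_unmapped"] == 0
        # every mapped count lands on the gene owning that tag
        for tag, count in lib.clean.items():
            genes = db.genes_for(tag)
            if len(genes) == 1:
                assert next(iter(genes)) in lib.mapped_unambiguous

    def test_simple_percentage(self, small_db):
        from cottondge.tags import TagLibrary

        lib = TagLibrary("L", 10, {"A" * 21: 10}, 10, {"g": 8},
                         {"n_mapped": 8, "n_ambiguous_excluded": 2, "n_unmapped": 0,
                          "n_short_removed": 0, "n_singletons_removed": 0})
        stats = summarize_library(lib, small_db)
        assert stats["pct_unambiguous_mapped"] == pytest.approx(0.8)

    def test_zero_clean_tags_warns_not_raises(self, small_db):
        from cottondge.tags import TagLibrary

        lib = TagLibrary("L", 2, {}, 0, {}, {"n_mapped": 0})
        with pytest.warns(UserWarning, match="zero clean tags"):
            stats = summarize_library(lib, small_db)
        assert stats["pct_unambiguous_mapped"] == 0.0
        assert stats["pct_genes_hit"] == 0.0
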