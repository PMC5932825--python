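"""Matrix pipeline: alien index, paralog pruning, occupancy, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from phylorigins import (
    HitTable,
    Partition,
    alien_index_filter,
    clade_filter,
    concatenate_supermatrix,
    enrichment_test,
    occupancy_filter,
    occupancy_profile,
    overlap_report,
    parse_newick,
    prune_paralogs,
    read_hit_table,
)

from _oracles import bruteforce_single_copy_size, fisher_two_sided


def hit_rows(qseqid, e_in=None, e_out=None):
    rows = []
    if e_in is not None:
        rows.append({"qseqid": qseqid, "sseqid": "in1", "evalue": e_in,
                     "bitscore": 100.0, "group": "ingroup"})
    if e_out is not None:
        rows.append({"qseqid": qseqid, "sseqid": "out1", "evalue": e_out,
                     "bitscore": 100.0, "group": "outgroup"})
    return rows


class TestAlienIndex:
    def test_outgroup_better_is_flagged(self):
        table = HitTable(pd.DataFrame(hit_rows("q1", 1e-5, 1e-20)))
        kept, flagged, scores = alien_index_filter(table)
        assert flagged == ["q1"]
        assert scores["q1"] == pytest.approx(
            math.log(1e-5 + 1e-200) - math.log(1e-20 + 1e-200)
        )
        assert scores["q1"] == pytest.approx(34.5, abs=0.1)

    def test_ingroup_only_is_kept(self):
        table = HitTable(pd.DataFrame(hit_rows("q1", e_in=1e-50)))
        kept, flagged, scores = alien_index_filter(table)
        assert kept == ["q1"] and not flagged
        assert scores["q1"] < 0

    def test_equal_evalues_kept_at_default_threshold(self):
        table = HitTable(pd.DataFrame(hit_rows("q1", 1e-10, 1e-10)))
        kept, flagged, scores = alien_index_filter(table)
        assert kept == ["q1"]
        assert scores["q1"] == pytest.approx(0.0)

    def test_query_with_no_hits_kept_scored_zero(self):
        table = HitTable(pd.DataFrame(hit_rows("q1", 1e-10, 1e-5)))
        kept, flagged, scores = alien_index_filter(table, all_queries=["q1", "q2"])
        assert "q2" in kept
        assert scores["q2"] == 0.0

    def test_no_outgroup_records_flags_nothing(self):
        rows = hit_rows("q1", e_in=1e-30) + hit_rows("q2", e_in=1e-3)
        _, flagged, _ = alien_index_filter(HitTable(pd.DataFrame(rows)))
        assert flagged == []

    def test_lowering_outgroup_evalue_never_unflags(self):
        base = HitTable(pd.DataFrame(hit_rows("q1", 1e-8, 1e-12)))
        _, flagged_before, _ = alien_index_filter(base)
        better = HitTable(pd.DataFrame(hit_rows("q1", 1e-8, 1e-40)))
        _, flagged_after, _ = alien_index_filter(better)
        assert set(flagged_before) <= set(flagged_after)

    def test_round_trip_through_files(self, tmp_path):
        hits = tmp_path / "hits.tsv"
        hits.write_text(
            "q1\tin1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-30\t120\n"
            "q1\tout1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-60\t150\n"
        )
        groups = tmp_path / "groups.tsv"
        groups.write_text("in1\tingroup\nout1\toutgroup\n")
        table = read_hit_table(hits, groups)
        _, flagged, _ = alien_index_filter(table)
        assert flagged == ["q1"]

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            HitTable(pd.DataFrame(hit_rows("q1", -1e-5, 1e-5)))


def random_orthogroup(rng, n_tips):
    """Random topology over tips that reuse a small taxon pool."""
    from phylorigins import Node, Phylogeny

    taxa = [f"T{j}" for j in range(max(2, n_tips - 3))]
    tips = []
    for i in range(n_tips):
        taxon = taxa[rng.integers(len(taxa))]
        tips.append(Node(label=f"{taxon}|s{i}", length=rng.uniform(0.1, 1.0)))
    while len(tips) > 1:
        a = tips.pop(rng.integers(len(tips)))
        b = tips.pop(rng.integers(len(tips))) if len(tips) else None
        parent = Node(length=rng.uniform(0.1, 1.0))
        parent.add_child(a)
        if b is not None:
            parent.add_child(b)
        tips.append(parent)
    root = tips[0]
    root.length = None
    return Phylogeny(root)


class TestPruneParalogs:
    def test_single_copy_tree_keeps_all_taxa(self):
        og = parse_newick("((A|1:1,B|1:1):1,(C|1:1,D|1:1):1);")
        part = prune_paralogs(og)
        assert part.members == {"A": "1", "B": "1", "C": "1", "D": "1"}

    def test_duplicated_taxon_picks_larger_subtree(self):
        og = parse_newick("(((A|1:1,B|1:1):1,C|1:1):1,(A|2:1,D|1:1):1);")
        part = prune_paralogs(og)
        assert sorted(part.members) == ["A", "B", "C"]
        assert part.members["A"] == "1"

    def test_tip_monophyletic_duplicates_count_once(self):
        og = parse_newick("(((A|x1:1,A|x22:1):1,B|1:1):1,C|1:1);")
        part = prune_paralogs(og)
        assert sorted(part.members) == ["A", "B", "C"]
        assert part.members["A"] == "x22"  # longest-named representative

    def test_support_collapse_dissolves_weak_groupings(self):
        og = parse_newick("(((A|1:1,A|2:1)0.1:1,B|1:1):1,A|3:1);")
        strict = prune_paralogs(og, support_collapse=0.0)
        collapsed = prune_paralogs(og, support_collapse=0.5)
        assert len(strict.members) == 2  # merged A pair + B
        assert len(collapsed.members) < len(strict.members)

    def test_worst_case_single_tip(self):
        og = parse_newick("(A|1:1,A|2:2);")
        part = prune_paralogs(og)
        assert len(part.members) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            og = random_orthogroup(rng, int(rng.integers(4, 11)))
            part = prune_paralogs(og)
            assert len(part.members) == bruteforce_single_copy_size(og)


def make_partitions(occupancies, n_taxa):
    parts = []
    for i, occ in enumerate(occupancies):
        k = round(occ * n_taxa)
        parts.append(Partition(
            name=f"p{i:02d}",
            members={f"t{j:03d}": f"s{j}" for j in range(k)},
            n_study_taxa=n_taxa,
        ))
    return parts


class TestOccupancyFilter:
    def test_boundary_is_strict(self):
        half, above = make_partitions([31 / 62, 32 / 62], 62)
        kept = occupancy_filter([half, above], 0.5)
        assert [p.name for p in kept] == [above.name]

    def test_stepped_occupancies(self):
        parts = make_partitions([i / 10 for i in range(1, 11)], 10)
        kept = occupancy_filter(parts, 0.5)
        assert len(kept) == 5

    def test_idempotent_and_partitioning(self):
        parts = make_partitions([0.2, 0.4, 0.6, 0.8], 10)
        kept = occupancy_filter(parts, 0.5)
        removed = [p for p in parts if p not in kept]
        assert occupancy_filter(kept, 0.5) == kept
        assert sorted(p.name for p in kept + removed) == sorted(
            p.name for p in parts
        )

    def test_empty_input(self):
        assert occupancy_filter([], 0.5) == []


class TestSupermatrix:
    def _partitions(self):
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        p1 = Partition("locus_a", {t: t for t in taxa},
                       {t: "A" * 100 for t in taxa}, 5)
        p2 = Partition("locus_b", {t: t for t in taxa[:4]},
                       {t: "C" * 50 for t in taxa[:4]}, 5)
        return taxa, [p1, p2]

    def test_lengths_and_boundaries(self):
        taxa, parts = self._partitions()
        sm = concatenate_supermatrix(parts, taxa)
        assert sm.length == 150
        assert sm.boundaries == [("locus_a", 1, 100), ("locus_b", 101, 150)]

    def test_missing_taxon_gap_filled(self):
        taxa, parts = self._partitions()
        sm = concatenate_supermatrix(parts, taxa)
        assert sm.rows["t5"].endswith("-" * 50)

    def test_round_trip_split(self):
        taxa, parts = self._partitions()
        back = concatenate_supermatrix(parts, taxa).split()
        assert [p.name for p in back] == ["locus_a", "locus_b"]
        for orig, rec in zip(parts, back):
            assert rec.alignment == orig.alignment

    def test_unequal_lengths_rejected(self):
        bad = Partition("bad", {"t1": "t1", "t2": "t2"})
        bad.alignment = {"t1": "AAAA", "t2": "AA"}
        with pytest.raises(ValueError, match="bad"):
            concatenate_supermatrix([bad], ["t1", "t2"])

    def test_partition_file_format(self):
        taxa, parts = self._partitions()
        text = concatenate_supermatrix(parts, taxa).partition_file()
        assert "PROT, locus_a = 1-100" in text


class TestOccupancyProfile:
    def test_double_counting_identity(self):
        parts = make_partitions([0.3, 0.5, 0.9], 10)
        prof = occupancy_profile(parts, [f"t{j:03d}" for j in range(10)])
        assert prof.taxon_counts.sum() == prof.partition_counts.sum()

    def test_clade_histogram_bins(self):
        taxa = [f"t{j:03d}" for j in range(10)]
        clade = taxa[:4]
        parts = make_partitions([0.1, 0.3, 0.6], 10)  # 1, 3, 6 taxa present
        prof = occupancy_profile(parts, taxa, {"focal": clade})
        assert prof.clade_histograms["focal"] == {1: 1, 3: 1, 4: 1}

    def test_unknown_clade_member_errors(self):
        parts = make_partitions([0.5], 10)
        with pytest.raises(ValueError, match="unknown"):
            occupancy_profile(parts, [f"t{j:03d}" for j in range(10)],
                              {"focal": ["nope"]})


class TestCladeFilter:
    def test_min_members_three_drops_two(self):
        taxa = [f"t{j:03d}" for j in range(10)]
        clade = set(taxa[:4])
        two, four = make_partitions([0.2, 0.6], 10)
        kept = clade_filter([two, four], clade, min_members=3)
        assert kept == [four]

    def test_min_zero_is_identity(self):
        parts = make_partitions([0.2, 0.6], 10)
        assert clade_filter(parts, {"t000"}, min_members=0) == parts

    def test_absent_clade_partitions_kept_by_default(self):
        taxa = [f"t{j:03d}" for j in range(10)]
        part = make_partitions([0.3], 10)[0]
        assert clade_filter([part], {"t009"}, min_members=3) == [part]
        assert clade_filter([part], {"t009"}, min_members=3,
                            drop_absent=True) == []


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = ("A", {"p1": "x", "p2": "y"})
        b = ("B", {"q1": "x", "q2": "y"})
        c = ("C", {"r1": "z"})
        rep = overlap_report([a, b])
        assert rep[frozenset(("A", "B"))] == 2
        rep2 = overlap_report([a, c])
        assert rep2[frozenset(("A", "C"))] == 0

    def test_triple_overlap(self):
        sets = [
            ("d1", {"p1": "a", "p2": "b", "p3": "c"}),
            ("d2", {"q1": "b", "q2": "c", "q3": "d"}),
            ("d3", {"r1": "c"}),
        ]
        rep = overlap_report(sets)
        assert rep[frozenset(("d1", "d2", "d3"))] == 1
        assert rep[frozenset(("d1", "d2"))] == 2

    def test_duplicates_deduplicated(self):
        rep = overlap_report([("A", {"p1": "x", "p2": "x"})])
        assert rep[frozenset(("A",))] == 1


class TestEnrichment:
    def test_identical_proportions_null(self):
        df = enrichment_test({"GO1": 5, "GO2": 5}, {"GO1": 50, "GO2": 50},
                             subset_total=10, background_total=100)
        assert np.allclose(df["odds_ratio"], 1.0)
        assert np.allclose(df["p_value"], 1.0)
        assert (df["call"] == "ns").all()

    def test_matches_hypergeometric_enumeration(self):
        df = enrichment_test({"GO1": 5}, {"GO1": 55},
                             subset_total=10, background_total=1010)
        want = fisher_two_sided(5, 5, 50, 950)
        assert df["p_value"].iloc[0] == pytest.approx(want, rel=1e-9)

    def test_zero_subset_large_background_is_depleted(self):
        df = enrichment_test({"GO1": 0, "GO2": 500}, {"GO1": 400, "GO2": 600},
                             subset_total=500, background_total=1000)
        row = df[df.term == "GO1"].iloc[0]
        assert row.call == "depleted"
        assert row.odds_ratio < 1

    def test_subset_exceeding_background_errors(self):
        with pytest.raises(ValueError):
            enrichment_test({"GO1": 10}, {"GO1": 5},
                            subset_total=20, background_total=50)
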