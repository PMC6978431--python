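"""Clumping, locus construction, universe, and locus-set enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pleioscan.lsea import (
    Clump,
    ClumpVariant,
    DEFAULT_EXCLUSIONS,
    EnrichmentResult,
    GeneAnnotation,
    IntervalGeneSet,
    LDTable,
    LocusInterval,
    LocusUniverse,
    Region,
    bh_adjust,
    build_interval_gene_sets,
    build_loci,
    build_universe,
    clump_variants,
    holm_adjust,
    hypergeom_upper_tail,
    lsea_enrich,
    read_gmt,
    shared_cluster_enrichments,
    write_gmt,
)
from pleioscan.trait_clustering import TraitClustering


def cv(vid, pos, p, chrom="1"):
    return ClumpVariant(variant_id=vid, chrom=chrom, pos=pos, pvalue=p)


def clump_at(start, end, chrom="1", name=None):
    """A clump spanning [start, end) in 0-based half-open coordinates."""
    a = cv(name or f"s{start}", start + 1, 1e-10, chrom=chrom)
    b = cv((name or f"s{start}") + "_r", end, 1e-9, chrom=chrom)
    return Clump(index_variant=a, members=[a, b], chrom=chrom)


def genes_of(rows):
    return GeneAnnotation(pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"]))


def reference_greedy_clump(variants, r2, r2_threshold, window_bp):
    """Independent naive restatement of the greedy clumping rule."""
    out = []
    left = {v.variant_id: v for v in variants}
    while left:
        idx = min(left.values(), key=lambda v: (v.pvalue, v.chrom, v.pos, v.variant_id))
        members = [
            v
            for v in left.values()
            if v.chrom == idx.chrom
            and abs(v.pos - idx.pos) <= window_bp
            and (v.variant_id == idx.variant_id
                 or r2.get(frozenset((idx.variant_id, v.variant_id)), 0.0) >= r2_threshold)
        ]
        for m in members:
            del left[m.variant_id]
        out.append((idx.variant_id, frozenset(m.variant_id for m in members)))
    return sorted(out)


class TestClumping:
    def test_worked_example(self):
        s1, s2, s3 = cv("s1", 100_000, 1e-12), cv("s2", 150_000, 1e-10), cv("s3", 200_000, 1e-9)
        ld = LDTable({("s1", "s2"): 0.8, ("s1", "s3"): 0.1, ("s2", "s3"): 0.2})
        clumps = clump_variants([s1, s2, s3], ld)
        got = {c.index_variant.variant_id: {m.variant_id for m in c.members} for c in clumps}
        assert got == {"s1": {"s1", "s2"}, "s3": {"s3"}}

    def test_single_variant_is_a_singleton_clump(self):
        clumps = clump_variants([cv("s1", 100, 1e-9)], LDTable({}))
        assert len(clumps) == 1 and clumps[0].members == [clumps[0].index_variant]

    def test_window_limits_assignment(self):
        s1, s2 = cv("s1", 100_000, 1e-12), cv("s2", 400_000, 1e-10)
        ld = LDTable({("s1", "s2"): 0.99})
        assert len(clump_variants([s1, s2], ld, window_kb=250)) == 2

    def test_matches_reference_greedy_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = 20
            variants = [
                cv(f"v{i}", int(rng.integers(1, 500_000)), float(rng.uniform(1e-12, 1e-8)),
                   chrom=str(rng.integers(1, 3)))
                for i in range(n)
            ]
            pairs = {}
            for a, b in itertools.combinations(variants, 2):
                if rng.random() < 0.3:
                    pairs[(a.variant_id, b.variant_id)] = float(rng.random())
            got = sorted(
                (c.index_variant.variant_id, frozenset(m.variant_id for m in c.members))
                for c in clump_variants(variants, LDTable(pairs), r2_threshold=0.5, window_kb=100)
            )
            want = reference_greedy_clump(
                variants, {frozenset(k): v for k, v in pairs.items()}, 0.5, 100_000
            )
            assert got == want


class TestBuildLoci:
    def test_mhc_overlap_is_dropped(self):
        clump = clump_at(29_000_000, 29_100_000, chrom="6")
        assert build_loci([clump]) == []
        # the same span outside chromosome 6 survives
        assert len(build_loci([clump_at(29_000_000, 29_100_000, chrom="1")])) == 1

    def test_hist1_overlap_is_dropped(self):
        assert build_loci([clump_at(26_000_000, 26_001_000, chrom="6")]) == []

    def test_seventy_percent_merge_rule_on_shorter_interval(self):
        merged = build_loci([clump_at(100, 200), clump_at(110, 190)], exclusions=())
        assert [(iv.start, iv.end) for iv in merged] == [(100, 200)]
        apart = build_loci([clump_at(100, 200), clump_at(150, 260)], exclusions=())
        assert [(iv.start, iv.end) for iv in apart] == [(100, 200), (150, 260)]

    def test_same_gene_merges_distant_intervals(self):
        genes = genes_of([("1", 50, 500, "G")])
        merged = build_loci([clump_at(100, 150), clump_at(400, 450)], genes=genes, exclusions=())
        assert [(iv.start, iv.end) for iv in merged] == [(100, 450)]

    def test_malformed_gene_annotation_is_an_error(self):
        with pytest.raises(ValueError):
            genes_of([("1", 500, 50, "G")])


class TestUniverse:
    def test_overlapping_trait_loci_are_merged(self):
        u = build_universe(
            {"T1": [LocusInterval("1", 100, 200)], "T2": [LocusInterval("1", 150, 300)]}
        )
        assert [(iv.start, iv.end) for iv in u.intervals] == [(100, 300)]

    def test_disjoint_loci_pass_through(self):
        u = build_universe({"T1": [LocusInterval("1", 100, 200), LocusInterval("2", 100, 200)]})
        assert len(u) == 2

    def test_idempotent_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            loci = [
                LocusInterval(str(rng.integers(1, 3)), s, s + int(rng.integers(10, 2000)))
                for s in rng.integers(0, 10_000, size=15)
            ]
            once = build_universe({"T": loci})
            twice = build_universe({"T": once.intervals})
            assert [(iv.chrom, iv.start, iv.end) for iv in once.intervals] == [
                (iv.chrom, iv.start, iv.end) for iv in twice.intervals
            ]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            build_universe({"T1": []})


def disjoint_universe(n, chrom="1", width=100, gap=100):
    return LocusUniverse(
        [LocusInterval(chrom, i * (width + gap), i * (width + gap) + width) for i in range(n)]
    )


class TestIntervalGeneSets:
    def test_interval_counted_once_per_set(self):
        u = disjoint_universe(3)
        genes = genes_of([("1", 10, 30, "G1"), ("1", 40, 60, "G2")])  # both inside u0
        sets = build_interval_gene_sets({"S": ["G1", "G2"]}, genes, u)
        assert sets[0].universe_members == frozenset({0})

    def test_set_without_universe_overlap_is_empty(self):
        u = disjoint_universe(3)
        genes = genes_of([("2", 10, 30, "G1")])
        sets = build_interval_gene_sets({"S": ["G1", "MISSING"]}, genes, u)
        assert sets[0].universe_members == frozenset()

    def test_membership_matches_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        u = disjoint_universe(12)
        gene_rows = [
            ("1", int(s), int(s) + int(rng.integers(5, 400)), f"G{i}")
            for i, s in enumerate(rng.integers(0, 2500, size=30))
        ]
        genes = genes_of(gene_rows)
        gene_sets = {
            f"S{k}": [f"G{i}" for i in rng.choice(30, size=6, replace=False)] for k in range(5)
        }
        sets = build_interval_gene_sets(gene_sets, genes, u)
        for s in sets:
            expected = set()
            for sym in gene_sets[s.set_name]:
                c, gs, ge, _ = next(r for r in gene_rows if r[3] == sym)
                for j, iv in enumerate(u.intervals):
                    if iv.chrom == c and gs < iv.end and ge > iv.start:
                        expected.add(j)
            assert s.universe_members == frozenset(expected)


class TestEnrichment:
    def test_hypergeometric_worked_examples(self):
        assert hypergeom_upper_tail(3, 10, 4, 3) == pytest.approx(4 / 120)
        assert hypergeom_upper_tail(0, 10, 4, 3) == 1.0
        assert hypergeom_upper_tail(2, 6, 3, 2) == pytest.approx(3 / 15)

    def test_lsea_enrich_counts_and_pvalue(self):
        u = disjoint_universe(10)
        sets = [IntervalGeneSet("S", frozenset({0, 1, 2, 3})), IntervalGeneSet("E", frozenset())]
        query = [LocusInterval("1", iv.start, iv.end) for iv in u.intervals[:3]]
        results = {r.set_name: r for r in lsea_enrich(query, sets, u)}
        assert (results["S"].F, results["S"].n_query, results["S"].K_set) == (3, 3, 4)
        assert results["S"].pvalue == pytest.approx(4 / 120)
        assert results["E"].F == 0 and results["E"].pvalue == 1.0

    def test_query_outside_universe_is_a_contract_violation(self):
        u = disjoint_universe(3)
        with pytest.raises(ValueError, match="overlaps no universe interval"):
            lsea_enrich([LocusInterval("9", 0, 10)], [], u)

    def test_pvalue_monotonicity(self):
        # with n, K fixed: p non-increasing in F, and non-increasing in N
        # (a larger universe makes a given overlap more surprising)
        for F in range(0, 4):
            assert hypergeom_upper_tail(F + 1, 20, 8, 5) <= hypergeom_upper_tail(F, 20, 8, 5)
        for N in range(10, 30):
            assert hypergeom_upper_tail(3, N + 1, 8, 5) <= hypergeom_upper_tail(3, N, 8, 5)

    def test_statistic_bounds(self, small_result):
        for r in small_result.pleiotropic_enrichment:
            assert 0 <= r.F <= min(r.n_query, r.K_set)
            assert 0 < r.pvalue <= 1
            assert r.p_adjusted >= r.pvalue - 1e-15


class TestHolm:
    def test_worked_example(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_and_capped(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.5])

    def test_bh_is_less_conservative_than_holm(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) <= holm_adjust(p) + 1e-12).all()


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = {"A": ["G1", "G2"], "B": ["G3"]}
        write_gmt(tmp_path / "s.gmt", sets)
        assert read_gmt(tmp_path / "s.gmt") == sets

    def test_malformed_line_is_an_error(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("ONLY_NAME\n")
        with pytest.raises(ValueError, match="malformed GMT"):
            read_gmt(tmp_path / "bad.gmt")


class TestSharedClusterEnrichments:
    @staticmethod
    def result(name, p_adj):
        return EnrichmentResult(name, 1, 1, 1, 10, p_adj, p_adjusted=p_adj)

    def test_set_enriched_in_two_traits_is_retained(self):
        clustering = TraitClustering(
            {"T1": "A", "T2": "A", "T3": "A"}, k=1, silhouette_profile={}
        )
        per_trait = {
            "T1": [self.result("S", 0.01), self.result("D", 0.2)],
            "T2": [self.result("S", 0.5)],
            "T3": [self.result("S", 0.04), self.result("D", 0.01)],
        }
        table = shared_cluster_enrichments(per_trait, clustering)
        assert table.to_dict("records") == [
            {"cluster_id": "A", "set": "S", "n_enriched_traits": 2}
        ]

    def test_singleton_cluster_yields_no_rows(self):
        clustering = TraitClustering({"T1": "A"}, k=1, silhouette_profile={})
        table = shared_cluster_enrichments({"T1": [self.result("S", 0.001)]}, clustering)
        assert table.empty

    def test_planted_shared_set_retained_and_decoys_excluded(self):
        # three traits in one cluster; two of them query loci concentrated in
        # the planted set, decoy sets cover disjoint universe regions
        u = disjoint_universe(40)
        sets = [IntervalGeneSet("PLANTED", frozenset(range(10)))] + [
            IntervalGeneSet(f"D{k}", frozenset(range(10 * k, 10 * k + 10))) for k in (1, 2, 3)
        ]
        query_of = {
            "T1": range(0, 8),  # 8/8 loci in the planted set
            "T2": range(20, 28),  # none
            "T3": list(range(0, 7)) + [35],  # 7/8
        }
        per_trait = {
            t: lsea_enrich(
                [LocusInterval("1", u.intervals[i].start, u.intervals[i].end) for i in idx],
                sets, u,
            )
            for t, idx in query_of.items()
        }
        clustering = TraitClustering(
            {"T1": "A", "T2": "A", "T3": "A"}, k=1, silhouette_profile={}
        )
        table = shared_cluster_enrichments(per_trait, clustering, alpha=0.05)
        assert table.to_dict("records") == [
            {"cluster_id": "A", "set": "PLANTED", "n_enriched_traits": 2}
        ]
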