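import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipregulon.annotate import PeakAnnotation, annotate_all
from chipregulon.concordance import MergedPeak
from chipregulon.enrich import (
    category_table,
    compare_lists,
    expected_count,
    fisher_2x2,
    genelist_enrichment,
)
from chipregulon.formats import GeneList, GeneRecord, GenomeModel, ValidationError


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)
                / math.comb(n, r1))

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-7))


class TestExpectedCount:
    def test_zero_category(self):
        assert expected_count(0, 1393, 7379) == (0.0, 0)

    def test_linear_in_category_size(self):
        raw1, _ = expected_count(100, 500, 5000)
        raw2, _ = expected_count(200, 500, 5000)
        assert raw2 == 2 * raw1

    def test_partition_sums_to_near_total(self, rng):
        total = 5000
        sizes = rng.multinomial(total, np.full(7, 1 / 7))
        raws = [expected_count(int(s), 830, total)[0] for s in sizes]
        assert sum(raws) == pytest.approx(830)

    def test_zero_universe_rejected(self):
        with pytest.raises(ValidationError):
            expected_count(10, 5, 0)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_2x2(5, 5, 5, 5) == 1.0

    def test_tiny_table_enumeration(self):
        # 3 tables share margins (2,2),(2,2); the observed one has prob 1/6,
        # the opposite diagonal 1/6, the middle 4/6 -> two-sided p = 1/3
        assert fisher_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_2x2(-1, 2, 3, 4)

    @given(a=st.integers(0, 15), b=st.integers(0, 15),
           c=st.integers(0, 15), d=st.integers(0, 15))
    @settings(max_examples=120, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return  # degenerate margins
        assert fisher_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7)

    @given(a=st.integers(0, 20), b=st.integers(0, 20),
           c=st.integers(0, 20), d=st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_symmetries(self, a, b, c, d):
        p = fisher_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_2x2(a, c, b, d))  # transpose
        assert p == pytest.approx(fisher_2x2(d, c, b, a))  # row+col swap


def make_universe(n_genes=60, categories=("c1", "c2"), seed=0):
    rng = np.random.default_rng(seed)
    genes = []
    pos = 100
    for i in range(n_genes):
        cat = categories[int(rng.integers(len(categories)))]
        genes.append(GeneRecord(f"g{i}", "+", pos, pos + 500, category=cat))
        pos += 1000
    return GenomeModel("chr", pos + 100, genes)


def annotations_for(genome, hit_gene_ids):
    """Minimal annotations giving each listed gene one promoter hit."""
    anns = []
    for rank, gid in enumerate(sorted(hit_gene_ids), 1):
        g = genome.gene(gid)
        coord = g.tsc - 50
        mp = MergedPeak(coordinate=coord, replicate_coordinates=(coord, coord),
                        replicate_ranks=(rank, rank), replicate_distance=0,
                        overall_rank=rank)
        anns.append(PeakAnnotation(mp, "noncoding", [(gid, -50)],
                                   [(gid, -50)], False))
    return anns


class TestCategoryTable:
    def test_single_category_no_contrast(self):
        genome = make_universe(categories=("only",))
        anns = annotations_for(genome, genome.gene_ids[:10])
        df = category_table(anns, genome)
        row = df[df["label"] == "only"].iloc[0]
        assert row["n_observed"] == 10
        assert row["p_value"] == 1.0

    def test_raw_expected_sums_to_near_total(self):
        genome = make_universe(categories=("c1", "c2", "c3"), seed=4)
        anns = annotations_for(genome, genome.gene_ids[::3])
        df = category_table(anns, genome)
        body = df[df["label"] != "Total"]
        near_total = df[df["label"] == "Total"]["n_observed"].iloc[0]
        assert body["n_expected_raw"].sum() == pytest.approx(near_total)

    def test_planted_category_is_most_significant(self):
        rng = np.random.default_rng(8)
        genome = make_universe(n_genes=200, categories=("hot", "c2", "c3"),
                               seed=8)
        hot = [g.gene_id for g in genome.genes if g.category == "hot"]
        rest = [g.gene_id for g in genome.genes if g.category != "hot"]
        hits = set(rng.choice(hot, size=min(40, len(hot)), replace=False)) | \
            set(rng.choice(rest, size=10, replace=False))
        df = category_table(annotations_for(genome, hits), genome)
        body = df[df["label"] != "Total"]
        assert body.loc[body["p_value"].idxmin(), "label"] == "hot"


class TestGeneListEnrichment:
    def test_all_genes_list_gives_p_one(self):
        genome = make_universe()
        anns = annotations_for(genome, genome.gene_ids[:20])
        row = genelist_enrichment(anns, GeneList("all", set(genome.gene_ids)),
                                  genome)
        assert row.p_value == 1.0
        assert row.n_observed == 20

    def test_empty_list_rejected(self):
        genome = make_universe()
        with pytest.raises(ValidationError):
            genelist_enrichment([], GeneList("empty", set()), genome)

    def test_depletion_detected_two_sided(self):
        genome = make_universe(n_genes=300, seed=2)
        hits = set(genome.gene_ids[:150])
        disjoint = GeneList("cold", set(genome.gene_ids[200:260]))
        row = genelist_enrichment(annotations_for(genome, hits), disjoint,
                                  genome)
        assert row.n_observed == 0
        assert row.p_value <= 0.05

    def test_operon_collapse_changes_margin(self, dataset):
        genome = dataset.genome
        operon_map = {g.gene_id: (g.operon_id, g.operon_position)
                      for g in genome.genes if g.operon_id}
        downstream = {g for g, (_, pos) in operon_map.items() if pos > 1}
        members = set(list(downstream)[:20]) | set(genome.gene_ids[:30])
        anns, _ = annotate_all(
            [MergedPeak(coordinate=s.coordinate,
                        replicate_coordinates=(s.coordinate, s.coordinate),
                        replicate_ranks=(i + 1, i + 1), replicate_distance=0,
                        overall_rank=i + 1)
             for i, s in enumerate(dataset.true_sites)], genome)
        plain = genelist_enrichment(anns, GeneList("l", members), genome)
        collapsed = genelist_enrichment(anns, GeneList("l", members), genome,
                                        operon_map, collapse_operons=True)
        assert collapsed.n_genome < plain.n_genome


class TestTypeIError:
    def test_null_false_positive_rate(self):
        # with no planted enrichment the fraction of category rows with
        # p < 0.05 stays near or below the nominal level (exact tests are
        # conservative)
        rng = np.random.default_rng(123)
        n_rows = sig = 0
        for rep in range(200):
            genome = make_universe(n_genes=80,
                                   categories=("a", "b", "c", "d"),
                                   seed=int(rng.integers(2**31)))
            hits = set(rng.choice(genome.gene_ids, size=20, replace=False))
            df = category_table(annotations_for(genome, hits), genome)
            body = df[df["label"] != "Total"]
            n_rows += len(body)
            sig += int((body["p_value"] < 0.05).sum())
        assert sig / n_rows <= 0.07


class TestCompareLists:
    def test_set_algebra(self):
        a, b = GeneList("a", {"g1", "g2"}), GeneList("b", {"g2", "g3"})
        assert compare_lists(a, b) == (["g2"], ["g1"], ["g3"])

    def test_disjoint_and_subset(self):
        a, b = GeneList("a", {"g1"}), GeneList("b", {"g2"})
        assert compare_lists(a, b)[0] == []
        sub, sup = GeneList("s", {"g1"}), GeneList("S", {"g1", "g2"})
        assert compare_lists(sub, sup)[1] == []
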