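import numpy as np
import pytest

from chipregulon import formats
from chipregulon.annotate import promoter_hits
from chipregulon.concordance import filter_concordant
from chipregulon.formats import ValidationError
from chipregulon.motif import scan_iupac
from chipregulon.peakcall import call_peaks
from chipregulon.synthetic import (
    expand_pattern,
    make_dataset,
    make_gene_lists,
    make_genome,
    plant_sites,
    sample_motif_instance,
    simulate_reads,
    simulate_replicate_peaks,
)

PATTERN = expand_pattern("TGTYN8RAC")


class TestMakeGenome:
    def test_coding_fraction_near_request(self):
        genome, seq, _ = make_genome(n_genes=200, coding_fraction=0.9, seed=1)
        assert genome.coding_fraction() == pytest.approx(0.9, abs=0.02)
        assert len(seq) == genome.length

    def test_byte_reproducible(self, tmp_path):
        files = []
        for run in range(2):
            genome, seq, _ = make_genome(n_genes=100, seed=42)
            fa = tmp_path / f"g{run}.fasta"
            gff = tmp_path / f"g{run}.gff3"
            formats.write_fasta("chr", seq, fa)
            formats.write_gff3(genome, gff)
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]

    def test_all_forward_when_requested(self):
        genome, _, _ = make_genome(n_genes=50, forward_probability=1.0, seed=0)
        assert all(g.strand == "+" for g in genome.genes)

    def test_gc_content(self):
        _, seq, _ = make_genome(n_genes=100, gc_content=0.69, seed=3)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.69, abs=0.02)

    def test_operons_are_same_strand_and_contiguous(self):
        genome, _, operon_map = make_genome(n_genes=300, seed=7)
        assert operon_map  # some operons exist at default probability
        by_op = {}
        for gid, (op, pos) in operon_map.items():
            by_op.setdefault(op, []).append((pos, gid))
        for op, members in by_op.items():
            members.sort()
            strands = {genome.gene(g).strand for _, g in members}
            assert len(strands) == 1
            assert [p for p, _ in members] == list(range(1, len(members) + 1))

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            make_genome(coding_fraction=1.5)
        with pytest.raises(ValidationError):
            make_genome(n_genes=0)


class TestPlantSites:
    def test_full_promoter_bias_all_sites_hit_promoters(self):
        genome, seq, _ = make_genome(n_genes=200, seed=2)
        _, sites = plant_sites(genome, seq, n_sites=60, promoter_bias=1.0,
                               seed=2)
        for s in sites:
            hits, _ = promoter_hits(s.coordinate, genome, (-400, 100))
            assert any(g == s.target_gene for g, _ in hits)

    def test_motif_written_at_recorded_offset(self):
        genome, seq, _ = make_genome(n_genes=200, seed=3)
        seq2, sites = plant_sites(genome, seq, n_sites=60, seed=3)
        w = len(PATTERN)
        for s in sites:
            assert seq2[s.motif_offset:s.motif_offset + w] == s.motif_text
            # the planted text matches the pattern on one strand
            assert scan_iupac(s.motif_text, PATTERN)

    def test_unbiased_sites_hit_promoters_at_geometric_rate(self):
        genome, seq, _ = make_genome(n_genes=400, seed=4)
        _, sites = plant_sites(genome, seq, n_sites=150, promoter_bias=0.0,
                               seed=4)
        n_hit = sum(bool(promoter_hits(s.coordinate, genome, (-400, 100))[0])
                    for s in sites)
        # upper bound: 501 window bp per gene over the genome (windows overlap)
        expected_max = 400 * 501 / genome.length
        assert n_hit / len(sites) < expected_max + 0.1

    def test_sampled_instances_match_pattern(self, rng):
        for _ in range(50):
            assert scan_iupac(sample_motif_instance(rng), PATTERN,
                              both_strands=False)


class TestReplicatePeaks:
    def _sites(self, n=100, spacing=5000):
        from chipregulon.synthetic import TrueSite

        return [TrueSite(i, 1000 + spacing * i, 0, "", "+", None, None,
                         strength=float(10 + i))
                for i in range(n)]

    def test_zero_jitter_full_recovery(self):
        sites = self._sites()
        r1, r2, shared = simulate_replicate_peaks(
            sites, genome_length=10**6, shared_fraction=1.0, jitter_scale=0.0,
            n_false_per_replicate=0, seed=0)
        merged = filter_concordant(r1, r2, 0)
        assert len(merged) == len(sites)
        assert sorted(m.coordinate for m in merged) == \
               sorted(s.coordinate for s in sites)
        assert shared == [s.site_id for s in sites]

    def test_shared_fraction_respected(self):
        sites = self._sites(200)
        _, _, shared = simulate_replicate_peaks(
            sites, 10**7, shared_fraction=0.8, seed=1)
        assert len(shared) == 160

    def test_false_peak_chance_collisions_are_rare(self):
        # unshared uniform false peaks pair only by chance; expected survivor
        # count ~ n_false * (density of other replicate) * 2 * cutoff
        rng = np.random.default_rng(9)
        L = 10**7
        n_false = 300
        f1 = [(int(c), 1.0) for c in rng.integers(0, L, n_false)]
        f2 = [(int(c), 1.0) for c in rng.integers(0, L, n_false)]
        r1 = formats.build_peaks(f1, "r1")
        r2 = formats.build_peaks(f2, "r2")
        merged = filter_concordant(r1, r2, 65)
        expected = n_false * (n_false / L) * 2 * 65
        assert len(merged) <= max(5, 5 * expected)

    def test_true_sites_score_higher_than_false_peaks(self):
        genome, seq, _ = make_genome(n_genes=200, seed=5)
        _, sites = plant_sites(genome, seq, n_sites=50, seed=5)
        r1, _, _ = simulate_replicate_peaks(sites, genome.length,
                                            n_false_per_replicate=50, seed=5)
        scores = sorted(p.enrichment for p in r1)
        median = scores[len(scores) // 2]
        true_like = sum(1 for s in scores if s > median)
        assert true_like >= len(scores) * 0.4  # bimodal score mix


class TestGeneLists:
    def test_validation_errors(self, dataset):
        genome = dataset.genome
        hits = {s.target_gene for s in dataset.true_sites if s.target_gene}
        with pytest.raises(ValidationError):
            make_gene_lists(genome, hits, [("bad", 0, 1.0)])
        with pytest.raises(ValidationError):
            make_gene_lists(genome, hits, [("bad", 10**6, 1.0)])
        with pytest.raises(ValidationError):
            make_gene_lists(genome, hits, [("bad", 10, 50.0)])

    def test_planted_fold_realized_in_expectation(self, dataset):
        genome = dataset.genome
        hits = {s.target_gene for s in dataset.true_sites if s.target_gene}
        G, h = len(genome.genes), len(hits)
        base_rate = h / G
        counts = []
        for seed in range(30):
            lists, _ = make_gene_lists(genome, hits, [("l", 100, 1.7)],
                                       seed=seed)
            counts.append(len(lists["l"].members & hits))
        realized_fold = np.mean(counts) / (100 * base_rate)
        assert realized_fold == pytest.approx(1.7, abs=0.25)


class TestSimulateReads:
    def test_zero_sites_matches_control_distribution(self):
        chip, ctrl = simulate_reads(10**5, [], reads_per_site=0,
                                    background_depth=0.02, seed=0)
        from scipy import stats

        ks = stats.ks_2samp(chip.positions, ctrl.positions)
        assert ks.pvalue > 0.01

    def test_single_site_closed_loop_with_caller(self):
        from chipregulon.synthetic import TrueSite

        site = TrueSite(0, 50000, 0, "", "+", None, None, 1.0)
        chip, ctrl = simulate_reads(10**5, [site], reads_per_site=500,
                                    background_depth=0.01, seed=1)
        peaks = call_peaks(chip, ctrl, genome_length=10**5)
        assert len(peaks) == 1
        assert abs(peaks[0].coordinate - 50000) <= 50

    def test_strand_balance(self):
        from chipregulon.synthetic import TrueSite

        site = TrueSite(0, 50000, 0, "", "+", None, None, 1.0)
        chip, _ = simulate_reads(10**5, [site], reads_per_site=400,
                                 background_depth=0.0, seed=2)
        n_fwd = int((chip.strands == "+").sum())
        # binomial(400, 1/2): 3 sigma ~ 30
        assert abs(n_fwd - 200) < 45


class TestFullDataset:
    def test_reproducible(self):
        a = make_dataset(seed=5, n_genes=100, n_sites=20,
                         n_false_per_replicate=5)
        b = make_dataset(seed=5, n_genes=100, n_sites=20,
                         n_false_per_replicate=5)
        assert a.sequence == b.sequence
        assert [(p.coordinate, p.enrichment) for p in a.replicate_peaks[0]] == \
               [(p.coordinate, p.enrichment) for p in b.replicate_peaks[0]]
        assert a.gene_lists.keys() == b.gene_lists.keys()
        for k in a.gene_lists:
            assert a.gene_lists[k].members == b.gene_lists[k].members

    def test_truth_json_round_trip(self, dataset, tmp_path):
        import json

        path = tmp_path / "truth.json"
        dataset.to_json(path)
        truth = json.loads(path.read_text())
        assert truth["length"] == dataset.genome.length
        assert len(truth["true_sites"]) == len(dataset.true_sites)
        assert truth["planted_enrichment"]["up_regulated"] == 1.7
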