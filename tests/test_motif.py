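import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipregulon.concordance import MergedPeak
from chipregulon.formats import ValidationError
from chipregulon.motif import (
    IUPAC,
    Motif,
    consensus_from_pwm,
    em_discover,
    extract_flanks,
    information_content,
    partition_ranked,
    reverse_complement,
    scan_iupac,
)
from chipregulon.synthetic import expand_pattern, sample_motif_instance

PATTERN = expand_pattern("TGTYN8RAC")


def merged_at(coord, rank):
    return MergedPeak(coordinate=coord, replicate_coordinates=(coord, coord),
                      replicate_ranks=(rank, rank), replicate_distance=0,
                      overall_rank=rank)


def planted_sequences(n, seed, length=101, width=15):
    """Random GC-rich backgrounds each carrying one sampled motif instance."""
    rng = np.random.default_rng(seed)
    out, offsets = [], []
    for _ in range(n):
        bg = "".join(rng.choice(list("ACGT"), length,
                                p=[.155, .345, .345, .155]))
        inst = sample_motif_instance(rng)
        if rng.random() < 0.5:
            inst = reverse_complement(inst)
        j = int(rng.integers(0, length - width + 1))
        out.append(bg[:j] + inst + bg[j + width:])
        offsets.append(j)
    return out, offsets


class TestExtractFlanks:
    GENOME = "".join(np.random.default_rng(0).choice(list("ACGT"), 5000))
    # (partition tests below build their own longer dummy genome)

    def test_length_and_center_base(self):
        flanks = extract_flanks([merged_at(2000, 1)], self.GENOME, 50)
        assert len(flanks[0].sequence) == 101
        assert flanks[0].sequence[50] == self.GENOME[2000]
        assert not flanks[0].clamped

    def test_edge_peak_clamped_and_flagged(self):
        flanks = extract_flanks([merged_at(10, 1)], self.GENOME, 50)
        assert flanks[0].clamped
        assert flanks[0].sequence == self.GENOME[:61]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            extract_flanks([merged_at(5000, 1)], self.GENOME, 50)


class TestPartitionRanked:
    def _flanks(self, n):
        return extract_flanks(
            [merged_at(100 + 7 * i, i + 1) for i in range(n)],
            "A" * 6000, 10)

    def test_ten_partitions_of_fifty(self):
        parts = partition_ranked(self._flanks(600), top_n=500, partition_size=50)
        assert [len(p) for p in parts] == [50] * 10
        ranks = [f.peak_rank for p in parts for f in p]
        assert ranks == sorted(ranks) == list(range(1, 501))

    def test_ragged_tail(self):
        parts = partition_ranked(self._flanks(55), top_n=55, partition_size=50)
        assert [len(p) for p in parts] == [50, 5]

    def test_single_partition(self):
        parts = partition_ranked(self._flanks(30), top_n=30, partition_size=100)
        assert [len(p) for p in parts] == [30]


class TestScanIUPAC:
    def test_forward_hit(self):
        hits = scan_iupac("TGTCAAAAAAAAGAC", PATTERN)
        assert any(h.strand == "+" and h.offset == 0 for h in hits)

    def test_reverse_complement_hit(self):
        hits = scan_iupac("GTCTTTTTTTTGACA", PATTERN)
        rev = [h for h in hits if h.strand == "-"]
        assert rev and rev[0].offset == 0
        assert rev[0].matched_text == "TGTCAAAAAAAAGAC"

    def test_single_mismatch_rejected(self):
        assert scan_iupac("TGTAAAAAAAAAGAC", PATTERN, both_strands=False) == []

    def test_invalid_code_rejected(self):
        with pytest.raises(ValidationError):
            scan_iupac("ACGT", "AXGT")

    def test_ambiguous_genome_base_fails_non_n_positions(self):
        assert scan_iupac("TNTCAAAAAAAAGAC", PATTERN, both_strands=False) == []
        # N in the genome is accepted at pattern N positions
        assert scan_iupac("TGTCNNNNNNNNGAC", PATTERN, both_strands=False)

    @given(st.text(alphabet="ACGT", min_size=15, max_size=60))
    @settings(max_examples=80, deadline=None)
    def test_strand_closure(self, seq):
        # scanning a sequence and its reverse complement gives mirror hits
        hits = scan_iupac(seq, PATTERN)
        rc_hits = scan_iupac(reverse_complement(seq), PATTERN)
        w = len(PATTERN)
        mirrored = sorted(
            (len(seq) - h.offset - w, {"+": "-", "-": "+"}[h.strand])
            for h in hits)
        assert mirrored == sorted((h.offset, h.strand) for h in rc_hits)


class TestInformationContent:
    @pytest.mark.parametrize("col,expected", [
        ([1, 0, 0, 0], 2.0),
        ([0.25, 0.25, 0.25, 0.25], 0.0),
        ([0.5, 0.5, 0, 0], 1.0),
    ])
    def test_uniform_background_values(self, col, expected):
        assert information_content(np.array([col]))[0] == pytest.approx(expected)

    def test_bounds(self, rng):
        pwm = rng.dirichlet(np.ones(4), size=20)
        ic = information_content(pwm)
        assert (ic >= -1e-12).all() and (ic <= 2 + 1e-12).all()


class TestConsensus:
    def test_dominant_base(self):
        pwm = np.array([[0.02, 0.02, 0.01, 0.95]])
        assert consensus_from_pwm(pwm, 0.8) == "T"

    def test_two_base_class(self):
        pwm = np.array([[0.03, 0.5, 0.02, 0.45]])
        assert consensus_from_pwm(pwm, 0.8) == "Y"

    def test_exact_threshold_three_base_class(self):
        # ACG sums to 0.8 exactly -> V by the >= rule, not N
        pwm = np.array([[0.3, 0.3, 0.2, 0.2]])
        assert consensus_from_pwm(pwm, 0.8) == "V"

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            consensus_from_pwm(np.array([[1, 0, 0, 0]]), 0.3)


class TestEMDiscover:
    def test_planted_exact_site_recovered(self):
        # every sequence carries the same exact instance; EM must lock on
        rng = np.random.default_rng(42)
        site = "TGTCAAAAAAAAGAC"
        seqs = []
        for _ in range(50):
            bg = "".join(rng.choice(list("ACGT"), 101,
                                    p=[.155, .345, .345, .155]))
            j = int(rng.integers(0, 101 - 15 + 1))
            seqs.append(bg[:j] + site + bg[j + 15:])
        motif, ll = em_discover(seqs, width=15, n_restarts=10, rng_seed=0)
        cons = motif.consensus_iupac(0.85)
        assert cons in (site, reverse_complement(site))

    def test_uniform_sequences_carry_little_information(self):
        # OOPS EM must place one occurrence per sequence even in pure noise,
        # so its null motifs are not flat; but the best spurious alignment of
        # 100 random sequences stays far below the ~2-bit conserved columns
        # that genuine planted sites produce
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("ACGT"), 101)) for _ in range(100)]
            motif, _ = em_discover(seqs, width=15, n_restarts=3, rng_seed=seed)
            assert motif.ic.max() < 1.6

    def test_input_order_invariance(self):
        seqs, _ = planted_sequences(30, seed=5)
        m1, ll1 = em_discover(seqs, width=15, n_restarts=1, rng_seed=3)
        m2, ll2 = em_discover(seqs[::-1], width=15, n_restarts=1, rng_seed=3)
        assert np.allclose(m1.pwm, m2.pwm, atol=1e-6)
        assert ll1 == pytest.approx(ll2)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            em_discover(["ACGTACGT"], width=15)

    def test_consensus_scan_recovers_planted_offsets(self):
        # closed loop: scan the discovered consensus back over the training set
        seqs, offsets = planted_sequences(50, seed=9)
        motif, _ = em_discover(seqs, width=15, n_restarts=10, rng_seed=9)
        cons = motif.consensus_iupac(0.85)
        recovered = 0
        for seq, j in zip(seqs, offsets):
            hits = scan_iupac(seq, cons)
            recovered += any(h.offset == j for h in hits)
        assert recovered >= int(0.9 * len(seqs))


def test_pwm_from_exact_sites_has_two_bits_at_conserved_positions():
    # zero-pseudocount PWM built directly from planted instances
    rng = np.random.default_rng(0)
    insts = [sample_motif_instance(rng) for _ in range(200)]
    counts = np.zeros((15, 4))
    for inst in insts:
        for j, b in enumerate(inst):
            counts[j, "ACGT".index(b)] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)
    motif = Motif(counts=counts, pwm=pwm, background=np.full(4, 0.25),
                  n_sites=200)
    conserved = [0, 1, 2, 13, 14]  # T G T ... A C are single-base positions
    for j in conserved:
        assert motif.ic[j] == pytest.approx(2.0)
    for j in range(4, 12):  # the N8 spacer
        assert motif.ic[j] < 0.2
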