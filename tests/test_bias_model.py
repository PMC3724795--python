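"""Window extraction, PWM construction and bias scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnasebias import bias_model as bm
from dnasebias.io_formats import GenomeSequence, Tag


def _single_column_pwm(p_a: float) -> bm.PWM:
    """1-column PWM putting probability p_a on A, rest split evenly."""
    rest = (1 - p_a) / 3
    p = np.array([p_a, rest, rest, rest])
    return bm.PWM(np.log2(p / 0.25)[:, None], np.full(4, 0.25), 0.0, bm.Window(0, 0))


class TestExtractWindow:
    def test_plus_strand_uniform_contig(self, all_a_genome):
        w = bm.extract_window(Tag("c1", 5, "+"), all_a_genome)
        assert w == "A" * 15

    def test_minus_strand_reverse_complement(self, toy_genome):
        # genome AACCGGTTAACCGGTTAACC; five_prime=12, window -1..+1 covers
        # positions 11..13 = "CGG"; reverse complement = "CCG"
        w = bm.extract_window(Tag("c1", 12, "-"), toy_genome, bm.Window(-1, 1))
        assert w == "CCG"

    def test_minus_strand_matches_per_base_oracle(self, toy_genome):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = toy_genome["c1"]
        window = bm.Window(-2, 3)
        for fp in range(4, 16):
            got = bm.extract_window(Tag("c1", fp, "-"), toy_genome, window)
            expect = "".join(
                comp[seq[fp - off]] for off in range(window.start_offset, 4)
            )
            assert got == expect

    def test_edge_overrun_is_null(self, all_a_genome):
        assert bm.extract_window(Tag("c1", 2, "+"), all_a_genome) is None

    def test_n_in_window_is_null(self):
        g = GenomeSequence({"c1": "AAAAAAAANAAAAAAAAAAA"})
        assert bm.extract_window(Tag("c1", 8, "+"), g, bm.Window(-2, 2)) is None

    def test_unknown_contig_raises(self, all_a_genome):
        with pytest.raises(KeyError):
            bm.extract_window(Tag("cX", 5, "+"), all_a_genome)


class TestCountMatrix:
    def test_identical_tags_count_once_each(self, all_a_genome):
        tags = [Tag("c1", 20, "+")] * 4
        cm = bm.build_count_matrix(tags, all_a_genome)
        assert cm.n_sequences == 4
        assert np.array_equal(cm.counts[0], np.full(15, 4))
        assert cm.counts[1:].sum() == 0

    def test_strands_accumulate_in_read_orientation(self):
        # + tag at 2 reads "AC"; - tag at 9 reads comp of (9,8) = comp("GT") = "CA"...
        # construct so both read "AC": minus tag window positions fp, fp-1 are T,G
        g = GenomeSequence({"c1": "ACAAAAAGTA"})
        window = bm.Window(0, 1)
        tags = [Tag("c1", 0, "+", 2), Tag("c1", 8, "-", 2)]
        assert bm.extract_window(tags[0], g, window) == "AC"
        assert bm.extract_window(tags[1], g, window) == "AC"
        cm = bm.build_count_matrix(tags, g, window)
        assert cm.n_sequences == 2
        assert cm.counts[0, 0] == 2 and cm.counts[1, 1] == 2

    def test_edge_tags_excluded(self, all_a_genome):
        tags = [Tag("c1", 2, "+"), Tag("c1", 20, "+")]
        cm = bm.build_count_matrix(tags, all_a_genome)
        assert cm.n_sequences == 1 and cm.n_excluded == 1

    def test_all_edge_tags_is_error(self, all_a_genome):
        with pytest.raises(ValueError, match="no usable"):
            bm.build_count_matrix([Tag("c1", 0, "+")], all_a_genome)

    def test_gather_matches_scalar_extraction(self, toy_genome):
        window = bm.Window(-2, 2)
        tags = [
            Tag("c1", fp, strand) for fp in range(20) for strand in "+-"
        ]
        codes, valid = bm.gather_windows(tags, toy_genome, window)
        for i, t in enumerate(tags):
            scalar = bm.extract_window_codes(t, toy_genome, window)
            if scalar is None:
                assert not valid[i]
            else:
                assert valid[i] and np.array_equal(codes[i], scalar)


class TestCountsToPwm:
    def test_counts_matching_expectation_give_zero_weights(self):
        cm = bm.CountMatrix(np.ones((4, 2), dtype=int), 4, bm.Window(0, 1))
        for pc in (0.0, 1.0, 10.0):
            pwm = bm.counts_to_pwm(cm, pseudocount=pc)
            assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_column(self):
        counts = np.array([[2], [1], [1], [0]])
        cm = bm.CountMatrix(counts, 4, bm.Window(0, 0))
        pwm = bm.counts_to_pwm(cm, pseudocount=1.0)
        # p_A = (2 + 0.25) / 5 = 0.45 -> log2(0.45/0.25)
        assert pwm.weights[0, 0] == pytest.approx(np.log2(0.45 / 0.25))
        assert pwm.weights[0, 0] == pytest.approx(0.8480, abs=1e-4)

    def test_expected_freqs_from_intervals(self, biased_truth):
        e = bm.expected_freqs_from_intervals(biased_truth.genome, biased_truth.open_regions)
        assert e.shape == (4,) and e.sum() == pytest.approx(1.0)
        assert np.all(e > 0.2)  # uniform genome

    def test_zero_pseudocount_with_zero_count_rejected(self):
        counts = np.array([[4], [0], [0], [0]])
        cm = bm.CountMatrix(counts, 4, bm.Window(0, 0))
        with pytest.raises(ValueError, match="zero-probability"):
            bm.counts_to_pwm(cm, pseudocount=0.0)

    @given(
        data=st.lists(
            st.lists(st.integers(0, 30), min_size=4, max_size=4),
            min_size=1,
            max_size=8,
        ),
        pc=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_columns_are_proper_probabilities(self, data, pc):
        """Invariant: sum_b 2**w * e == 1 for every column of every model."""
        arr = np.array(data).T
        n = int(arr.sum(axis=0).max())
        arr[0] += n - arr.sum(axis=0)  # pad A so columns agree
        cm = bm.CountMatrix(arr, n, bm.Window(0, arr.shape[1] - 1))
        e = np.array([0.2, 0.3, 0.3, 0.2])
        pwm = bm.counts_to_pwm(cm, expected_freqs=e, pseudocount=pc)
        colsum = (np.exp2(pwm.weights) * e[:, None]).sum(axis=0)
        assert np.allclose(colsum, 1.0, atol=1e-9)


class TestShiftTags:
    def test_plus_shifts_upstream(self, ):
        g = GenomeSequence({"c1": "A" * 1000})
        assert bm.shift_tags([Tag("c1", 500, "+")], g, 100)[0].five_prime == 400

    def test_minus_shifts_downstream(self):
        g = GenomeSequence({"c1": "A" * 1000})
        assert bm.shift_tags([Tag("c1", 500, "-")], g, 100)[0].five_prime == 600

    def test_out_of_contig_dropped(self):
        g = GenomeSequence({"c1": "A" * 1000})
        assert bm.shift_tags([Tag("c1", 50, "+")], g, 100) == []

    def test_shift_must_be_positive(self):
        g = GenomeSequence({"c1": "A" * 1000})
        with pytest.raises(ValueError):
            bm.shift_tags([Tag("c1", 50, "+")], g, 0)


class TestBiasScore:
    def test_m_equals_b_scores_zero(self, all_a_genome):
        counts = np.tile([[3], [1], [1], [1]], (1, 15))
        cm = bm.CountMatrix(counts, 6, bm.Window())
        pwm = bm.counts_to_pwm(cm)
        assert bm.bias_score(Tag("c1", 20, "+"), pwm, pwm, all_a_genome) == 0.0

    def test_single_column_probability_ratio(self):
        g = GenomeSequence({"c1": "AAAA"})
        m = _single_column_pwm(0.8)
        b = _single_column_pwm(0.2)
        s = bm.bias_score(Tag("c1", 1, "+"), m, b, g)
        assert s == pytest.approx(np.log2(0.8 / 0.2))
        assert s == pytest.approx(2.0)

    def test_additivity_over_columns(self, toy_genome):
        rng = np.random.default_rng(1)
        def rand_pwm(window):
            p = rng.dirichlet(np.ones(4), size=window.width).T
            return bm.PWM(np.log2(p / 0.25), np.full(4, 0.25), 0.0, window)
        m2, b2 = rand_pwm(bm.Window(0, 1)), rand_pwm(bm.Window(0, 1))
        tag = Tag("c1", 4, "+")
        total = bm.bias_score(tag, m2, b2, toy_genome)
        parts = 0.0
        for j in range(2):
            m1 = bm.PWM(m2.weights[:, [j]], m2.expected_freqs, 0.0, bm.Window(0, 0))
            b1 = bm.PWM(b2.weights[:, [j]], b2.expected_freqs, 0.0, bm.Window(0, 0))
            parts += bm.bias_score(Tag("c1", 4 + j, "+"), m1, b1, toy_genome)
        assert total == pytest.approx(parts)

    def test_window_mismatch_rejected(self):
        m = _single_column_pwm(0.5)
        b = bm.PWM(np.zeros((4, 2)), np.full(4, 0.25), 0.0, bm.Window(0, 1))
        with pytest.raises(ValueError, match="window"):
            bm.score_windows(np.zeros((1, 1), dtype=np.uint8), m, b)

    def test_edge_tag_scores_nan(self, all_a_genome):
        m = b = _single_column_pwm(0.5)
        m15 = bm.PWM(np.zeros((4, 15)), np.full(4, 0.25), 0.0, bm.Window())
        scores = bm.score_tags([Tag("c1", 0, "+"), Tag("c1", 20, "+")], m15, m15, all_a_genome)
        assert np.isnan(scores[0]) and scores[1] == 0.0


class TestStrandSymmetry:
    def test_scores_invariant_under_genome_reverse_complement(self, biased_truth, bias_models):
        """Reverse-complementing the genome and mirroring every tag leaves
        every bias score unchanged."""
        m, b = bias_models
        genome = biased_truth.genome
        tags = biased_truth.tags[:500]
        scores = bm.score_tags(tags, m, b, genome)
        rc = genome.reverse_complement()
        L = genome.lengths["chrS"]
        flipped = [
            Tag(t.contig, L - 1 - t.five_prime, "-" if t.strand == "+" else "+", t.length)
            for t in tags
        ]
        rc_scores = bm.score_tags(flipped, m, b, rc)
        assert np.allclose(scores, rc_scores, equal_nan=True)


class TestScoreSignLaw:
    def test_mean_score_converges_to_kl_divergences(self, bias_models):
        """Windows sampled from M score +KL(M||B) on average; windows
        sampled from B score -KL(B||M), each within 3 standard errors."""
        m, b = bias_models
        pm, pb = m.probabilities, b.probabilities
        kl_mb = float((pm * np.log2(pm / pb)).sum())
        kl_bm = float((pb * np.log2(pb / pm)).sum())
        n = 20_000
        for probs, expected, sign in ((pm, kl_mb, 1), (pb, kl_bm, -1)):
            wins = bm.sample_windows_from_probs(probs, n, seed=42)
            scores = bm.score_windows(wins, m, b)
            se = scores.std(ddof=1) / np.sqrt(n)
            assert abs(scores.mean() - sign * expected) < 3 * se
        assert kl_mb >= 0 and kl_bm >= 0


class TestPositionInformation:
    def test_flat_column_zero_bits(self):
        cm = bm.CountMatrix(np.ones((4, 1), dtype=int), 4, bm.Window(0, 0))
        assert bm.position_information(cm)[0] == pytest.approx(0.0)

    def test_pure_column_two_bits(self):
        cm = bm.CountMatrix(np.array([[4], [0], [0], [0]]), 4, bm.Window(0, 0))
        assert bm.position_information(cm)[0] == pytest.approx(2.0)

    def test_half_half_column_one_bit(self):
        cm = bm.CountMatrix(np.array([[2], [2], [0], [0]]), 4, bm.Window(0, 0))
        assert bm.position_information(cm)[0] == pytest.approx(1.0)
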