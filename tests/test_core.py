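"""Unit tests for the scoring engines: oracle, blocked driver, guards."""

import numpy as np
import pytest

from swblock import (
    BlockBoundary,
    ConfigurationError,
    KernelConfig,
    ScoringScheme,
    Sequence,
    WidthOverflowError,
    check_width,
    min_int_width,
    pad_target,
    process_block,
    sw_score_blocked,
    sw_score_full,
)
from swblock.core import PAD_RESIDUE, sw_matrices

from conftest import random_pair


@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        ("ACGT", "ACGT", 4),   # identical: length x match
        ("", "ACGT", 0),       # empty matrix
        ("GGGG", "TTTT", 0),   # all-mismatch: no positive cell
        ("ACGT", "AGT", 2),    # best local alignment is the substring "GT"
    ],
)
def test_full_oracle_scores(scheme, s1, s2, expected):
    result = sw_score_full(Sequence("a", s1), Sequence("b", s2), scheme)
    assert result.score == expected


def test_full_oracle_zero_score_has_no_locus(scheme):
    result = sw_score_full(Sequence("a", "GGGG"), Sequence("b", "TTTT"), scheme)
    assert (result.max_i, result.max_j) == (0, 0)


def test_full_oracle_argmax_is_first_row_major(scheme):
    # two disjoint copies of the query: maxima tie at (4, 4) and (4, 9);
    # row-major tie-breaking must report the leftmost
    result = sw_score_full(
        Sequence("a", "ACGT"), Sequence("b", "ACGTTACGT"), scheme)
    assert result.score == 4
    assert (result.max_i, result.max_j) == (4, 4)


def test_substitution_rules():
    scheme = ScoringScheme(2, -1, 5, 2)
    assert scheme.substitution("A", "A") == 2
    assert scheme.substitution("A", "C") == -1
    assert scheme.substitution("N", "N") == -1  # non-ACGT never matches
    assert scheme.substitution(PAD_RESIDUE, PAD_RESIDUE) == -1


def test_negative_gap_penalties_rejected():
    with pytest.raises(ValueError):
        ScoringScheme(1, -3, -5, 2)


class TestPadTarget:
    def test_pads_to_next_multiple(self):
        padded = pad_target(Sequence("t", "ACGTACGTAC"), 4)
        assert len(padded) == 12
        assert padded.residues == "ACGTACGTAC" + PAD_RESIDUE * 2

    def test_exact_multiple_unchanged(self):
        seq = Sequence("t", "ACGTACGT")
        assert pad_target(seq, 4) is seq

    @pytest.mark.parametrize("seed", range(12))
    def test_padding_never_changes_score_or_locus(self, scheme, seed):
        s1, s2 = random_pair(seed, max_len=80)
        base = sw_score_full(s1, s2, scheme)
        padded = sw_score_full(s1, pad_target(s2, 7), scheme)
        assert (padded.score, padded.max_i, padded.max_j) == (
            base.score, base.max_i, base.max_j)


class TestProcessBlock:
    def test_single_cell_block(self, scheme):
        boundary, bmax, argmax = process_block(
            Sequence("a", "A"), Sequence("b", "A"), scheme,
            BlockBoundary.zero(1), KernelConfig(block_width=1))
        assert boundary.h_col.tolist() == [1]
        assert boundary.e_col.tolist() == [-2]  # max(0-7, 0-2)
        assert bmax == 1 and argmax == (1, 1)

    def test_all_pad_block_stays_zero(self, scheme):
        boundary, bmax, _ = process_block(
            Sequence("a", "ACGTACGT"), Sequence("b", PAD_RESIDUE * 4), scheme,
            BlockBoundary.zero(8), KernelConfig(block_width=4))
        assert bmax == 0
        assert (boundary.h_col == 0).all()

    def test_boundary_length_mismatch_rejected(self, scheme):
        with pytest.raises(ConfigurationError):
            process_block(Sequence("a", "ACGT"), Sequence("b", "AC"), scheme,
                          BlockBoundary.zero(3), KernelConfig(block_width=2))

    @pytest.mark.parametrize("seed", range(8))
    def test_boundaries_equal_oracle_columns(self, scheme, seed):
        """Each block's outgoing H/E column matches the full-matrix slice."""
        s1, s2 = random_pair(seed, max_len=120)
        bw = 5
        s2p = pad_target(s2, bw)
        H, E, _ = sw_matrices(s1, s2p, scheme)
        boundary = BlockBoundary.zero(len(s1))
        config = KernelConfig(block_width=bw)
        for b in range(len(s2p) // bw):
            block = Sequence("blk", s2p.residues[b * bw:(b + 1) * bw])
            boundary, _, _ = process_block(s1, block, scheme, boundary, config)
            np.testing.assert_array_equal(boundary.h_col, H[1:, (b + 1) * bw])
            np.testing.assert_array_equal(boundary.e_col, E[1:, (b + 1) * bw])


class TestBlockedEngine:
    def test_single_block_degenerate_case(self, scheme):
        s1 = Sequence("a", "ACGTTGCA")
        s2 = Sequence("b", "ACGATGCA")
        full = sw_score_full(s1, s2, scheme)
        one = sw_score_blocked(s1, s2, scheme, KernelConfig(block_width=len(s2)))
        assert (one.score, one.max_i, one.max_j) == (
            full.score, full.max_i, full.max_j)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_across_block_widths(self, scheme, seed):
        s1, s2 = random_pair(seed, max_len=300)
        full = sw_score_full(s1, s2, scheme)
        n = len(s2)
        for bw in (1, 7, 64, 256, n, n + 3):
            got = sw_score_blocked(s1, s2, scheme, KernelConfig(block_width=bw))
            assert (got.score, got.max_i, got.max_j) == (
                full.score, full.max_i, full.max_j), f"bw={bw}"

    def test_row_major_tie_break_across_blocks(self, scheme):
        # maxima tie in separate blocks; the leftmost column must win
        s1 = Sequence("a", "ACGT")
        s2 = Sequence("b", "ACGTTACGT")
        got = sw_score_blocked(s1, s2, scheme, KernelConfig(block_width=3))
        assert (got.score, got.max_i, got.max_j) == (4, 4, 4)

    def test_empty_inputs(self, scheme):
        r = sw_score_blocked(Sequence("a", ""), Sequence("b", "ACGT"), scheme)
        assert (r.score, r.max_i, r.max_j, r.cells) == (0, 0, 0, 0)

    def test_cells_and_metadata_use_unpadded_lengths(self, scheme):
        s1, s2 = Sequence("a", "ACGTA"), Sequence("b", "ACGTACG")
        r = sw_score_blocked(s1, s2, scheme, KernelConfig(block_width=4))
        assert (r.m, r.n, r.cells) == (5, 7, 35)

    def test_refuses_inadmissible_width_naming_minimum(self, scheme):
        s = Sequence("a", "ACGT" * 50)  # length 200 > 127
        with pytest.raises(WidthOverflowError) as exc:
            sw_score_blocked(s, s, scheme, KernelConfig(int_width=8))
        assert exc.value.min_width == 16
        assert "16" in str(exc.value)

    def test_nonnegative_mismatch_with_padding_rejected(self):
        s = Sequence("a", "ACGTA")
        with pytest.raises(ConfigurationError):
            sw_score_blocked(s, s, ScoringScheme(1, 0, 5, 2),
                             KernelConfig(block_width=3))


class TestWidthGuard:
    @pytest.mark.parametrize(
        "m, n, width, admissible",
        [
            (200, 200, 8, False),   # 200 > 127
            (100, 100, 8, True),    # 100 <= 127
            (10_000_000, 10_000_000, 32, True),
            (40_000, 40_000, 16, False),  # 40000 > 32767
            (32_767, 40_000, 16, True),
        ],
    )
    def test_admissibility(self, scheme, m, n, width, admissible):
        ok, bound = check_width(m, n, scheme, KernelConfig(int_width=width))
        assert ok is admissible
        assert bound == min(m, n) * scheme.match

    def test_bound_scales_with_match_score(self):
        config = KernelConfig(int_width=8)
        ok, bound = check_width(100, 500, ScoringScheme(2, -3, 5, 2), config)
        assert bound == 200 and not ok

    def test_min_int_width(self):
        assert min_int_width(100) == 8
        assert min_int_width(128) == 16
        assert min_int_width(40_000) == 32
        assert min_int_width(2**40) is None

    def test_kernel_config_max_values(self):
        assert KernelConfig(int_width=8).max_value == 127
        assert KernelConfig(int_width=16).max_value == 32767
        assert KernelConfig(int_width=32).max_value == 2147483647
        with pytest.raises(ConfigurationError):
            KernelConfig(int_width=64)

    @pytest.mark.parametrize("seed", range(5))
    def test_width_consistency(self, scheme, seed):
        """All admissible widths produce identical results."""
        s1, s2 = random_pair(seed, max_len=120)
        results = []
        for width in (8, 16, 32):
            config = KernelConfig(block_width=16, int_width=width)
            ok, _ = check_width(len(s1), len(s2), scheme, config)
            if ok:
                r = sw_score_blocked(s1, s2, scheme, config)
                results.append((r.score, r.max_i, r.max_j))
        assert len(set(results)) == 1


def test_external_aligner_agrees_with_oracle(scheme):
    """Biopython's PairwiseAligner as an independent check of the oracle.

    Its gap model charges open+extend for the first gap position, so a gap of
    length k costs 7 + 2(k-1) = 5 + 2k, identical to the affine model here.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-2)
    for seed in range(25):
        s1, s2 = random_pair(seed, max_len=150)
        ours = sw_score_full(s1, s2, scheme).score
        theirs = aligner.score(s1.residues, s2.residues)
        assert ours == theirs
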