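"""Divergence-mapping tests: affine-gap aligner against a brute-force
oracle, column scoring, the per-residue divergence scale, and B-factor
mapping onto a structural model."""

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hvkit.divergence import (
    AlignedPair,
    column_scores,
    count_substitutions,
    divergence_scale,
    global_align_affine,
    map_scale_to_structure,
    percent_identity,
)
from hvkit.orchestrator import SYNTHETIC_FASTA, _synthetic_pdb_text

BLOSUM62 = substitution_matrices.load("BLOSUM62")
OPEN, EXTEND = 8.0, 1.0


def oracle_best_score(a: str, b: str) -> float:
    """Exhaustive affine-gap global alignment score by recursion over all
    (substitution / gap-in-a / gap-in-b) paths with gap-state tracking.

    Independent of the production aligner: no dynamic-programming reuse of
    its matrices, just brute recursion with memoization on the state.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(float(BLOSUM62[a[i], b[j]]) + rec(i + 1, j + 1, "m"))
        if i < len(a):  # gap in b
            cost = EXTEND if state == "gb" else OPEN
            options.append(-cost + rec(i + 1, j, "gb"))
        if j < len(b):  # gap in a
            cost = EXTEND if state == "ga" else OPEN
            options.append(-cost + rec(i, j + 1, "ga"))
        return max(options)

    return rec(0, 0, "m")


class TestAlignerOracle:
    def test_small_derived_example(self):
        pair = global_align_affine("AAW", "AW")
        assert pair.score == 7.0  # 4 (A:A) + 11 (W:W) - 8 (one gap)
        assert pair.aligned_b.count("-") == 1

    def test_empty_query_costs_one_gap_run(self):
        pair = global_align_affine("A", "")
        assert pair.score == -8.0
        assert pair.aligned_b == "-"

    def test_identical_sequences_score_diagonal_sum(self):
        seq = "MKTWLE"
        pair = global_align_affine(seq, seq)
        assert "-" not in pair.aligned_a + pair.aligned_b
        assert pair.score == sum(float(BLOSUM62[c, c]) for c in seq)

    def test_matches_bruteforce_on_random_short_pairs(self):
        """Optimality check against exhaustive enumeration for all pairs of
        lengths <= 6 over a 4-letter alphabet (random seeded sample)."""
        rng = np.random.default_rng(0)
        alphabet = "ACDW"
        for _ in range(60):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            pair = global_align_affine(a, b)
            assert pair.score == oracle_best_score(a, b), (a, b)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            global_align_affine("AXJ?", "AW")


class TestColumnScores:
    def test_identical_columns_take_diagonal_values(self):
        pair = global_align_affine("MKW", "MKW")
        cols = column_scores(pair)
        assert cols.scores.tolist() == [
            float(BLOSUM62[c, c]) for c in "MKW"
        ]
        assert cols.gap_state == ["none"] * 3

    def test_gap_run_scoring(self):
        pair = AlignedPair(
            seq_a="AWWWA", seq_b="AA",
            aligned_a="AWWWA", aligned_b="A---A", score=float("nan"),
        )
        cols = column_scores(pair)
        assert cols.scores[1:4].tolist() == [-8.0, -1.0, -1.0]
        assert cols.gap_state[1:4] == ["open", "extend", "extend"]

    def test_random_alignment_matches_hand_lookup(self):
        rng = np.random.default_rng(3)
        letters = list("ARNDCQEGHILKMFPSTWYV")
        a = "".join(rng.choice(letters, 10))
        b = "".join(rng.choice(letters, 10))
        pair = AlignedPair(seq_a=a, seq_b=b, aligned_a=a, aligned_b=b,
                           score=float("nan"))
        cols = column_scores(pair)
        for k in range(10):
            assert cols.scores[k] == float(BLOSUM62[a[k], b[k]])

    def test_double_gap_column_rejected(self):
        pair = AlignedPair(seq_a="AW", seq_b="AW",
                           aligned_a="A-W", aligned_b="A-W", score=0.0)
        with pytest.raises(ValueError):
            column_scores(pair)

    def test_score_sum_consistency_with_aligner(self):
        """Total alignment score equals the sum of its column scores."""
        rng = np.random.default_rng(9)
        letters = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(10):
            a = "".join(rng.choice(letters, rng.integers(5, 25)))
            b = "".join(rng.choice(letters, rng.integers(5, 25)))
            pair = global_align_affine(a, b)
            cols = column_scores(pair)
            assert cols.scores.sum() == pytest.approx(pair.score)


class TestDivergenceScale:
    def _pair_from_scores(self, n):
        seq = "A" * n
        return AlignedPair(seq_a=seq, seq_b=seq, aligned_a=seq, aligned_b=seq,
                           score=float("nan"))

    def test_constant_scores_give_zero_scale(self):
        pair = global_align_affine("AAAA", "AAAA")
        scale = divergence_scale(column_scores(pair), pair)
        assert np.all(scale.values == 0.0)

    def test_window_one_is_identity_smoothing(self):
        pair = global_align_affine("AAWA", "AAAA")
        cols = column_scores(pair)
        scale = divergence_scale(cols, pair, window=1)
        d = cols.scores.mean() - cols.scores
        expected = (d - d.min()) / (d.max() - d.min())
        assert scale.values == pytest.approx(expected)

    def test_impulse_spreads_over_window(self):
        """A single divergent column yields a local maximum of 1 spread
        over the 5-residue window (hand-computed moving average)."""
        from hvkit.divergence import ColumnScores

        n = 11
        scores = np.full(n, 4.0)
        scores[5] = -6.0  # one impulse
        pair = self._pair_from_scores(n)
        cols = ColumnScores(scores=scores, gap_state=["none"] * n)
        scale = divergence_scale(cols, pair, window=5)
        assert scale.values[5] == 1.0
        # neighbors within the window share the smoothed impulse equally
        assert scale.values[4] == pytest.approx(scale.values[6])
        assert scale.values[3] == pytest.approx(scale.values[7])
        assert scale.values[0] == 0.0
        # hand computation: windowed mean at the impulse = (4*4 - 6)/5 - ...
        d = scores.mean() - scores
        sm5 = d[3:8].mean()
        sm0 = d[0]
        expected_peak_over_base = (sm5 - sm0)
        rng = scale.raw_range
        assert scale.values[5] - scale.values[0] == pytest.approx(
            expected_peak_over_base / (rng[1] - rng[0])
        )

    def test_bounds_reached_for_nonconstant_input(self):
        pair = global_align_affine("MKWLEDAARN", "MKALEDAARN")
        scale = divergence_scale(column_scores(pair), pair)
        assert scale.values.min() == 0.0
        assert scale.values.max() == 1.0

    def test_smoothing_is_a_contraction(self):
        from hvkit.divergence import _centered_moving_average

        rng = np.random.default_rng(4)
        for w in (3, 5, 7):
            x = rng.normal(size=40)
            y = _centered_moving_average(x, w)
            assert y.min() >= x.min() - 1e-12
            assert y.max() <= x.max() + 1e-12

    def test_gap_in_reference_penalty_assigned_to_flank(self):
        # insertion in seq_b relative to the reference (seq_a)
        pair = AlignedPair(
            seq_a="AAAA", seq_b="AAWAA",
            aligned_a="AA-AA"[:5].replace("AA-AA", "AA-AA"), aligned_b="AAWAA",
            score=float("nan"),
        )
        cols = column_scores(pair)
        scale = divergence_scale(cols, pair, window=1)
        # four reference residues despite five columns
        assert scale.values.size == 4
        assert scale.residue_numbers.tolist() == [1, 2, 3, 4]

    def test_even_window_rejected(self):
        pair = global_align_affine("AAAA", "AAAA")
        with pytest.raises(ValueError):
            divergence_scale(column_scores(pair), pair, window=4)


class TestIdentityAndSubstitutions:
    def test_identical_sequences_are_100_percent(self):
        pair = global_align_affine("MKTWLE", "MKTWLE")
        assert percent_identity(pair) == 100.0

    def test_half_identical_gapless(self):
        pair = AlignedPair(seq_a="AAAA", seq_b="AATT",
                           aligned_a="AAAA", aligned_b="AATT", score=0.0)
        assert percent_identity(pair) == 50.0

    def test_symmetry(self):
        a, b = SYNTHETIC_FASTA["toyA"], SYNTHETIC_FASTA["toyB"]
        assert percent_identity(global_align_affine(a, b)) == pytest.approx(
            percent_identity(global_align_affine(b, a))
        )
        assert count_substitutions(a, b) == count_substitutions(b, a)

    def test_point_substitution_counting(self):
        assert count_substitutions("MKTWLE", "MKTWLE") == 0
        assert count_substitutions("MKTWLE", "MKAWLE") == 1
        subs, gaps = count_substitutions("MKTWLE", "MKWLE", with_gaps=True)
        assert gaps >= 1


class TestStructureMapping:
    @pytest.fixture
    def toy_scale(self):
        a, b = SYNTHETIC_FASTA["toyA"], SYNTHETIC_FASTA["toyB"]
        pair = global_align_affine(a, b)
        return divergence_scale(column_scores(pair), pair)

    @pytest.fixture
    def toy_pdb(self, tmp_path):
        p = tmp_path / "toy_synthetic.pdb"
        p.write_text(_synthetic_pdb_text(len(SYNTHETIC_FASTA["toyA"])))
        return p

    def test_bfactor_round_trip(self, toy_scale, toy_pdb, tmp_path):
        import gemmi

        out = tmp_path / "mapped.pdb"
        unmatched = map_scale_to_structure(toy_scale, toy_pdb, out, chain="A")
        assert unmatched == []
        st = gemmi.read_structure(str(out))
        for res in st[0]["A"]:
            expect = round(float(toy_scale.values[res.seqid.num - 1]) * 100.0, 2)
            for atom in res:
                assert atom.b_iso == pytest.approx(expect, abs=0.005)

    def test_offset_out_of_range_rejected(self, toy_scale, toy_pdb, tmp_path):
        with pytest.raises(ValueError, match="no residues matched"):
            map_scale_to_structure(
                toy_scale, toy_pdb, tmp_path / "x.pdb", chain="A",
                numbering_offset=1000,
            )

    def test_missing_chain_rejected(self, toy_scale, toy_pdb, tmp_path):
        with pytest.raises(ValueError, match="chain"):
            map_scale_to_structure(
                toy_scale, toy_pdb, tmp_path / "x.pdb", chain="Z"
            )
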