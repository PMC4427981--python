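import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from discons import (
    Msa,
    ConservationConfig,
    apply_gap_penalty_and_window,
    bin_score,
    column_distribution,
    disorder_conservation,
    jsd_score,
    sequence_weights,
    score_columns,
)
from discons.conservation import (
    AA_INDEX,
    ScoreValidationError,
    UNIFORM20_BACKGROUND,
    UndefinedColumnError,
)
from discons.disorder import AlignedDisorderMatrix

rng = np.random.default_rng(20260923)


def random_distribution(k=20):
    v = rng.dirichlet(np.ones(k))
    return v


class TestSequenceWeights:
    def test_identical_sequences_share_weight(self):
        msa = Msa.from_records([("a", "ACDE"), ("b", "ACDE")])
        assert np.allclose(sequence_weights(msa, "henikoff"), [0.5, 0.5])

    def test_uniform_scheme(self, toy_msa):
        assert np.allclose(sequence_weights(toy_msa, "uniform"), 0.25)

    def test_henikoff_matches_hand_computation(self, toy_msa):
        # columns: AAAA, AAAC, EEEE, EEEE.  Per-column shares:
        # uniform columns give 1/4 each; column AAAC gives the three A
        # carriers 1/(2*3) and the C carrier 1/(2*1).
        per_seq = np.array(
            [
                (1 / 4 + 1 / 6 + 1 / 4 + 1 / 4) / 4,
                (1 / 4 + 1 / 6 + 1 / 4 + 1 / 4) / 4,
                (1 / 4 + 1 / 6 + 1 / 4 + 1 / 4) / 4,
                (1 / 4 + 1 / 2 + 1 / 4 + 1 / 4) / 4,
            ]
        )
        expected = per_seq / per_seq.sum()
        assert np.allclose(sequence_weights(toy_msa, "henikoff"), expected)


class TestColumnDistribution:
    def test_uniform_column_is_delta(self, toy_msa):
        d = column_distribution(toy_msa, 1, np.full(4, 0.25))
        assert d[AA_INDEX["A"]] == pytest.approx(1.0)

    def test_all_gap_column_is_undefined(self):
        msa = Msa.from_records([("a", "A-"), ("b", "C-")])
        assert column_distribution(msa, 2, np.array([0.5, 0.5])) is None

    def test_gaps_excluded_from_counts(self):
        msa = Msa.from_records([("a", "A"), ("b", "A"), ("c", "C"), ("d", "-")])
        d = column_distribution(msa, 1, np.full(4, 0.25))
        assert d[AA_INDEX["A"]] == pytest.approx(2 / 3)
        assert d[AA_INDEX["C"]] == pytest.approx(1 / 3)

    def test_out_of_range_column(self, toy_msa):
        with pytest.raises(IndexError):
            column_distribution(toy_msa, 5, np.full(4, 0.25))


class TestJsd:
    def test_self_divergence_is_zero(self):
        for _ in range(200):
            p = random_distribution()
            assert jsd_score(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_delta_vs_uniform_closed_form(self):
        delta = np.zeros(20)
        delta[0] = 1.0
        # independent oracle 1: direct entropy summation
        m = 0.5 * delta + 0.5 * UNIFORM20_BACKGROUND
        h = lambda v: -sum(x * math.log2(x) for x in v if x > 0)
        oracle = h(m) - 0.5 * h(delta) - 0.5 * h(UNIFORM20_BACKGROUND)
        # independent oracle 2: scipy jensenshannon distance squared
        oracle2 = jensenshannon(delta, UNIFORM20_BACKGROUND, base=2) ** 2
        value = jsd_score(delta, UNIFORM20_BACKGROUND)
        assert value == pytest.approx(0.855008, abs=1e-4)
        assert value == pytest.approx(oracle, abs=1e-12)
        assert value == pytest.approx(oracle2, abs=1e-9)

    def test_point_mass_maximizes_divergence(self):
        q = UNIFORM20_BACKGROUND
        delta = np.zeros(20)
        delta[3] = 1.0
        top = jsd_score(delta, q)
        for _ in range(200):
            assert jsd_score(random_distribution(), q) <= top + 1e-12

    def test_scores_bounded(self):
        for _ in range(100):
            s = jsd_score(random_distribution(), random_distribution())
            assert 0.0 <= s <= 1.0

    def test_unnormalized_input_rejected(self):
        bad = np.full(20, 0.06)
        with pytest.raises(ScoreValidationError):
            jsd_score(bad, UNIFORM20_BACKGROUND)


class TestPenaltyAndWindow:
    def test_identity_without_penalty_or_window(self):
        cfg = ConservationConfig(gap_penalty=False, window_size=0)
        scores = np.array([0.2, 0.8])
        out = apply_gap_penalty_and_window(scores, np.zeros(2), cfg)
        assert np.allclose(out, scores)

    def test_gap_penalty_scales_score(self):
        cfg = ConservationConfig(gap_penalty=True, window_size=0)
        out = apply_gap_penalty_and_window(
            np.array([0.8]), np.array([0.5]), cfg
        )
        assert out[0] == pytest.approx(0.4)

    def test_window_smoothing_hand_example(self):
        cfg = ConservationConfig(
            gap_penalty=False, window_size=1, window_weight=0.5
        )
        out = apply_gap_penalty_and_window(
            np.array([1.0, 0.0, 1.0]), np.zeros(3), cfg
        )
        assert out[1] == pytest.approx(0.5 * 0.0 + 0.5 * (2 / 3))


class TestDisorderConservation:
    def make_matrix(self, *cols):
        values = np.array(cols, dtype=float).T
        return AlignedDisorderMatrix(
            ids=tuple(f"s{i}" for i in range(values.shape[0])), values=values
        )

    def test_simple_fraction(self):
        m = self.make_matrix([1, 1, 0, 1])
        assert disorder_conservation(m, 1) == pytest.approx(0.75)

    def test_gaps_excluded_from_denominator(self):
        m = self.make_matrix([1, np.nan, np.nan])
        assert disorder_conservation(m, 1) == pytest.approx(1.0)
        m2 = self.make_matrix([0, 0, np.nan])
        assert disorder_conservation(m2, 1) == pytest.approx(0.0)

    def test_all_na_column_undefined(self):
        m = self.make_matrix([np.nan, np.nan])
        with pytest.raises(UndefinedColumnError):
            disorder_conservation(m, 1)

    def test_matches_brute_force_on_random_matrices(self):
        for _ in range(1000):
            n, c = rng.integers(1, 8), rng.integers(1, 8)
            values = rng.choice([0.0, 1.0, np.nan], size=(n, c))
            m = AlignedDisorderMatrix(ids=tuple(map(str, range(n))), values=values)
            for col in range(1, c + 1):
                cells = [values[i, col - 1] for i in range(n)]
                known = [x for x in cells if not np.isnan(x)]
                if not known:
                    with pytest.raises(UndefinedColumnError):
                        disorder_conservation(m, col)
                else:
                    expected = sum(1 for x in known if x == 1.0) / len(known)
                    assert disorder_conservation(m, col) == pytest.approx(expected)


class TestBinning:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.0, 0), (1.0, 9), (0.75, 7), (0.5, 5), (0.0999, 0), (0.1, 1)],
    )
    def test_floor_by_deciles(self, raw, expected):
        assert bin_score(raw) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ScoreValidationError):
                bin_score(bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=0, max_value=1, allow_nan=False),
        b=st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert bin_score(lo) <= bin_score(hi)


class TestScoreColumns:
    def test_permutation_invariance_across_rows(self):
        cfg = ConservationConfig(
            gap_penalty=False,
            window_size=0,
            pseudocount=0.0,
            sequence_weighting="uniform",
        )
        msa1 = Msa.from_records([("a", "AK"), ("b", "CK"), ("c", "CK")])
        msa2 = Msa.from_records([("a", "CK"), ("b", "CK"), ("c", "AK")])
        tracks = np.zeros((3, 2))
        mat = AlignedDisorderMatrix(ids=("a", "b", "c"), values=tracks)
        s1 = score_columns(msa1, mat, cfg)
        s2 = score_columns(msa2, mat, cfg)
        assert s1[0].seq_raw == pytest.approx(s2[0].seq_raw)

    def test_methods_agree_on_rank_of_extreme_columns(self):
        # fully conserved column vs maximally diverse 20-symbol column
        aas = "ACDEFGHIKLMNPQRSTVWY"
        records = [(f"s{i}", "A" + aas[i]) for i in range(20)]
        msa = Msa.from_records(records)
        mat = AlignedDisorderMatrix(
            ids=msa.ids, values=np.zeros((20, 2))
        )
        for method in ("jsd", "shannon_entropy"):
            cfg = ConservationConfig(
                method=method, gap_penalty=False, window_size=0
            )
            s = score_columns(msa, mat, cfg)
            assert s[0].seq_raw > s[1].seq_raw

    def test_column_scores_invariants(self, family_seed7_profile):
        _, scores, _ = family_seed7_profile
        for s in scores:
            assert 0.0 <= s.seq_raw <= 1.0 and 0.0 <= s.dis_raw <= 1.0
            assert s.seq_bin == min(int(math.floor(10 * s.seq_raw)), 9)
            assert s.dis_bin == min(int(math.floor(10 * s.dis_raw)), 9)
            assert (s.dis_bin == 0) == (s.dis_raw < 0.1)
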