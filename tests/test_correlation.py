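import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csdnet import (ExpressionMatrix, default_subsample_size,
                    expected_spurious_perfect_correlations,
                    generate_subsample_design, pair_correlation_profile,
                    rank_transform, spearman_rho)
from csdnet.correlation import SubsampleDesign


class TestRankTransform:
    @pytest.mark.parametrize("x, expected", [
        ([3, 1, 2], [3, 1, 2]),
        ([1, 1, 2], [1.5, 1.5, 3]),
        ([5, 5, 5], [2, 2, 2]),
    ])
    def test_examples(self, x, expected):
        np.testing.assert_allclose(rank_transform(x), expected)

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=20)  # heavy ties
        assert rank_transform(x).sum() == 20 * 21 / 2

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([1.0, np.nan, 2.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(1, 8)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -(x ** 3)) == pytest.approx(-1.0)

    def test_derived_example(self):
        # rank deviations (-1.5,-0.5,0.5,1.5) vs (-1.5,0.5,-0.5,1.5)
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20,
                    unique=True))
    def test_invariance_under_monotone_transforms(self, ints):
        x = np.asarray(ints) / 20.0  # well-spaced distinct values
        y = np.sin(x)  # arbitrary partner signal
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(0.05 * x),
                            2 * y + 5) == pytest.approx(base, abs=1e-9)


class TestSubsampleDesign:
    def test_n4_k2_covers_every_pair_once(self):
        d = generate_subsample_design(4, 2)
        assert d.subsamples == ((0, 1), (2, 3), (0, 2), (0, 3), (1, 2),
                                (1, 3))
        d.validate()

    def test_first_pass_blocks_n100(self):
        d = generate_subsample_design(100, 8)
        expected = tuple(tuple(range(s, s + 8)) for s in range(0, 96, 8))
        assert d.subsamples[:12] == expected
        d.validate()

    def test_deterministic(self):
        assert generate_subsample_design(50, 7) == \
            generate_subsample_design(50, 7)

    @pytest.mark.parametrize("N, n", [(5, 6), (10, 1)])
    def test_invalid_sizes(self, N, n):
        with pytest.raises(ValueError):
            generate_subsample_design(N, n)

    def test_n9_k3_all_full_and_pair_unique(self):
        d = generate_subsample_design(9, 3)
        assert all(len(s) == 3 for s in d.subsamples)
        d.validate()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 120).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(2, min(N, 15)))))
    def test_pair_uniqueness_property(self, Nn):
        N, n = Nn
        generate_subsample_design(N, n).validate()

    def test_large_case_pair_unique(self):
        generate_subsample_design(200, 14).validate()

    def test_default_size_rule(self):
        assert default_subsample_size(200) == 14
        assert default_subsample_size(49) == 7
        assert default_subsample_size(20) == 7  # clipped up to 7
        assert default_subsample_size(5) == 5  # never above N


def _two_gene_matrix(x, y):
    return ExpressionMatrix(["A", "B"], [f"s{i}" for i in range(len(x))],
                            np.array([x, y], dtype=float))


class TestPairCorrelationProfile:
    def test_sem_from_two_subsamples(self):
        # block ranks chosen so the two subsample correlations are
        # exactly 0.5 and 0.7 -> SEM = sd(0.5, 0.7)/sqrt(2) = 0.1
        design = SubsampleDesign(N=10, n=5, subsamples=(
            (0, 1, 2, 3, 4), (5, 6, 7, 8, 9)))
        x = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        y = [2, 4, 1, 3, 5, 1, 4, 2, 3, 5]
        pc = pair_correlation_profile(_two_gene_matrix(x, y), design)
        assert pc.sigma[0, 1] == pytest.approx(0.1)
        assert pc.sigma[0, 1] == pc.sigma[1, 0]

    def test_perfectly_monotone_pair(self):
        design = generate_subsample_design(12, 3)
        x = np.arange(12.0)
        pc = pair_correlation_profile(_two_gene_matrix(x, x ** 2), design)
        assert pc.rho[0, 1] == pytest.approx(1.0)
        assert pc.sigma[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_fallback_sigma_without_design(self):
        pc = pair_correlation_profile(
            _two_gene_matrix([1, 2, 3, 4], [4, 1, 3, 2]), None,
            sigma_fallback=0.0)
        assert not pc.subsampling_used
        assert pc.sigma[0, 1] == 0.0

    def test_design_sample_count_must_match(self):
        design = generate_subsample_design(8, 2)
        with pytest.raises(ValueError):
            pair_correlation_profile(
                _two_gene_matrix([1, 2, 3], [3, 2, 1]), design)

    def test_constant_gene_flagged_undefined(self):
        design = generate_subsample_design(9, 3)
        pc = pair_correlation_profile(
            _two_gene_matrix(np.ones(9), np.arange(9.0)), design)
        assert math.isnan(pc.rho[0, 1])

    def test_tables_symmetric(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix([f"G{i}" for i in range(5)],
                             [f"s{i}" for i in range(30)],
                             rng.standard_normal((5, 30)))
        pc = pair_correlation_profile(m, generate_subsample_design(30, 5))
        np.testing.assert_allclose(pc.rho, pc.rho.T)
        np.testing.assert_allclose(pc.sigma, pc.sigma.T)

    def test_subsample_correlations_sharpen_with_size(self):
        # larger subsamples give per-subsample correlations that scatter
        # less and whose mean sits closer to the full-sample value
        rng = np.random.default_rng(7)
        z = rng.standard_normal(120)
        x = z + 0.5 * rng.standard_normal(120)
        y = z + 0.5 * rng.standard_normal(120)
        full = spearman_rho(x, y)
        spread, bias = {}, {}
        for n in (5, 20):
            design = generate_subsample_design(120, n)
            rs = np.array([spearman_rho(x[list(s)], y[list(s)])
                           for s in design.subsamples])
            spread[n] = rs.std(ddof=1)
            bias[n] = abs(rs.mean() - full)
        assert spread[20] < spread[5]
        assert bias[20] < bias[5]

    def test_low_sample_count_warns(self, caplog):
        with caplog.at_level("WARNING"):
            pair_correlation_profile(
                _two_gene_matrix([1, 2, 3, 4], [2, 1, 4, 3]), None)
        assert any("recommended minimum" in r.message
                   for r in caplog.records)


def test_spurious_perfect_correlation_formula():
    # 1000 genes, 8 samples: ~12 perfect rank correlations by chance
    value = expected_spurious_perfect_correlations(1000, 8)
    assert value == pytest.approx(1000 * 999 / (2 * math.factorial(8)))
    assert value == pytest.approx(12.4, abs=0.05)
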