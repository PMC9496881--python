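"""One-way/two-way ANOVA against loop oracles, and the block fitness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blockseg import anova_fitness, f_pvalue, oneway_anova, twoway_anova

from _oracles import f_upper_tail_quadrature, twoway_ss_oracle


class TestOneWay:
    def test_two_group_example(self):
        # frozen from the loop oracle: groups {1,2,3},{4,5,6}
        t = oneway_anova([[1, 2, 3], [4, 5, 6]])
        assert t.SSF == pytest.approx(13.5)
        assert t.SSE == pytest.approx(4.0)
        assert t.SST == pytest.approx(17.5)
        assert t.F == pytest.approx(13.5)
        assert t.df_factor == 1 and t.df_residual == 4
        assert t.p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-10)

    def test_constant_data_degenerates_to_zero(self):
        t = oneway_anova([[3.0, 3.0], [3.0, 3.0]])
        assert t.SSF == t.SSE == t.SST == 0.0
        assert t.F == 0.0 and t.p == 1.0

    def test_decomposition_and_df_identities(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(2, 7)).tolist()
                      for _ in range(rng.integers(2, 5))]
            t = oneway_anova(groups)
            assert t.SST == pytest.approx(t.SSF + t.SSE, rel=1e-9)
            assert t.df_factor + t.df_residual == t.N - 1
            assert min(t.SSF, t.SSE) >= 0

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.3, 1.0)]
        t = oneway_anova(groups)
        F, p = stats.f_oneway(*groups)
        assert t.F == pytest.approx(F, rel=1e-10)
        assert t.p == pytest.approx(p, rel=1e-8)

    @pytest.mark.parametrize("bad", [
        [[1, 2, 3]],                  # one group
        [[1, 2], []],                 # empty group
        [[1], [2]],                   # N < k+1
    ])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            oneway_anova(bad)


class TestTwoWay:
    def test_worked_example(self):
        t = twoway_anova([[[1, 3], [2, 4]], [[5, 7], [6, 8]]])
        assert t.SSA == pytest.approx(32.0)
        assert t.SSB == pytest.approx(2.0)
        assert t.SSAB == pytest.approx(0.0, abs=1e-12)
        assert t.SSE == pytest.approx(8.0)
        assert t.SST == pytest.approx(42.0)
        assert t.MSE == pytest.approx(2.0)
        assert t.F_A == pytest.approx(16.0)
        assert t.F_B == pytest.approx(1.0)
        assert (t.df_A, t.df_B, t.df_AB, t.df_residual) == (1, 1, 1, 4)

    def test_constant_data(self):
        t = twoway_anova(np.full((2, 2, 2), 7.0))
        assert t.SSA == t.SSB == t.SSAB == t.SSE == t.SST == 0.0
        assert t.F_A == 0.0 and t.p_A == 1.0

    def test_matches_loop_oracle_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b = rng.integers(2, 5, size=2)
            n = rng.integers(2, 6)
            Y = rng.normal(size=(a, b, n))
            t = twoway_anova(Y)
            SSA, SSB, SSAB, SSE, SST = twoway_ss_oracle(Y)
            assert t.SSA == pytest.approx(SSA, rel=1e-9, abs=1e-12)
            assert t.SSB == pytest.approx(SSB, rel=1e-9, abs=1e-12)
            assert t.SSAB == pytest.approx(SSAB, rel=1e-9, abs=1e-12)
            assert t.SSE == pytest.approx(SSE, rel=1e-9, abs=1e-12)
            assert t.SST == pytest.approx(t.SSA + t.SSB + t.SSAB + t.SSE, rel=1e-9)

    def test_p_values_match_scipy_f(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(3, 4, 5))
        t = twoway_anova(Y)
        assert t.p_A == pytest.approx(stats.f.sf(t.F_A, t.df_A, t.df_residual), rel=1e-9)
        assert t.p_B == pytest.approx(stats.f.sf(t.F_B, t.df_B, t.df_residual), rel=1e-9)
        assert t.p_AB == pytest.approx(stats.f.sf(t.F_AB, t.df_AB, t.df_residual), rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    def test_translation_invariance_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(2, 3, 4))
        base = twoway_anova(Y)
        shifted = twoway_anova(Y + shift)
        for f in ("SSA", "SSB", "SSAB", "SSE"):
            assert getattr(shifted, f) == pytest.approx(getattr(base, f), rel=1e-6, abs=1e-9)
        scaled = twoway_anova(Y * scale)
        for f in ("SSA", "SSB", "SSAB", "SSE", "SST"):
            assert getattr(scaled, f) == pytest.approx(scale ** 2 * getattr(base, f), rel=1e-6)
        assert scaled.F_A == pytest.approx(base.F_A, rel=1e-6)
        assert scaled.F_B == pytest.approx(base.F_B, rel=1e-6)

    def test_unbalanced_and_singleton_cells_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            twoway_anova([[[1, 2], [3]], [[4, 5], [6, 7]]])
        with pytest.raises(ValueError, match="n >= 2"):
            twoway_anova([[[1], [2]], [[3], [4]]])
        with pytest.raises(ValueError):
            twoway_anova([[[1, 2], [3, 4]]])  # a = 1


class TestFPValue:
    def test_boundaries_and_symmetry(self):
        assert f_pvalue(0.0, 3, 7) == pytest.approx(1.0)
        # P(F >= 1) = 0.5 when df1 == df2, by reciprocal symmetry
        assert f_pvalue(1.0, 6, 6) == pytest.approx(0.5, abs=1e-12)
        assert f_pvalue(float("inf"), 2, 5) == 0.0

    def test_against_quadrature_oracle(self):
        for F, df1, df2 in [(16.0, 1, 4), (2.5, 3, 12), (0.7, 5, 2)]:
            assert f_pvalue(F, df1, df2) == pytest.approx(
                f_upper_tail_quadrature(F, df1, df2), abs=1e-8)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            f_pvalue(1.0, 0, 4)
        with pytest.raises(ValueError):
            f_pvalue(-1.0, 2, 4)


class TestFitness:
    def test_constant_identical_pair_is_zero(self):
        block = np.full((4, 4), 0.5)
        assert anova_fitness(block, block) == 0.0

    def test_offset_on_nonconstant_reference_raises_fitness(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0.2, 0.4, (8, 8))
        assert anova_fitness(ref + 0.2, ref) > anova_fitness(ref, ref)

    def test_symmetric_in_image_roles(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(size=(6, 7))
        r = rng.uniform(size=(6, 7))
        assert anova_fitness(c, r) == pytest.approx(anova_fitness(r, c), rel=1e-12)

    def test_matches_full_table_mean_squares(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(size=(5, 6))
        r = rng.uniform(size=(5, 6))
        t = twoway_anova(np.stack([c.T, r.T]))
        expected = (t.MSA + t.MSB) / (t.MSE + 1e-12)
        assert anova_fitness(c, r) == pytest.approx(expected, rel=1e-12)

    def test_layouts_and_validation(self):
        rng = np.random.default_rng(6)
        c, r = rng.uniform(size=(4, 9)), rng.uniform(size=(4, 9))
        assert anova_fitness(c, r, factor_layout="rows-as-B") == pytest.approx(
            anova_fitness(c.T, r.T), rel=1e-12)
        with pytest.raises(ValueError, match="shape"):
            anova_fitness(c, r[:, :-1])
        with pytest.raises(ValueError, match="factor_layout"):
            anova_fitness(c, r, factor_layout="diagonal")

    def test_tumor_block_beats_tissue_block(self, pair64):
        """On the phantom, a tumor-covering block far outscores pure tissue."""
        d, r = pair64.diseased, pair64.reference
        tumor = d[17:33, 30:46], r[17:33, 30:46]   # covers the (25,38) r=5 disk
        tissue = d[30:46, 12:28], r[30:46, 12:28]
        assert anova_fitness(*tumor) > 10 * anova_fitness(*tissue)
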