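"""Expression computations: TPM, median-of-ratios, Spearman, overdispersion,
quantile SD profile and the NB marker screen, against hand-computed and
scipy oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silentdropout import (
    CountMatrix,
    DESpec,
    benjamini_hochberg,
    compute_tpm,
    de_screen,
    overdispersion_compare,
    overdispersion_table,
    quantile_sd_profile,
    simulate_expression,
    size_factors_median_of_ratios,
    spearman_rho,
)
from silentdropout.errors import (
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
    NoReferenceError,
    UndefinedCorrelationError,
)

GROUPS = ["normal"] * 24 + ["pre_dropout"] * 4


def _matrix(counts, lengths=None, groups=None):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(counts[0]))],
    )
    n = counts.shape[1]
    lengths = pd.Series(
        lengths if lengths is not None else [1000.0] * len(counts), index=counts.index
    )
    groups = pd.Series(
        groups if groups is not None else ["normal"] * (n - n // 2) + ["pre_dropout"] * (n // 2),
        index=counts.columns,
    )
    return CountMatrix(counts, lengths, groups)


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        tpm = compute_tpm(_matrix([[7, 3]]))
        assert (tpm.iloc[0] == 1e6).all()

    def test_length_rate_arithmetic(self):
        """Equal counts at lengths 1000 and 2000 bp split 2:1."""
        tpm = compute_tpm(_matrix([[10, 10], [10, 10]], lengths=[1000.0, 2000.0]))
        assert tpm.iloc[0, 0] == pytest.approx(2e6 / 3)
        assert tpm.iloc[1, 0] == pytest.approx(1e6 / 3)

    def test_depth_invariance(self):
        base = _matrix([[5, 50], [9, 90], [2, 20]])
        tpm = compute_tpm(base)
        pd.testing.assert_series_equal(
            tpm.iloc[:, 0], tpm.iloc[:, 1], check_names=False
        )

    def test_column_sums_are_one_million(self):
        a, _, _, _ = simulate_expression(300, GROUPS, 0.3, 0.05, seed=1)
        sums = compute_tpm(a).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, atol=1e-3)

    def test_all_zero_column_flagged(self):
        m = _matrix([[0, 5], [0, 3]])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(m)
        assert (tpm.iloc[:, 0] == 0).all()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        f = size_factors_median_of_ratios(_matrix([[4, 4], [9, 9], [1, 1]]))
        np.testing.assert_allclose(f, 1.0)

    def test_scale_equivariance(self):
        base = [[4, 8], [10, 20], [7, 14]]
        f = size_factors_median_of_ratios(_matrix(base))
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_hand_enumerated_five_gene_instance(self):
        """Explicit geometric-mean reference and per-sample median ratios."""
        counts = np.array(
            [[10, 20, 30], [5, 5, 5], [100, 50, 25], [8, 16, 8], [3, 9, 27]],
            dtype=float,
        )
        ref = np.exp(np.mean(np.log(counts), axis=1))
        expected = np.median(counts / ref[:, None], axis=0)
        f = size_factors_median_of_ratios(_matrix(counts.tolist()))
        np.testing.assert_allclose(f.to_numpy(), expected)

    def test_gene_order_invariance(self):
        counts = [[10, 20], [5, 5], [100, 50], [8, 16]]
        a = size_factors_median_of_ratios(_matrix(counts))
        b = size_factors_median_of_ratios(_matrix(counts[::-1]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_zero_rows_excluded_from_reference(self):
        with_zeros = _matrix([[10, 20], [0, 5], [100, 50]])
        no_zeros = _matrix([[10, 20], [100, 50]])
        np.testing.assert_allclose(
            size_factors_median_of_ratios(with_zeros).to_numpy(),
            size_factors_median_of_ratios(no_zeros).to_numpy(),
        )

    def test_no_reference_gene_rejected(self):
        with pytest.raises(NoReferenceError):
            size_factors_median_of_ratios(_matrix([[0, 5], [3, 0]]))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.3, 1.2, 2.0, 5.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == 1.0

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(6.0)
        assert spearman_rho(x, -x) == -1.0

    def test_tied_instance_matches_midrank_pearson_by_hand(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0, 3.0]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        assert spearman_rho(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            spearman_rho([1.0, 2.0], [1.0, 2.0])


class TestOverdispersion:
    def test_poisson_counts_give_unit_ratio(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50.0, size=(300, 500))
        m = _matrix(counts.tolist())
        ratios = overdispersion_table(m)
        assert 0.85 <= float(ratios.median()) <= 1.15

    def test_nb_counts_match_moment_identity(self):
        """NB(mu=50, r=5): var/mean = 1 + mu/r = 11 within MC tolerance."""
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 5 / 55, size=(300, 500))
        ratios = overdispersion_table(_matrix(counts.tolist()))
        assert 9.0 <= float(ratios.median()) <= 13.0

    def test_zero_mean_gene_flagged_undefined(self):
        ratios = overdispersion_table(_matrix([[0, 0, 0], [10, 12, 9], [5, 6, 7]]))
        assert np.isnan(ratios.iloc[0])
        assert ratios.iloc[1:].notna().all()

    def test_self_comparison_p_is_one(self):
        a, _, _, _ = simulate_expression(200, GROUPS, 0.3, 0.05, seed=5)
        _, _, test = overdispersion_compare(a, a)
        assert test.p_value == 1.0
        assert test.n_nonzero == 0

    def test_noisier_method_detected_one_sided(self):
        a, b, _, _ = simulate_expression(1000, GROUPS, 0.5, 0.05, seed=6)
        ta, tb, test = overdispersion_compare(a, b)
        assert float(ta.median()) > float(tb.median())
        assert test.p_value < 1e-6

    def test_mismatched_gene_sets_rejected(self):
        a = _matrix([[1, 2], [3, 4]])
        b = _matrix([[1, 2], [3, 4], [5, 6]])
        with pytest.raises(InvalidInputError):
            overdispersion_compare(a, b)


class TestQuantileSdProfile:
    def test_eleven_levels(self):
        a, _, _, _ = simulate_expression(300, GROUPS, 0.3, 0.05, seed=7)
        prof = quantile_sd_profile(compute_tpm(a))
        assert len(prof.levels) == 11
        np.testing.assert_allclose(prof.levels, np.arange(0.25, 0.751, 0.05))
        assert (prof.sd >= 0).all()

    def test_identical_columns_give_zero_sd(self):
        tpm = pd.DataFrame({"s0": [1.0, 5.0, 9.0], "s1": [1.0, 5.0, 9.0]})
        prof = quantile_sd_profile(tpm)
        np.testing.assert_allclose(prof.sd, 0.0)

    def test_scaled_column_induces_positive_sd(self):
        col = np.array([1.0, 5.0, 9.0, 20.0])
        tpm = pd.DataFrame({"s0": col, "s1": 2 * col})
        prof = quantile_sd_profile(tpm)
        assert (prof.sd > 0).all()

    def test_low_dispersion_method_sits_below_high(self):
        """Same means, different NB dispersion: the quieter method's profile
        is lower at >= 9 of the 11 levels."""
        a, b, _, _ = simulate_expression(2000, GROUPS, 0.5, 0.05, seed=8)
        prof_a = quantile_sd_profile(compute_tpm(a))
        prof_b = quantile_sd_profile(compute_tpm(b))
        assert int(np.sum(prof_b.sd < prof_a.sd)) >= 9

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            quantile_sd_profile(pd.DataFrame({"s0": [1.0, 2.0]}))


class TestBenjaminiHochberg:
    def test_monotone_in_pvalue_order(self, rng):
        p = rng.random(200)
        fdr = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(100)
        ours = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_flag_monotone_in_threshold(self, rng):
        p = rng.random(100) ** 2
        fdr = benjamini_hochberg(p)
        assert set(np.flatnonzero(fdr < 0.01)) <= set(np.flatnonzero(fdr < 0.05))


class TestDeScreen:
    def test_fold_change_gate_is_conjunctive(self):
        """A hugely significant gene with fold-change 1.5 is not a marker."""
        rng = np.random.default_rng(9)
        n0, n1 = 24, 4
        counts = rng.poisson(200.0, size=(300, n0 + n1)).astype(float)
        counts[0, n0:] *= 1.5  # strong signal, small fold change
        m = _matrix(counts.tolist(), groups=["normal"] * n0 + ["pre_dropout"] * n1)
        res = de_screen(m)
        assert res.iloc[0]["fold_change"] < 2.0
        assert not res.iloc[0]["marker"]

    def test_null_simulation_flags_almost_nothing(self):
        total = 0
        for seed in range(5):
            _, b, _, _ = simulate_expression(2000, GROUPS, 0.5, 0.05, DESpec(0), seed=seed)
            total += int(de_screen(b)["marker"].sum())
        assert total / 5 <= 0.05 * 2000

    def test_planted_markers_recovered(self):
        _, b, _, truth = simulate_expression(
            2000, GROUPS, 0.5, 0.05, DESpec(40, 4.0), seed=10
        )
        res = de_screen(b)
        flagged = set(res.index[res["marker"]])
        planted = set(truth.index[truth["is_de"]])
        assert len(flagged & planted) / 40 >= 0.7
        assert len(flagged - planted) <= 0.1 * max(len(flagged), 1)

    def test_directionality_all_flags_upregulated(self):
        _, b, _, _ = simulate_expression(
            1500, GROUPS, 0.5, 0.05, DESpec(50, 3.0), seed=11
        )
        res = de_screen(b)
        assert (res.loc[res["marker"], "fold_change"] > 1.0).all()

    def test_small_group_rejected(self):
        m = _matrix([[1, 2, 3], [4, 5, 6]], groups=["normal", "normal", "pre_dropout"])
        with pytest.raises(InvalidDesignError):
            de_screen(m)
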