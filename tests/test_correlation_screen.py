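from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexscreen.correlation_screen import (
    STATUS_CONSTANT,
    STATUS_LOW_N,
    STATUS_OK,
    ScreenError,
    SignedGeneLists,
    correlate_with_seed,
    split_by_sign,
)
from coexscreen.synthetic_data import (
    SEED_GENE,
    GroupDesign,
    SyntheticConfig,
    generate_cohorts,
)
from tests.conftest import make_cohort


def cohort_with_seed(seed_values, gene_rows, gene_names=None):
    rows = [seed_values] + list(gene_rows)
    names = ["seed"] + (
        gene_names if gene_names else [f"g{i}" for i in range(len(gene_rows))]
    )
    return make_cohort(rows, features=names)


class TestCorrelateWithSeed:
    def test_duplicate_of_seed_has_r_one(self):
        seed = [1.0, 2.0, 3.0, 4.0, 5.0]
        cohort = cohort_with_seed(seed, [seed])
        table = correlate_with_seed(cohort, "seed")
        row = table.rows.loc["g0"]
        assert row["status"] == STATUS_OK
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_negation_has_r_minus_one(self):
        cohort = cohort_with_seed([1, 2, 3, 4, 5], [[5, 4, 3, 2, 1]])
        table = correlate_with_seed(cohort, "seed")
        assert table.rows.loc["g0", "r"] == pytest.approx(-1.0)

    def test_n6_oracle_case(self):
        # frozen from the covariance formula: r = 29/35
        cohort = cohort_with_seed([0, 1, 2, 3, 4, 5], [[1, 0, 3, 2, 5, 4]])
        table = correlate_with_seed(cohort, "seed")
        assert table.rows.loc["g0", "r"] == pytest.approx(29 / 35, abs=1e-12)
        assert table.rows.loc["g0", "p"] == pytest.approx(0.04156268221574339, abs=1e-12)

    def test_n6_t_p_matches_exhaustive_permutation_p(self):
        x = np.array([0, 1, 2, 3, 4, 5], float)
        y = np.array([1, 0, 3, 2, 5, 4], float)
        cohort = cohort_with_seed(x, [y])
        p_t = correlate_with_seed(cohort, "seed").rows.loc["g0", "p"]

        # independent oracle: exhaustive 6!-permutation two-sided p on |r|
        dx = x - x.mean()
        sxx = (dx * dx).sum()
        r_obs = abs((dx * (y - y.mean())).sum() / math.sqrt(sxx * ((y - y.mean()) ** 2).sum()))
        hits = 0
        total = 0
        for perm in itertools.permutations(y):
            yp = np.array(perm)
            dyp = yp - yp.mean()
            rp = (dx * dyp).sum() / math.sqrt(sxx * (dyp * dyp).sum())
            hits += abs(rp) >= r_obs - 1e-12
            total += 1
        assert abs(p_t - hits / total) < 0.02

    def test_constant_gene_excluded(self):
        cohort = cohort_with_seed([1, 2, 3, 4, 5], [[4, 4, 4, 4, 4]])
        table = correlate_with_seed(cohort, "seed")
        row = table.rows.loc["g0"]
        assert row["status"] == STATUS_CONSTANT
        assert np.isnan(row["r"])

    def test_low_n_excluded(self):
        gene = [1.0, 2.0, np.nan, np.nan, 5.0, 6.0]
        cohort = cohort_with_seed([1, 2, 3, 4, 5, 6], [gene])
        table = correlate_with_seed(cohort, "seed")
        assert table.rows.loc["g0", "status"] == STATUS_LOW_N
        assert table.rows.loc["g0", "n_used"] == 4

    def test_pairwise_complete_n_used(self):
        gene = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        cohort = cohort_with_seed([1, 2, 3, 4, 5, 6], [gene])
        table = correlate_with_seed(cohort, "seed")
        assert table.rows.loc["g0", "n_used"] == 5
        assert table.rows.loc["g0", "status"] == STATUS_OK

    def test_seed_absent_errors(self, small_cohort):
        with pytest.raises(ScreenError, match="absent"):
            correlate_with_seed(small_cohort, "NOPE")

    def test_seed_constant_errors(self):
        cohort = cohort_with_seed([5, 5, 5, 5, 5], [[1, 2, 3, 4, 5]])
        with pytest.raises(ScreenError, match="constant"):
            correlate_with_seed(cohort, "seed")

    def test_too_few_samples_errors(self):
        cohort = cohort_with_seed([1, 2, 3], [[3, 2, 1]])
        with pytest.raises(ScreenError, match="samples"):
            correlate_with_seed(cohort, "seed")

    def test_seed_not_a_row(self, small_cohort):
        table = correlate_with_seed(small_cohort, "gene0")
        assert "gene0" not in table.rows.index

    def test_matches_scipy_pearson(self, rng):
        values = rng.normal(7, 1, (20, 15))
        cohort = make_cohort(values)
        table = correlate_with_seed(cohort, "gene0")
        from scipy import stats

        for g in ("gene1", "gene7", "gene19"):
            r_ref, p_ref = stats.pearsonr(values[0], values[int(g[4:])])
            assert table.rows.loc[g, "r"] == pytest.approx(r_ref, abs=1e-12)
            assert table.rows.loc[g, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_matches_scipy_spearman(self, rng):
        values = rng.normal(7, 1, (10, 12))
        cohort = make_cohort(values)
        table = correlate_with_seed(cohort, "gene0", method="spearman")
        from scipy import stats

        r_ref, _ = stats.spearmanr(values[0], values[3])
        assert table.rows.loc["gene3", "r"] == pytest.approx(r_ref, abs=1e-12)

    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_pearson_shift_invariance(self, shift):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        base = correlate_with_seed(cohort_with_seed(x, [y]), "seed").rows.loc["g0", "r"]
        shifted = correlate_with_seed(
            cohort_with_seed(x, [y + shift]), "seed"
        ).rows.loc["g0", "r"]
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        base = correlate_with_seed(
            cohort_with_seed(x, [y]), "seed", method="spearman"
        ).rows.loc["g0", "r"]
        transformed = correlate_with_seed(
            cohort_with_seed(x, [np.exp(y) + 3]), "seed", method="spearman"
        ).rows.loc["g0", "r"]
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_deterministic(self, small_cohort):
        t1 = correlate_with_seed(small_cohort, "gene0")
        t2 = correlate_with_seed(small_cohort, "gene0")
        assert t1.rows.equals(t2.rows)


class TestSplitBySign:
    def make_table(self, rows):
        import pandas as pd

        from coexscreen.correlation_screen import CorrelationTable

        frame = pd.DataFrame(
            rows, columns=["r", "p", "n_used", "status"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        return CorrelationTable("c1", "seed", "pearson", frame)

    def test_significant_positive_listed(self):
        table = self.make_table([(0.9, 0.001, 10, STATUS_OK)])
        lists = split_by_sign(table, alpha=0.05)
        assert "g0" in lists.positive and not lists.negative

    def test_non_significant_unlisted(self):
        table = self.make_table([(-0.4, 0.20, 10, STATUS_OK)])
        lists = split_by_sign(table, alpha=0.05)
        assert not lists.positive and not lists.negative

    def test_default_alpha_is_005(self):
        table = self.make_table([(0.5, 0.049, 10, STATUS_OK), (0.5, 0.051, 10, STATUS_OK)])
        lists = split_by_sign(table)
        assert lists.alpha == 0.05
        assert lists.positive == {"g0"}

    def test_excluded_rows_never_listed(self):
        table = self.make_table(
            [(np.nan, np.nan, 10, STATUS_CONSTANT), (np.nan, np.nan, 3, STATUS_LOW_N)]
        )
        lists = split_by_sign(table)
        assert not lists.positive and not lists.negative

    def test_min_abs_r_floor(self):
        table = self.make_table([(0.03, 0.001, 2000, STATUS_OK)])
        assert split_by_sign(table, min_abs_r=0.1).positive == frozenset()
        assert split_by_sign(table, min_abs_r=0.0).positive == {"g0"}

    def test_sign_consistency(self, rng):
        n = 50
        rows = [
            (r, p, 20, STATUS_OK)
            for r, p in zip(rng.uniform(-1, 1, n), rng.uniform(0, 1, n))
        ]
        table = self.make_table(rows)
        lists = split_by_sign(table, alpha=0.3)
        for gene in lists.positive:
            assert table.rows.loc[gene, "r"] > 0
        for gene in lists.negative:
            assert table.rows.loc[gene, "r"] < 0

    def test_alpha_out_of_range(self):
        table = self.make_table([(0.5, 0.01, 10, STATUS_OK)])
        with pytest.raises(ScreenError):
            split_by_sign(table, alpha=1.5)

    def test_bh_flag_shrinks_lists(self):
        rows = [(0.5, p, 20, STATUS_OK) for p in (0.001, 0.02, 0.03, 0.04, 0.049)]
        table = self.make_table(rows)
        raw = split_by_sign(table, alpha=0.05)
        adj = split_by_sign(table, alpha=0.05, bh=True)
        assert adj.positive <= raw.positive

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ScreenError):
            SignedGeneLists("c", frozenset({"A"}), frozenset({"A"}), 0.05)


class TestNullCalibration:
    def test_positive_fraction_near_half_alpha_under_null(self):
        # beta = 0: no planted signal; background fraction in the positive
        # list should be alpha/2 within 3 SE over >= 10 cohorts
        alpha = 0.05
        config = SyntheticConfig(
            groups=(GroupDesign("null", 10, (100, 100)),),
            genes_total=2000,
            module_size_pos=0,
            module_size_neg=0,
            beta=0.0,
            seed=11,
        )
        cohorts, _ = generate_cohorts(config)
        hits = 0
        trials = 0
        for cohort in cohorts:
            table = correlate_with_seed(cohort, SEED_GENE)
            lists = split_by_sign(table, alpha=alpha)
            hits += len(lists.positive)
            trials += table.rows.shape[0]
        frac = hits / trials
        expected = alpha / 2
        se = math.sqrt(expected * (1 - expected) / trials)
        assert abs(frac - expected) < 3 * se
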