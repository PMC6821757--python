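"""t-tests, chi-square, the expression screen and qPCR closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoquant import synthgen
from endoquant.stats import (
    chi_square_test,
    relative_expression,
    screen_filter,
    t_test_two_sample,
)


class TestTTest:
    def test_identical_samples_null(self):
        with pytest.warns(UserWarning):
            stat, p = t_test_two_sample([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (stat, p) == (0.0, 1.0)

    def test_extreme_separation(self):
        _, p = t_test_two_sample([1, 2, 3], [101, 102, 103])
        assert p < 1e-6

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        _, p = t_test_two_sample(a, b, variant="student")
        # permutation distribution of the pooled-variance t statistic
        pooled = np.concatenate([a, b])
        t_obs = abs(sps.ttest_ind(a, b).statistic)
        n_perm = 10_000
        perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        t = np.abs(sps.ttest_ind(perms[:, :8], perms[:, 8:], axis=1).statistic)
        p_perm = (t >= t_obs).mean()
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_identical_rows_null(self):
        chi2, df, p = chi_square_test([[10, 20, 30], [10, 20, 30]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_diagonal_table(self):
        chi2, df, p = chi_square_test([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning):
            chi_square_test([[4, 1], [1, 4]])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 5], [0, 10]])

    def test_phenotype_table_integration(self):
        t = pd.concat([
            synthgen.make_phenotype_counts(80, [0.8, 0.15, 0.05], 1, "control"),
            synthgen.make_phenotype_counts(80, [0.3, 0.4, 0.3], 2, "morphant"),
        ])
        chi2, df, p = chi_square_test(t)
        assert df == 2 and p < 1e-4


class TestScreenFilter:
    def test_null_table_passes_nothing(self):
        table, _ = synthgen.make_expression_table(100, 0, noise_sd=0.0, seed=0)
        assert len(screen_filter(table)) == 0

    def test_regulated_genes_recovered_and_match_brute_force(self):
        table, truth = synthgen.make_expression_table(300, 12, 4.0, 4, 0.05,
                                                      seed=1)
        hits = screen_filter(table)
        expected = set(np.array(truth.gene_ids)[truth.regulated_flags])
        assert set(hits.gene_id) == expected
        # brute-force per-gene recomputation
        brute = set()
        ctrl = [c for c in table if c.startswith("control")]
        morph = [c for c in table if c.startswith("morphant")]
        for _, row in table.iterrows():
            fc = row[morph].mean() / row[ctrl].mean()
            p = sps.ttest_ind(row[morph].astype(float),
                              row[ctrl].astype(float), equal_var=False).pvalue
            if max(fc, 1 / fc) > 3.8 and p < 0.05:
                brute.add(row.gene_id)
        assert set(hits.gene_id) == brute

    def test_exact_threshold_excluded(self):
        # "more than 3.8-fold" is strict: a gene at exactly 3.8 fails
        table, _ = synthgen.make_expression_table(5, 0, noise_sd=0.0, seed=2)
        morph = [c for c in table if c.startswith("morphant")]
        ctrl = [c for c in table if c.startswith("control")]
        table.loc[0, morph] = table.loc[0, ctrl].to_numpy() * 3.8
        table.loc[1, morph] = table.loc[1, ctrl].to_numpy() * 3.81
        hits = screen_filter(table)
        assert table.loc[0, "gene_id"] not in set(hits.gene_id)

    def test_invariance_to_ordering_and_label_swap(self):
        table, _ = synthgen.make_expression_table(200, 8, 4.5, 4, 0.05, seed=3)
        hits = screen_filter(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert set(screen_filter(shuffled).gene_id) == set(hits.gene_id)
        # swapping condition labels inverts fold changes, same gene set
        swapped = table.rename(columns=lambda c: c
                               .replace("control", "tmp")
                               .replace("morphant", "control")
                               .replace("tmp", "morphant"))
        swapped = swapped[table.columns]
        hits_sw = screen_filter(swapped)
        assert set(hits_sw.gene_id) == set(hits.gene_id)
        merged = hits.merge(hits_sw, on="gene_id")
        np.testing.assert_allclose(merged.fold_change_x,
                                   1.0 / merged.fold_change_y, rtol=1e-9)

    def test_top_n_truncation_by_effect_size(self):
        table, _ = synthgen.make_expression_table(300, 20, 5.0, 4, 0.05, seed=4)
        hits = screen_filter(table, top_n=10)
        assert len(hits) == 10


class TestRelativeExpression:
    def _samples(self, ddcts):
        rows = [{"condition": "wild_type", "ct_target": 20.0,
                 "ct_reference": 15.0} for _ in range(3)]
        for i, d in enumerate(ddcts):
            rows += [{"condition": f"cond{i}", "ct_target": 20.0 + d,
                      "ct_reference": 15.0} for _ in range(3)]
        return pd.DataFrame(rows)

    def test_baseline_normalizes_to_one(self):
        _, summary = relative_expression(self._samples([1.0]))
        base = summary[summary.condition == "wild_type"]
        assert base.relative_expression.iloc[0] == 1.0

    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_closed_forms(self, ddct, expected):
        _, summary = relative_expression(self._samples([ddct]))
        val = summary.loc[summary.condition == "cond0",
                          "relative_expression"].iloc[0]
        assert val == pytest.approx(expected, abs=1e-12)

    def test_missing_reference_rejected(self):
        df = self._samples([1.0])
        df.loc[0, "ct_reference"] = np.nan
        with pytest.raises(ValueError):
            relative_expression(df)

    def test_missing_baseline_rejected(self):
        df = self._samples([1.0])
        with pytest.raises(ValueError):
            relative_expression(df, baseline_condition="absent")
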