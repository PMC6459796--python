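"""ddCt folds and t statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tssmeta import qpcr
from tssmeta import simulate as sim


def unpaired_table(wt_dct, mut_dct, gene="Tgt", reference="Hprt"):
    rows = []
    for arm, dcts in (("WT", wt_dct), ("Mut", mut_dct)):
        for i, d in enumerate(dcts):
            sample = f"{arm}{i}"
            rows.append((sample, reference, 20.0, arm))
            rows.append((sample, gene, 20.0 + d, arm))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "arm"])


class TestDeltaCt:
    @pytest.mark.parametrize("target, ref, expected", [(25, 23, 2), (23, 23, 0), (20, 22, -2)])
    def test_difference(self, target, ref, expected):
        assert qpcr.delta_ct(target, ref) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            qpcr.delta_ct(float("nan"), 20.0)


class TestUnpairedExpression:
    def test_wt_folds_all_one_when_dct_constant(self):
        result = qpcr.unpaired_expression(unpaired_table([2, 2, 2], [3, 3.5]), "Tgt")
        wt_folds = result.folds.loc[result.folds["arm"] == "WT", "fold"]
        assert np.allclose(wt_folds, 1.0)

    def test_shifted_mutant_fold(self):
        """A mutant sample one cycle above dCt_mean has fold 0.5."""
        result = qpcr.unpaired_expression(unpaired_table([2, 2, 2], [3, 3]), "Tgt")
        mut_folds = result.folds.loc[result.folds["arm"] == "Mut", "fold"]
        assert np.allclose(mut_folds, 0.5)

    def test_wt_log2_folds_mean_exactly_zero(self):
        rng = np.random.default_rng(8)
        result = qpcr.unpaired_expression(
            unpaired_table(rng.normal(2, 0.5, 6), rng.normal(3, 0.5, 6)), "Tgt"
        )
        wt_folds = result.folds.loc[result.folds["arm"] == "WT", "fold"]
        assert np.log2(wt_folds).mean() == pytest.approx(0.0, abs=1e-12)

    def test_t_and_p_match_pooled_variance_formula(self):
        """Folds {0.9, 1.0, 1.1} vs {0.5, 0.6, 0.7} through the textbook t."""
        wt_dct = -np.log2([0.9, 1.0, 1.1])
        mut_dct = -np.log2([0.5, 0.6, 0.7])
        result = qpcr.unpaired_expression(unpaired_table(wt_dct, mut_dct), "Tgt")
        wt = result.folds.loc[result.folds["arm"] == "WT", "fold"].to_numpy()
        mut = result.folds.loc[result.folds["arm"] == "Mut", "fold"].to_numpy()
        n1, n2 = len(mut), len(wt)
        sp2 = ((n2 - 1) * wt.var(ddof=1) + (n1 - 1) * mut.var(ddof=1)) / (n1 + n2 - 2)
        t_oracle = (mut.mean() - wt.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), n1 + n2 - 2)
        assert result.t == pytest.approx(t_oracle, rel=1e-12)
        assert result.p == pytest.approx(p_oracle, rel=1e-12)
        assert result.df == 4

    def test_symmetric_perturbations_multiply_to_one(self):
        result = qpcr.unpaired_expression(unpaired_table([1.7, 2.3, 2.0], [3.0, 3.0]), "Tgt")
        folds = result.folds.loc[result.folds["arm"] == "WT", "fold"].to_numpy()
        # dCt 1.7 and 2.3 sit symmetrically around dCt_mean = 2.0
        assert folds[0] * folds[1] == pytest.approx(1.0)

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            qpcr.unpaired_expression(unpaired_table([2, 2], [3]), "Tgt")

    def test_missing_reference_rejected(self):
        table = unpaired_table([2, 2], [3, 3])
        table = table[~((table["sample_id"] == "WT0") & (table["gene"] == "Hprt"))]
        with pytest.raises(ValueError, match="Hprt"):
            qpcr.unpaired_expression(table, "Tgt")

    def test_technical_replicates_averaged_on_ct_scale(self):
        table = unpaired_table([2, 2], [3, 3])
        dup = table[table["sample_id"] == "WT0"].assign(ct=lambda t: t["ct"] + 1.0)
        result = qpcr.unpaired_expression(pd.concat([table, dup]), "Tgt")
        # both genes shifted by the same amount average back to dCt = 2
        wt_folds = result.folds.loc[result.folds["arm"] == "WT", "fold"]
        assert np.allclose(wt_folds, 1.0)

    def test_zero_variance_degenerate_returns_t0_p1(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            result = qpcr.unpaired_expression(unpaired_table([2, 2, 2], [2, 2, 2]), "Tgt")
        assert (result.t, result.p) == (0.0, 1.0)


def paired_table(ddcts, base=2.0, gene="Tgt", reference="Hprt"):
    rows = []
    for i, ddct in enumerate(ddcts):
        pair = f"E{i}"
        for arm, dct in (("vehicle", base), ("drug", base + ddct)):
            sample = f"{pair}_{arm}"
            rows.append((sample, reference, 20.0, arm, pair))
            rows.append((sample, gene, 20.0 + dct, arm, pair))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "arm", "pair_id"])


class TestPairedExpression:
    def test_minus_one_ddct_doubles(self):
        result = qpcr.paired_expression(paired_table([-1.0, -1.0]), "Tgt")
        assert np.allclose(result.folds["fold_drug"], 2.0)
        assert np.allclose(result.folds["fold_vehicle"], 1.0)

    def test_no_change_gives_t0_p1(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            result = qpcr.paired_expression(paired_table([0.0, 0.0, 0.0]), "Tgt")
        assert (result.t, result.p) == (0.0, 1.0)

    def test_matches_one_sample_t_oracle(self):
        """Folds {1.2, 1.3, 1.4, 1.5} vs 1 through the one-sample closed form."""
        folds = np.array([1.2, 1.3, 1.4, 1.5])
        result = qpcr.paired_expression(paired_table(list(-np.log2(folds))), "Tgt")
        t_oracle = (folds.mean() - 1) / (folds.std(ddof=1) / np.sqrt(4))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 3)
        assert result.t == pytest.approx(t_oracle, rel=1e-12)
        assert result.p == pytest.approx(p_oracle, rel=1e-12)
        assert result.df == 3

    def test_unmatched_pair_named(self):
        table = paired_table([-1.0, -1.0, -1.0])
        table = table[~((table["pair_id"] == "E1") & (table["arm"] == "drug"))]
        with pytest.raises(ValueError, match="E1"):
            qpcr.paired_expression(table, "Tgt")

    def test_delta_scale_alternative(self):
        ddcts = [-1.0, -0.5, -1.5, -0.8]
        result = qpcr.paired_expression(paired_table(ddcts), "Tgt", on_delta_scale=True)
        res = stats.ttest_1samp(np.array(ddcts), 0.0)
        assert result.t == pytest.approx(float(res.statistic))


class TestParameterRecovery:
    def test_planted_shift_recovered_exactly_at_zero_sd(self):
        table = sim.simulate_ct(4, 4, planted_shift_e=1.0, sd=0.0, seed=3)
        result = qpcr.unpaired_expression(table, "Tgt")
        assert result.group_means["Mut"] == pytest.approx(0.5, abs=1e-12)

    def test_planted_shift_recovered_within_ci_at_noise(self):
        """KO mean fold converges to 2^-e; check a CI over replicate seeds."""
        estimates = [
            qpcr.unpaired_expression(
                sim.simulate_ct(50, 50, planted_shift_e=1.0, sd=0.2, seed=s), "Tgt"
            ).group_means["Mut"]
            for s in range(10)
        ]
        mean = np.mean(estimates)
        half_ci = 1.96 * np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.5) < max(half_ci, 0.02)
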