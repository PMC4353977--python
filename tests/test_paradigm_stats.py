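from itertools import product

import numpy as np
import pandas as pd
import pytest

from thetanet.paradigm_stats import (
    enc_vs_post_contrast, paired_t, rm_anova_interaction, rm_anova_oneway,
    validate_measure_table,
)
from thetanet.signal_io import ValidationError


def long_table(values, subjects=None, factor="period", region="R"):
    """values: array (n_subjects, n_levels) -> long-format measure table."""
    values = np.asarray(values)
    n, k = values.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    rows = [{"subject": subjects[i], "region": region,
             factor: f"Enc{j + 1}", "measure": "m", "value": values[i, j]}
            for i in range(n) for j in range(k)]
    df = pd.DataFrame(rows)
    if factor != "period":
        df = df.rename(columns={factor: factor})
    return df


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([3, 5, 4, 6], [1, 2, 2, 3], direction="two-sided")
        assert res.df == 3
        assert res.t == pytest.approx(np.sqrt(3) * 2.5 / 0.5, rel=1e-6)

    def test_known_t_value(self):
        # d = (2,3,2,3): mean 2.5, sd 0.5774 -> t = 2.5 / (0.5774/2) = 8.6603
        res = paired_t([3, 5, 4, 6], [1, 2, 2, 3])
        assert res.t == pytest.approx(8.6603, abs=1e-3)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(6)
        res = paired_t(a, a + rng.standard_normal(6), n_comparisons=50)
        assert res.p_corrected == min(1.0, res.p_raw * 50)
        assert res.p_corrected <= 1.0

    def test_degenerate_zero_variance(self):
        res = paired_t([2, 2, 2, 2], [1, 1, 1, 1])
        assert res.degenerate and res.p_raw == 0.0
        res0 = paired_t([1, 2, 3], [1, 2, 3])
        assert res0.t == 0.0 and res0.p_raw == 1.0

    def test_one_sided_direction(self):
        a, b = [3.0, 4, 5, 6], [1.0, 2, 3, 4]
        g = paired_t(a, b, direction="greater")
        l = paired_t(a, b, direction="less")
        assert g.p_raw < 0.05 < l.p_raw

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(8)
        b = rng.standard_normal(8)
        r1 = paired_t(a, b)
        r2 = paired_t(a + 7.7, b + 7.7)
        assert r1.t == pytest.approx(r2.t, rel=1e-12)

    def test_matches_exhaustive_sign_flip_permutation(self):
        """One-sided t p-value tracks the exact sign-flip null at n=8."""
        diffs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(8) + 0.5
            res = paired_t(a, np.zeros(8), direction="greater")
            ts = []
            for signs in product((1.0, -1.0), repeat=8):
                d = a * np.array(signs)
                ts.append(d.mean() / (d.std(ddof=1) / np.sqrt(8)))
            p_perm = np.mean(np.asarray(ts) >= res.t - 1e-12)
            diffs.append(abs(p_perm - res.p_raw))
        assert np.mean(diffs) < 0.01


class TestRmAnovaOneway:
    def test_identical_values_give_zero_f(self):
        tbl = long_table(np.ones((6, 5)) * 4.2 +
                         np.arange(6)[:, None] * 0.5)  # subject offsets only
        res = rm_anova_oneway(tbl, factor="period")
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_two_level_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        tbl = long_table(np.column_stack([a, b]))
        res = rm_anova_oneway(tbl, factor="period")
        t = paired_t(a, b).t
        assert res.F == pytest.approx(t ** 2, rel=1e-9)

    def test_subject_constant_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((8, 5))
        f1 = rm_anova_oneway(long_table(v), factor="period").F
        f2 = rm_anova_oneway(long_table(v + np.arange(8)[:, None] * 100),
                             factor="period").F
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_missing_cells_rejected(self):
        tbl = long_table(np.random.default_rng(0).standard_normal((5, 4)))
        with pytest.raises(ValidationError):
            rm_anova_oneway(tbl.iloc[:-1], factor="period")

    def test_type_one_error_calibration(self):
        """Exchangeable null: rejection rate at alpha=0.05 within 0.05 +- 0.02."""
        rej = 0
        n_seeds = 400
        for seed in range(n_seeds):
            v = np.random.default_rng(seed).standard_normal((8, 5))
            rej += rm_anova_oneway(long_table(v), factor="period").p < 0.05
        assert abs(rej / n_seeds - 0.05) < 0.025


class TestRmAnovaInteraction:
    @staticmethod
    def table_2x2(values):
        rows = []
        for i in range(values.shape[0]):
            for j, exp in enumerate(("FC", "SR")):
                for k, band in enumerate(("low", "high")):
                    rows.append({"subject": f"S{i}", "experiment": exp,
                                 "band": band, "value": values[i, j, k]})
        return pd.DataFrame(rows)

    def test_additive_null_rate(self):
        rej = 0
        n_seeds = 300
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            v = rng.standard_normal((8, 2, 2))
            v += rng.standard_normal((8, 1, 2)) * 0  # noise only, no interaction
            v[:, 1, :] += 1.0   # pure main effect of experiment
            v[:, :, 1] += 0.5   # pure main effect of band
            rej += rm_anova_interaction(self.table_2x2(v)).p < 0.05
        assert abs(rej / n_seeds - 0.05) < 0.03

    def test_crossover_detected_and_symmetric(self):
        rng = np.random.default_rng(5)
        v = 0.3 * rng.standard_normal((6, 2, 2))
        v[:, 0, 0] += 3.0  # FC low up
        v[:, 1, 1] += 3.0  # SR high up
        tbl = self.table_2x2(v)
        res = rm_anova_interaction(tbl)
        assert res.p < 0.01
        swapped = tbl.rename(columns={"experiment": "band", "band": "experiment"})
        res2 = rm_anova_interaction(swapped)
        assert res2.F == pytest.approx(res.F, rel=1e-9)

    def test_single_level_factor_rejected(self):
        v = np.random.default_rng(0).standard_normal((4, 2, 2))
        tbl = self.table_2x2(v)
        with pytest.raises(ValidationError):
            rm_anova_interaction(tbl[tbl["experiment"] == "FC"])


class TestEncVsPost:
    @staticmethod
    def table(enc, post):
        rows = []
        for i in range(len(enc)):
            for k in range(1, 6):
                rows.append({"subject": f"S{i}", "region": "MeA",
                             "period": f"Enc{k}", "measure": "dtp_db",
                             "value": enc[i]})
                rows.append({"subject": f"S{i}", "region": "MeA",
                             "period": f"Post{k}", "measure": "dtp_db",
                             "value": post[i]})
        return pd.DataFrame(rows)

    def test_equal_means_give_zero_t(self):
        v = np.random.default_rng(0).standard_normal(6)
        res = enc_vs_post_contrast(self.table(v, v))
        assert res["MeA"].t == 0.0

    def test_detects_enc_excess(self):
        rng = np.random.default_rng(1)
        enc = 3.0 + 0.3 * rng.standard_normal(8)
        post = 0.2 * rng.standard_normal(8)
        res = enc_vs_post_contrast(self.table(enc, post))
        assert res["MeA"].p_raw < 0.01

    def test_duplicate_cells_rejected(self):
        tbl = self.table(np.ones(4), np.zeros(4))
        with pytest.raises(ValidationError):
            validate_measure_table(pd.concat([tbl, tbl.iloc[:1]]))
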