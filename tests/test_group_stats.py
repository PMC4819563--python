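import math

import numpy as np
import pandas as pd
import pytest

from relaxo.group_stats import cohort_report, compare_adjusted, compare_groups


def _table(preterm, term, variable="wm_t2_ms"):
    rows = []
    for i, v in enumerate(preterm):
        rows.append({"subject_id": f"p{i}", "group": "preterm", "sex": "female", variable: v})
    for i, v in enumerate(term):
        rows.append({"subject_id": f"t{i}", "group": "term", "sex": "male", variable: v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        res = compare_groups(_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "wm_t2_ms")
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation_is_significant(self):
        res = compare_groups(_table([1.0, 2.0, 3.0], [11.0, 12.0, 13.0]), "wm_t2_ms")
        assert res.p_value < 0.001

    def test_matches_hand_computed_pooled_t(self):
        # Pooled two-sample t on a printed toy table, computed from the
        # closed-form formula independently of scipy.
        a = [66.0, 70.0, 68.0, 72.0]
        b = [64.0, 65.0, 67.0, 66.0]
        res = compare_groups(_table(a, b), "wm_t2_ms")
        ma, mb = np.mean(a), np.mean(b)
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((len(a) - 1) * sa2 + (len(b) - 1) * sb2) / (len(a) + len(b) - 2)
        t_hand = (ma - mb) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-12)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), len(a) + len(b) - 2)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_affine_invariance(self):
        table = _table([66.0, 70.0, 68.0], [64.0, 65.0, 67.0])
        base = compare_groups(table, "wm_t2_ms")
        table2 = table.assign(wm_t2_ms=2.5 * table.wm_t2_ms + 7.0)
        scaled = compare_groups(table2, "wm_t2_ms")
        assert scaled.t_statistic == pytest.approx(base.t_statistic, rel=1e-12)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_row_order_independence(self):
        table = _table([66.0, 70.0, 68.0, 71.0], [64.0, 65.0, 67.0])
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = compare_groups(shuffled, "wm_t2_ms")
        b = compare_groups(table, "wm_t2_ms")
        assert a.t_statistic == pytest.approx(b.t_statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.n == b.n

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(_table([1.0, 2.0], [3.0]), "wm_t2_ms")

    def test_both_split_yields_pairwise_contrasts(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in ("preterm", "term"):
            for s in ("male", "female"):
                for i in range(3):
                    rows.append(
                        {"subject_id": f"{g}{s}{i}", "group": g, "sex": s, "wm_t2_ms": rng.normal(68, 3)}
                    )
        results = compare_groups(pd.DataFrame(rows), "wm_t2_ms", split="both")
        assert len(results) == 6  # C(4, 2) strata pairs

    def test_welch_differs_under_unequal_variance(self):
        table = _table([60.0, 80.0, 50.0, 90.0], [67.0, 67.1, 66.9, 67.0])
        pooled = compare_groups(table, "wm_t2_ms")
        welch = compare_groups(table, "wm_t2_ms", welch=True)
        assert pooled.p_value != welch.p_value


class TestCompareAdjusted:
    def _confounded_table(self, n=12, seed=0, noise_sd=0.3):
        # WM T2 is a linear function of WM volume plus group-independent
        # noise; groups differ only in volume, so adjusting for volume must
        # absorb the group difference.
        rng = np.random.default_rng(seed)
        rows = []
        for group, mean_vol in (("preterm", 0.35), ("term", 0.42)):
            for i in range(n):
                vol = rng.normal(mean_vol, 0.02)
                rows.append(
                    {
                        "subject_id": f"{group}{i}",
                        "group": group,
                        "sex": "female",
                        "wm_volume_l": vol,
                        "wm_t2_ms": 50.0 + 50.0 * vol + rng.normal(0.0, noise_sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_pure_confound_fully_explained(self):
        table = self._confounded_table()
        unadjusted = compare_groups(table, "wm_t2_ms")
        res = compare_adjusted(table, "wm_t2_ms", covariate="wm_volume_l")
        assert res.adjusted and res.covariate == "wm_volume_l"
        assert unadjusted.p_value < 1e-6  # the confound drives a huge raw effect
        assert res.p_value > 0.05  # which adjustment fully absorbs

    def test_matches_closed_form_ols_on_small_fixture(self):
        # 6-row fixture solved by explicit normal equations.
        table = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["preterm"] * 3 + ["term"] * 3,
                "sex": ["male"] * 6,
                "wm_t2_ms": [70.0, 68.0, 71.0, 66.0, 67.0, 65.0],
                "wm_volume_l": [0.36, 0.34, 0.35, 0.42, 0.44, 0.40],
            }
        )
        res = compare_adjusted(table, "wm_t2_ms", covariate="wm_volume_l")
        X = np.column_stack(
            [np.ones(6), (table.group == "preterm").astype(float), table.wm_volume_l]
        )
        y = table.wm_t2_ms.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.t_statistic == pytest.approx(beta[1] / se, rel=1e-9)

    def test_zero_variance_covariate_rejected(self):
        table = self._confounded_table().assign(wm_volume_l=0.4)
        with pytest.raises(ValueError, match="zero variance"):
            compare_adjusted(table, "wm_t2_ms", covariate="wm_volume_l")


class TestCohortReport:
    def test_strata_means_and_ratios(self):
        rows = []
        values = {"preterm": 0.35, "term": 0.40}
        for g, v in values.items():
            for s in ("male", "female"):
                for i in range(2):
                    rows.append(
                        {
                            "subject_id": f"{g}{s}{i}",
                            "group": g,
                            "sex": s,
                            "wm_volume_l": v + 0.01 * i,
                        }
                    )
        rep = cohort_report(pd.DataFrame(rows))
        assert rep["strata"]["preterm"]["wm_volume_l"]["mean"] == pytest.approx(0.355)
        expected_ratio = 0.355 / 0.405
        assert rep["volume_ratios"]["female"]["wm_volume_l"] == pytest.approx(expected_ratio)

    def test_single_subject_stratum_warns_sd_zero(self):
        rows = [
            {"subject_id": "a", "group": "preterm", "sex": "male", "wm_volume_l": 0.38},
            {"subject_id": "b", "group": "term", "sex": "female", "wm_volume_l": 0.41},
        ]
        with pytest.warns(UserWarning):
            rep = cohort_report(pd.DataFrame(rows))
        assert rep["strata"]["preterm"]["wm_volume_l"]["sd"] == 0.0
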