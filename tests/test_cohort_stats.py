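import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holterhrv import early_late_screen, lsd_compare, spearman, to_long


def brute_spearman_rho(x, y):
    """Independent oracle: average ranks by double loop, then the Pearson
    product-moment formula written out longhand."""

    def ranks(v):
        out = []
        for a in v:
            less = sum(1 for b in v if b < a)
            equal = sum(1 for b in v if b == a)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def long_table(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "age_months", "variable", "value"])


class TestSpearman:
    def test_monotone_is_one(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_reversal_flips_sign(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 0.5]
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x, [-v for v in y])
        assert rho2 == pytest.approx(-rho1)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 5, n).astype(float)  # ties guaranteed often
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(brute_spearman_rho(x, y), abs=1e-12)

    def test_neighbor_swap_case(self):
        x = list(range(8))
        y = [0, 1, 3, 2, 4, 5, 6, 7]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(brute_spearman_rho(x, y), abs=1e-12)

    def test_exact_permutation_p_small_n(self, rng):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, p = spearman(x, y)
        # oracle: enumerate all permutations explicitly
        ry = list(y)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = brute_spearman_rho(x, perm)
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_large_n_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=2.0, size=40)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLsdCompare:
    def _table(self, g1, g2, age=4.0, var="hr"):
        rows = []
        for i, v in enumerate(g1):
            rows.append((f"a{i}", "GRMD", age, var, v))
        for i, v in enumerate(g2):
            rows.append((f"b{i}", "healthy", age, var, v))
        return long_table(rows)

    def test_identical_groups_p_one(self):
        t = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = lsd_compare(t, "hr")
        c = res.contrasts[0]
        assert c.t_stat == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_single_timepoint_reduces_to_pooled_t(self, rng):
        g1 = rng.normal(10.0, 2.0, 8)
        g2 = rng.normal(12.0, 2.0, 8)
        res = lsd_compare(self._table(g1, g2), "hr")
        ref = stats.ttest_ind(g1, g2)  # classical pooled two-sample t
        assert res.contrasts[0].t_stat == pytest.approx(ref.statistic)
        assert res.contrasts[0].p_value == pytest.approx(ref.pvalue)

    def test_one_group_only_errors(self):
        rows = [(f"a{i}", "GRMD", 4.0, "hr", float(i)) for i in range(4)]
        with pytest.raises(ValueError, match="no contrast possible"):
            lsd_compare(long_table(rows), "hr")

    def test_pooled_df_zero_errors(self):
        rows = [("a0", "GRMD", 4.0, "hr", 1.0), ("b0", "healthy", 4.0, "hr", 2.0)]
        with pytest.raises(ValueError, match="pooled error df"):
            lsd_compare(long_table(rows), "hr")

    def test_pooled_error_shared_across_ages(self, rng):
        rows = []
        for age in (4.0, 12.0):
            for i in range(6):
                rows.append((f"a{i}", "GRMD", age, "hr", float(rng.normal(100, 5))))
                rows.append((f"b{i}", "healthy", age, "hr", float(rng.normal(90, 5))))
        res = lsd_compare(long_table(rows), "hr")
        assert res.pooled_df == 4 * (6 - 1)
        assert len(res.contrasts) == 2
        assert all(c.p_value is not None for c in res.contrasts)

    def test_planted_three_sd_shift_detected(self):
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            g1 = r.normal(100.0 + 3.0 * 5.0, 5.0, 8)
            g2 = r.normal(100.0, 5.0, 8)
            res = lsd_compare(self._table(g1, g2), "hr")
            if res.contrasts[0].p_value < 0.01:
                detected += 1
        assert detected >= int(0.9 * n_seeds)

    def test_age_effect_reported(self, rng):
        rows = []
        for age in (4.0, 12.0, 24.0):
            for i in range(5):
                rows.append((f"a{i}", "GRMD", age, "hr", float(rng.normal(120 - age, 3))))
                rows.append((f"b{i}", "healthy", age, "hr", float(rng.normal(110 - age, 3))))
        res = lsd_compare(long_table(rows), "hr")
        assert set(res.age_effect_p) == {"GRMD", "healthy"}
        assert res.age_effect_p["GRMD"] < 0.05


class TestScreen:
    def _planted_table(self, seed=0, n=8, beta=0.01, eps=0.05):
        r = np.random.default_rng(seed)
        rows = []
        vlf = r.lognormal(mean=7.0, sigma=0.6, size=n)
        lvfs = 20.0 + beta * vlf + r.normal(0, eps, n)
        hr = 140.0 - 0.002 * vlf + r.normal(0, 0.5, n)
        for i in range(n):
            rows.append((f"g{i}", "GRMD", 4.0, "vlf_ms2", vlf[i]))
            rows.append((f"g{i}", "GRMD", 4.0, "hr_bpm", hr[i]))
            rows.append((f"g{i}", "GRMD", 24.0, "lvfs_24m", lvfs[i]))
        return long_table(rows)

    def test_planted_positive_law_recovered(self):
        t = self._planted_table()
        res = early_late_screen(t, [("vlf_ms2", 4.0)], outcome="lvfs_24m")
        assert res[0].spearman_rho > 0.8
        assert res[0].n == 8

    def test_negative_hr_effect_sign(self):
        t = self._planted_table()
        res = early_late_screen(t, [("hr_bpm", 4.0)], outcome="lvfs_24m")
        assert res[0].spearman_rho < 0

    def test_shuffled_outcome_near_null(self):
        rhos = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            t = self._planted_table(seed=seed)
            mask = t["variable"] == "lvfs_24m"
            t.loc[mask, "value"] = r.permutation(t.loc[mask, "value"].to_numpy())
            res = early_late_screen(t, [("vlf_ms2", 4.0)], outcome="lvfs_24m")
            rhos.append(res[0].spearman_rho)
        assert abs(np.mean(rhos)) < 0.25

    def test_sorted_by_abs_rho_and_bh_column(self):
        t = self._planted_table()
        res = early_late_screen(
            t, [("vlf_ms2", 4.0), ("hr_bpm", 4.0)], outcome="lvfs_24m"
        )
        assert abs(res[0].spearman_rho) >= abs(res[1].spearman_rho)
        assert all(r.bh_q is not None for r in res)
        assert all(r.bh_q >= r.p_value - 1e-12 for r in res)

    def test_permutation_invariance_to_row_order(self, rng):
        t = self._planted_table()
        shuffled = t.sample(frac=1.0, random_state=7).reset_index(drop=True)
        r1 = early_late_screen(t, [("vlf_ms2", 4.0)])
        r2 = early_late_screen(shuffled, [("vlf_ms2", 4.0)])
        assert r1[0].spearman_rho == pytest.approx(r2[0].spearman_rho, abs=1e-12)

    def test_small_n_skipped(self):
        rows = [
            ("g0", "GRMD", 4.0, "x", 1.0),
            ("g0", "GRMD", 24.0, "lvfs_24m", 30.0),
            ("g1", "GRMD", 4.0, "x", 2.0),
            ("g1", "GRMD", 24.0, "lvfs_24m", 31.0),
        ]
        res = early_late_screen(long_table(rows), [("x", 4.0)])
        assert res == []

    def test_missing_outcome_errors(self):
        rows = [("g0", "GRMD", 4.0, "x", 1.0)]
        with pytest.raises(ValueError, match="outcome"):
            early_late_screen(long_table(rows), [("x", 4.0)])


class TestToLong:
    def test_melt_and_duplicate_guard(self):
        wide = pd.DataFrame(
            {
                "subject": ["a", "b"],
                "group": ["GRMD", "healthy"],
                "age_months": [4.0, 4.0],
                "hr_bpm": [120.0, 100.0],
                "vlf_ms2": [500.0, None],
            }
        )
        long = to_long(wide)
        assert len(long) == 3  # NaN dropped
        dup = pd.concat([wide, wide])
        with pytest.raises(ValueError, match="duplicate"):
            to_long(dup)
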