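import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from oppokin.io_formats import ValidationError
from oppokin.stats import (
    greenhouse_geisser_epsilon,
    huynh_feldt_epsilon,
    participant_means,
    posthoc_pairwise,
    rm_anova_1way,
    rm_anova_2way,
    rm_anova_effector,
)


def _long(X, factor="cond", subject="participant", value="value"):
    n, k = X.shape
    return pd.DataFrame(
        {
            subject: np.repeat([f"S{i}" for i in range(n)], k),
            factor: np.tile([f"c{j}" for j in range(k)], n),
            value: X.ravel(),
        }
    )


class TestParticipantMeans:
    def test_single_trial_identity(self, small_results):
        one = small_results[small_results["trial"] == small_results["trial"].min()]
        out = participant_means(one, "D")
        merged = one[one["measure"] == "D"].merge(
            out, on=["participant", "task", "effector", "measure"], suffixes=("", "_m")
        )
        np.testing.assert_allclose(merged["value"], merged["value_m"])

    def test_matches_groupby_oracle(self, small_results):
        out = participant_means(small_results, "z_D")
        oracle = (
            small_results[small_results["measure"] == "z_D"]
            .groupby(["participant", "task", "effector"])["value"]
            .mean()
        )
        for _, row in out.iterrows():
            assert row["value"] == pytest.approx(
                oracle.loc[(row["participant"], row["task"], row["effector"])]
            )

    def test_missing_cell_rejected(self, small_results):
        broken = small_results[
            ~(
                (small_results["participant"] == "P01")
                & (small_results["task"] == "ID")
            )
        ]
        with pytest.raises(ValidationError, match="incomplete"):
            participant_means(broken, "D")


class TestEpsilon:
    def test_two_levels_always_one(self, rng):
        X = rng.normal(size=(12, 2))
        assert huynh_feldt_epsilon(X) == 1.0

    def test_compound_symmetry_limit(self, rng):
        """Under compound symmetry sphericity holds, so epsilon -> 1 for
        large samples."""
        n, k = 200, 4
        subject = rng.normal(size=(n, 1))
        X = subject + rng.normal(size=(n, k))
        assert huynh_feldt_epsilon(X) > 0.95
        assert greenhouse_geisser_epsilon(X) > 0.90

    def test_gg_lower_bound(self, rng):
        """GG epsilon can never fall below 1/(k-1), even for maximally
        non-spherical data (all variance in one contrast)."""
        n, k = 30, 4
        base = rng.normal(size=(n, 1))
        X = np.hstack([base * 10, np.zeros((n, k - 1))]) + rng.normal(size=(n, k)) * 1e-3
        eps = greenhouse_geisser_epsilon(X)
        assert eps >= 1.0 / (k - 1) - 1e-12

    def test_matches_pingouin(self, rng):
        X = rng.normal(size=(10, 4)) @ np.diag([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame(X)
        assert greenhouse_geisser_epsilon(X) == pytest.approx(
            float(pg.epsilon(df, correction="gg")), rel=1e-10
        )
        assert huynh_feldt_epsilon(X) == pytest.approx(
            float(pg.epsilon(df, correction="hf")), rel=1e-10
        )

    def test_few_subjects_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            huynh_feldt_epsilon(rng.normal(size=(3, 4)))


class TestOneWayRmAnova:
    def test_zero_variance_gives_f_zero(self):
        X = np.tile([1.0, 1.0, 1.0], (6, 1)) + np.arange(6)[:, None]
        res = rm_anova_1way(X)
        assert res.f_value == 0.0 and res.p_value == 1.0

    def test_two_level_equals_paired_t_squared(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            X = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            res = rm_anova_1way(X)
            t, p = sps.ttest_rel(X[:, 0], X[:, 1])
            assert res.f_value == pytest.approx(t**2, abs=1e-8, rel=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_pingouin_multilevel(self, rng):
        X = rng.normal(size=(9, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
        res = rm_anova_1way(X)
        out = pg.rm_anova(
            data=_long(X, factor="cond"), dv="value", within="cond",
            subject="participant", correction=True, detailed=True,
        )
        assert res.f_value == pytest.approx(float(out.loc[0, "F"]), rel=1e-9)
        assert res.p_uncorrected == pytest.approx(float(out.loc[0, "p_unc"]), rel=1e-9)

    def test_effector_wrapper_and_design_errors(self, small_results):
        zd = participant_means(small_results, "z_D")
        task = zd[zd["task"] == "ID"]
        res = rm_anova_effector(task)
        wide = task.pivot_table(index="participant", columns="effector", values="value")
        t, _ = sps.ttest_rel(wide["thumb"], wide["finger"])
        assert res.f_value == pytest.approx(t**2, rel=1e-9)
        with pytest.raises(ValidationError, match="2 levels"):
            rm_anova_effector(task[task["effector"] == "thumb"])


class TestTwoWayRmAnova:
    def _cells(self, rng, n=8, a=4, b=3, effects=True):
        rows = []
        fa = [f"f{i}" for i in range(a)]
        fb = [f"p{j}" for j in range(b)]
        for s in range(n):
            s_off = rng.normal()
            for i, la in enumerate(fa):
                for j, lb in enumerate(fb):
                    mu = (0.4 * i + 0.7 * j) if effects else 0.0
                    rows.append(
                        {
                            "participant": f"S{s}",
                            "finger": la,
                            "phalanx": lb,
                            "value": mu + s_off + rng.normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_zero_variance_gives_all_f_zero(self):
        cells = self._cells(np.random.default_rng(0), effects=False)
        cells["value"] = 5.0
        for res in rm_anova_2way(cells).values():
            assert res.f_value == 0.0

    def test_ss_partition_is_exact(self, rng):
        cells = self._cells(rng)
        results = rm_anova_2way(cells)
        wide = cells.pivot_table(
            index="participant", columns=["finger", "phalanx"], values="value"
        ).to_numpy()
        ss_total = float(((wide - wide.mean()) ** 2).sum())
        n = wide.shape[0]
        subj = wide.mean(axis=1)
        ss_subj = 12 * float(((subj - wide.mean()) ** 2).sum())
        parts = ss_subj + sum(r.ss_effect + r.ss_error for r in results.values())
        assert parts == pytest.approx(ss_total, rel=1e-12)

    def test_matches_pingouin_two_way(self, rng):
        cells = self._cells(rng)
        res = rm_anova_2way(cells)
        out = pg.rm_anova(
            data=cells, dv="value", within=["finger", "phalanx"],
            subject="participant", detailed=True,
        ).set_index("Source")
        assert res["finger"].f_value == pytest.approx(float(out.loc["finger", "F"]), rel=1e-8)
        assert res["phalanx"].f_value == pytest.approx(float(out.loc["phalanx", "F"]), rel=1e-8)
        inter = [s for s in out.index if "*" in s][0]
        assert res["interaction"].f_value == pytest.approx(float(out.loc[inter, "F"]), rel=1e-8)

    def test_f_invariant_to_shift_and_scale(self, rng):
        cells = self._cells(rng)
        base = {k: r.f_value for k, r in rm_anova_2way(cells).items()}
        shifted = cells.copy()
        shifted["value"] = 3.0 * shifted["value"] + 11.0
        other = {k: r.f_value for k, r in rm_anova_2way(shifted).items()}
        for k in base:
            assert other[k] == pytest.approx(base[k], rel=1e-9)

    def test_adjusted_p_not_smaller_when_eps_below_one(self, rng):
        """Shrinking both degrees of freedom inflates the p-value whenever
        F >= 1 (for F < 1 the F-distribution tail behaves oppositely, so the
        guarantee is scoped to the rejection-relevant regime)."""
        for seed in range(5):
            cells = self._cells(np.random.default_rng(seed))
            for res in rm_anova_2way(cells).values():
                if res.f_value >= 1.0:
                    assert res.p_value >= res.p_uncorrected - 1e-12
                assert 0.0 < res.epsilon_hf <= 1.0

    def test_reduced_two_level_factor_equals_paired_t(self, rng):
        cells = self._cells(rng, a=2, b=2)
        res = rm_anova_2way(cells)["finger"]
        wide = cells.pivot_table(index="participant", columns="finger", values="value")
        t, _ = sps.ttest_rel(wide["f0"], wide["f1"])
        assert res.f_value == pytest.approx(t**2, abs=1e-8, rel=1e-8)
        assert res.epsilon_hf == 1.0

    def test_incomplete_design_rejected(self, rng):
        cells = self._cells(rng)
        broken = cells[~((cells.participant == "S0") & (cells.finger == "f0"))]
        with pytest.raises(ValidationError, match="incomplete"):
            rm_anova_2way(broken)


class TestPosthoc:
    def test_identical_levels_all_p_one(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = posthoc_pairwise(_long(X), "cond")
        assert all(r.p_adjusted == 1.0 for r in res)

    def test_adjusted_p_never_below_raw(self, rng):
        X = rng.normal(size=(10, 4))
        for method in ("bonferroni", "holm"):
            for r in posthoc_pairwise(_long(X), "cond", method=method):
                assert r.p_adjusted >= r.p_raw - 1e-15

    def test_strong_monotone_effect_all_pairs_significant(self, rng):
        """A distal > middle > proximal gradient large against the paired
        noise makes every pairwise comparison significant at 0.001
        (n = 8 participants, 1.0 separation vs 0.15 noise)."""
        n = 8
        X = np.array([2.0, 1.0, 0.0]) + rng.normal(size=(n, 3)) * 0.15
        res = posthoc_pairwise(_long(X, factor="phalanx"), "phalanx")
        assert len(res) == 3
        assert all(r.p_adjusted < 0.001 for r in res)
        # ordering information is reported
        diffs = {(r.level_a, r.level_b): r.mean_diff for r in res}
        assert diffs[("c0", "c1")] > 0 and diffs[("c1", "c2")] > 0

    def test_bonferroni_matches_manual(self, rng):
        X = rng.normal(size=(9, 3))
        res = posthoc_pairwise(_long(X), "cond", method="bonferroni")
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            posthoc_pairwise(_long(rng.normal(size=(5, 3))), "cond", method="fdr")
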