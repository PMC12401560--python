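"""Group statistics: ANCOVA, nonparametrics, bootstrap, effect sizes, ICC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fastball.stats import (
    ancova_group_by_electrode,
    ancova_max_electrode,
    bootstrap_regression,
    cohens_d,
    icc_band,
    icc_two_way,
    kruskal_wallis_posthoc,
)


class TestCohensD:
    def test_one_sd_shift(self, rng):
        x = rng.normal(0, 1, 100_000)
        assert cohens_d(x + 1, x) == pytest.approx(1.0, abs=0.01)

    def test_identical_samples(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_textbook_two_sample(self):
        # hand computation: means 4 and 2, pooled SD sqrt(((2)*1 + (2)*1)/4) = 1
        x, y = [3, 4, 5], [1, 2, 3]
        assert cohens_d(x, y) == pytest.approx(2.0)


def metrics_table_for(groups, n_per_group, rng, shift=0.0, electrodes=("Cz", "P8")):
    rows = []
    for gi, g in enumerate(groups):
        for s in range(n_per_group):
            sid = f"{g}_{s}"
            cov = rng.normal(5, 1)
            base = rng.normal(2 + shift * gi, 0.5)
            f_by_e = {e: base + rng.normal(0, 0.2) for e in electrodes}
            fmax = max(f_by_e.values())
            for e in electrodes:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": g,
                        "electrode": e,
                        "f_plus": f_by_e[e],
                        "F_snr": cov,
                        "f_plus_max": fmax,
                        "F_snr_scalp_avg": cov,
                    }
                )
    return pd.DataFrame(rows)


class TestANCOVA:
    def test_identical_groups_give_null_group_effect(self, rng):
        tbl_a = metrics_table_for(["A"], 12, np.random.default_rng(1))
        tbl_b = tbl_a.copy()
        tbl_b["group"] = "B"
        tbl_b["subject_id"] = tbl_b["subject_id"].str.replace("A", "B")
        tbl = pd.concat([tbl_a, tbl_b], ignore_index=True)
        res = ancova_group_by_electrode(tbl)
        row = res["anova"].loc["C(group, Sum)"]
        assert row["F"] == pytest.approx(0.0, abs=1e-10)
        assert row["PR(>F)"] == pytest.approx(1.0, abs=1e-10)
        assert res["cohens_d"]["A vs B"] == pytest.approx(0.0, abs=1e-12)

    def test_group_shift_detected(self, rng):
        tbl = metrics_table_for(["A", "B"], 30, rng, shift=0.8)
        res = ancova_group_by_electrode(tbl)
        assert res["anova"].loc["C(group, Sum)", "PR(>F)"] < 0.001

    def test_type_iii_ss_match_projection_oracle(self, rng):
        # brute force: SS(term) = RSS(model without term) - RSS(full),
        # with sum-to-zero coding built by hand for 2x2 factors
        tbl = metrics_table_for(["A", "B"], 4, rng, shift=0.5)
        g = np.where(tbl["group"] == "A", 1.0, -1.0)
        e = np.where(tbl["electrode"] == "Cz", 1.0, -1.0)
        cov = tbl["F_snr"].to_numpy()
        y = tbl["f_plus"].to_numpy()
        cols = {
            "Intercept": np.ones(len(tbl)),
            "C(group, Sum)": g,
            "C(electrode, Sum)": e,
            "C(group, Sum):C(electrode, Sum)": g * e,
            "F_snr": cov,
        }

        def rss(names):
            X = np.column_stack([cols[n] for n in names])
            r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return r @ r

        full = rss(list(cols))
        res = ancova_group_by_electrode(tbl)["anova"]
        for term in ["C(group, Sum)", "C(electrode, Sum)", "C(group, Sum):C(electrode, Sum)", "F_snr"]:
            others = [n for n in cols if n != term]
            assert res.loc[term, "sum_sq"] == pytest.approx(rss(others) - full, rel=1e-8)

    def test_singular_design_names_aliased_terms(self, rng):
        tbl = metrics_table_for(["A", "B"], 6, rng)
        tbl["F_snr"] = 1.0  # constant covariate aliases the intercept
        with pytest.raises(ValueError, match="aliased"):
            ancova_group_by_electrode(tbl)

    def test_max_electrode_model_runs(self, rng):
        tbl = metrics_table_for(["A", "B", "C"], 15, rng, shift=0.5)
        res = ancova_max_electrode(tbl)
        assert "C(group, Sum)" in res["anova"].index
        assert set(res["cohens_d"]) == {"A vs B", "A vs C", "B vs C"}


class TestKruskalWallis:
    def test_identical_groups(self):
        tbl = pd.DataFrame(
            {"group": ["A"] * 10 + ["B"] * 10 + ["C"] * 10, "y": list(range(10)) * 3}
        )
        res = kruskal_wallis_posthoc(tbl, "y")
        assert res["p"] == pytest.approx(1.0, abs=1e-9)
        assert res["df"] == 2

    def test_complete_separation(self):
        tbl = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3, "y": [1, 2, 3, 4, 5, 6]})
        res = kruskal_wallis_posthoc(tbl, "y")
        row = res["posthoc"].iloc[0]
        assert row["U"] == 0.0
        assert row["Z"] < 0

    def test_normal_approximation_close_to_exact_permutation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([4.0, 6.0, 7.0, 8.0])
        tbl = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4, "y": np.r_[x, y]})
        row = kruskal_wallis_posthoc(tbl, "y")["posthoc"].iloc[0]
        # exact two-sided p by enumerating all group assignments
        pooled = np.r_[x, y]
        u_obs = row["U"]

        def u_stat(idx):
            xs = pooled[list(idx)]
            ranks = pd.Series(pooled).rank().to_numpy()
            r1 = ranks[list(idx)].sum()
            return r1 - len(idx) * (len(idx) + 1) / 2

        n1n2 = len(x) * len(y)
        us = [u_stat(idx) for idx in itertools.combinations(range(8), 4)]
        dev = abs(u_obs - n1n2 / 2)
        p_exact = np.mean([abs(u - n1n2 / 2) >= dev - 1e-9 for u in us])
        assert row["p"] == pytest.approx(p_exact, abs=0.06)


class TestBootstrapRegression:
    def test_noiseless_slope_recovered_with_degenerate_ci(self, rng):
        x = rng.normal(size=40)
        res = bootstrap_regression(pd.DataFrame({"x": x}), 2 * x, B=200, seed=1)
        assert res.coef["x"] == pytest.approx(2.0)
        assert res.ci.loc["x", "upper"] - res.ci.loc["x", "lower"] < 1e-9
        assert res.p_boot["x"] < 0.02

    def test_seeded_runs_bit_identical(self, rng):
        x = rng.normal(size=50)
        y = 1 + 0.5 * x + rng.normal(size=50)
        X = pd.DataFrame({"x": x})
        a = bootstrap_regression(X, y, B=300, seed=7)
        b = bootstrap_regression(X, y, B=300, seed=7)
        assert a.ci.equals(b.ci) and a.p_boot.equals(b.p_boot)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            bootstrap_regression(X, x, B=200, seed=0)

    def test_small_b_warns(self, rng):
        x = rng.normal(size=30)
        with pytest.warns(UserWarning):
            bootstrap_regression(pd.DataFrame({"x": x}), x, B=50, seed=0)

    def test_standardized_coefficient_scale(self, rng):
        x = rng.normal(0, 3, size=400)
        y = 2 * x + rng.normal(0, 1, size=400)
        res = bootstrap_regression(pd.DataFrame({"x": x}), y, B=200, seed=3)
        # nearly deterministic relation: standardized beta close to r ~ 0.986
        assert res.std_coef["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.01)


class TestICC:
    def test_perfect_replication(self):
        M = np.tile(np.arange(10.0)[:, None], (1, 2))
        res = icc_two_way(M)
        assert res.icc_single_consistency == 1.0
        assert res.icc_single_agreement == pytest.approx(1.0)
        assert res.icc_average_agreement == pytest.approx(1.0)

    def test_constant_session_shift(self):
        s1 = np.arange(10.0)
        M = np.column_stack([s1, s1 + 3.0])
        res = icc_two_way(M)
        assert res.icc_single_consistency == pytest.approx(1.0)
        assert res.icc_single_agreement < 1.0
        assert res.bias_F[0] > 1e6  # infinite-ish session bias

    def test_matches_independent_implementation(self, rng):
        M = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        res = icc_two_way(M)
        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "session": np.tile([1, 2], 10),
                "y": M.ravel(),
            }
        )
        tbl = pg.intraclass_corr(long, targets="subject", raters="session", ratings="y")
        tbl = tbl.set_index("Type")
        assert res.icc_single_agreement == pytest.approx(tbl.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res.icc_single_consistency == pytest.approx(tbl.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert res.icc_average_agreement == pytest.approx(tbl.loc["ICC(A,k)", "ICC"], abs=1e-9)
        assert res.icc_average_consistency == pytest.approx(tbl.loc["ICC(C,k)", "ICC"], abs=1e-9)
        ci = tbl.loc["ICC(C,1)", "CI95"]
        assert res.ci["single_consistency"] == pytest.approx(tuple(ci), abs=0.005)

    def test_agreement_never_exceeds_consistency(self, rng):
        # holds when both estimated variance components are non-negative
        # (for negative reliabilities the arithmetic ordering reverses)
        checked = 0
        for _ in range(30):
            M = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
            M[:, 1] += rng.normal(0, 0.5)  # session effect
            res = icc_two_way(M)
            ms = res.mean_squares
            if ms["msc"] >= ms["mse"] and ms["msr"] >= ms["mse"]:
                assert res.icc_single_agreement <= res.icc_single_consistency + 1e-12
                assert res.icc_average_agreement <= res.icc_average_consistency + 1e-12
                checked += 1
        assert checked > 0

    def test_missing_sessions_dropped(self, rng):
        M = rng.normal(size=(12, 2))
        M[3, 1] = np.nan
        res = icc_two_way(M)
        assert res.n_subjects == 11
        assert res.n_dropped == 1

    def test_permutation_invariance(self, rng):
        M = rng.normal(size=(15, 2))
        perm = rng.permutation(15)
        a = icc_two_way(M)
        b = icc_two_way(M[perm])
        assert a.icc_single_agreement == pytest.approx(b.icc_single_agreement)


class TestICCBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.58, "moderate"), (0.74, "good"), (0.39, "poor"), (0.40, "poor"),
         (0.41, "moderate"), (0.60, "good"), (0.75, "excellent"), (0.90, "excellent")],
    )
    def test_band_labels(self, value, band):
        assert icc_band(value) == band
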