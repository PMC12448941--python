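"""Statistical chain: filters, VIF, mixed model, multiplicity, report."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from tractgain import (
    RandomInterceptLME,
    SimulationConfig,
    bonferroni_adjust,
    compute_vif,
    drop_collinear,
    filter_observations,
    fit_lme,
    report,
    simulate_coupled_dataset,
)
from tractgain.association import results_table
from tractgain.errors import ConfigurationError, DataError


def _table(rng, n_subj=6, n_per=30, beta=(30.0, 6.0, 1.0, -0.01),
           sb=2.0, se=4.0):
    rows = []
    for i in range(n_subj):
        b = rng.normal(0, sb)
        fa = rng.uniform(0.2, 0.6, n_per)
        npa = rng.uniform(0, 10, n_per)
        ln = rng.uniform(10, 200, n_per)
        y = (beta[0] + beta[1] * fa + beta[2] * npa + beta[3] * ln
             + b + rng.normal(0, se, n_per))
        rows.append(pd.DataFrame(dict(
            subject=f"s{i}", fa=fa, n_per_area=npa, length=ln,
            pf_ratio=y, peak_gain=y, omega_p=np.full(n_per, 10.0))))
    return pd.concat(rows, ignore_index=True)


class TestFilterObservations:
    def test_identical_rows_not_removed(self):
        df = pd.DataFrame(dict(subject=["a"] * 5, pf_ratio=1.0, peak_gain=2.0,
                               omega_p=10.0))
        filtered, audit = filter_observations(df)
        assert len(filtered) == 5 and audit.empty

    def test_planted_outlier_removed_with_reason(self, rng):
        df = _table(rng)
        mean = df.loc[df.subject == "s0", "pf_ratio"].mean()
        sd = df.loc[df.subject == "s0", "pf_ratio"].std()
        df.loc[0, "pf_ratio"] = mean + 5 * sd
        filtered, audit = filter_observations(df)
        assert 0 not in filtered.index
        reasons = audit.set_index("index")["reason"]
        assert reasons.loc[0].startswith("outlier:pf_ratio")

    def test_low_peak_frequency_removed_regardless_of_value(self, rng):
        df = _table(rng)
        df.loc[3, "omega_p"] = 1.0
        filtered, audit = filter_observations(df, min_peak_freq=1.5)
        assert 3 not in filtered.index
        assert (audit.set_index("index").loc[3, "reason"] == "low_peak_freq")

    def test_single_pass_idempotence(self, rng):
        df = _table(rng)
        df.loc[5, "pf_ratio"] += 100.0
        once, _ = filter_observations(df)
        twice, audit2 = filter_observations(once)
        # a second pass on the already-filtered table may only act on the
        # recomputed statistics; with a single planted outlier nothing is left
        assert len(audit2) == 0
        assert twice.equals(once)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            filtered, audit = filter_observations(pd.DataFrame(
                columns=["subject", "pf_ratio", "peak_gain", "omega_p"]))
        assert filtered.empty and audit.empty


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        design = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
            "c": np.cos(4 * np.pi * t / n),
        })
        vifs = compute_vif(design)
        np.testing.assert_allclose(vifs.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=50)
        vifs = compute_vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_correlation_09_closed_form(self, rng):
        """r = 0.9 exactly: VIF = 1/(1−0.81) ≈ 5.263."""
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # exact orthogonalization
        z /= z.std()
        y = 0.9 * x + np.sqrt(1 - 0.81) * z
        vifs = compute_vif(pd.DataFrame({"x": x, "y": y}))
        assert vifs["x"] == pytest.approx(1 / (1 - 0.81), abs=0.01)

    def test_vif_always_at_least_one(self, rng):
        design = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        assert (compute_vif(design) >= 1.0 - 1e-12).all()


class TestDropCollinear:
    def test_replication_policy_drops_ad_keeps_fa(self, rng):
        x = rng.normal(size=300)
        design = pd.DataFrame({
            "fa": x, "ad": x + 0.05 * rng.normal(size=300),
            "n_per_area": rng.normal(size=300), "length": rng.normal(size=300),
        })
        reduced, dropped = drop_collinear(design, policy="replication")
        assert dropped == ["ad"]
        assert "fa" in reduced.columns

    def test_no_flags_leaves_design_unchanged(self, rng):
        design = pd.DataFrame(rng.normal(size=(100, 3)), columns=["fa", "n_per_area", "length"])
        reduced, dropped = drop_collinear(design, policy="generic")
        assert dropped == [] and list(reduced.columns) == list(design.columns)

    def test_iterative_drop_of_mutually_collinear_set(self, rng):
        x = rng.normal(size=400)
        design = pd.DataFrame({
            "p": x + 0.01 * rng.normal(size=400),
            "q": x + 0.01 * rng.normal(size=400),
            "r": x + 0.01 * rng.normal(size=400),
            "s": rng.normal(size=400),
        })
        reduced, dropped = drop_collinear(design, policy="generic")
        assert (compute_vif(reduced) <= 5.0).all()
        assert len(dropped) == 2


class TestMixedModel:
    def test_noiseless_exact_recovery(self):
        cfg = SimulationConfig(random_intercept_sd=0.0, residual_sd=0.0,
                               true_beta=(30.0, 6.0, 1.0, -0.01))
        table, truth = simulate_coupled_dataset(cfg, seed=2)
        res = fit_lme(table, "pf_ratio")
        np.testing.assert_allclose(res.params, truth.true_beta, atol=1e-6)

    def test_zero_random_variance_agrees_with_ols(self, rng):
        df = _table(rng, sb=0.0, se=3.0)
        # remove all between-subject variation so the REML estimate of the
        # random-intercept variance sits at the zero boundary
        df["pf_ratio"] -= df.groupby("subject")["pf_ratio"].transform("mean")
        with pytest.warns(UserWarning, match="boundary"):
            res = fit_lme(df, "pf_ratio")
        assert res.sigma_b2 == 0.0
        X = np.column_stack([np.ones(len(df)), df.fa, df.n_per_area, df.length])
        ols = np.linalg.lstsq(X, df.pf_ratio.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.params, ols, atol=1e-6)

    def test_variance_components_recovered_when_clusters_dominate(self, rng):
        df = _table(rng, n_subj=40, n_per=25, sb=5.0, se=1.0)
        res = fit_lme(df, "pf_ratio")
        icc = res.sigma_b2 / (res.sigma_b2 + res.sigma_e2)
        true_icc = 25.0 / 26.0
        assert icc == pytest.approx(true_icc, abs=0.05)

    def test_monte_carlo_recovery_of_all_fixed_effects(self):
        """Replicate means of every coefficient lie within 2 MC SEs of truth."""
        cfg = SimulationConfig()
        n_rep = 60
        ests = []
        for rep in range(n_rep):
            table, _ = simulate_coupled_dataset(cfg, seed=5000 + rep)
            ests.append(fit_lme(table, "pf_ratio").params)
        ests = np.asarray(ests)
        truth = np.array(cfg.true_beta)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(ests.mean(axis=0) - truth) < 2.5 * mc_se + 1e-12)

    def test_single_group_falls_back_to_ols(self, rng):
        df = _table(rng, n_subj=1, n_per=50, sb=0.0)
        with pytest.warns(UserWarning, match="single group"):
            res = fit_lme(df, "pf_ratio")
        assert res.sigma_b2 == 0.0 and res.n_subjects == 1

    def test_groups_required(self, rng):
        model = RandomInterceptLME()
        with pytest.raises(ConfigurationError):
            model.fit(rng.normal(size=(20, 2)), rng.normal(size=20))


class TestAgainstLmerTest:
    """Independent oracle: R lme4/lmerTest on the same small dataset."""

    def test_estimates_se_df_match_lmertest(self, rng, tmp_path):
        df = _table(rng, n_subj=8, n_per=40)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(pf_ratio ~ fa + n_per_area + length + (1|subject), data=d, REML=TRUE)
co <- summary(m)$coefficients
vc <- as.data.frame(VarCorr(m))
out <- list(est=unname(co[,1]), se=unname(co[,2]), df=unname(co[,3]),
            sb2=vc$vcov[1], se2=vc$vcov[2])
cat(jsonlite::toJSON(out, digits=12))
""")
        proc = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(proc.stdout)
        res = fit_lme(df, "pf_ratio")
        np.testing.assert_allclose(res.params, ref["est"], rtol=1e-4)
        np.testing.assert_allclose(res.bse, ref["se"], rtol=1e-4)
        np.testing.assert_allclose(res.df, ref["df"], rtol=2e-2)
        assert res.sigma_b2 == pytest.approx(ref["sb2"][0], rel=1e-3, abs=1e-6)
        assert res.sigma_e2 == pytest.approx(ref["se2"][0], rel=1e-3)


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 3, 0.03),
        (0.5, 3, 1.0),
        (0.2, 1, 0.2),
    ])
    def test_scalar_cases(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_vector_matches_scalar_loop(self, rng):
        p = rng.uniform(size=10)
        adj = bonferroni_adjust(p, 4)
        for pi, ai in zip(p, adj):
            assert ai == bonferroni_adjust(float(pi), 4)

    def test_identity_when_single_test(self, rng):
        p = rng.uniform(size=5)
        np.testing.assert_allclose(bonferroni_adjust(p, 1), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bonferroni_adjust(1.5, 2)


class TestReport:
    def _results(self, rng):
        df = _table(rng)
        return {"pf_ratio": fit_lme(df, "pf_ratio"),
                "peak_gain": fit_lme(df, "peak_gain")}

    def test_schema_and_invariants(self, rng):
        results = self._results(rng)
        rep = report(results)
        for name, entry in rep["outcomes"].items():
            assert 0.0 <= entry["marginal_r2"] <= 1.0
            for term, c in entry["coefficients"].items():
                assert c["ci"][0] <= c["estimate"] <= c["ci"][1]
                assert c["p_adj"] >= c["p"] - 1e-15
                assert c["p_adj"] <= 1.0
        table = results_table(results)
        assert {"outcome", "R2", "n_obs", "N_pid"} <= set(table.columns)

    def test_serialization_roundtrip_is_byte_identical(self, rng):
        rep = report(self._results(rng))
        s1 = json.dumps(rep, sort_keys=True, indent=2)
        s2 = json.dumps(json.loads(s1), sort_keys=True, indent=2)
        assert s1 == s2
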