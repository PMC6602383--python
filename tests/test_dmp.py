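"""Per-probe association models: OLS and the donor-random-intercept REML fit.

Oracles: OLS against explicit normal equations; the mixed model against a
dense grid over the variance ratio on the same REML criterion computed
independently with full matrix inverses.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcortex import dmp
from methcortex import synthdata as sd
from methcortex.ioformats import FormatError


def _pheno(n_ctl, n_case, region="PFC", rng=None, case="iASD"):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_ctl + n_case):
        rows.append(
            {
                "sample_id": f"s{i}",
                "donor_id": f"d{i}",
                "region": region,
                "diagnosis": case if i >= n_ctl else "CTL",
                "age": float(rng.uniform(10, 70)),
                "sex": "M" if rng.random() < 0.5 else "F",
                "bank": rng.choice(["A", "B"]),
                "neuronal_proportion": float(rng.uniform(0.2, 0.6)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


class TestOls:
    def test_constant_probe_gives_zero_effect_p_one(self):
        ph = _pheno(4, 4)
        beta = pd.DataFrame(0.42, index=["cg1"], columns=ph.index)
        res = dmp.fit_ols(beta, ph, case="iASD", covariates=())
        assert res.loc["cg1", "effect"] == pytest.approx(0.0)
        assert res.loc["cg1", "p_value"] == 1.0

    def test_two_group_means_without_covariates(self):
        ph = _pheno(2, 2)
        beta = pd.DataFrame([[0.1, 0.1, 0.3, 0.3]], index=["cg1"], columns=ph.index)
        res = dmp.fit_ols(beta, ph, case="iASD", covariates=())
        assert res.loc["cg1", "effect"] == pytest.approx(0.2)

    def test_matches_normal_equations_oracle(self):
        """Effect and SE match a brute-force normal-equations solution on
        hundreds of random small designs."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(8, 20))
            ph = _pheno(n // 2, n - n // 2, rng=rng)
            beta = pd.DataFrame(
                rng.uniform(0.1, 0.9, size=(1, n)), index=["cg1"], columns=ph.index
            )
            res = dmp.fit_ols(beta, ph, case="iASD", covariates=("age", "sex"))
            x = np.column_stack(
                [
                    np.ones(n),
                    (ph["diagnosis"] == "iASD").to_numpy(float),
                    ph["age"].to_numpy(float),
                    (ph["sex"] == "M").to_numpy(float),
                ]
            )
            if np.linalg.matrix_rank(x) < x.shape[1]:
                continue  # e.g. single-sex draw: design not estimable
            y = beta.iloc[0].to_numpy()
            xtx_inv = np.linalg.inv(x.T @ x)
            coef = xtx_inv @ x.T @ y
            resid = y - x @ coef
            s2 = resid @ resid / (n - x.shape[1])
            se = np.sqrt(s2 * xtx_inv[1, 1])
            assert res.loc["cg1", "effect"] == pytest.approx(coef[1], abs=1e-8)
            assert res.loc["cg1", "se"] == pytest.approx(se, abs=1e-8)

    def test_planted_effect_recovered_with_power(self):
        rng = np.random.default_rng(2)
        ph = _pheno(30, 30, rng=rng)
        case = (ph["diagnosis"] == "iASD").to_numpy(float)
        y = 0.4 + 0.1 * case + rng.normal(0, 0.03, len(ph))
        beta = pd.DataFrame([y], index=["cg1"], columns=ph.index)
        res = dmp.fit_ols(beta, ph, case="iASD", covariates=())
        assert res.loc["cg1", "effect"] == pytest.approx(0.1, abs=0.02)
        assert res.loc["cg1", "p_value"] < 1.198e-7

    def test_singular_design_flagged(self):
        ph = _pheno(4, 4)
        ph["bank"] = np.where(ph["diagnosis"] == "iASD", "X", "Y")  # confounded
        beta = pd.DataFrame(
            np.random.default_rng(0).uniform(size=(3, 8)), index=list("abc"), columns=ph.index
        )
        res = dmp.fit_ols(beta, ph, case="iASD", covariates=("bank",))
        assert res["p_value"].isna().all()

    def test_listwise_deletion(self):
        rng = np.random.default_rng(3)
        ph = _pheno(10, 10, rng=rng)
        y = rng.uniform(0.2, 0.8, 20)
        beta = pd.DataFrame([y], index=["cg1"], columns=ph.index)
        beta.iloc[0, :3] = np.nan
        res = dmp.fit_ols(beta, ph, case="iASD", covariates=())
        assert res.loc["cg1", "n_used"] == 17
        sub = ph.index[3:]
        res_sub = dmp.fit_ols(beta[sub], ph.loc[sub], case="iASD", covariates=())
        assert res.loc["cg1", "effect"] == pytest.approx(res_sub.loc["cg1", "effect"], abs=1e-12)


def _reml_oracle(y, x, z, lam_grid):
    """-2 restricted log-likelihood evaluated naively for each lambda."""
    n, p = x.shape
    crits = []
    for lam in lam_grid:
        v = np.eye(n) + lam * (z @ z.T)
        vi = np.linalg.inv(v)
        a = x.T @ vi @ x
        b = x.T @ vi @ y
        coef = np.linalg.solve(a, b)
        rss = (y - x @ coef) @ vi @ (y - x @ coef)
        sign, logdet_v = np.linalg.slogdet(v)
        crit = (n - p) * np.log(rss) + logdet_v + np.linalg.slogdet(a)[1]
        crits.append(crit)
    return np.array(crits)


class TestLme:
    @staticmethod
    def _paired_pheno(n_donors, rng, case="iASD"):
        rows = []
        for i in range(n_donors):
            dx = case if i >= n_donors // 2 else "CTL"
            for region in ("PFC", "TC"):
                rows.append(
                    {
                        "sample_id": f"d{i}_{region}",
                        "donor_id": f"d{i}",
                        "region": region,
                        "diagnosis": dx,
                        "age": float(rng.uniform(10, 70)),
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "bank": "A",
                        "neuronal_proportion": np.nan,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def test_zero_donor_variance_reduces_to_pooled_ols(self):
        """When donor means carry no extra variance (within-donor symmetric
        noise), the variance ratio hits the boundary and the fixed effect
        equals pooled OLS."""
        rng = np.random.default_rng(4)
        ph = self._paired_pheno(20, rng)
        noise = rng.normal(0, 0.03, 20)
        y = 0.5 + np.repeat(0.0, 40)
        # antisymmetric within donors: donor means are all exactly 0.5
        y = 0.5 + np.concatenate([[e, -e] for e in noise])
        case = (ph["diagnosis"] == "iASD").to_numpy(float)
        y = y + 0.02 * case
        beta = pd.DataFrame([y], index=["cg1"], columns=ph.index)
        lme = dmp.fit_lme(beta, ph, case="iASD", covariates=(), include_region_effect=False)
        ols = dmp.fit_ols(beta, ph, case="iASD", covariates=())
        assert lme.loc["cg1", "variance_ratio"] == 0.0
        assert lme.loc["cg1", "effect"] == pytest.approx(ols.loc["cg1", "effect"], abs=1e-6)

    def test_reml_optimum_beats_dense_grid(self):
        """The profiled optimum's criterion is at least as good as any point
        of an independent dense grid (step 1e-3 on the ratio)."""
        rng = np.random.default_rng(5)
        ph = self._paired_pheno(12, rng)
        donor = pd.Categorical(ph["donor_id"]).codes
        z = np.zeros((len(ph), donor.max() + 1))
        z[np.arange(len(ph)), donor] = 1.0
        for rep in range(5):
            y = (
                0.5
                + 0.03 * (ph["diagnosis"] == "iASD").to_numpy(float)
                + z @ rng.normal(0, 0.03, z.shape[1])
                + rng.normal(0, 0.02, len(ph))
            )
            beta = pd.DataFrame([y], index=["cg1"], columns=ph.index)
            res = dmp.fit_lme(beta, ph, case="iASD", covariates=(), include_region_effect=False)
            lam_hat = res.loc["cg1", "variance_ratio"]
            x = np.column_stack([np.ones(len(ph)), (ph["diagnosis"] == "iASD").to_numpy(float)])
            grid = np.arange(0.0, 5.0, 1e-3)
            oracle = _reml_oracle(y, x, z, np.append(grid, lam_hat))
            assert oracle[-1] <= oracle[:-1].min() + 1e-6

    def test_single_region_matches_ols(self):
        rng = np.random.default_rng(6)
        ph = _pheno(10, 10, rng=rng)
        y = rng.uniform(0.2, 0.8, 20)
        beta = pd.DataFrame([y], index=["cg1"], columns=ph.index)
        lme = dmp.fit_lme(
            beta, ph, case="iASD", regions=("PFC",), covariates=("age",), include_region_effect=True
        )
        ols = dmp.fit_ols(beta, ph, case="iASD", region="PFC", covariates=("age",))
        # one sample per donor: no donor variance is estimable
        assert lme.loc["cg1", "effect"] == pytest.approx(ols.loc["cg1", "effect"], abs=1e-6)

    def test_planted_cross_cortex_effect_recovered(self, cortex_cohort):
        design, man, beta, _, pheno, truth = cortex_cohort
        spiked = truth.spiked_dmps["probe_id"]
        res = dmp.fit_lme(beta.loc[spiked], pheno, case="iASD")
        expected = truth.spiked_dmps.set_index("probe_id")["delta"]
        err = (res["effect"] - expected).abs()
        assert err.median() < 0.02


class TestThresholdsAndCalls:
    def test_experiment_wide_threshold_from_probe_count(self):
        # 0.05 / 417460 = 1.1977e-7
        thr = dmp.experiment_wide_threshold(417_460)
        assert thr == pytest.approx(1.198e-7, rel=5e-4)

    def test_boundary_p_not_discovery(self):
        res = pd.DataFrame(
            {"p_value": [5e-05, 4.9e-05, 1e-9]}, index=["a", "b", "c"]
        )
        calls = dmp.call_dmps(res, n_probes=417_460)
        assert calls.loc["a", "tier"] == ""
        assert calls.loc["b", "tier"] == "discovery"
        assert calls.loc["c", "tier"] == "experiment-wide"

    def test_experiment_wide_subset_of_discovery(self, cortex_cohort):
        _, _, beta, _, pheno, _ = cortex_cohort
        res = dmp.call_dmps(dmp.fit_lme(beta, pheno, case="iASD"))
        ew = set(res.index[res["tier"] == "experiment-wide"])
        disc = set(res.index[res["tier"] != ""])
        assert ew <= disc

    def test_empty_results(self):
        calls = dmp.call_dmps(pd.DataFrame(columns=["p_value"]))
        assert len(calls) == 0


class TestSummariesAndClustering:
    def test_constant_matrix_means(self):
        ph = _pheno(5, 5)
        beta = pd.DataFrame(0.5, index=["a", "b"], columns=ph.index)
        summary, tests = dmp.global_methylation_summary(beta, ph)
        assert (summary.to_numpy() == 0.5).all()
        assert (tests["p_value"] == 1.0).all()

    def test_planted_global_shift_detected(self):
        rng = np.random.default_rng(8)
        ph = _pheno(20, 20, rng=rng)
        case = (ph["diagnosis"] == "iASD").to_numpy(float)
        beta = pd.DataFrame(
            np.clip(0.5 + rng.normal(0, 0.02, size=(200, 40)) + 0.01 * case[None, :], 0, 1),
            index=[f"cg{i}" for i in range(200)],
            columns=ph.index,
        )
        _, tests = dmp.global_methylation_summary(beta, ph)
        row = tests[(tests["region"] == "PFC") & (tests["diagnosis"] == "iASD")].iloc[0]
        assert row["delta"] == pytest.approx(0.01, abs=0.004)
        assert row["p_value"] < 0.01

    def test_perfectly_separated_clusters(self):
        ph = _pheno(6, 6)
        rng = np.random.default_rng(9)
        base = rng.uniform(0.3, 0.6, 20)
        case = (ph["diagnosis"] == "iASD").to_numpy(float)
        delta = rng.choice([-0.3, 0.3], 20)  # probe-specific directions
        beta = pd.DataFrame(
            base[:, None] + delta[:, None] * case[None, :] + rng.normal(0, 0.01, (20, 12)),
            index=[f"cg{i}" for i in range(20)],
            columns=ph.index,
        )
        _, purity = dmp.cluster_samples_at_dmps(beta, beta.index, ph, case="iASD")
        fracs = sorted(purity["case_fraction"])
        assert fracs == [0.0, 1.0]

    def test_cohort_dmp_clustering_enriches_cases(self, cortex_cohort):
        _, _, beta, _, pheno, truth = cortex_cohort
        pfc = pheno.index[pheno["region"] == "PFC"]
        _, purity = dmp.cluster_samples_at_dmps(
            beta[pfc], truth.spiked_dmps["probe_id"], pheno.loc[pfc], case="iASD"
        )
        assert purity["case_fraction"].max() >= 0.7

    def test_too_few_dmps_rejected(self, cortex_cohort):
        _, _, beta, _, pheno, _ = cortex_cohort
        with pytest.raises(FormatError):
            dmp.cluster_samples_at_dmps(beta, beta.index[:1], pheno, case="iASD")


class TestConcordance:
    def test_identical_and_negated_effects(self):
        rng = np.random.default_rng(10)
        a = pd.Series(rng.normal(size=50), index=[f"cg{i}" for i in range(50)])
        same = dmp.effect_concordance(a, a)
        flipped = dmp.effect_concordance(a, -a)
        assert same.loc["all", "r"] == pytest.approx(1.0)
        assert flipped.loc["all", "r"] == pytest.approx(-1.0)

    def test_independent_effects_near_zero(self):
        rng = np.random.default_rng(11)
        idx = [f"cg{i}" for i in range(100)]
        rs = []
        for _ in range(50):
            a = pd.Series(rng.normal(size=100), index=idx)
            b = pd.Series(rng.normal(size=100), index=idx)
            rs.append(dmp.effect_concordance(a, b).loc["all", "r"])
        assert abs(np.mean(rs)) < 0.05
        assert np.mean(np.abs(rs) < 0.2) > 0.9

    def test_interval_stratification(self, cortex_cohort):
        _, man, _, _, _, _ = cortex_cohort
        rng = np.random.default_rng(12)
        eff = pd.Series(rng.normal(size=len(man)), index=man.index)
        chrom = man["chrom"].iloc[0]
        lo, hi = int(man["pos"].min()), int(man["pos"].median())
        res = dmp.effect_concordance(eff, eff * 0.5, manifest=man, interval=(chrom, lo, hi))
        inside = man.index[(man["chrom"] == chrom) & man["pos"].between(lo, hi)]
        assert res.loc["inside", "n"] == len(inside)
        assert res.loc["inside", "n"] + res.loc["outside", "n"] == res.loc["all", "n"]


class TestFisherZ:
    def test_equal_correlations_give_p_one(self):
        z, p = dmp.fisher_z_diff(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_known_value(self):
        # atanh(0.5) * sqrt(50) with n1 = n2 = 103
        z, p = dmp.fisher_z_diff(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) * np.sqrt(50), rel=1e-12)
        assert p == pytest.approx(1.04e-4, rel=0.02)

    def test_tiny_samples_rejected(self):
        with pytest.raises(FormatError):
            dmp.fisher_z_diff(0.5, 3, 0.2, 100)

    def test_matches_permutation_null(self):
        """Under exchangeable bivariate data, the Fisher z p-value is close
        to a permutation estimate of the two-correlation difference."""
        rng = np.random.default_rng(13)
        n = 150
        x = rng.normal(size=2 * n)
        y = 0.3 * x + rng.normal(size=2 * n) * np.sqrt(1 - 0.09)
        r1 = np.corrcoef(x[:n], y[:n])[0, 1]
        r2 = np.corrcoef(x[n:], y[n:])[0, 1]
        _, p_analytic = dmp.fisher_z_diff(r1, n, r2, n)
        obs = abs(np.arctanh(r1) - np.arctanh(r2))
        count = 0
        reps = 2000
        idx = np.arange(2 * n)
        for _ in range(reps):
            rng.shuffle(idx)
            ra = np.corrcoef(x[idx[:n]], y[idx[:n]])[0, 1]
            rb = np.corrcoef(x[idx[n:]], y[idx[n:]])[0, 1]
            if abs(np.arctanh(ra) - np.arctanh(rb)) >= obs:
                count += 1
        p_perm = count / reps
        assert abs(p_perm - p_analytic) < 0.06


class TestExpressionIntegration:
    def test_empty_de_table(self, cortex_cohort):
        _, man, _, _, _, truth = cortex_cohort
        res_df = pd.DataFrame({"effect": 0.1}, index=truth.spiked_dmps["probe_id"])
        de = pd.DataFrame(columns=["gene", "log_fold_change", "fdr"])
        out = dmp.integrate_expression(res_df, res_df.index, man, de)
        assert out["n_overlap_de"] == 0
        assert np.isnan(out["effect_correlation"])

    def test_negative_coupling_recovered(self, cortex_cohort):
        _, man, _, _, _, truth = cortex_cohort
        rng = np.random.default_rng(14)
        probes = truth.spiked_dmps["probe_id"]
        effects = truth.spiked_dmps.set_index("probe_id")["delta"]
        res_df = pd.DataFrame({"effect": effects})
        genes = {}
        for p in probes:
            anns = [g for g in str(man.loc[p, "genes"]).split(";") if g]
            for g in anns:
                genes[g] = -2.0 * effects[p] + rng.normal(0, 0.05)
        de = pd.DataFrame(
            {"gene": list(genes), "log_fold_change": list(genes.values()), "fdr": 0.01}
        )
        out = dmp.integrate_expression(res_df, probes, man, de)
        assert out["n_overlap_de"] > 0
        assert out["effect_correlation"] < -0.5

    def test_multi_gene_probe_contributes_two_pairs(self):
        from methcortex.ioformats import validate_manifest

        man = validate_manifest(
            pd.DataFrame(
                {
                    "probe_id": ["cgA"],
                    "chrom": ["chr1"],
                    "pos": [100],
                    "design_type": ["II"],
                    "genes": ["G1;G2"],
                    "tss_distance": ["10;20"],
                }
            )
        )
        res_df = pd.DataFrame({"effect": [0.1]}, index=["cgA"])
        de = pd.DataFrame(
            {"gene": ["G1", "G2"], "log_fold_change": [-0.5, -0.7], "fdr": [0.01, 0.01]}
        )
        out = dmp.integrate_expression(res_df, ["cgA"], man, de)
        assert out["n_pairs"] == 2
        assert out["n_overlap_de"] == 1
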