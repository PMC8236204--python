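"""Interaction, standard and reverse per-probe fits against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cellewas as ce

from conftest import make_matrix, make_phenotypes, make_proportions


def normal_equations(x, y):
    """Independent closed-form OLS oracle: solve X'X b = X'y directly."""
    xtx = x.T @ x
    b = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ b
    df = x.shape[0] - x.shape[1]
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * s2)
    return b, se, df


class TestFitCelldmc:
    def test_noiseless_recovery_of_all_coefficients(self):
        """Data built exactly from (mu, beta, rho) is recovered exactly."""
        rng = np.random.default_rng(31)
        n, k, q, p = 50, 3, 2, 8
        props = make_proportions(n, k, seed=1)
        pheno = make_phenotypes(n, seed=2, covariates=q)
        f = props.fractions.to_numpy()
        y = pheno.y
        z = pheno.z
        mu = rng.normal(0, 2, (k, p))
        beta = rng.normal(0, 1, (k, p))
        rho = rng.normal(0, 0.5, (q, p))
        x_resp = f @ mu + (f * y[:, None]) @ beta + z @ rho
        mat = make_matrix(x_resp.T, scale="M")
        res = ce.fit_celldmc(mat, props, pheno)
        tab = res.table.set_index(["probe", "cell_type"])
        for j, ct in enumerate(props.cell_types):
            for i, probe in enumerate(mat.probe_ids):
                assert tab.loc[(probe, ct), "mu"] == pytest.approx(mu[j, i], abs=1e-8)
                assert tab.loc[(probe, ct), "estimate"] == pytest.approx(
                    beta[j, i], abs=1e-8
                )
        np.testing.assert_allclose(res.covariate_effects.to_numpy(), rho.T, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(32)
        n, k, q = 40, 3, 2
        props = make_proportions(n, k, seed=3)
        pheno = make_phenotypes(n, seed=4, covariates=q)
        vals = rng.normal(size=(5, n))
        mat = make_matrix(vals, scale="M")
        res = ce.fit_celldmc(mat, props, pheno)
        f = props.fractions.to_numpy()
        design = np.hstack([f, f * pheno.y[:, None], pheno.z])
        tab = res.table.set_index(["probe", "cell_type"])
        for i, probe in enumerate(mat.probe_ids):
            b, se, df = normal_equations(design, vals[i])
            assert df == res.df_resid
            for j, ct in enumerate(props.cell_types):
                row = tab.loc[(probe, ct)]
                assert row["estimate"] == pytest.approx(b[k + j], abs=1e-10)
                assert row["se"] == pytest.approx(se[k + j], abs=1e-10)
                tt = b[k + j] / se[k + j]
                assert row["p"] == pytest.approx(2 * stats.t.sf(abs(tt), df), abs=1e-12)

    def test_constant_zero_phenotype_flags_interactions_missing(self):
        n = 30
        props = make_proportions(n, 3, seed=5)
        pheno = make_phenotypes(n, seed=6, covariates=1)
        pheno.data["phenotype"] = 0.0
        mat = make_matrix(np.random.default_rng(7).normal(size=(4, n)), scale="M")
        res = ce.fit_celldmc(mat, props, pheno)
        assert res.table["estimate"].isna().all()
        assert res.table["mu"].notna().all()

    def test_beta_scale_estimates_clipped_and_flagged(self):
        n = 30
        props = make_proportions(n, 2, seed=8)
        pheno = make_phenotypes(n, seed=9, covariates=0)
        # half-unit phenotype with a per-unit effect of 1.8 keeps betas in
        # [0, 1] while the coefficient itself exceeds 1
        pheno.data["phenotype"] = np.tile([0.0, 0.5], n // 2)
        f = props.fractions.to_numpy()
        vals = (0.05 + 1.8 * f[:, 0] * pheno.y)[None, :]
        assert vals.min() >= 0 and vals.max() <= 1
        mat = make_matrix(vals, scale="beta")
        res = ce.fit_celldmc(mat, props, pheno)
        assert (res.table["estimate"].abs() <= 1).all()
        assert res.table["clipped"].any()
        assert res.scale == "beta"

    def test_misaligned_samples_rejected(self):
        props = make_proportions(20, 3, seed=10)
        pheno = make_phenotypes(25, seed=11)
        mat = make_matrix(np.zeros((3, 20)), scale="M")
        with pytest.raises(ValueError, match="sample sets differ"):
            ce.fit_celldmc(mat, props, pheno)

    def test_type_one_error_calibrated(self):
        """Null simulation: per-cell-type rejection rate near alpha."""
        cfg = ce.SimulationConfig(n_samples=200, n_probes=4000, markers_per_type=0,
                                  phenotype="continuous", seed=33)
        ds = ce.simulate_dataset(cfg)
        res = ce.fit_celldmc(ds.methylation, ds.true_proportions, ds.phenotypes)
        rates = res.table.groupby("cell_type")["p"].apply(lambda p: (p < 0.05).mean())
        se3 = 3 * np.sqrt(0.05 * 0.95 / 4000)
        assert ((rates - 0.05).abs() < se3 + 1e-9).all(), rates

    def test_scale_duality_design_identical(self):
        """Beta- and M-scale fits of the same study share one design matrix:
        the t-ranking differs only through the response transform."""
        cfg = ce.SimulationConfig(n_samples=80, n_probes=30, markers_per_type=0,
                                  mixing_scale="beta", noise_sd=0.02, seed=34)
        ds = ce.simulate_dataset(cfg)
        res_b = ce.fit_celldmc(ds.methylation, ds.true_proportions, ds.phenotypes)
        res_m = ce.fit_celldmc(
            ce.beta_to_m(ds.methylation), ds.true_proportions, ds.phenotypes
        )
        assert res_b.df_resid == res_m.df_resid
        assert res_b.metadata["design_columns"] == res_m.metadata["design_columns"]
        assert res_b.scale == "beta" and res_m.scale == "M"


class TestStandardEwas:
    def test_equal_effects_collapse_to_main_effect(self):
        """An effect spiked identically in every cell type is a pure bulk
        main effect; the adjusted standard EWAS recovers it."""
        b = 1.5
        n_probes = 40
        effects = tuple(
            ce.EffectSpec(f"cg{i:08d}", ct, b)
            for i in range(n_probes)
            for ct in ce.CORD_BLOOD_CELL_TYPES
        )
        cfg = ce.SimulationConfig(n_samples=275, n_probes=n_probes,
                                  markers_per_type=0, phenotype="continuous",
                                  effects=effects, seed=35)
        ds = ce.simulate_dataset(cfg)
        res = ce.fit_standard_ewas(ds.methylation, ds.true_proportions, ds.phenotypes)
        est = res.table["estimate"]
        # each probe's CI should cover b at roughly the nominal rate
        tcrit = stats.t.ppf(0.975, res.df_resid)
        covered = (np.abs(est - b) <= tcrit * res.table["se"]).mean()
        assert covered > 0.85
        assert est.mean() == pytest.approx(b, abs=0.05)

    def test_invariant_to_reference_cell_type(self):
        cfg = ce.SimulationConfig(n_samples=60, n_probes=12, markers_per_type=0,
                                  seed=36)
        ds = ce.simulate_dataset(cfg)
        t_stats = []
        for ref in ("B", "Gran", "nRBC"):
            res = ce.fit_standard_ewas(
                ds.methylation, ds.true_proportions, ds.phenotypes,
                reference_cell_type=ref,
            )
            t_stats.append(res.table["t"].to_numpy())
        np.testing.assert_allclose(t_stats[0], t_stats[1], atol=1e-8)
        np.testing.assert_allclose(t_stats[0], t_stats[2], atol=1e-8)

    def test_null_pvalues_uniform(self):
        cfg = ce.SimulationConfig(n_samples=200, n_probes=4000, markers_per_type=0,
                                  phenotype="continuous", seed=37)
        ds = ce.simulate_dataset(cfg)
        res = ce.fit_standard_ewas(ds.methylation, ds.true_proportions, ds.phenotypes)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(38)
        n, k = 45, 4
        props = make_proportions(n, k, seed=12)
        pheno = make_phenotypes(n, seed=13, covariates=2)
        vals = rng.normal(size=(3, n))
        mat = make_matrix(vals, scale="M")
        res = ce.fit_standard_ewas(mat, props, pheno, reference_cell_type="ct0")
        f = props.fractions.drop(columns=["ct0"]).to_numpy()
        design = np.hstack([np.ones((n, 1)), pheno.y[:, None], pheno.z, f])
        for i in range(3):
            b, se, df = normal_equations(design, vals[i])
            assert res.table.loc[i, "estimate"] == pytest.approx(b[1], abs=1e-10)
            assert res.table.loc[i, "se"] == pytest.approx(se[1], abs=1e-10)


class TestReverseInteraction:
    def test_exact_recovery_of_constructed_outcome(self):
        rng = np.random.default_rng(39)
        n, k, q, p = 60, 3, 2, 4
        props = make_proportions(n, k, seed=14)
        pheno = make_phenotypes(n, seed=15, covariates=q)
        f = props.fractions.to_numpy()
        z = pheno.z
        xc = rng.normal(size=(p, n))
        nu = rng.normal(0, 1, k)
        gamma = rng.normal(0, 0.5, k)
        rho = rng.normal(0, 0.3, q)
        # build y exactly for probe 0 and fit only that probe
        y = f @ nu + (f * xc[0][:, None]) @ gamma + z @ rho
        pheno.data["phenotype"] = y
        mat = make_matrix(xc[:1], scale="M")
        res = ce.fit_reverse_interaction(mat, props, pheno)
        tab = res.table.set_index("cell_type")
        for j, ct in enumerate(props.cell_types):
            assert tab.loc[ct, "nu"] == pytest.approx(nu[j], abs=1e-8)
            assert tab.loc[ct, "estimate"] == pytest.approx(gamma[j], abs=1e-8)
        np.testing.assert_allclose(res.covariate_effects.to_numpy()[0], rho, atol=1e-8)

    def test_constant_methylation_inestimable(self):
        n = 40
        props = make_proportions(n, 3, seed=16)
        pheno = make_phenotypes(n, seed=17, covariates=1)
        mat = make_matrix(np.full((2, n), 1.3), scale="M")
        res = ce.fit_reverse_interaction(mat, props, pheno)
        assert res.table["estimate"].isna().all()

    def test_binary_phenotype_warns(self):
        n = 40
        props = make_proportions(n, 3, seed=18)
        pheno = make_phenotypes(n, seed=19, continuous=False, covariates=0)
        mat = make_matrix(np.random.default_rng(20).normal(size=(2, n)), scale="M")
        with pytest.warns(UserWarning, match="binary"):
            ce.fit_reverse_interaction(mat, props, pheno)

    def test_null_pvalues_uniform(self):
        cfg = ce.SimulationConfig(n_samples=150, n_probes=700, markers_per_type=0,
                                  phenotype="continuous", seed=40)
        ds = ce.simulate_dataset(cfg)
        res = ce.fit_reverse_interaction(
            ds.methylation, ds.true_proportions, ds.phenotypes
        )
        assert stats.kstest(res.table["p"].dropna(), "uniform").pvalue > 0.01


class TestMultipleTesting:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.001, 0.9], [0.06, 0.003, 0.9]),
            ([0.2], [0.2]),
        ],
    )
    def test_bh_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(ce.bh_fdr(np.array(p)), expected, atol=1e-12)

    def test_bh_handles_missing_and_dominates_p(self):
        p = np.array([0.01, np.nan, 0.5, 0.04])
        out = ce.bh_fdr(p)
        assert np.isnan(out[1])
        mask = ~np.isnan(p)
        assert (out[mask] >= p[mask] - 1e-15).all()
        assert (out[mask] <= 1).all()

    def test_bh_empty(self):
        assert ce.bh_fdr(np.array([])).size == 0

    def test_bonferroni_epigenome_wide_threshold(self):
        thr = ce.bonferroni_threshold(0.05, 790_563)
        assert float(f"{thr:.1e}") == pytest.approx(6.3e-8)

    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 1, 0.05), (0.01, 100, 1e-4)]
    )
    def test_bonferroni_closed_form(self, alpha, n, expected):
        assert ce.bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            ce.bonferroni_threshold(0.05, 0)

    def test_fdr_families(self):
        cfg = ce.SimulationConfig(n_samples=60, n_probes=50, markers_per_type=0,
                                  seed=41)
        ds = ce.simulate_dataset(cfg)
        per = ce.fit_celldmc(ds.methylation, ds.true_proportions, ds.phenotypes,
                             fdr_family="per_cell_type")
        pooled = ce.fit_celldmc(ds.methylation, ds.true_proportions, ds.phenotypes,
                                fdr_family="pooled")
        # identical tests, different adjustment families
        np.testing.assert_allclose(per.table["p"], pooled.table["p"])
        assert not np.allclose(per.table["fdr"], pooled.table["fdr"])
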