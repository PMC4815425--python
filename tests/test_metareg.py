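"""Categorical meta-regression: design construction, fits and Q_M."""

import numpy as np
import pandas as pd
import pytest

import metadeg as md
from metadeg.datamodel import DataError, RunConfig, contrast_table
from metadeg.metareg import (
    DesignMatrix,
    _fit_metareg_table_loop,
    build_design,
    fit_meta_regression,
    fit_metareg_table,
    gdl_tau2,
    qm_test,
)
from metadeg.synthgen import SimParams, default_roster, simulate_collection


@pytest.fixture(scope="module")
def roster_contrasts():
    study, _, _ = simulate_collection(SimParams(n_genes=5, seed=0))
    return contrast_table(study)


class TestBuildDesign:
    def test_part_design_excludes_seedling(self, roster_contrasts):
        design = build_design(roster_contrasts, "part")
        assert design.X.shape == (9, 2)
        assert design.level_names == ["root", "shoot"]
        assert [c for c, _ in design.exclusions] == ["studyE:seedling"]
        assert (design.X.sum(axis=1) == 1).all()  # one-hot rows

    def test_method_design_excludes_peg(self, roster_contrasts):
        design = build_design(roster_contrasts, "method")
        assert design.X.shape == (9, 3)
        assert set(design.level_names) == {
            "water_withholding", "mannitol", "deracination",
        }
        assert [c for c, _ in design.exclusions] == ["studyE:seedling"]

    def test_single_level_aborts(self, roster_contrasts):
        only_shoot = roster_contrasts[roster_contrasts["part"] == "shoot"]
        with pytest.raises(DataError, match="at least 2"):
            build_design(only_shoot, "part")

    def test_row_order_does_not_change_fit(self, roster_contrasts):
        design = build_design(roster_contrasts, "part")
        shuffled = build_design(
            roster_contrasts.sample(frac=1, random_state=1), "part"
        )
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(0, 1, 9), index=design.contrast_ids)
        v = pd.Series(rng.uniform(0.05, 0.2, 9), index=design.contrast_ids)
        a = fit_meta_regression(y, v, design)
        b = fit_meta_regression(y, v, shuffled)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)
        assert a.qm == pytest.approx(b.qm, rel=1e-12)


def two_level_design(n_root=3, n_shoot=3):
    cids = [f"r{i}" for i in range(n_root)] + [f"s{i}" for i in range(n_shoot)]
    X = pd.DataFrame(0.0, index=pd.Index(cids, name="contrast_id"),
                     columns=["root", "shoot"])
    X.iloc[:n_root, 0] = 1.0
    X.iloc[n_root:, 1] = 1.0
    return DesignMatrix("part", X, ["root", "shoot"], [])


class TestFit:
    def test_saturated_level_means(self):
        design = two_level_design()
        y = pd.Series([0.4] * 3 + [-0.2] * 3, index=design.contrast_ids)
        v = pd.Series([0.1] * 6, index=design.contrast_ids)
        fit = fit_meta_regression(y, v, design)
        assert fit.tau2_resid == 0.0  # residual Q is exactly zero
        np.testing.assert_allclose(fit.coefficients["beta"], [0.4, -0.2])

    def test_one_contrast_per_level_interpolates(self):
        design = two_level_design(1, 1)
        y = pd.Series([0.7, -0.3], index=design.contrast_ids)
        v = pd.Series([0.1, 0.2], index=design.contrast_ids)
        fit = fit_meta_regression(y, v, design)
        assert fit.tau2_resid == 0.0  # no residual degrees of freedom
        np.testing.assert_allclose(fit.coefficients["beta"], [0.7, -0.3])

    def test_matches_gls_oracle_to_1e10(self):
        rng = np.random.default_rng(3)
        design = two_level_design()
        y = rng.normal(0, 0.6, 6)
        v = rng.uniform(0.02, 0.2, 6)
        fit = fit_meta_regression(y, v, design)
        # independent GLS solve at the same tau2
        X = design.X.to_numpy()
        V = np.diag(v + fit.tau2_resid)
        beta = np.linalg.solve(X.T @ np.linalg.inv(V) @ X,
                               X.T @ np.linalg.inv(V) @ y)
        np.testing.assert_allclose(fit.coefficients["beta"], beta, atol=1e-10)

    def test_single_level_design_reduces_to_meta_mean(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0.2, 0.5, 7)
        v = rng.uniform(0.03, 0.3, 7)
        X = pd.DataFrame(
            1.0, index=pd.Index([f"c{i}" for i in range(7)], name="contrast_id"),
            columns=["all"],
        )
        design = DesignMatrix("part", X, ["all"], [])
        fit = fit_meta_regression(y, v, design)
        meta_fit = md.fit_random_effects(
            y, v, RunConfig(tau2_method_meta="dl", ci_distribution="normal")
        )
        assert fit.tau2_resid == pytest.approx(meta_fit.tau2, rel=1e-12, abs=1e-15)
        assert fit.coefficients["beta"].iloc[0] == pytest.approx(
            meta_fit.mu_hat, rel=1e-12
        )
        assert fit.coefficients["se"].iloc[0] == pytest.approx(
            meta_fit.se_mu, rel=1e-12
        )

    def test_gdl_with_intercept_only_equals_dl(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 6)
        v = rng.uniform(0.05, 0.5, 6)
        assert gdl_tau2(y, v, np.ones((6, 1))) == pytest.approx(
            md.dl_tau2(y, v), rel=1e-12, abs=1e-15
        )


class TestQM:
    def test_exactly_equal_means_give_zero(self):
        qm, df, p = qm_test([0.3, 0.3], np.diag([0.1, 0.04]))
        assert qm == 0.0 and df == 1 and p == 1.0

    def test_two_level_hand_value(self):
        s = 0.2
        x = 0.5
        qm, df, p = qm_test([0.0, x], np.diag([s**2, s**2]))
        assert qm == pytest.approx(x**2 / (2 * s**2), rel=1e-12)
        assert df == 1

    def test_m_convention_tests_all_zero(self):
        beta = np.array([0.4, 0.4])
        cov = np.diag([0.01, 0.01])
        qm_eq, df_eq, _ = qm_test(beta, cov, "m_minus_1")
        qm_all, df_all, _ = qm_test(beta, cov, "m")
        assert qm_eq == 0.0 and df_eq == 1
        assert qm_all == pytest.approx(32.0) and df_all == 2

    def test_opposite_signed_levels_classified_reversed(self):
        # a part-moderated outcome: strong Q_M, significant opposite means
        design = two_level_design()
        y = pd.Series([0.8, 0.9, 0.85, -0.8, -0.75, -0.9],
                      index=design.contrast_ids)
        v = pd.Series([0.01] * 6, index=design.contrast_ids)
        fit = fit_meta_regression(y, v, design, gene_id="g")
        assert fit.p_qm < 0.01
        gene_table = pd.DataFrame(
            [{"gene_id": "g", "tau2_resid": fit.tau2_resid, "qm": fit.qm,
              "qm_df": fit.qm_df, "p_qm": fit.p_qm}]
        )
        coef = fit.coefficients.copy()
        coef.insert(0, "gene_id", "g")
        labels = md.metareg.classify_moderation(gene_table, coef, alpha=0.05)
        assert labels["label"].iloc[0] == "reversed"


class TestVectorisedTable:
    def test_table_matches_scalar_loop(self, sim_study):
        study, _, _ = sim_study
        eff = md.compute_effects(study).query("gene_id < '254030_at'")
        design = build_design(eff, "method")
        fast_gene, fast_coef = fit_metareg_table(eff, design)
        slow_gene, slow_coef = _fit_metareg_table_loop(eff, design, RunConfig())
        np.testing.assert_allclose(
            fast_gene[["tau2_resid", "qm", "p_qm"]],
            slow_gene[["tau2_resid", "qm", "p_qm"]],
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            fast_coef[["beta", "se", "z", "p"]],
            slow_coef[["beta", "se", "z", "p"]],
            rtol=1e-10,
        )

    def test_level_relabelling_invariance(self, sim_study):
        study, _, _ = sim_study
        eff = md.compute_effects(study)
        design = build_design(eff, "part")
        flipped = DesignMatrix(
            "part",
            design.X[["shoot", "root"]],
            ["shoot", "root"],
            design.exclusions,
        )
        a_gene, a_coef = fit_metareg_table(eff, design)
        b_gene, b_coef = fit_metareg_table(eff, flipped)
        np.testing.assert_allclose(a_gene["qm"], b_gene["qm"], rtol=1e-10)
        a_root = a_coef[a_coef["level"] == "root"].reset_index(drop=True)
        b_root = b_coef[b_coef["level"] == "root"].reset_index(drop=True)
        np.testing.assert_allclose(a_root["beta"], b_root["beta"], rtol=1e-12)
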