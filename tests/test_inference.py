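"""BH adjustment, gene calls, forest orderings and set comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metadeg as md
from metadeg.datamodel import DataError
from metadeg.inference import (
    bh_adjust,
    classify_genes,
    compare_gene_sets,
    sort_forest,
)


def bh_brute_force(p):
    """Step-up definition applied literally: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_textbook_example_collapses_to_common_value(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_all_ones_stay_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_brute_force_on_1000_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            if rng.random() < 0.3:  # inject ties
                p[: m // 2] = p[0]
            np.testing.assert_array_equal(bh_adjust(p), bh_brute_force(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 500) ** 2
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_p_names_index(self):
        with pytest.raises(DataError, match="index 2"):
            bh_adjust([0.5, 0.1, 1.5])
        with pytest.raises(DataError, match="index 0"):
            bh_adjust([0.0, 0.1])


def fits_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "mu_hat", "ci_lo", "ci_hi", "p"]
    )


class TestClassify:
    def test_calls_follow_q_and_sign(self):
        fits = fits_frame(
            [
                ("up1", 0.3, 0.1, 0.5, 1e-5),
                ("dn1", -0.4, -0.6, -0.2, 1e-5),
                ("ns1", 2.0, -1.0, 5.0, 0.9),
            ]
        )
        calls = classify_genes(fits, alpha=0.05).set_index("gene_id")
        assert calls.loc["up1", "call"] == "up"
        assert calls.loc["dn1", "call"] == "down"
        assert calls.loc["ns1", "call"] == "ns"  # regardless of mu magnitude
        assert calls.loc["ns1", "ci_gap"] == 0.0
        assert calls.loc["up1", "ci_gap"] == pytest.approx(0.1)

    def test_discoveries_shrink_as_alpha_tightens(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 1, 200), rng.uniform(0, 1e-4, 50)])
        fits = fits_frame(
            [(f"g{i}", 0.5, 0.1, 0.9, pv) for i, pv in enumerate(p)]
        )
        n_05 = (classify_genes(fits, 0.05)["call"] != "ns").sum()
        n_01 = (classify_genes(fits, 0.01)["call"] != "ns").sum()
        assert n_01 <= n_05

    def test_matched_distribution_ci_and_call_agree(self):
        # with normal CIs and normal p-values, q < raw p-threshold implies
        # the CI excludes zero whenever the call is significant
        rng = np.random.default_rng(3)
        eff, _ = md.synthgen.simulate_effect_table(300, 6, 0.05, seed=3)
        fits = md.fit_random_effects_table(
            eff, md.RunConfig(ci_distribution="normal")
        )
        calls = classify_genes(fits, alpha=0.05)
        sig = calls["call"] != "ns"
        assert (calls.loc[sig, "ci_gap"] > 0).all()


class TestSortForest:
    def test_gap_order_simple(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "mu_hat": [1.0, 1.0],
                "ci_gap": [0.5, 0.1],
            }
        )
        assert list(sort_forest(calls, "ci_gap")) == ["a", "b"]

    def test_gap_group_dominates_magnitude(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["A", "B"],
                "mu_hat": [2.0, 0.01],
                "ci_gap": [0.0, 0.01],
            }
        )
        assert list(sort_forest(calls, "ci_gap")) == ["B", "A"]

    def test_magnitude_mode_matches_key_sort_oracle(self):
        rng = np.random.default_rng(4)
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "mu_hat": np.round(rng.normal(0, 1, 60), 1),  # force ties
                "ci_gap": rng.uniform(0, 1, 60),
            }
        )
        expect = sorted(
            calls["gene_id"],
            key=lambda g: (
                -abs(calls.set_index("gene_id").loc[g, "mu_hat"]), g,
            ),
        )
        assert list(sort_forest(calls, "mu_magnitude")) == expect

    def test_unknown_mode_rejected(self):
        with pytest.raises(DataError):
            sort_forest(pd.DataFrame({"gene_id": [], "mu_hat": [], "ci_gap": []}),
                        "zscore")


class TestCompareGeneSets:
    def meta_calls(self, genes, sig, mus=None):
        mus = mus or {g: 0.5 for g in genes}
        return pd.DataFrame(
            {
                "gene_id": list(genes),
                "mu_hat": [mus[g] for g in genes],
                "call": ["up" if g in sig else "ns" for g in genes],
            }
        )

    def test_three_way_partition(self):
        calls = self.meta_calls(["a", "b", "c"], {"a", "b"})
        rep = compare_gene_sets(calls, {"c1": {"b", "c"}})
        assert rep.meta_only == {"a"}
        assert rep.both == {"b"}
        assert rep.t_only == {"c"}

    def test_zero_deg_contrast_contributes_zeros(self):
        calls = self.meta_calls(["a", "b"], {"a"})
        rep = compare_gene_sets(calls, {"c1": {"a"}, "c2": set()})
        assert rep.per_contrast_counts["c2"] == 0
        assert rep.pairwise["c2"] == 0
        assert rep.support_counts["a"] == 1

    def test_support_counts_accumulate(self):
        calls = self.meta_calls(["g"], {"g"})
        rep = compare_gene_sets(calls, {c: {"g"} for c in ("c1", "c2", "c3")})
        assert rep.support_counts["g"] == 3

    def test_small_effect_flagging_of_meta_only_genes(self):
        calls = self.meta_calls(
            ["tiny", "big"], {"tiny", "big"}, {"tiny": 0.02, "big": 1.4}
        )
        rep = compare_gene_sets(calls, {"c1": set()})
        assert rep.meta_only == {"tiny", "big"}
        assert rep.meta_only_small == {"tiny"}

    def test_foreign_gene_universe_fatal(self):
        calls = self.meta_calls(["a"], set())
        with pytest.raises(DataError, match="outside the meta universe"):
            compare_gene_sets(calls, {"c1": {"zz"}})


def test_forest_rendering_writes_image(tmp_path, sim_study):
    study, _, _ = sim_study
    res = md.run_meta_pipeline(study)
    out = tmp_path / "forest.png"
    md.inference.render_forest(res.calls, out, max_genes=100)
    assert out.stat().st_size > 0
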