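import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexstrat.io import GROUPS
from sexstrat.linmod import (DifferentialExpressionModel, apply_contrasts,
                             balanced_sensitivity, bh_adjust, build_design,
                             call_degs, ebayes_moderate, fit_weighted_lm,
                             partition_degs, standard_contrasts,
                             trigamma_inverse, venn_counts)
from sexstrat.normalize import WeightedLogExpression
from sexstrat.simulate import SimulationConfig, generate_counts


def _meta(n_studies=2, per_group=2):
    rows = []
    for k in range(n_studies):
        for g in GROUPS:
            cond, sex = g.split("_")
            for i in range(per_group):
                rows.append((f"st{k}_{g}_{i}", f"st{k}", cond, sex))
    return pd.DataFrame(rows, columns=["sample_id", "study", "condition", "sex"])


class TestBuildDesign:
    def test_two_studies_four_groups(self):
        X = build_design(_meta(2, 2))
        assert X.shape == (16, 5)
        assert np.linalg.matrix_rank(X.to_numpy()) == 5
        assert (X[list(GROUPS)].sum(axis=1) == 1).all()

    def test_single_study_no_block_columns(self):
        X = build_design(_meta(1, 2))
        assert X.shape == (8, 4)
        assert not any(c.startswith("study:") for c in X.columns)

    def test_unbalanced_study_still_estimable(self):
        """A study contributing only PS_male samples leaves the design full
        rank (explicit rank oracle)."""
        meta = _meta(2, 2)
        keep = (meta["study"] == "st0") | (
            meta["condition"].str.cat(meta["sex"], sep="_") == "PS_male")
        X = build_design(meta[keep].reset_index(drop=True))
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_confounded_study_rejected(self):
        """A study perfectly aligned with one group is collinear."""
        meta = _meta(1, 3)
        meta.loc[meta["condition"].str.cat(meta["sex"], sep="_") == "PS_male",
                 "study"] = "stX"
        with pytest.raises(ValueError, match="rank"):
            build_design(meta)


def _wle(E, W=None):
    E = pd.DataFrame(E)
    E.index = [f"g{i}" for i in range(E.shape[0])]
    W = pd.DataFrame(np.ones_like(E.to_numpy()) if W is None else W,
                     index=E.index, columns=E.columns)
    return WeightedLogExpression(logcpm=E, weights=W)


class TestFitWeightedLM:
    def test_unit_weights_orthogonal_design_gives_group_means(self):
        meta = _meta(1, 3)
        X = build_design(meta)
        rng = np.random.default_rng(0)
        E = rng.normal(size=(5, len(meta)))
        fit = fit_weighted_lm(_wle(E), X)
        groups = meta["condition"].str.cat(meta["sex"], sep="_").to_numpy()
        for g in GROUPS:
            np.testing.assert_allclose(fit.coefficients[g],
                                       E[:, groups == g].mean(axis=1),
                                       atol=1e-12)

    def test_weight_two_equals_duplicated_observation(self):
        """Weight 2 on one sample reproduces the fit with that sample
        entered twice at weight 1, to 1e-10."""
        rng = np.random.default_rng(1)
        n = 8
        X = pd.DataFrame({"a": np.ones(n), "b": rng.normal(size=n)})
        E = rng.normal(size=(12, n))
        W = np.ones((12, n))
        W[:, 0] = 2.0
        fit_w = fit_weighted_lm(_wle(E, W), X)

        X2 = pd.concat([X.iloc[[0]], X], ignore_index=True)
        E2 = np.hstack([E[:, [0]], E])
        fit_dup = fit_weighted_lm(_wle(E2), X2)
        np.testing.assert_allclose(fit_w.coefficients.to_numpy(),
                                   fit_dup.coefficients.to_numpy(), atol=1e-10)

    def test_noiseless_recovery_exact(self):
        meta = _meta(2, 2)
        X = build_design(meta)
        beta_true = np.arange(1.0, 6.0)[None, :] * np.ones((15, 1))
        E = beta_true @ X.to_numpy().T
        fit = fit_weighted_lm(_wle(E), X)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_true,
                                   atol=1e-10)
        assert np.all(fit.sigma2 < 1e-20)

    def test_no_residual_df_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_weighted_lm(_wle(np.ones((12, 3))), X)


class TestEbayesModeration:
    def _fit(self, sigma2, df=10.0):
        n = len(sigma2)
        fit = fit_weighted_lm(
            _wle(np.random.default_rng(0).normal(size=(n, 13))),
            pd.DataFrame({"a": np.ones(13), "b": np.arange(13.0),
                          "c": np.arange(13.0) ** 2}))
        fit.sigma2 = pd.Series(np.asarray(sigma2, float), index=fit.sigma2.index)
        return fit

    def test_infinite_prior_df_collapses_to_prior_variance(self):
        fit = self._fit(np.linspace(0.5, 2.0, 50))
        mod = ebayes_moderate(fit, prior_df=np.inf)
        assert np.allclose(mod.post_var, mod.s0_sq)

    def test_zero_prior_df_disables_moderation(self):
        """d0 = 0: posterior variances are the raw per-gene variances, so
        the moderated t equals the ordinary t."""
        fit = self._fit(np.linspace(0.5, 2.0, 50))
        mod = ebayes_moderate(fit, prior_df=0.0)
        np.testing.assert_allclose(mod.post_var, fit.sigma2, atol=1e-12)

    def test_equal_variances_hit_infinite_d0_branch(self):
        fit = self._fit(np.full(40, 1.7))
        mod = ebayes_moderate(fit)
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(mod.post_var, 1.7, atol=1e-12)

    def test_prior_parameter_recovery(self):
        """(d0, s0^2) recovered within 15% from 5000 scaled-chi-square
        variances with known truth (d0 = 4, s0^2 = 2, d_g = 10)."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, dg, n = 4.0, 2.0, 10.0, 5000
        sigma_g2 = d0_true * s0_true / rng.chisquare(d0_true, size=n)
        s2 = sigma_g2 * rng.chisquare(dg, size=n) / dg
        fit = self._fit(s2)
        fit.df_resid = dg
        mod = ebayes_moderate(fit)
        assert mod.d0 == pytest.approx(d0_true, rel=0.15)
        assert mod.s0_sq == pytest.approx(s0_true, rel=0.15)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for x in (0.1, 1.0, 7.3, 150.0):
            assert trigamma_inverse(float(polygamma(1, x))) == \
                pytest.approx(x, rel=1e-8)

    def test_too_few_genes_rejected(self):
        fit = self._fit(np.linspace(0.5, 2, 5))
        with pytest.raises(ValueError, match="10 genes"):
            ebayes_moderate(fit)


class TestContrasts:
    def _fitted(self, E, meta):
        X = build_design(meta)
        fit = fit_weighted_lm(_wle(E), X)
        return ebayes_moderate(fit, prior_df=0.0), X

    def test_interaction_is_male_minus_female_exactly(self):
        meta = _meta(2, 3)
        rng = np.random.default_rng(3)
        mod, X = self._fitted(rng.normal(size=(30, len(meta))), meta)
        tabs = apply_contrasts(mod)
        np.testing.assert_allclose(
            tabs["interaction"]["logFC"],
            tabs["male"]["logFC"] - tabs["female"]["logFC"], atol=1e-12)

    def test_equal_sex_effects_null_interaction(self):
        meta = _meta(1, 3)
        X = build_design(meta)
        groups = meta["condition"].str.cat(meta["sex"], sep="_")
        shift = groups.isin(["PS_male", "PS_female"]).to_numpy(float) * 2.0
        E = np.tile(shift, (15, 1))
        mod, _ = self._fitted(E, meta)
        tabs = apply_contrasts(mod)
        np.testing.assert_allclose(tabs["interaction"]["logFC"], 0, atol=1e-10)
        np.testing.assert_allclose(tabs["male"]["logFC"], 2.0, atol=1e-10)

    def test_noiseless_contrast_recovers_group_difference(self):
        meta = _meta(1, 3)
        groups = meta["condition"].str.cat(meta["sex"], sep="_")
        E = np.tile((groups == "PS_male").to_numpy(float) * 3.0, (12, 1))
        mod, _ = self._fitted(E, meta)
        tabs = apply_contrasts(mod)
        np.testing.assert_allclose(tabs["male"]["logFC"], 3.0, atol=1e-10)

    def test_contrast_touching_study_columns_rejected(self):
        meta = _meta(2, 2)
        rng = np.random.default_rng(4)
        mod, X = self._fitted(rng.normal(size=(15, len(meta))), meta)
        bad = np.zeros(X.shape[1])
        bad[-1] = 1.0
        with pytest.raises(ValueError, match="study"):
            apply_contrasts(mod, {"bad": bad})


def _bh_oracle(p):
    """Naive O(n^2) step-up: adj_i = min over j with p_j >= p_i of n*p_j/j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_matches_bruteforce_oracle_small_n(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestCallDegs:
    def _table(self, lfc, adj):
        return pd.DataFrame({"logFC": lfc, "t": 0.0, "p_value": adj,
                             "adj_p_value": adj},
                            index=[f"g{i}" for i in range(len(lfc))])

    def test_strict_thresholds(self):
        tab = call_degs(self._table([1.0, 1.2, -3.0], [0.001, 0.01, 0.2]))
        assert tab["is_deg"].tolist() == [False, True, False]
        assert tab["direction"].tolist() == ["n.s.", "Up", "n.s."]

    def test_downregulated_direction(self):
        tab = call_degs(self._table([-1.5], [0.01]))
        assert tab.loc["g0", "direction"] == "Down"


class TestPartition:
    def _deg_table(self, genes_dirs):
        idx = [g for g, _ in genes_dirs]
        lfc = [2.0 if d == "Up" else -2.0 if d == "Down" else 0.0
               for _, d in genes_dirs]
        adj = [0.01 if d != "n.s." else 0.9 for _, d in genes_dirs]
        return call_degs(pd.DataFrame({"logFC": lfc, "adj_p_value": adj},
                                      index=idx))

    def test_disjoint_sets(self):
        f = self._deg_table([("a", "Up"), ("b", "n.s.")])
        m = self._deg_table([("a", "n.s."), ("b", "Up")])
        part = partition_degs(f, m)
        assert venn_counts(part) == {"female_only": 1, "male_only": 1,
                                     "overlap": 0}

    def test_opposite_directions_labelled(self):
        """A gene up in males and down in females gets the combined
        'Up (M) Down (F)' label with consistency flagged False."""
        f = self._deg_table([("psg4_like", "Down")])
        m = self._deg_table([("psg4_like", "Up")])
        part = partition_degs(f, m)
        row = part.loc["psg4_like"]
        assert row["membership"] == "overlap"
        assert row["label"] == "Up (M) Down (F)"
        assert row["consistent"] == False  # noqa: E712

    def test_consistent_overlap_label(self):
        f = self._deg_table([("g", "Up")])
        m = self._deg_table([("g", "Up")])
        assert partition_degs(f, m).loc["g", "label"] == "Up (M, F)"

    def test_planted_sets_recovered_within_power_envelope(self, de_results):
        """Planted shared / female-only / male-only disease genes are
        recovered into the right Venn compartments (generator-truth oracle;
        large effects, so recovery should be near-total)."""
        truth, res = de_results
        part = res.partition()
        vc = venn_counts(part)
        n_shared, n_f, n_m = (len(truth.shared_degs),
                              len(truth.female_unique_degs),
                              len(truth.male_unique_degs))
        assert vc["overlap"] >= 0.8 * n_shared
        recovered_f = set(part.index[part["membership"] == "female-only"])
        assert len(recovered_f & set(truth.female_unique_degs)) >= 0.7 * n_f
        recovered_m = set(part.index[part["membership"] == "male-only"])
        assert len(recovered_m & set(truth.male_unique_degs)) >= 0.7 * n_m
        # shared DEGs planted with one sign are called in that direction
        for g, fc in list(truth.shared_degs.items())[:10]:
            if g in part.index and part.loc[g, "membership"] == "overlap":
                want = "Up" if fc > 0 else "Down"
                assert part.loc[g, "direction_male"] == want


@pytest.fixture(scope="module")
def de_results(small_sim):
    _, counts, meta, truth = small_sim
    res = DifferentialExpressionModel(counts, meta, filter_genes=False).fit()
    return truth, res


class TestDEModel:
    def test_summary_reports_counts_consistent_with_tables(self, de_results):
        _, res = de_results
        counts = res.deg_counts()
        for name, tab in res.tables.items():
            assert counts[name] == int(tab["is_deg"].sum())
        text = res.summary()
        assert "interaction" in text and "overlap" in text

    def test_moderated_table_invariants(self, de_results):
        _, res = de_results
        mod = res.moderated
        post = ((mod.d0 * mod.s0_sq + mod.fit.df_resid * mod.fit.sigma2)
                / (mod.d0 + mod.fit.df_resid))
        np.testing.assert_allclose(mod.post_var, post, rtol=1e-10)
        for tab in res.tables.values():
            assert (tab["adj_p_value"] >= tab["p_value"] - 1e-15).all()
            assert tab["adj_p_value"].between(0, 1).all()


class TestBalancedSensitivity:
    def test_already_balanced_identity(self):
        cfg = SimulationConfig(
            n_genes=300, n_shared_degs=30, n_female_unique_degs=5,
            n_male_unique_degs=5, n_interaction_genes=0, n_studies=1,
            samples_per_group_per_study={g: 8 for g in GROUPS}, seed=21)
        counts, meta, _ = generate_counts(cfg)
        out = balanced_sensitivity(counts, meta, seed=0, filter_genes=False)
        assert out["n_balanced"] == out["n_full"]
        assert all(j == 1.0 for j in out["jaccard"].values())

    def test_imbalanced_run_consistent_with_full(self):
        """2:1 male excess with strong planted effects: balanced re-run
        reproduces the full-data DEG sets (Jaccard >= 0.8)."""
        cfg = SimulationConfig(
            n_genes=400, n_shared_degs=40, n_female_unique_degs=8,
            n_male_unique_degs=8, n_interaction_genes=0, n_studies=2,
            samples_per_group_per_study={"PS_male": 12, "PS_female": 6,
                                         "Control_male": 12,
                                         "Control_female": 6}, seed=22)
        counts, meta, _ = generate_counts(cfg)
        out = balanced_sensitivity(counts, meta, seed=5, filter_genes=False)
        assert out["jaccard"]["male"] >= 0.8
        assert out["jaccard"]["female"] >= 0.8

    def test_subsample_deterministic_given_seed(self):
        cfg = SimulationConfig(
            n_genes=120, n_shared_degs=5, n_female_unique_degs=2,
            n_male_unique_degs=2, n_interaction_genes=1, n_studies=1,
            samples_per_group_per_study={"PS_male": 6, "PS_female": 3,
                                         "Control_male": 4,
                                         "Control_female": 4}, seed=23)
        counts, meta, _ = generate_counts(cfg)
        a = balanced_sensitivity(counts, meta, seed=9, filter_genes=False)
        b = balanced_sensitivity(counts, meta, seed=9, filter_genes=False)
        assert a["kept_samples"] == b["kept_samples"]

    def test_single_sex_condition_rejected(self):
        meta = _meta(1, 2)
        meta.loc[meta["condition"] == "PS", "sex"] = "male"
        counts = pd.DataFrame(
            np.random.default_rng(0).integers(0, 100, size=(20, len(meta))),
            index=[f"g{i}" for i in range(20)],
            columns=meta["sample_id"].to_numpy())
        with pytest.raises(ValueError, match="single sex"):
            balanced_sensitivity(counts, meta, seed=0, filter_genes=False)
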