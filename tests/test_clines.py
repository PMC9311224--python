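"""LSMEANS, cline regressions, Holm correction, fitness cline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aridclines as ac


def _arid(populations, values):
    return {p: v for p, v in zip(populations, values)}


def _lsmeans_frame(slopes, offsets, aridity, noise=None, trait="biomass"):
    """Construct an exact LSMEANS table: lsmean = slope_t * a + offset_t."""
    rows = []
    for i, a in enumerate(aridity):
        for t, (s, o) in zip(("dry", "wet"), zip(slopes, offsets)):
            rows.append({"trait": trait, "population": f"P{i+1}",
                         "treatment": t, "aridity": a,
                         "lsmean": s * a + o, "se": 0.1})
    df = pd.DataFrame(rows)
    if noise is not None:
        df["lsmean"] += noise
    return df


class TestFixedLsmeans:
    def test_equal_cell_means_balanced(self, field_std):
        _, std, _ = field_std
        out = ac.fit_lsmeans_fixed(std, "biomass", "field2019")
        df = pd.DataFrame({"y": std.values["biomass"],
                           "population": std.design["population"],
                           "treatment": std.groups["treatment"]})
        direct = df.groupby(["population", "treatment"])["y"].mean()
        for _, row in out.iterrows():
            assert row["lsmean"] == pytest.approx(
                direct[(row["population"], row["treatment"])], abs=1e-12)

    def test_equal_cell_means_unbalanced(self, field_std):
        table, _, _ = field_std
        # drop rows non-uniformly to unbalance the design
        sub = table.drop(table.index[::5]).reset_index(drop=True)
        std = ac.transform_and_standardize(sub, transform="none")
        out = ac.fit_lsmeans_fixed(std, "sla", "field2019")
        df = pd.DataFrame({"y": std.values["sla"],
                           "population": std.design["population"],
                           "treatment": std.groups["treatment"]})
        direct = df.groupby(["population", "treatment"])["y"].mean()
        for _, row in out.iterrows():
            assert row["lsmean"] == pytest.approx(
                direct[(row["population"], row["treatment"])], abs=1e-12)

    def test_empty_cell_rejected(self, field_std):
        table, _, _ = field_std
        sub = table[~((table["population"] == "P3") &
                      (table["treatment"] == "dry"))].reset_index(drop=True)
        std = ac.transform_and_standardize(sub, transform="none")
        with pytest.raises(ValueError, match="P3"):
            ac.fit_lsmeans_fixed(std, "biomass", "field2019")


class TestMixedLsmeans:
    def test_reduces_to_fixed_when_no_random_variance(self):
        cfg = ac.SyntheticConfig(patch_sd=0.0, block_sd=0.0)
        gh, _ = ac.generate_glasshouse_study(cfg, seed=31)
        std = ac.transform_and_standardize(gh, transform="none")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed, vcomp = ac.fit_lsmeans_mixed(std, "biomass", "glasshouse2018")
        fixed = ac.fit_lsmeans_fixed(std, "biomass", "glasshouse2018")
        merged = mixed.merge(fixed, on=["population", "treatment"],
                             suffixes=("_m", "_f"))
        assert np.abs(merged["lsmean_m"] - merged["lsmean_f"]).max() < 1e-6
        assert vcomp["patch"] < 0.05 and vcomp["block"] < 0.05

    def test_patch_variance_component_recovered(self):
        # moderate replicate count keeps this quick; the median guards
        # against the occasional boundary estimate
        errors = []
        for rep in range(12):
            cfg = ac.SyntheticConfig(
                patch_sd=1.0, block_sd=0.0, residual_sd=np.full(13, 0.5),
                n_patches_per_population=4,
                cline_slopes=np.zeros(13), treatment_effects=np.zeros(13))
            gh, _ = ac.generate_glasshouse_study(cfg, seed=400 + rep)
            std = ac.transform_and_standardize(gh, transform="none")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, vcomp = ac.fit_lsmeans_mixed(std, "fv_fm", "glasshouse2018")
            # standardization shrinks all variances by the group SD^2
            sd2 = float(std.group_sds.loc[("glasshouse2018", "wet"), "fv_fm"] ** 2)
            errors.append(vcomp["patch"] * sd2)
        assert 0.7 < np.median(errors) < 1.3

    def test_requires_multilevel_grouping(self, field_std):
        table, _, _ = field_std
        solo = table.copy()
        solo["patch"] = "only"
        solo["block"] = "only"
        std = ac.transform_and_standardize(solo, transform="none")
        with pytest.raises(ValueError, match=">= 2 levels"):
            ac.fit_lsmeans_mixed(std, "biomass", "field2019")


class TestClineRegression:
    def test_exact_line_recovered(self):
        aridity = np.linspace(0.5, 4.0, 8)
        df = _lsmeans_frame((0.25, 0.25), (0.0, 0.0), aridity)
        fit = ac.ClineRegression(trait="biomass").fit(df).to_cline_fit()
        assert fit.slope_aridity == pytest.approx(0.25, abs=1e-10)
        assert fit.f_interaction == pytest.approx(0.0, abs=1e-16)
        assert fit.model_used == "additive"

    def test_offset_between_treatments(self):
        aridity = np.linspace(0.5, 4.0, 8)
        df = _lsmeans_frame((0.25, 0.25), (0.0, 1.0), aridity)
        fit = ac.ClineRegression().fit(df).to_cline_fit()
        assert fit.model_used == "additive"
        assert abs(fit.treatment_effect) == pytest.approx(1.0, abs=1e-10)

    def test_interaction_retained_when_slopes_oppose(self):
        aridity = np.linspace(0.5, 4.0, 8)
        rng = np.random.default_rng(77)
        kept = 0
        for _ in range(100):
            noise = rng.normal(0.0, 0.02, size=16)
            df = _lsmeans_frame((0.4, -0.4), (0.0, 0.0), aridity, noise=noise)
            est = ac.ClineRegression().fit(df)
            kept += est.model_used_ == "interaction"
        assert kept >= 90

    def test_marginal_slopes_from_interaction_model(self):
        aridity = np.linspace(0.5, 4.0, 8)
        df = _lsmeans_frame((0.3, -0.3), (0.0, 0.0), aridity,
                            noise=np.random.default_rng(8).normal(0, 1e-3, 16))
        est = ac.ClineRegression(force_interaction=True).fit(df)
        slopes = {r["treatment"]: r["slope"]
                  for _, r in est.marginal_slopes_.iterrows()}
        assert slopes["dry"] == pytest.approx(0.3, abs=0.01)
        assert slopes["wet"] == pytest.approx(-0.3, abs=0.01)

    def test_additive_model_shares_slope(self):
        aridity = np.linspace(0.5, 4.0, 8)
        df = _lsmeans_frame((0.2, 0.2), (0.0, 0.5), aridity,
                            noise=np.random.default_rng(9).normal(0, 0.05, 16))
        est = ac.ClineRegression().fit(df)
        ms = est.marginal_slopes_
        assert ms["slope"].nunique() == 1
        assert ms["lower95"].nunique() == 1

    def test_too_few_aridity_values_rejected(self):
        df = _lsmeans_frame((0.2, 0.2), (0.0, 0.0), [1.0, 2.0])
        with pytest.raises(ValueError, match="3 distinct aridity"):
            ac.ClineRegression().fit(df)

    def test_null_slope_ci_coverage_near_nominal(self):
        aridity = np.linspace(0.5, 4.0, 8)
        rng = np.random.default_rng(55)
        covered = 0
        n_rep = 300
        for _ in range(n_rep):
            df = _lsmeans_frame((0.0, 0.0), (0.0, 0.0), aridity,
                                noise=rng.normal(0, 0.3, 16))
            est = ac.ClineRegression(force_interaction=False).fit(df)
            row = est.marginal_slopes_.iloc[0]
            covered += row["lower95"] <= 0.0 <= row["upper95"]
        assert covered / n_rep == pytest.approx(0.95, abs=0.03)


class TestHolm:
    @pytest.mark.parametrize("pvals, expected", [
        ([0.001, 0.02, 0.03, 0.04], [True, False, False, False]),
        ([0.01, 0.02, 0.04], [True, True, True]),
        ([0.049], [True]),
    ])
    def test_hand_computed_decisions(self, pvals, expected):
        reject, _ = ac.holm_bonferroni(pvals, alpha=0.05)
        assert list(reject) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ac.holm_bonferroni([0.1, 1.2], 0.05)

    @staticmethod
    def brute_force_holm(pvals, alpha):
        """Literal step-down: sort, walk until the first failure."""
        order = np.argsort(pvals)
        m = len(pvals)
        reject = np.zeros(m, bool)
        for rank, idx in enumerate(order):
            if pvals[idx] <= alpha / (m - rank):
                reject[idx] = True
            else:
                break
        return reject

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_brute_force_oracle(self, pvals):
        reject, _ = ac.holm_bonferroni(pvals, 0.05)
        oracle = self.brute_force_holm(np.asarray(pvals), 0.05)
        assert list(reject) == list(oracle)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_sandwiched_by_bonferroni_and_unadjusted(self, pvals):
        p = np.asarray(pvals)
        holm, _ = ac.holm_bonferroni(p, 0.05)
        bonf = p <= 0.05 / len(p)
        raw = p <= 0.05
        assert holm.sum() >= bonf.sum()
        assert holm.sum() <= raw.sum()


class TestFitnessCline:
    def test_exact_construction_recovers_slopes(self):
        rng = np.random.default_rng(13)
        aridity = np.linspace(0.5, 4.0, 8)
        rows = []
        for i, a in enumerate(aridity):
            for t, slope in (("dry", 0.2), ("wet", 0.0)):
                for j in range(5):
                    rows.append({"population": f"P{i+1}", "treatment": t,
                                 "relative_fitness": 1.0 + slope * a})
        records = pd.DataFrame(rows)
        fit = ac.fitness_cline(records, _arid([f"P{i+1}" for i in range(8)], aridity))
        slopes = {r["treatment"]: r["slope"] for _, r in fit.per_treatment.iterrows()}
        assert slopes["dry"] == pytest.approx(0.2, abs=1e-8)
        assert slopes["wet"] == pytest.approx(0.0, abs=1e-8)
        assert fit.p_interaction < 1e-10

    def test_identical_clines_give_null_interaction(self):
        aridity = np.linspace(0.5, 4.0, 8)
        rows = [{"population": f"P{i+1}", "treatment": t,
                 "relative_fitness": 1.0 + 0.1 * a}
                for i, a in enumerate(aridity) for t in ("dry", "wet")]
        fit = ac.fitness_cline(pd.DataFrame(rows),
                               _arid([f"P{i+1}" for i in range(8)], aridity))
        assert fit.f_interaction == pytest.approx(0.0, abs=1e-16)

    def test_interaction_df_structure(self, field_std):
        table, _, truth = field_std
        fit = ac.fitness_cline(table, truth.aridity)
        assert fit.df_interaction == (1, 12)   # 2*8 obs - 4 parameters


def test_cline_table_runs_all_traits(field_std):
    _, std, truth = field_std
    table, fits = ac.cline_table(std, truth.aridity, experiment="field2019")
    assert len(table) == 13
    assert set(table["trait"]) == set(ac.TRAIT_NAMES)
    assert table["holm_significant"].notna().all()
    # Holm never rejects more than the unadjusted tests
    assert table["holm_significant"].sum() <= (table["p_aridity"] < 0.05).sum()
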