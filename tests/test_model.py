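"""Gravity-model fitting, AIC competition, and effect-size conversion."""

import numpy as np
import pandas as pd
import pytest

from gravnet.model import (
    NULL_SPEC,
    GravityModel,
    ModelSpec,
    cohens_d,
    effect_sizes,
    fit_gravity,
    hierarchical_competition,
    interpretation_report,
    log_offset_transform,
    prepare_design,
)


def synthetic_edges(seed=0, n_groups=6, per_group=40, beta=(1.0, -0.5, 0.3), sd=0.2, u_sd=0.3):
    """Hand-rolled edge table: length + one between-site covariate."""
    rng = np.random.default_rng(seed)
    rows = []
    b0, b_len, b_cov = beta
    for g in range(n_groups):
        u = u_sd * rng.standard_normal()
        for _ in range(per_group):
            length = rng.uniform(100, 5000)
            cov = rng.uniform(0.5, 4.0)
            ln_flow = b0 + b_len * np.log(length) + b_cov * np.log(cov)
            ln_flow += u + sd * rng.standard_normal()
            rows.append({"from": f"a{g}", "to": "b", "from_site": f"site{g}",
                         "length": length, "btw_cov": cov, "flow": np.exp(ln_flow)})
    return pd.DataFrame(rows)


SPEC_COV = ModelSpec("cov", btw_vars=("cov",), round_tag="btw")


class TestLogOffsetTransform:
    def test_strictly_positive_no_offset(self):
        t, delta, flipped = log_offset_transform(np.array([1.0, 2.0, 4.0]))
        assert delta == 0.0 and not flipped
        assert np.allclose(t, np.log([1, 2, 4]))

    def test_zeros_get_half_min_positive(self):
        t, delta, flipped = log_offset_transform(np.array([0.0, 2.0, 6.0]))
        assert delta == 1.0 and not flipped
        assert np.allclose(t, np.log([1.0, 3.0, 7.0]))

    def test_negatives_flip_sign(self):
        t, delta, flipped = log_offset_transform(np.array([-1.0, -2.0, 3.0]))
        assert flipped
        assert np.allclose(t, np.log([1.0, 2.0, 3.0]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            log_offset_transform(np.zeros(4))


class TestPrepareDesign:
    def test_missing_column_rejected(self):
        df = synthetic_edges()
        with pytest.raises(ValueError):
            prepare_design(df, ModelSpec("x", btw_vars=("nope",)))

    def test_sign_flip_recorded(self):
        df = synthetic_edges()
        df["btw_neg"] = -df["btw_cov"]
        frame = prepare_design(df, ModelSpec("n", btw_vars=("neg",)))
        assert frame.sign_flip_log["btw_neg"] is True

    def test_sign_flip_for_sub_unit_columns(self):
        # a covariate whose log values are negative (raw < 1) reverses direction
        rng = np.random.default_rng(12)
        df = synthetic_edges()
        df["btw_frac"] = rng.uniform(0.05, 0.8, len(df))
        frame = prepare_design(df, ModelSpec("f", btw_vars=("frac",)))
        assert frame.sign_flip_log["btw_frac"] is True
        # while a column comfortably above 1 does not
        frame2 = prepare_design(df, SPEC_COV)
        assert frame2.sign_flip_log["btw_cov"] is False

    def test_constant_flow_allowed(self):
        df = synthetic_edges()
        df["flow"] = 1.0
        frame = prepare_design(df, SPEC_COV)
        assert np.allclose(frame.y, frame.y[0])

    def test_scaled_covariate_same_t_statistics(self):
        df = synthetic_edges(seed=3)
        f1 = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        df2 = df.copy()
        df2["btw_cov"] = 10.0 * df2["btw_cov"]
        f2 = fit_gravity(prepare_design(df2, SPEC_COV), "ML")
        assert f1.params.loc["btw_cov", "t_value"] == pytest.approx(
            f2.params.loc["btw_cov", "t_value"], rel=1e-6)


class TestFitGravity:
    def test_noiseless_recovery_exact(self):
        df = synthetic_edges(seed=1, sd=0.0, u_sd=0.0)
        fit = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        assert fit.degenerate
        est = fit.params["estimate"]
        assert est["(intercept)"] == pytest.approx(1.0, rel=1e-6)
        assert est["length"] == pytest.approx(-0.5, rel=1e-6)
        assert est["btw_cov"] == pytest.approx(0.3, rel=1e-6)

    def test_edge_order_invariance(self):
        df = synthetic_edges(seed=2)
        f1 = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        f2 = fit_gravity(prepare_design(shuffled, SPEC_COV), "ML")
        assert np.allclose(f1.params["estimate"], f2.params["estimate"], atol=1e-8)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)

    @pytest.mark.parametrize("reml", [False, True])
    def test_matches_statsmodels_mixedlm(self, reml):
        sm = pytest.importorskip("statsmodels.api")
        df = synthetic_edges(seed=5, sd=0.3, u_sd=0.4)
        frame = prepare_design(df, SPEC_COV)
        mine = fit_gravity(frame, "REML" if reml else "ML")
        res = sm.MixedLM(frame.y, frame.X, groups=frame.groups).fit(reml=reml)
        assert mine.log_likelihood >= res.llf - 1e-6
        assert np.allclose(mine.params["estimate"].to_numpy(), res.fe_params, atol=1e-4)
        assert np.allclose(mine.params["se"].to_numpy(), res.bse_fe, atol=1e-3)

    def test_reml_equals_ml_when_group_variance_zero(self):
        df = synthetic_edges(seed=6, sd=0.25, u_sd=0.0)
        ml = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        reml = fit_gravity(prepare_design(df, SPEC_COV), "REML")
        assert np.allclose(ml.params["estimate"], reml.params["estimate"], atol=1e-4)

    def test_aic_identity(self):
        df = synthetic_edges(seed=7)
        fit = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        assert fit.aic == pytest.approx(2 * fit.k_parameters - 2 * fit.log_likelihood)

    def test_requires_two_groups(self):
        df = synthetic_edges(n_groups=1)
        with pytest.raises(ValueError):
            fit_gravity(prepare_design(df, SPEC_COV), "ML")

    def test_wrapper_class_fitted_attributes(self):
        df = synthetic_edges(seed=8)
        m = GravityModel(SPEC_COV, estimation="ML").fit(df)
        assert hasattr(m, "coef_") and np.isfinite(m.aic_)


class TestHierarchicalCompetition:
    def test_ranking_matches_bruteforce_refits(self, tiny_dataset):
        et = tiny_dataset.edge_table
        comp = hierarchical_competition(et)
        # oracle: refit every round-2 spec independently, rank by AIC
        specs = {}
        for name in comp.round_combined["model"]:
            specs[name] = comp.fits[name].spec
        oracle = []
        for name, spec in specs.items():
            fit = fit_gravity(prepare_design(et, spec), "ML")
            oracle.append((fit.aic, name))
        oracle_order = [n for _, n in sorted(oracle)]
        assert list(comp.round_combined["model"]) == oracle_order

    def test_duplicate_specs_deduplicated_deterministically(self, tiny_dataset):
        et = tiny_dataset.edge_table
        procs = {"veg_a": ["shrub", "cti"], "veg_b": ["shrub", "cti"]}
        comp = hierarchical_competition(et, at_processes=procs, btw_processes={"t": ["hli"]})
        c1 = hierarchical_competition(et, at_processes=procs, btw_processes={"t": ["hli"]})
        assert comp.selected.name == c1.selected.name
        # identical covariate sets collapse to one round-2 entry
        names = list(comp.round_combined["model"])
        assert len(names) == len(set(names))

    def test_survivor_rule_excludes_null(self, tiny_dataset):
        comp = hierarchical_competition(tiny_dataset.edge_table)
        assert all(s.round_tag != "null" for s in comp.survivors_at + comp.survivors_btw)


TABLE5_ROWS = [
    # (t, df, printed Cohen's D)
    (-3.638, 1724, -0.1752),
    (-1.3421, 126, -0.2391),
    (-2.4917, 126, -0.444),
    (-2.2216, 126, -0.3958),
    (0.3744, 126, 0.0667),
    (1.7797, 126, 0.3171),
    (2.45, 126, 0.4365),
    (-2.3702, 1724, -0.1142),
    (-2.8105, 1724, -0.1354),
    (2.7826, 1724, 0.134),
    (2.9189, 1724, 0.1406),
    (-4.2578, 1724, -0.2051),
    (-0.8763, 1724, -0.0422),
]


class TestEffectSizes:
    @pytest.mark.parametrize("t,df,expected", TABLE5_ROWS)
    def test_cohens_d_from_t(self, t, df, expected):
        assert round(cohens_d(t, df), 4) == pytest.approx(expected, abs=5e-5)

    def test_zero_t_is_null_effect(self):
        assert cohens_d(0.0, 50) == 0.0

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0)

    def make_reml_fit(self, seed=9, flip=False):
        df = synthetic_edges(seed=seed, sd=0.2, u_sd=0.2)
        if flip:
            df["btw_cov"] = -df["btw_cov"]
        return fit_gravity(prepare_design(df, SPEC_COV), "REML")

    def test_significance_matches_ci(self):
        es = effect_sizes(self.make_reml_fit())
        for _, row in es.table.iterrows():
            assert row["significant"] == (not row["ci_low"] <= 0 <= row["ci_high"])

    def test_direction_reversed_for_between_site_and_flips(self):
        plain = effect_sizes(self.make_reml_fit(flip=False))
        flipped = effect_sizes(self.make_reml_fit(flip=True))
        row_p = plain.table.loc["btw_cov"]
        row_f = flipped.table.loc["btw_cov"]
        assert not row_p["flipped"] and row_f["flipped"]
        # btw_cov is between-site: direction is sign(d) reversed once (btw),
        # and reversed again when the log-transform flipped the sign
        if row_p["significant"]:
            d_sign = "+" if row_p["cohens_d"] > 0 else "-"
            assert row_p["direction"] != d_sign
        if row_f["significant"]:
            assert row_f["direction"] == ("+" if row_f["cohens_d"] > 0 else "-")

    def test_requires_reml(self):
        df = synthetic_edges(seed=10)
        fit = fit_gravity(prepare_design(df, SPEC_COV), "ML")
        with pytest.raises(ValueError):
            effect_sizes(fit)

    def test_calibrated_ci_rule_halfwidth(self):
        es = effect_sizes(self.make_reml_fit(), ci_rule="calibrated")
        row = es.table.loc["length"]
        half = (row["ci_high"] - row["ci_low"]) / 2
        df_len = self.make_reml_fit().params.loc["length", "df"]
        assert half == pytest.approx(1.40 * 2 / np.sqrt(df_len))


class TestInterpretationReport:
    def test_verdicts(self):
        table = pd.DataFrame(
            {
                "cohens_d": [0.4, -0.4, 0.1, 0.5],
                "ci_low": [0.2, -0.6, -0.1, 0.3],
                "ci_high": [0.6, -0.2, 0.3, 0.7],
                "p_value": [0.01, 0.01, 0.5, 0.01],
                "significant": [True, True, False, True],
                "direction": ["+", "-", "none", "+"],
                "flipped": [False] * 4,
            },
            index=["at_sand", "at_adi", "at_hli", "mystery"],
        )
        from gravnet.model import EffectSizeTable
        rep = interpretation_report(EffectSizeTable(table, "normal"))
        assert rep.loc["at_sand", "verdict"] == "supported"      # predicted +
        assert rep.loc["at_adi", "verdict"] == "contradicted"    # predicted +
        assert rep.loc["at_hli", "verdict"] == "insignificant"
        assert rep.loc["mystery", "verdict"] == "unregistered"
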