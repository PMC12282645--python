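import numpy as np
import pandas as pd
import pytest

from nightscratch.agreement import (
    VarianceComponents,
    bland_altman_repeated,
    bootstrap_icc,
    fit_variance_components,
    icc_from_components,
)
from nightscratch.simulate import simulate_log_outcomes


def _drop_nights(df, n_drop, seed):
    """Drop whole nights (both sources) to unbalance the design."""
    nights = df[["participant", "night"]].drop_duplicates()
    drop = nights.sample(n_drop, random_state=seed).assign(_d=1)
    out = df.merge(drop, how="left", on=["participant", "night"])
    return out[out["_d"].isna()].drop(columns="_d")


class TestIccFromComponents:
    @pytest.mark.parametrize(
        "comps, expected",
        [((3.0, 1.0, 1.0), 0.8), ((1.0, 0.0, 0.0), 1.0), ((1.0, 1.0, 2.0), 0.5)],
    )
    def test_adjusted_ratio(self, comps, expected):
        vc = VarianceComponents(*comps, fixed_source_effects={}, var_fixed=0.0)
        assert icc_from_components(vc, "adjusted") == pytest.approx(expected)

    def test_unadjusted_adds_fixed_effect_variance(self):
        vc = VarianceComponents(3.0, 1.0, 1.0, {"A": -0.5, "B": 0.5}, var_fixed=0.25)
        assert icc_from_components(vc, "unadjusted") == pytest.approx(4 / 5.25)
        assert icc_from_components(vc, "adjusted") > icc_from_components(vc, "unadjusted")

    def test_all_zero_undefined(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, {}, var_fixed=0.0)
        assert icc_from_components(vc) is None


class TestFitVarianceComponents:
    def test_balanced_anova_equals_statsmodels_reml(self):
        df = simulate_log_outcomes(20, 6, ["A", "B"], (0.8, 0.4, 0.6),
                                   source_effects=[0, 0.3], seed=11)
        va = fit_variance_components(df, method="anova")
        vr = fit_variance_components(df, method="reml")
        assert vr.converged
        for attr in ("var_participant", "var_night", "var_residual", "var_fixed"):
            assert getattr(va, attr) == pytest.approx(getattr(vr, attr), abs=2e-3)

    def test_profile_equals_statsmodels_reml_unbalanced(self):
        df = _drop_nights(
            simulate_log_outcomes(18, 8, ["A", "B"], (0.8, 0.4, 0.6),
                                  source_effects=[0, 0.3], seed=5),
            20, seed=1,
        )
        vp = fit_variance_components(df, method="profile")
        vr = fit_variance_components(df, method="reml")
        assert vr.converged
        for attr in ("var_participant", "var_night", "var_residual"):
            assert getattr(vp, attr) == pytest.approx(getattr(vr, attr), rel=1e-3, abs=1e-5)

    def test_perfect_agreement_limit(self):
        """Identical outcomes across sources: residual 0, ICC 1."""
        df = simulate_log_outcomes(10, 4, ["A"], (1.0, 0.5, 0.0), seed=3)
        df2 = df.assign(source="B")
        both = pd.concat([df, df2], ignore_index=True)
        vc = fit_variance_components(both)
        assert vc.method == "degenerate"
        assert vc.var_residual == 0.0
        assert icc_from_components(vc) == 1.0

    def test_pure_noise_has_no_hierarchy(self):
        """Independent noise only: participant and night components near zero."""
        vals = []
        for r in range(20):
            df = simulate_log_outcomes(28, 8, ["A", "B"], (0.0, 0.0, 1.0), seed=100 + r)
            vc = fit_variance_components(df)
            vals.append((vc.var_participant, vc.var_night))
        mean_p, mean_n = np.mean(vals, axis=0)
        assert mean_p < 0.05 and mean_n < 0.05

    def test_component_recovery_at_study_scale(self):
        """(1.0, 0.5, 0.5) recovered within +-0.15 on average over replicates."""
        comps = []
        for r in range(25):
            df = simulate_log_outcomes(28, 8, ["A", "B"], (1.0, 0.5, 0.5),
                                       source_effects=[0, 0.2], seed=500 + r)
            vc = fit_variance_components(df)
            comps.append((vc.var_participant, vc.var_night, vc.var_residual))
        mean = np.mean(comps, axis=0)
        assert np.allclose(mean, [1.0, 0.5, 0.5], atol=0.15)

    def test_fixed_effect_absorption(self):
        """Shifting one source's outcomes changes unadjusted but not adjusted ICC."""
        df = simulate_log_outcomes(20, 6, ["A", "B"], (0.8, 0.4, 0.6), seed=7)
        shifted = df.copy()
        shifted.loc[shifted["source"] == "B", "y"] += 1.0
        v0, v1 = fit_variance_components(df), fit_variance_components(shifted)
        assert icc_from_components(v1, "adjusted") == pytest.approx(
            icc_from_components(v0, "adjusted"), abs=1e-9
        )
        assert icc_from_components(v1, "unadjusted") < icc_from_components(v0, "unadjusted")

    def test_too_few_sources_rejected(self):
        df = simulate_log_outcomes(5, 4, ["A"], (1.0, 0.5, 0.5), seed=1)
        with pytest.raises(ValueError, match="2 sources"):
            fit_variance_components(df)


class TestBootstrapIcc:
    def test_same_seed_reproducible(self):
        df = simulate_log_outcomes(15, 5, ["A", "B"], (1.0, 0.5, 0.5), seed=9)
        r1 = bootstrap_icc(df, n_boot=100, seed=42)
        r2 = bootstrap_icc(df, n_boot=100, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_brackets_estimate_in_unit_interval(self):
        df = simulate_log_outcomes(15, 5, ["A", "B"], (1.0, 0.5, 0.5), seed=9)
        for ci_method in ("cluster-t", "percentile", "basic"):
            res = bootstrap_icc(df, n_boot=100, seed=1, ci_method=ci_method)
            assert 0.0 <= res.ci_low <= res.estimate <= res.ci_high <= 1.0

    def test_perfect_agreement_upper_bound(self):
        df = simulate_log_outcomes(10, 4, ["A"], (1.0, 0.5, 0.0), seed=3)
        both = pd.concat([df, df.assign(source="B")], ignore_index=True)
        res = bootstrap_icc(both, n_boot=50, seed=0)
        assert res.ci_high >= 0.99

    def test_unbalanced_profile_bootstrap_runs(self):
        df = _drop_nights(
            simulate_log_outcomes(12, 6, ["A", "B"], (1.0, 0.5, 0.5), seed=2), 8, seed=2
        )
        res = bootstrap_icc(df, n_boot=100, seed=5)
        assert res.components.method == "profile"
        assert res.n_used == 100
        assert res.ci_low < res.estimate < res.ci_high


class TestBlandAltman:
    def test_all_zero_differences(self):
        df = pd.DataFrame({"participant": ["P1"] * 3 + ["P2"] * 3, "diff": [0.0] * 6})
        res = bland_altman_repeated(df, n_boot=20, seed=0)
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_constant_differences(self):
        df = pd.DataFrame({"participant": ["P1"] * 3 + ["P2"] * 3, "diff": [0.42] * 6})
        res = bland_altman_repeated(df, n_boot=20, seed=0)
        assert res.bias == pytest.approx(0.42)
        assert res.loa_low == res.loa_high == pytest.approx(0.42)

    def test_limits_symmetric_about_bias(self, rng):
        rows = [
            {"participant": f"P{p}", "diff": rng.normal(0.3, 0.5) + rng.normal(0, 0.5)}
            for p in range(10)
            for _ in range(6)
        ]
        res = bland_altman_repeated(pd.DataFrame(rows), n_boot=50, seed=1)
        assert res.loa_high - res.bias == pytest.approx(res.bias - res.loa_low)

    def test_accepts_tso_hour_columns(self):
        df = pd.DataFrame(
            {
                "participant": ["P1", "P1", "P2", "P2"],
                "dht_tso_hours": [8.5, 8.1, 7.9, 8.2],
                "ref_tso_hours": [8.0, 8.0, 8.0, 8.0],
            }
        )
        res = bland_altman_repeated(df, n_boot=20, seed=0)
        assert res.bias == pytest.approx(np.mean([0.5, 0.1, -0.1, 0.2]))

    def test_single_participant_rejected(self):
        df = pd.DataFrame({"participant": ["P1"] * 4, "diff": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="participants"):
            bland_altman_repeated(df)

    def test_unbalanced_profile_matches_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        rows = []
        for p in range(12):
            b = rng.normal(0.4, 0.7)
            for _ in range(int(rng.integers(2, 8))):
                rows.append({"participant": f"P{p}", "diff": b + rng.normal(0, 0.6)})
        df = pd.DataFrame(rows)
        res = bland_altman_repeated(df, n_boot=20, seed=0)
        assert res.method == "profile"
        mm = smf.mixedlm("diff ~ 1", df, groups="participant").fit(reml=True)
        assert res.bias == pytest.approx(float(mm.fe_params["Intercept"]), abs=1e-5)
        assert res.var_between == pytest.approx(float(np.asarray(mm.cov_re)[0, 0]), abs=1e-4)
        assert res.var_within == pytest.approx(float(mm.scale), abs=1e-4)
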