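"""Feature filtering, LOWESS normalization, error-weighted combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfsarray as ta
from tfsarray.normalize import (
    ErrorModelParams,
    combine_replicates,
    exclusion_reasons,
    filter_features,
    lowess_normalize,
    model_variance,
)

from conftest import quiet_design

EM = ErrorModelParams()


def _hyb(n=100, seed=0, orientation="forward"):
    rng = np.random.default_rng(seed)
    inten = rng.uniform(100, 10000, size=(n, 2))
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:03d}" for i in range(n)],
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "channel_A_intensity": inten[:, 0],
            "channel_B_intensity": inten[:, 1],
            "dye_orientation": orientation,
            "flag_saturated_A": False,
            "flag_saturated_B": False,
            "flag_nonuniform_A": False,
            "flag_nonuniform_B": False,
        }
    )


class TestFilterFeatures:
    @pytest.mark.parametrize(
        "sat_a, sat_b, nu_a, nu_b, kept",
        [
            (False, False, False, False, True),
            (True, False, False, False, True),    # saturated in one channel only
            (True, True, False, False, False),    # saturated in both
            (False, False, True, False, False),   # non-uniform in either
            (False, False, False, True, False),
            (True, False, False, True, False),
        ],
    )
    def test_exclusion_rules(self, sat_a, sat_b, nu_a, nu_b, kept):
        h = _hyb(n=1)
        h.loc[0, ["flag_saturated_A", "flag_saturated_B"]] = [sat_a, sat_b]
        h.loc[0, ["flag_nonuniform_A", "flag_nonuniform_B"]] = [nu_a, nu_b]
        assert (len(filter_features(h)) == 1) is kept

    def test_unflagged_table_unchanged(self):
        h = _hyb(n=20)
        pd.testing.assert_frame_equal(filter_features(h), h)

    def test_reasons_labelled(self):
        h = _hyb(n=3)
        h.loc[1, ["flag_saturated_A", "flag_saturated_B"]] = True
        h.loc[2, "flag_nonuniform_B"] = True
        assert exclusion_reasons(h).tolist() == ["ok", "saturated_both", "nonuniform"]


class TestLowessNormalize:
    def test_null_noise_free_is_exactly_zero(self):
        sim = ta.simulate_experiment(
            quiet_design(sigma_add=0, sigma_mult=0, dye_bias_amplitude=0)
        )
        norm = lowess_normalize(sim.hybridizations[1][0], params=EM)
        assert np.nanmax(np.abs(norm["M"])) == 0.0

    def test_planted_effects_survive_detrending(self):
        # noise-free: the planted gene must keep its +2/-0 pattern after
        # LOWESS (the trend is fit robustly, so the outlier is not absorbed);
        # the pseudo-intensity offset keeps this from being exact
        patterns = {"g00005": ((1, 0, 0, 1), 2.0)}
        sim = ta.simulate_experiment(
            quiet_design(
                planted_patterns=patterns, sigma_add=0, sigma_mult=0,
                dye_bias_amplitude=0,
            )
        )
        for comp, expected in [(1, 2.0), (2, 0.0), (3, 0.0), (4, 2.0)]:
            for hyb in sim.hybridizations[comp]:
                norm = lowess_normalize(hyb, params=EM)
                m = norm.loc[norm["probe_id"] == "p_g00005_a", "M"].iloc[0]
                assert m == pytest.approx(expected, abs=0.01)

    def test_dye_swap_symmetry_raw_ratios(self):
        sim = ta.simulate_experiment(
            quiet_design(sigma_add=0, sigma_mult=0, dye_bias_amplitude=0)
        )
        fwd, rev = sim.hybridizations[1][0], sim.hybridizations[1][1]
        ratio_f = fwd["channel_A_intensity"] / fwd["channel_B_intensity"]
        ratio_r = rev["channel_A_intensity"] / rev["channel_B_intensity"]
        assert np.allclose(ratio_f * ratio_r, 1.0)

    def test_orientation_invariance(self):
        h = _hyb(n=200, seed=5)
        swapped = h.copy()
        swapped["channel_A_intensity"] = h["channel_B_intensity"]
        swapped["channel_B_intensity"] = h["channel_A_intensity"]
        swapped["dye_orientation"] = "reverse"
        a = lowess_normalize(h, params=EM)
        b = lowess_normalize(swapped, params=EM)
        np.testing.assert_allclose(a["M"], b["M"], atol=1e-12)
        np.testing.assert_allclose(a["A"], b["A"], atol=1e-12)

    def test_span_and_probe_count_validation(self):
        h = _hyb(n=200)
        with pytest.raises(ValueError, match="span"):
            lowess_normalize(h, span=1.5, params=EM)
        with pytest.raises(ValueError, match="usable"):
            lowess_normalize(_hyb(n=10), params=EM)

    def test_excluded_rows_kept_with_reason(self):
        h = _hyb(n=100)
        h.loc[3, "flag_nonuniform_A"] = True
        norm = lowess_normalize(h, params=EM)
        assert len(norm) == 100
        assert not norm.loc[3, "usable"]
        assert np.isnan(norm.loc[3, "M"])
        assert norm.loc[3, "exclusion_reason"] == "nonuniform"


def _ratios(ms, a=13.0):
    return pd.DataFrame(
        {
            "probe_id": "p1",
            "gene_id": "g1",
            "A": a,
            "M": ms,
            "usable": True,
            "exclusion_reason": "ok",
        }
    )


class TestCombineReplicates:
    def test_symmetric_pair(self):
        out = combine_replicates([_ratios([1.0]), _ratios([1.0])], EM)
        row = out.iloc[0]
        assert row["log2_ratio"] == pytest.approx(1.0)
        assert row["fold"] == pytest.approx(2.0)
        assert row["n_used"] == 2

    def test_cancelling_pair(self):
        out = combine_replicates([_ratios([1.0]), _ratios([-1.0])], EM)
        row = out.iloc[0]
        assert row["log2_ratio"] == pytest.approx(0.0)
        assert row["fold"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_hand_computed_weighted_mean_z_test(self):
        # equal model variances sigma=0.2 at high intensity; oracle = direct
        # arithmetic: xbar = 1.0, model SE = 0.1 > empirical SE, z = 10
        ln2 = np.log(2)
        params = ErrorModelParams(
            sigma_add=0.0, sigma_mult=ln2 * np.sqrt(0.02), sigma_floor=0.01
        )
        ms = [0.8, 1.2, 1.0, 1.0]
        out = combine_replicates([_ratios([m]) for m in ms], params)
        row = out.iloc[0]
        sigma2 = model_variance(np.array([13.0]), params)[0]
        assert sigma2 == pytest.approx(0.04, rel=1e-12)
        assert row["log2_ratio"] == pytest.approx(1.0, abs=1e-10)
        assert row["se"] == pytest.approx(0.1, abs=1e-10)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(10.0), rel=1e-10)
        assert row["fold"] == pytest.approx(2.0, abs=1e-9)

    def test_overdispersed_probe_uses_empirical_variance(self):
        params = ErrorModelParams(
            sigma_add=0.0, sigma_mult=np.log(2) * np.sqrt(0.02), sigma_floor=0.01
        )
        ms = [-2.0, 2.0, -2.0, 2.0]
        row = combine_replicates([_ratios([m]) for m in ms], params).iloc[0]
        s2 = np.var(ms, ddof=1)
        assert row["se"] == pytest.approx(np.sqrt(s2 / 4))

    def test_replication_tightens_the_error_model(self):
        # the model-based variance component always shrinks with replication;
        # the empirical component cannot grow when the added measurement sits
        # at the current combined estimate (an outlier replicate may
        # legitimately widen the empirical term — that is the point of the
        # max() guard)
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            ms = rng.normal(0, 0.5, n)
            base = [_ratios([m]) for m in ms]
            out0 = combine_replicates(base, EM).iloc[0]
            dup = base + [_ratios([out0["log2_ratio"]])]
            out1 = combine_replicates(dup, EM).iloc[0]
            assert out1["se"] <= out0["se"] + 1e-12
            # model component alone: strictly decreasing in n
            sigma2 = model_variance(np.array([13.0]), EM)[0]
            assert sigma2 / (n + 1) < sigma2 / n

    def test_result_invariants(self, default_run):
        for res in default_run["results"].values():
            assert ((res["p"] > 0) & (res["p"] <= 1)).all()
            assert (np.abs(res["fold"]) >= 1).all()
            assert (np.sign(res["fold"]) == np.sign(res["log2_ratio"])).all() or (
                res.loc[np.sign(res["fold"]) != np.sign(res["log2_ratio"]), "log2_ratio"]
                == 0
            ).all()
            assert (res["n_used"] >= 1).all()

    def test_variance_model_monotone_in_intensity(self):
        a = np.linspace(2, 16, 100)
        v = model_variance(a, EM)
        assert (np.diff(v) <= 1e-15).all()
        assert (v >= EM.sigma_floor**2 - 1e-15).all()

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            combine_replicates([], EM)
        bad = _ratios([np.nan])
        with pytest.raises(ValueError):
            combine_replicates([bad], EM)
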