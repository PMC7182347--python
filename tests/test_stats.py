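"""Correlation report, delta-sign splits, zero-entropy exclusion, resampling test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from disorderlink import (
    correlate_delta,
    exclude_zero_entropy_and_recompute,
    majority_vote_sign_test,
    pearson,
    ss_cross_correlations,
)


class TestPearson:
    def test_affine_relation_gives_one(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_direct_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        xc, yc = x - x.mean(), y - y.mean()
        direct = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert direct == pytest.approx(0.8)
        assert pearson(x, y) == pytest.approx(direct, abs=1e-12)

    def test_degenerate_inputs(self):
        assert pearson([1, 2], [3, 4]) is None          # too short
        assert pearson([1, 1, 1], [1, 2, 3]) is None    # zero variance
        assert pearson([1, np.nan, 2, 3, 4], [3, 5, np.nan, 7, 9]) == pytest.approx(1.0)

    @given(hst.floats(0.1, 10), hst.floats(-5, 5), hst.integers(0, 2**16))
    @settings(derandomize=True, max_examples=30)
    def test_affine_invariance_and_sign_flip(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson(x, y)
        assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson(-a * x, y) == pytest.approx(-r, abs=1e-9)


def _table(n=300, seed=0):
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-1, 1, n)
    return pd.DataFrame({
        "site": np.arange(1, n + 1),
        "delta": delta,
        "n_struct": np.full(n, 20),
        "dav": 8 + 3 * delta + rng.normal(0, 1, n),
        "s1": rng.uniform(0, 3, n),
        "sss1": rng.uniform(0, 1, n),
        "sss2": rng.uniform(0, 1, n),
        "s2": rng.uniform(0, 3, n),
        "ss1h": rng.uniform(0, 1, n),
        "ss1c": rng.uniform(0, 1, n),
        "ss1e": rng.uniform(0, 1, n),
    })


class TestCorrelateDelta:
    def test_planted_positive_coupling_recovered(self):
        rep = correlate_delta(_table())
        r_dav = rep.delta_vs_feature.set_index("feature").loc["dav", "r"]
        assert r_dav > 0.5

    def test_identical_feature_gives_one(self):
        t = _table()
        t["mirror"] = t["delta"]
        rep = correlate_delta(t)
        assert rep.delta_vs_feature.set_index("feature").loc["mirror", "r"] == pytest.approx(1.0)

    def test_permuted_feature_uncorrelated(self):
        t = _table(seed=1)
        rng = np.random.default_rng(2)
        t["shuffled"] = rng.permutation(t["dav"].to_numpy())
        rep = correlate_delta(t)
        assert abs(rep.delta_vs_feature.set_index("feature").loc["shuffled", "r"]) < 0.2

    def test_entropy_pairs_reported(self):
        rep = correlate_delta(_table())
        assert set(rep.entropy_pairs["pair"]) == {
            "s1:s2", "s1:sss1", "s1:sss2", "s2:sss1", "s2:sss2", "sss1:sss2"
        }


class TestSSCross:
    def test_identical_propensities_give_one(self):
        t = _table()
        for s in "hce":
            t[f"ss2{s}"] = t[f"ss1{s}"]
        out = ss_cross_correlations(t, split="by_delta_sign")
        assert np.allclose(out["r"].dropna(), 1.0)
        assert set(out["stratum"]) == {"all", "delta>=0", "delta<0"}

    def test_small_stratum_reports_na(self):
        t = _table(n=40)
        for s in "hce":
            t[f"ss2{s}"] = t[f"ss1{s}"]
        t.loc[t.index[:-2], "delta"] = -abs(t.loc[t.index[:-2], "delta"])  # <3 sites with delta>=0
        t.loc[t.index[-2:], "delta"] = 0.5
        out = ss_cross_correlations(t, split="by_delta_sign")
        sub = out[out["stratum"] == "delta>=0"]
        assert sub["r"].isna().all()

    def test_delta_zero_in_disordered_stratum(self):
        t = _table(n=30)
        for s in "hce":
            t[f"ss2{s}"] = t[f"ss1{s}"]
        t["delta"] = 0.0
        out = ss_cross_correlations(t, split="by_delta_sign")
        assert (out[out["stratum"] == "delta>=0"]["n_pairs"] == 30).all()
        assert (out[out["stratum"] == "delta<0"]["n_pairs"] == 0).all()


class TestZeroEntropyExclusion:
    def test_no_zero_sites_identical(self):
        t = _table()
        t["sss1"] = t["sss1"] + 0.01
        r_all, r_f = exclude_zero_entropy_and_recompute(t, "sss1")
        assert r_all == pytest.approx(r_f)

    def test_sign_reversal_on_constructed_fixture(self):
        # zero-entropy sites concentrated at extreme delta pull r negative;
        # among nonzero-entropy sites the relation is positive
        n = 100
        rng = np.random.default_rng(3)
        delta_pos = rng.uniform(0.5, 1.0, n // 2)
        sss_zero = np.zeros(n // 2)
        delta_rest = rng.uniform(-1.0, 0.0, n // 2)
        sss_rest = 0.5 + 0.4 * delta_rest + rng.normal(0, 0.02, n // 2)
        t = pd.DataFrame({"delta": np.concatenate([delta_pos, delta_rest]),
                          "sss1": np.concatenate([sss_zero, sss_rest])})
        r_all, r_filtered = exclude_zero_entropy_and_recompute(t, "sss1")
        assert r_all < 0 < r_filtered

    def test_empty_filtered_set(self):
        t = pd.DataFrame({"delta": [0.1, 0.2, 0.3], "sss1": [0.0, 0.0, 0.0]})
        r_all, r_filtered = exclude_zero_entropy_and_recompute(t, "sss1")
        assert r_all is None  # zero variance
        assert r_filtered is None


class TestMajorityVote:
    def test_unanimous_positive_p_value(self):
        x = np.arange(500.0)
        res = majority_vote_sign_test(x, 2 * x + 3, seed=0)
        assert res.unanimous
        assert res.p_value == pytest.approx(2**-10)
        assert res.round_signs == [1] * 10

    def test_perfectly_correlated_any_seed(self):
        x = np.linspace(-1, 1, 400)
        for seed in (1, 17, 993):
            res = majority_vote_sign_test(x, x, seed=seed)
            assert res.unanimous and res.p_value == pytest.approx(2**-10)

    def test_short_data_lowers_subset_size(self):
        x = np.arange(100.0)
        with pytest.warns(UserWarning, match="lowering subset size"):
            res = majority_vote_sign_test(x, -x, seed=4)
        assert res.subset_size == 80
        assert res.round_signs == [-1] * 10

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=300), rng.normal(size=300)
        a = majority_vote_sign_test(x, y, seed=42)
        b = majority_vote_sign_test(x, y, seed=42)
        assert a == b

    def test_null_round_signs_track_full_sample_sign(self):
        # With all subsets drawn from one fixed dataset the rounds are not
        # independent coin flips: the majority sign follows the sign of the
        # full-sample correlation.  Verify that actual behaviour under the
        # null, and that the full-sample correlation itself is near zero.
        rng = np.random.default_rng(12)
        agree = 0
        meta = 60
        for _ in range(meta):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            full_sign = 1 if pearson(x, y) >= 0 else -1
            res = majority_vote_sign_test(x, y, seed=int(rng.integers(2**31)))
            agree += sum(1 for s in res.round_signs if s == full_sign)
        # well above the 0.5 expected if rounds were independent fair coins
        assert agree / (meta * 10) > 0.7


def test_scatter_plot_export(tmp_path):
    from disorderlink import scatter_plot

    t = _table(n=50)
    out = tmp_path / "delta_vs_sss1.png"
    scatter_plot(t, "sss1", out)
    assert out.stat().st_size > 0
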