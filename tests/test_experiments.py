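"""Virtual-trial analyses: curve shapes, feature scan, switch scenarios,
threshold scan, and the pipeline plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bsabqsp import synthetic, vpop
from bsabqsp.experiments import (classify_curve_shape, dose_response_study,
                                 feature_scan, run_pipeline, switch_study,
                                 threshold_scan)


# ---------------------------------------------------------------------------
# curve shapes
# ---------------------------------------------------------------------------

class TestCurveShapes:
    @pytest.mark.parametrize("seq, expected", [
        ([0.10, 0.20, 0.30, 0.35, 0.40], "increasing"),
        ([0.20, 0.30, 0.35, 0.30, 0.20], "bell"),
        ([0.40, 0.30, 0.20, 0.10, 0.05], "decreasing"),
        ([0.30, 0.30, 0.30], "increasing"),     # flat counts as monotone
    ])
    def test_taxonomy(self, seq, expected):
        label, ok = classify_curve_shape(seq)
        assert label == expected and ok

    def test_multi_peak_flagged(self):
        label, ok = classify_curve_shape([0.1, 0.4, 0.1, 0.4, 0.1])
        assert label == "bell" and not ok

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            classify_curve_shape([0.1, 0.2])

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        for seq in ([0.1, 0.2, 0.3], [0.2, 0.3, 0.2], [0.3, 0.2, 0.1]):
            a = classify_curve_shape(seq)
            b = classify_curve_shape([x * scale for x in seq])
            assert a == b


# ---------------------------------------------------------------------------
# dose-response table
# ---------------------------------------------------------------------------

class TestDoseResponse:
    def test_empty_regimen_list(self, small_pool):
        table = dose_response_study(small_pool, [], regimen_ids=())
        assert table.empty

    def test_pooled_rate_is_member_weighted_stratum_mean(self, small_pool):
        fake = [vpop.VPop(member_pos=np.arange(40),
                          member_ids=small_pool.candidates.index.values[:40],
                          objective=0.0, breakdown={}, seed=0,
                          history=np.array([0.0]))]
        table = dose_response_study(small_pool, fake,
                                    regimen_ids=("two_step_priming_76qw",),
                                    with_priming=False)
        by = table.set_index("stratum")
        lhs = by.loc["all", "brr"] * by.loc["all", "n"]
        rhs = (by.loc["low", "brr"] * by.loc["low", "n"]
               + by.loc["high", "brr"] * by.loc["high", "n"])
        assert lhs == pytest.approx(rhs, abs=1e-9)
        assert by.loc["low", "n"] + by.loc["high", "n"] == by.loc["all", "n"]


# ---------------------------------------------------------------------------
# feature scan
# ---------------------------------------------------------------------------

class TestFeatureScan:
    def test_constant_feature_reports_p_one(self, rng):
        n = 90
        df = pd.DataFrame({"flat": np.ones(n),
                           "noise": rng.standard_normal(n)})
        shapes = pd.Series(np.repeat(["increasing", "bell", "decreasing"],
                                     n // 3))
        table = feature_scan(df, shapes).set_index("feature")
        assert table.loc["flat", "p_value"] == 1.0

    def test_discriminative_feature_ranks_first(self, rng):
        n = 150
        x = rng.standard_normal(n)
        # shape driven by x with overlap so the logit stays well-posed
        noisy = x + 0.5 * rng.standard_normal(n)
        shapes = pd.Series(np.where(noisy < -0.4, "decreasing",
                                    np.where(noisy > 0.4, "increasing",
                                             "bell")))
        df = pd.DataFrame({"driver": x,
                           "noise1": rng.standard_normal(n),
                           "noise2": rng.standard_normal(n)})
        table = feature_scan(df, shapes, joint_pair=("driver", "noise1"))
        assert table.iloc[0]["feature"] == "driver"
        joint = table[table["feature"].str.startswith("joint:")]
        assert len(joint) == 1 and joint.iloc[0]["p_value"] < 0.01

    def test_null_p_values_uniform(self, rng):
        """Groups drawn from one distribution yield approximately uniform
        p-values over 200 replicates."""
        pvals = []
        shapes = pd.Series(np.repeat(["a", "b", "c"], 30))
        for _ in range(200):
            df = pd.DataFrame({"x": rng.standard_normal(90)})
            pvals.append(float(feature_scan(df, shapes)["p_value"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_rejected(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(10)})
        with pytest.raises(ValueError):
            feature_scan(df, pd.Series(["bell"] * 10))


# ---------------------------------------------------------------------------
# switch scenarios
# ---------------------------------------------------------------------------

class TestSwitchStudy:
    @pytest.fixture(scope="module")
    def tiny_switch(self, small_pool):
        cache = small_pool.cache("two_step_priming_76qw")
        members = np.where(cache.persistent)[0][:3]
        fake = [vpop.VPop(member_pos=members,
                          member_ids=small_pool.candidates.index.values[members],
                          objective=0.0, breakdown={}, seed=0,
                          history=np.array([0.0]))]
        return switch_study(small_pool, fake, horizon=500.0)

    def test_scenarios_identical_before_switch(self, small_pool, tiny_switch):
        """With identical pre-switch inputs the scenario trajectories agree
        exactly up to the switch day."""
        from bsabqsp.regimens import (SwitchRule, simulate_adaptive,
                                      two_step_priming)
        cache = small_pool.cache("two_step_priming_76qw")
        i = int(np.where(cache.persistent)[0][0])
        params, init = vpop.build_patient(small_pool.candidates.iloc[i],
                                          small_pool.base_params)
        a, _ = simulate_adaptive(params, init, two_step_priming(), 300.0)
        b, log = simulate_adaptive(
            params, init, two_step_priming().with_switch_rule(SwitchRule()),
            300.0)
        assert log, "patient expected to switch"
        switch_day = log[0][0]
        pre = a.t <= switch_day
        assert np.array_equal(a.t[pre], b.t[pre])
        assert np.array_equal(a.y[:, pre], b.y[:, pre])

    def test_result_structure(self, tiny_switch):
        res = tiny_switch
        assert res.n_responders == 3
        assert set(res.pd_fraction) == {"constant_qw", "switch_q2w",
                                        "switch_q2w_q4w"}
        assert {"q2w_vs_qw_c13", "q4w_vs_q2w_end"} <= set(res.shrinkage_gain)
        assert set(res.trimer_ratio_tests) == {"c18", "c36"}

    def test_no_responders_informative_empty(self, small_pool):
        res = switch_study(small_pool, [vpop.VPop(
            member_pos=np.array([], dtype=int), member_ids=np.array([]),
            objective=0.0, breakdown={}, seed=0, history=np.array([0.0]))])
        assert res.n_responders == 0 and res.per_patient.empty


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

class TestThresholdScan:
    def test_recovers_generative_cutoff(self):
        data = synthetic.generate_threshold_dataset(500, 100.0, 0.7, 0.3,
                                                    seed=2024)
        scan = threshold_scan(data, np.arange(40, 201, 10))
        assert scan["selected_cutoff"] == 100.0
        assert not scan["low_confidence"]

    def test_recovery_rate_across_replicates(self):
        """The generative cutoff is recovered in at least 90% of 50 seeded
        replicates at n=500 with a 0.7 vs 0.3 response step."""
        hits = 0
        for seed in range(50):
            data = synthetic.generate_threshold_dataset(500, 100.0, 0.7, 0.3,
                                                        seed=seed)
            scan = threshold_scan(data, np.arange(40, 201, 10))
            hits += scan["selected_cutoff"] == 100.0
        assert hits >= 45, hits

    def test_null_data_flagged_low_confidence(self):
        data = synthetic.generate_threshold_dataset(400, p_resp_low=0.5,
                                                    p_resp_high=0.5, seed=8)
        scan = threshold_scan(data, np.arange(40, 201, 20))
        assert scan["low_confidence"]

    def test_empty_stratum_candidates_skipped(self):
        data = synthetic.generate_threshold_dataset(200, seed=1)
        lo = data["sbcma0"].min()
        hi = data["sbcma0"].max()
        scan = threshold_scan(data, [lo / 2, 100.0, hi * 2])
        assert scan["profile"]["cutoff"].tolist() == [100.0]

    def test_needs_two_candidates(self):
        data = synthetic.generate_threshold_dataset(100, seed=1)
        with pytest.raises(ValueError):
            threshold_scan(data, [100.0])


# ---------------------------------------------------------------------------
# pipeline plumbing
# ---------------------------------------------------------------------------

class TestPipeline:
    CONFIG = {
        "seed": 5,
        "pool_size": 60,
        "n_vpops": 1,
        "vpop_size": 20,
        "target_regimens": ["two_step_priming_76qw"],
        "ga_opts": {"generations": 10, "population": 20},
        "experiments": ["threshold_scan"],
        "threshold_n": 300,
    }

    def test_smoke_and_artifacts(self, tmp_path):
        cfg = dict(self.CONFIG, outdir=str(tmp_path / "run"))
        results = run_pipeline(cfg)
        assert results["vpops"][0].size == 20
        out = tmp_path / "run"
        for name in ("vpop_membership.csv", "objectives.json",
                     "bias_check.csv", "threshold_profile.csv",
                     "manifest.json"):
            assert (out / name).exists(), name

    def test_rerun_byte_identical(self, tmp_path):
        cfg1 = dict(self.CONFIG, outdir=str(tmp_path / "a"))
        cfg2 = dict(self.CONFIG, outdir=str(tmp_path / "b"))
        run_pipeline(cfg1)
        run_pipeline(cfg2)
        for name in ("vpop_membership.csv", "threshold_profile.csv",
                     "bias_check.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_config_errors_listed_before_compute(self, tmp_path):
        bad = {"pool_size": 3, "target_regimens": ["nope"],
               "outdir": str(tmp_path)}
        with pytest.raises(ValueError) as err:
            run_pipeline(bad)
        msg = str(err.value)
        assert "seed" in msg and "pool_size" in msg and "nope" in msg
        assert not any(tmp_path.iterdir())


# ---------------------------------------------------------------------------
# CLI wiring
# ---------------------------------------------------------------------------

def test_cli_threshold_scan(tmp_path):
    from click.testing import CliRunner
    from bsabqsp.cli import main
    out = tmp_path / "profile.csv"
    result = CliRunner().invoke(
        main, ["threshold-scan", "--n", "300", "--seed", "2024",
               "--out", str(out)])
    assert result.exit_code == 0, result.output
    assert "selected cutoff" in result.output
    assert out.exists()
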