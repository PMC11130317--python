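import numpy as np
import pandas as pd
import pytest

from crosstrait import mr, simulate
from tests.conftest import make_table


def _hset(beta_exp, beta_out, se_exp=0.01, se_out=0.02, eaf=None):
    n = len(beta_exp)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(se_exp, (n,)).astype(float),
            "beta_out": beta_out,
            "se_out": np.broadcast_to(se_out, (n,)).astype(float),
            "eaf_exp": eaf if eaf is not None else np.full(n, np.nan),
            "eaf_out": np.nan,
        }
    )
    return mr.HarmonizedSet(df=df)


class TestSelectInstruments:
    def _exposure(self, rows):
        return make_table(rows, trait_label="exp")

    def test_single_strong_snp_retained(self):
        panel = simulate.simulate_ld_panel(2, 5, 0.5, seed=0)
        t = self._exposure([("rs1", 1, 1, "A", "C", 0.5, 0.07, 1e-9, 1e5)])
        assert mr.select_instruments(t, panel) == ["rs1"]

    def test_greedy_clump_keeps_best_p(self):
        panel = simulate.simulate_ld_panel(1, 5, 0.71, seed=0)  # r2 ~ 0.5 adjacent
        ids = list(panel.blocks[0].snp_ids[:2])
        pos = panel.blocks[0].positions
        t = self._exposure(
            [
                (ids[0], 1, int(pos[0]), "A", "C", 0.5, 0.07, 1e-9, 1e5),
                (ids[1], 1, int(pos[1]), "A", "C", 0.5, 0.08, 1e-8, 1e5),
            ]
        )
        assert mr.select_instruments(t, panel) == [ids[0]]

    def test_no_significant_snps_fatal(self):
        panel = simulate.simulate_ld_panel(1, 5, 0.5, seed=0)
        t = self._exposure([("rs1", 1, 1, "A", "C", 0.1, 0.05, 1e-4, 1e5)])
        with pytest.raises(mr.MrError, match="no valid instruments"):
            mr.select_instruments(t, panel)

    def test_weak_instrument_excluded(self):
        panel = simulate.simulate_ld_panel(1, 5, 0.5, seed=0)
        # p below threshold but F = (0.03/0.01)^2 = 9 < 10
        t = self._exposure([("rs1", 1, 1, "A", "C", 0.03, 0.01, 1e-9, 1e5)])
        with pytest.raises(mr.MrError):
            mr.select_instruments(t, panel)


class TestHarmonize:
    def test_swapped_alleles_negate_outcome(self):
        exp = make_table([("rs1", 1, 100, "A", "G", 0.5, 0.05, 1e-9, 1e5)])
        out = make_table([("rs1", 1, 100, "G", "A", 0.3, 0.05, 1e-5, 1e5)])
        h = mr.harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(-0.3)

    def test_palindromic_without_eaf_dropped(self):
        exp = make_table([("rs1", 1, 100, "A", "T", 0.5, 0.05, 1e-9, 1e5)])
        out = make_table([("rs1", 1, 100, "A", "T", 0.3, 0.05, 1e-5, 1e5)])
        with pytest.raises(mr.MrError):
            mr.harmonize(exp, out)

    def test_palindromic_with_informative_eafs_kept(self):
        exp = make_table([("rs1", 1, 100, "A", "T", 0.5, 0.05, 1e-9, 1e5, 0.2)])
        out = make_table([("rs1", 1, 100, "A", "T", 0.3, 0.05, 1e-5, 1e5, 0.25)])
        h = mr.harmonize(exp, out)
        assert len(h) == 1

    def test_palindromic_near_half_frequency_dropped(self):
        exp = make_table([("rs1", 1, 100, "A", "T", 0.5, 0.05, 1e-9, 1e5, 0.5)])
        out = make_table([("rs1", 1, 100, "A", "T", 0.3, 0.05, 1e-5, 1e5, 0.5)])
        with pytest.raises(mr.MrError):
            mr.harmonize(exp, out)

    def test_identity_unchanged_and_audited(self):
        exp = make_table(
            [
                ("rs1", 1, 100, "A", "G", 0.5, 0.05, 1e-9, 1e5),
                ("rs2", 1, 200, "C", "A", 0.4, 0.05, 1e-9, 1e5),
            ]
        )
        h = mr.harmonize(exp, exp)
        assert len(h) == 2
        assert h.dropped == []
        assert np.allclose(h.df["beta_out"], h.df["beta_exp"])


class TestIvw:
    def test_exact_ratio(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = _hset(bx, 0.5 * bx)
        e = mr.ivw(h)
        assert e.theta == pytest.approx(0.5, abs=1e-12)
        assert e.or_ == pytest.approx(np.exp(0.5))

    def test_matches_matrix_algebra_oracle(self):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.1, 0.05, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        se_out = rng.uniform(0.01, 0.05, 10)
        h = _hset(bx, by, se_out=se_out)
        # oracle: weighted through-origin regression via lstsq on scaled data
        sw = 1.0 / se_out
        theta_oracle = np.linalg.lstsq(
            (bx * sw)[:, None], by * sw, rcond=None
        )[0][0]
        assert mr.ivw(h).theta == pytest.approx(theta_oracle, abs=1e-10)

    def test_or_ci_transform_exact(self):
        h = _hset(np.array([0.1, 0.2, 0.3]), np.array([0.05, 0.11, 0.14]))
        e = mr.ivw(h)
        assert e.ci_low == np.exp(e.theta - 1.96 * e.se)
        assert e.ci_high == np.exp(e.theta + 1.96 * e.se)

    def test_too_few_instruments(self):
        with pytest.raises(mr.MrError):
            mr.ivw(_hset(np.array([0.1]), np.array([0.05])))

    def test_null_coverage(self):
        cover = 0
        n_seeds = 100
        for s in range(n_seeds):
            cfg = simulate.MrSimConfig(n_inst=30, theta=0.0, seed=s)
            e = mr.ivw(simulate.simulate_mr_instruments(cfg))
            cover += e.ci_low <= 1.0 <= e.ci_high
        assert 0.90 * n_seeds <= cover <= 0.995 * n_seeds


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = _hset(bx, 0.1 + 0.3 * bx)
        e, pt = mr.mr_egger(h)
        assert e.theta == pytest.approx(0.3, abs=1e-10)
        assert pt.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_type_one_error_no_pleiotropy(self):
        rej = 0
        n_seeds = 100
        for s in range(n_seeds):
            cfg = simulate.MrSimConfig(n_inst=30, theta=0.2, seed=s)
            _, pt = mr.mr_egger(simulate.simulate_mr_instruments(cfg))
            rej += pt.p < 0.05
        assert rej <= 0.12 * n_seeds

    def test_power_under_directional_pleiotropy(self):
        rej = 0
        n_seeds = 40
        for s in range(n_seeds):
            cfg = simulate.MrSimConfig(
                n_inst=30, theta=0.2, pleiotropy_mode="directional",
                pleiotropy_sd=0.05, seed=s,
            )
            _, pt = mr.mr_egger(simulate.simulate_mr_instruments(cfg))
            rej += pt.p < 0.05
        assert rej > 0.5 * n_seeds

    def test_too_few_instruments(self):
        with pytest.raises(mr.MrError):
            mr.mr_egger(_hset(np.array([0.1, 0.2]), np.array([0.05, 0.1])))


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        e = mr.weighted_median(_hset(bx, by, se_exp=0.0, se_out=0.02), n_boot=10, seed=0)
        assert e.theta == pytest.approx(0.2)

    def test_robust_to_forty_percent_invalid(self):
        cfg = simulate.MrSimConfig(n_inst=20, theta=0.3, se_out=0.005, seed=1)
        h = simulate.simulate_mr_instruments(cfg)
        h.df.loc[:7, "beta_out"] += 0.5  # 8/20 grossly invalid
        e = mr.weighted_median(h, seed=2)
        assert e.theta == pytest.approx(0.3, abs=0.1)

    def test_bootstrap_se_deterministic(self):
        cfg = simulate.MrSimConfig(n_inst=15, theta=0.2, seed=3)
        h = simulate.simulate_mr_instruments(cfg)
        a = mr.weighted_median(h, seed=7)
        b = mr.weighted_median(h, seed=7)
        assert a.se == b.se


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        q = mr.cochran_q(_hset(bx, 0.4 * bx), 0.4)
        assert q.Q == pytest.approx(0.0, abs=1e-20)
        assert q.p == pytest.approx(1.0)
        assert q.df == 2

    def test_homogeneous_calibration(self):
        from scipy import stats

        # small se_exp: the regime where the first-order ratio SE is exact
        ps = []
        for s in range(200):
            cfg = simulate.MrSimConfig(n_inst=25, theta=0.2, se_exp=0.001, seed=s)
            h = simulate.simulate_mr_instruments(cfg)
            ps.append(mr.cochran_q(h, mr.ivw(h).theta).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_outlier_detected(self):
        hits = 0
        for s in range(20):
            cfg = simulate.MrSimConfig(
                n_inst=25, theta=0.2, n_outliers=1, outlier_shift=0.4,
                se_exp=0.001, seed=s,
            )
            h = simulate.simulate_mr_instruments(cfg)
            hits += mr.cochran_q(h, mr.ivw(h).theta).p < 0.05
        assert hits >= 18


class TestLeaveOneOut:
    def test_count(self):
        cfg = simulate.MrSimConfig(n_inst=3, theta=0.2, seed=0)
        h = simulate.simulate_mr_instruments(cfg)
        assert len(mr.leave_one_out(h)) == 3

    def test_homogeneous_estimates_stable(self):
        cfg = simulate.MrSimConfig(n_inst=25, theta=0.2, seed=4)
        h = simulate.simulate_mr_instruments(cfg)
        full = mr.ivw(h)
        for _, e in mr.leave_one_out(h):
            assert abs(e.theta - full.theta) < full.se

    def test_single_outlier_shifts_one_estimate(self):
        cfg = simulate.MrSimConfig(
            n_inst=25, theta=0.2, n_outliers=1, outlier_shift=0.4, seed=5
        )
        h = simulate.simulate_mr_instruments(cfg)
        full = mr.ivw(h)
        shifts = np.array(
            [abs(e.theta - full.theta) for _, e in mr.leave_one_out(h)]
        )
        assert np.argmax(shifts) == 0  # outlier is instrument 0
        assert shifts[0] > 3 * np.median(shifts[1:])


class TestPresso:
    def test_determinism(self):
        cfg = simulate.MrSimConfig(n_inst=20, theta=0.2, seed=6)
        h = simulate.simulate_mr_instruments(cfg)
        a = mr.mr_presso(h, n_sim=200, seed=9)
        b = mr.mr_presso(h, n_sim=200, seed=9)
        assert a.global_p == b.global_p

    def test_calibration_no_pleiotropy(self):
        ok = 0
        n_seeds = 30
        for s in range(n_seeds):
            cfg = simulate.MrSimConfig(n_inst=25, theta=0.2, seed=s)
            pr = mr.mr_presso(simulate.simulate_mr_instruments(cfg), n_sim=500, seed=s)
            ok += (pr.global_p > 0.05) and (pr.corrected is None)
        assert ok >= 0.85 * n_seeds

    def test_outlier_flagged_and_corrected_exact(self):
        flagged = 0
        n_seeds = 20
        for s in range(n_seeds):
            cfg = simulate.MrSimConfig(
                n_inst=25, theta=0.2, n_outliers=1, outlier_shift=0.3, seed=s
            )
            h = simulate.simulate_mr_instruments(cfg)
            pr = mr.mr_presso(h, n_sim=500, seed=s)
            if 0 in pr.outlier_indices:
                flagged += 1
                keep = [i for i in range(25) if i not in pr.outlier_indices]
                sub = mr.HarmonizedSet(df=h.df.iloc[keep].reset_index(drop=True))
                assert pr.corrected.theta == mr.ivw(sub).theta
                assert pr.distortion_p is not None
        assert flagged >= 0.9 * n_seeds

    def test_too_few_instruments(self):
        with pytest.raises(mr.MrError, match="PRESSO"):
            mr.mr_presso(_hset(np.array([0.1, 0.2, 0.3]), np.array([0.05, 0.1, 0.15])))


class TestMvmr:
    def _tables(self, seed=0, beta2_scale=0.0):
        rng = np.random.default_rng(seed)
        n = 30
        rows1, rows2, rows_out = [], [], []
        for i in range(n):
            bx1 = rng.normal(0.2, 0.05) * rng.choice([-1, 1])
            bx2 = beta2_scale * rng.normal(0.2, 0.05)
            by = 0.4 * bx1 + 0.2 * bx2 + rng.normal(0, 0.005)
            pos = 20_000_000 * (i + 1)
            se = 0.01
            rows1.append((f"rs{i}", 1, pos, "A", "C", bx1, se, 1e-60, 1e5))
            rows2.append((f"rs{i}", 1, pos, "A", "C", bx2 + rng.normal(0, 0.002), se, 1e-60, 1e5))
            rows_out.append((f"rs{i}", 1, pos, "A", "C", by, se, 0.5, 1e5))
        return (
            make_table(rows1, "exp1"),
            make_table(rows2, "exp2"),
            make_table(rows_out, "outcome"),
        )

    def test_null_covariate_matches_univariable_ivw(self):
        e1, e2, out = self._tables(seed=1, beta2_scale=0.0)
        ests = mr.mvmr([e1, e2], out, panel=None)
        h = mr.harmonize(e1, out, list(e1.df["snp_id"]))
        uni = mr.ivw(h)
        assert ests[0].theta == pytest.approx(uni.theta, abs=0.02)

    def test_conditional_effect_recovered(self):
        e1, e2, out = self._tables(seed=2, beta2_scale=1.0)
        ests = mr.mvmr([e1, e2], out, panel=None)
        assert ests[0].theta == pytest.approx(0.4, abs=0.05)
        assert ests[1].theta == pytest.approx(0.2, abs=0.05)

    def test_collinear_exposures_fatal(self):
        e1, _, out = self._tables(seed=3)
        import copy

        e1b = copy.deepcopy(e1)
        e1b.trait_label = "exp1-copy"
        with pytest.raises(mr.MrError, match="collinear|rank"):
            mr.mvmr([e1, e1b], out, panel=None)

    def test_needs_two_exposures(self):
        e1, _, out = self._tables()
        with pytest.raises(mr.MrError):
            mr.mvmr([e1], out, panel=None)


class TestBidirectional:
    def test_one_way_causality_detected(self):
        panel = simulate.simulate_ld_panel(60, 20, 0.3, seed=5)
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            ta, tb = simulate.simulate_mr_sumstats(panel, theta_forward=0.1, seed=s)
            rep = mr.run_bidirectional(ta, tb, panel, seed=s)
            fwd = rep["forward"].get("ivw")
            rev = rep["reverse"].get("ivw")
            if fwd and rev and fwd.p < 0.05 / 6 and rev.p > 0.05:
                hits += 1
        assert hits >= 9

    def test_threshold_six_traits(self):
        panel = simulate.simulate_ld_panel(40, 10, 0.3, seed=5)
        ta, tb = simulate.simulate_mr_sumstats(
            panel, theta_forward=0.1, n_inst_a=15, n_inst_b=15, seed=0
        )
        rep = mr.run_bidirectional(ta, tb, panel, n_traits_tested=6)
        assert rep["threshold"] == pytest.approx(8.33e-3, rel=5e-3)

    def test_failed_direction_reported_not_fatal(self):
        panel = simulate.simulate_ld_panel(40, 10, 0.3, seed=5)
        ta, tb = simulate.simulate_mr_sumstats(
            panel, theta_forward=0.1, n_inst_a=15, n_inst_b=15, seed=0
        )
        # cripple trait B so the reverse direction has no instruments
        tb.df["p"] = 0.5
        rep = mr.run_bidirectional(ta, tb, panel)
        assert "error" in rep["reverse"]
        assert "ivw" in rep["forward"]
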