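"""Mendelian randomisation estimators, diagnostics and invariances."""

import numpy as np
import pandas as pd
import pytest

from gwsub import (MRInstrumentSet, SyntheticTruth, bidirectional_run,
                   diagnostics, egger, ivw, select_instruments,
                   simulate_factor_sumstats, weighted_median)
from gwsub.mr import (IVWEstimator, WeightedMedianEstimator, cochran_q,
                      weighted_median_point)


def make_instruments(rng, n=30, theta=0.1, pleio_mean=0.0, pleio_sd=0.0,
                     se_x=0.004, se_y=0.01, invalid_frac=0.0,
                     invalid_shift=0.0, signed=True):
    """Instrument sets with a planted causal effect and optional pleiotropy.

    ``signed=False`` orients every exposure effect positive, the frame in
    which directional pleiotropy is defined.
    """
    bx_true = rng.uniform(0.03, 0.10, n)
    if signed:
        bx_true = bx_true * rng.choice([-1, 1], n)
    alpha = pleio_mean + pleio_sd * rng.standard_normal(n)
    n_bad = int(invalid_frac * n)
    alpha[:n_bad] += invalid_shift
    bx = bx_true + se_x * rng.standard_normal(n)
    by = theta * bx_true + alpha + se_y * rng.standard_normal(n)
    table = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "beta_exposure": bx, "se_exposure": np.full(n, se_x),
        "beta_outcome": by, "se_outcome": np.full(n, se_y),
        "eaf": rng.uniform(0.1, 0.9, n),
    })
    return MRInstrumentSet(table=table)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        inst = make_instruments(np.random.default_rng(0), n=5)
        one = MRInstrumentSet(table=inst.table.head(1))
        est = ivw(one)
        row = inst.table.iloc[0]
        assert est.beta == pytest.approx(
            row["beta_outcome"] / row["beta_exposure"], rel=1e-12)

    def test_replicated_ratio_recovered_exactly(self):
        bx = np.array([0.05, 0.08, 0.02])
        table = pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3"], "beta_exposure": bx,
            "se_exposure": 0.01, "beta_outcome": 0.3 * bx,
            "se_outcome": 0.01, "eaf": 0.5})
        est = ivw(MRInstrumentSet(table=table))
        assert est.beta == pytest.approx(0.3, rel=1e-12)

    def test_matches_weighted_least_squares_oracle(self):
        import statsmodels.api as sm

        inst = make_instruments(np.random.default_rng(1), n=40,
                                pleio_sd=0.005)
        est = ivw(inst, fixed_effects=True)
        bx, sx, by, sy = inst.arrays()
        fit = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_never_shrinks_se(self):
        inst = make_instruments(np.random.default_rng(2), n=25,
                                pleio_sd=0.02)
        assert ivw(inst).se >= ivw(inst, fixed_effects=True).se

    def test_planted_effect_recovered_over_seeds(self):
        # the estimator battery run at the scale of a weak causal effect
        estimates = [
            ivw(make_instruments(np.random.default_rng(1000 + k), n=40,
                                 theta=0.05, pleio_sd=0.01)).beta
            for k in range(200)
        ]
        mc_se = np.std(estimates) / np.sqrt(200)
        assert np.mean(estimates) == pytest.approx(0.05, abs=3 * mc_se)


class TestEgger:
    def test_directional_pleiotropy_recovered_in_expectation(self):
        intercepts = []
        for k in range(200):
            rng = np.random.default_rng(2000 + k)
            inst = make_instruments(rng, n=40, theta=0.1, pleio_mean=0.01,
                                    pleio_sd=0.005, signed=False)
            _, icept = egger(inst)
            intercepts.append(icept.beta)
        mc_se = np.std(intercepts) / np.sqrt(200)
        assert np.mean(intercepts) == pytest.approx(0.01, abs=3 * mc_se)

    def test_balanced_pleiotropy_intercept_calibrated(self):
        covered = 0
        for k in range(100):
            rng = np.random.default_rng(3000 + k)
            inst = make_instruments(rng, n=30, pleio_sd=0.01)
            _, icept = egger(inst)
            covered += abs(icept.beta) < 2 * icept.se
        assert covered >= 85

    def test_agrees_with_ivw_without_pleiotropy(self):
        inst = make_instruments(np.random.default_rng(4), n=50, theta=0.08)
        slope, _ = egger(inst)
        prim = ivw(inst)
        assert slope.beta == pytest.approx(
            prim.beta, abs=2 * np.hypot(slope.se, prim.se))

    def test_degenerate_exposure_spread_raises(self):
        table = pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3"], "beta_exposure": [0.05] * 3,
            "se_exposure": 0.01, "beta_outcome": [0.01, 0.02, 0.03],
            "se_outcome": 0.01, "eaf": 0.5})
        with pytest.raises(ValueError, match="spread"):
            egger(MRInstrumentSet(table=table))


class TestWeightedMedian:
    def test_equal_weights_odd_n_is_ordinary_median(self):
        by = np.array([0.01, 0.05, 0.03, 0.09, 0.02])
        table = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(5)],
            "beta_exposure": 1.0, "se_exposure": 1e-8,
            "beta_outcome": by, "se_outcome": 0.01, "eaf": 0.5})
        est = weighted_median(MRInstrumentSet(table=table), n_boot=10)
        assert est.beta == pytest.approx(np.median(by), rel=1e-9)

    def test_matches_bruteforce_quantile_scan(self):
        # independent oracle on <= 15 instruments: scalar-loop scan of the
        # centered weighted CDF with hand interpolation
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 16))
            ratios = rng.normal(0, 1, n)
            weights = rng.uniform(0.1, 5.0, n)
            est = weighted_median_point(ratios, weights)
            order = np.argsort(ratios)
            r = ratios[order]
            w = weights[order]
            total = w.sum()
            cdf = [(w[:k].sum() + w[k] / 2.0) / total for k in range(n)]
            if 0.5 <= cdf[0]:
                brute = r[0]
            elif 0.5 >= cdf[-1]:
                brute = r[-1]
            else:
                for k in range(n - 1):
                    if cdf[k] <= 0.5 <= cdf[k + 1]:
                        frac = (0.5 - cdf[k]) / (cdf[k + 1] - cdf[k])
                        brute = r[k] + frac * (r[k + 1] - r[k])
                        break
            assert est == pytest.approx(brute, abs=1e-12)
            # the estimate always lies between the bracketing ratios
            assert r.min() <= est <= r.max()

    def test_breakdown_robustness_against_invalid_instruments(self):
        # 60% valid instruments, 40% with shifted effects: the median stays
        # near the truth while IVW is pulled away
        rng = np.random.default_rng(8)
        inst = make_instruments(rng, n=40, theta=0.1, invalid_frac=0.4,
                                invalid_shift=0.012, se_y=0.002,
                                signed=False)
        wm = weighted_median(inst, random_state=0)
        prim = ivw(inst)
        assert wm.beta == pytest.approx(0.1, abs=2.5 * wm.se)
        assert abs(prim.beta - 0.1) > 2 * prim.se
        assert abs(prim.beta - 0.1) > abs(wm.beta - 0.1)

    def test_bootstrap_se_tracks_sampling_variability(self):
        betas, boot_ses = [], []
        for k in range(200):
            rng = np.random.default_rng(5000 + k)
            inst = make_instruments(rng, n=25, theta=0.1, pleio_sd=0.004)
            est = WeightedMedianEstimator(n_boot=200,
                                          random_state=k).fit(inst)
            betas.append(est.beta_)
            boot_ses.append(est.se_)
        assert np.mean(boot_ses) == pytest.approx(np.std(betas), rel=0.25)

    def test_penalized_variant_reduces_bias_from_heavy_outliers(self):
        # ~47% of the weight sits on pleiotropic instruments with grossly
        # shifted ratios: the penalty pushes their weight down, so the
        # penalized median is markedly less biased than the plain one
        plain_err, pen_err = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n, n_bad = 30, 9
            bx = rng.uniform(0.03, 0.1, n)
            sy = np.full(n, 0.01)
            sy[:n_bad] = 0.007  # invalid instruments are more precise
            by = 0.1 * bx + sy * rng.standard_normal(n)
            by[:n_bad] += 0.1
            table = pd.DataFrame({
                "snp": [f"rs{i}" for i in range(n)], "beta_exposure": bx,
                "se_exposure": 0.002, "beta_outcome": by, "se_outcome": sy,
                "eaf": 0.5})
            inst = MRInstrumentSet(table=table)
            plain = WeightedMedianEstimator(n_boot=10,
                                            random_state=seed).fit(inst)
            pen = WeightedMedianEstimator(penalized=True, n_boot=10,
                                          random_state=seed).fit(inst)
            plain_err.append(abs(plain.beta_ - 0.1))
            pen_err.append(abs(pen.beta_ - 0.1))
        assert np.mean(pen_err) < 0.6 * np.mean(plain_err)


class TestDiagnostics:
    def test_q_decomposes_into_contributions(self):
        inst = make_instruments(np.random.default_rng(10), n=30,
                                pleio_sd=0.01)
        est = ivw(inst)
        q, contrib = cochran_q(inst, est.beta)
        assert q == pytest.approx(contrib.sum(), abs=1e-10)
        d = diagnostics(inst, est)
        assert d.q_df == len(inst) - 1
        assert d.cochran_q == pytest.approx(q)

    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.05, 0.08, 0.02])
        table = pd.DataFrame({
            "snp": ["a", "b", "c"], "beta_exposure": bx,
            "se_exposure": 0.01, "beta_outcome": 0.2 * bx,
            "se_outcome": 0.01, "eaf": 0.5})
        inst = MRInstrumentSet(table=table)
        d = diagnostics(inst)
        assert d.cochran_q == pytest.approx(0.0, abs=1e-20)
        assert d.q_p == pytest.approx(1.0)

    def test_instrument_strength_statistics(self):
        # uniform beta/se of 6.07 -> F ~= 36.8, inside the strong-instrument
        # range, with the corresponding attenuation index
        n = 10
        table = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(n)],
            "beta_exposure": 6.07 * 0.01, "se_exposure": 0.01,
            "beta_outcome": np.linspace(0.01, 0.02, n),
            "se_outcome": 0.01, "eaf": 0.5})
        with pytest.raises(ValueError):
            egger(MRInstrumentSet(table=table))  # no exposure spread
        bx = 6.07 * 0.01 * (1 + 0.001 * np.arange(n))
        table["beta_exposure"] = bx
        d = diagnostics(MRInstrumentSet(table=table))
        expected_f = np.mean(bx ** 2 / 0.01 ** 2)  # ~= 6.07^2 ~= 36.9
        assert d.mean_f == pytest.approx(expected_f, rel=1e-12)
        assert 36.54 <= d.mean_f <= 49.22
        assert 0.97 <= d.i2_gx <= 0.98

    def test_leave_one_out_flags_planted_outlier(self):
        rng = np.random.default_rng(12)
        inst = make_instruments(rng, n=25, theta=0.1, se_y=0.002)
        tab = inst.table.copy()
        tab.loc[3, "beta_outcome"] += 0.08
        spiked = MRInstrumentSet(table=tab)
        full = ivw(spiked)
        d = diagnostics(spiked, full)
        shift = np.abs(d.loo_table["beta"] - full.beta) / d.loo_table["se"]
        flagged = d.loo_table.loc[shift > 2, "snp_left_out"]
        assert list(flagged) == ["rs4"]


class TestInvariances:
    def test_reorienting_instrument_alleles_changes_nothing(self):
        inst = make_instruments(np.random.default_rng(13), n=20,
                                pleio_sd=0.005)
        tab = inst.table.copy()
        flip = np.zeros(20, dtype=bool)
        flip[::3] = True
        tab.loc[flip, "beta_exposure"] *= -1
        tab.loc[flip, "beta_outcome"] *= -1
        flipped = MRInstrumentSet(table=tab)
        assert ivw(flipped).beta == pytest.approx(ivw(inst).beta, rel=1e-12)
        assert egger(flipped)[0].beta == pytest.approx(egger(inst)[0].beta,
                                                       rel=1e-12)
        assert weighted_median(flipped, random_state=3).beta == \
            pytest.approx(weighted_median(inst, random_state=3).beta,
                          rel=1e-9)


@pytest.fixture(scope="module")
def mr_sim():
    return simulate_factor_sumstats(SyntheticTruth(seed=3))


class TestSelectionAndPipeline:
    def test_no_hits_raises(self, mr_sim):
        with pytest.raises(ValueError, match="instruments"):
            select_instruments(mr_sim.sumstats["ea"], mr_sim.sumstats["iq"],
                               mr_sim.ld, p_threshold=1e-300)

    def test_instrument_count_matches_clumping(self, mr_sim):
        from gwsub import clump_hits

        exp = mr_sim.sumstats["bd"]
        inst = select_instruments(exp, mr_sim.sumstats["ea"], mr_sim.ld)
        n_clumped = len(clump_hits(exp, mr_sim.ld, p_threshold=5e-8,
                                   r2_threshold=0.001, window_kb=10_000))
        assert len(inst) == n_clumped
        assert (inst.table["snp"].isin(set(exp["snp"]))).all()

    def test_bidirectional_report_structure(self, mr_sim):
        rep = bidirectional_run(mr_sim.sumstats["bd"], mr_sim.sumstats["ea"],
                                mr_sim.ld, labels=("bd", "ea"),
                                binary=(True, False))
        fwd = rep["bd_on_ea"]
        assert fwd.error is None
        methods = {e.method for e in fwd.estimates}
        assert methods == {"IVW", "Egger-slope", "Egger-intercept",
                           "weighted-median", "penalized-weighted-median"}
        back = rep["ea_on_bd"]
        frame = back.estimates_frame()
        assert {"or", "ci_low", "ci_high"} <= set(frame.columns)

    def test_identical_traits_flagged_degenerate(self, mr_sim):
        rep = bidirectional_run(mr_sim.sumstats["bd"], mr_sim.sumstats["bd"],
                                mr_sim.ld, labels=("a", "b"))
        res = rep["a_on_b"]
        assert res.error is None
        assert res.estimates[0].beta == pytest.approx(1.0, abs=1e-9)
        assert any("degenerate" in f for f in res.flags)
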