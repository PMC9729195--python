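"""Statistics and fitting tests: R², information criteria, Fisher test,
multistart fits, anchoring, bootstrap, dilution γ-refit."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from nexis.datatypes import NexisParams, PathologyData
from nexis.estimators import NDM, NexisGlobal, NexisMicroglia
from nexis.inference import (
    bootstrap, fisher_compare, fit_gamma_only, fit_global, fit_microglia,
    information_criteria, objective, per_timepoint_r, pooled_pearson_r, pooled_r2,
)
from nexis.synthetic import SyntheticSpec, make_dataset


def patho(values, times=(4.0, 8.0, 12.0), seed="r1"):
    values = np.atleast_2d(np.asarray(values, float))
    labels = tuple(f"r{i+1}" for i in range(values.shape[0]))
    return PathologyData(values, np.asarray(times, float)[: values.shape[1]],
                         labels, (seed,))


class TestPooledR2:
    def test_perfect_prediction(self):
        obs = patho([[1, 2, 3], [4, 5, 6]])
        assert pooled_r2(obs.values, obs) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        obs = patho([[1, 2, 3], [4, 5, 6]])
        pred = np.full((2, 3), obs.values.mean())
        assert pooled_r2(pred, obs) == pytest.approx(0.0)

    def test_hand_computed_ratio(self):
        # obs (1,2,3,4) vs pred (1,2,3,5): SS_res=1, SS_tot=5 -> R²=0.8
        obs = patho([[1.0, 2.0], [3.0, 4.0]], times=(4.0, 8.0))
        pred = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert pooled_r2(pred, obs) == pytest.approx(0.8)

    def test_pooled_not_per_timepoint(self):
        # per-timepoint correlation is perfect but scale is wrong:
        # pooled R² must punish it
        obs = patho([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]], times=(4.0, 8.0))
        pred = obs.values * 5
        assert pooled_r2(pred, obs) < 0
        assert per_timepoint_r(pred, obs, 4.0) == pytest.approx(1.0)

    def test_missing_entries_excluded(self):
        vals = np.array([[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0]])
        obs = PathologyData(vals, [4.0, 8.0], ("r1", "r2", "r3"), ("r1",))
        pred = np.array([[1.0, 2.0], [999.0, 4.0], [5.0, 6.0]])
        assert pooled_r2(pred, obs) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        obs = patho([[2.0, 2.0], [2.0, 2.0]], times=(4.0, 8.0))
        with pytest.raises(ValueError):
            pooled_r2(obs.values, obs)

    def test_single_timepoint_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        y = rng.random(12)
        x = y + rng.normal(0, 0.05, 12)
        obs = PathologyData(y[:, None], [4.0],
                            tuple(f"r{i}" for i in range(12)), ("r0",))
        # zero-mean-error linear predictions: R² equals r² at one timepoint
        slope = np.polyfit(x, y, 1)
        pred = (slope[0] * x + slope[1])[:, None]
        r = per_timepoint_r(pred, obs, 4.0)
        assert pooled_r2(pred, obs) == pytest.approx(r ** 2, abs=1e-10)


class TestPerTimepointR:
    def test_identical(self):
        obs = patho([[1, 2], [3, 4], [5, 7]], times=(4.0, 8.0))
        assert per_timepoint_r(obs.values, obs, 8.0) == pytest.approx(1.0)

    def test_anti_ordered(self):
        obs = patho([[1, 1], [2, 2], [3, 3]], times=(4.0, 8.0))
        pred = np.array([[3, 3], [2, 2], [1, 1.0]])
        assert per_timepoint_r(pred, obs, 4.0) == pytest.approx(-1.0)

    def test_brute_force_formula(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 7.0])
        expected = (np.sum((x - x.mean()) * (y - y.mean())) /
                    np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        obs = patho(y[:, None].repeat(2, 1), times=(4.0, 8.0))
        assert per_timepoint_r(x[:, None].repeat(2, 1), obs, 4.0) == pytest.approx(expected)

    def test_zero_variance_flagged_missing(self):
        obs = patho([[1, 1], [2, 2], [3, 3]], times=(4.0, 8.0))
        assert np.isnan(per_timepoint_r(np.ones((3, 2)), obs, 4.0))


class TestObjective:
    def test_truth_on_noiseless_data_is_zero(self, clean_dataset):
        ds = clean_dataset
        assert objective(ds.params, ds.connectome, ds.gene, ds.data) < 1e-16

    def test_equals_sstot_times_one_minus_r2(self, desk_dataset):
        ds = desk_dataset
        params = NexisParams(gamma=2.0, alpha=0.2, beta=1.0, p=-0.2, b=1.0)
        sse = objective(params, ds.connectome, ds.gene, ds.data)
        obs = ds.data.values[ds.data.quantified_mask]
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        from nexis.model import simulate
        traj = simulate(ds.connectome, ds.gene, params, ds.data.seed_regions,
                        ds.data.times)
        assert sse == pytest.approx(ss_tot * (1 - pooled_r2(traj, ds.data)))

    def test_worse_params_higher_loss(self, clean_dataset):
        ds = clean_dataset
        off = replace(ds.params, gamma=ds.params.gamma * 1.5)
        assert objective(off, ds.connectome, ds.gene, ds.data) > \
            objective(ds.params, ds.connectome, ds.gene, ds.data)

    def test_overflow_maps_to_inf(self, clean_dataset):
        ds = clean_dataset
        data_late = PathologyData(ds.data.values, [400.0, 800.0, 1200.0],
                                  ds.data.region_ids, ds.data.seed_regions)
        wild = replace(ds.params, alpha=5.0)
        assert objective(wild, ds.connectome, ds.gene, data_late) == np.inf


class TestInformationCriteria:
    def test_penalty_monotone_in_k(self):
        a2, b2 = information_criteria(10.0, 100, 2)
        a5, b5 = information_criteria(10.0, 100, 5)
        assert a5 > a2 and b5 > b2

    def test_bic_penalty_exceeds_aic_for_n_at_least_8(self):
        for n in (8, 20, 100):
            aic, bic = information_criteria(3.0, n, 3)
            assert bic > aic  # ln n > 2

    def test_direct_formula(self):
        aic, bic = information_criteria(10.0, 100, 3)
        base = 100 * np.log(10.0 / 100)
        assert aic == pytest.approx(base + 6)
        assert bic == pytest.approx(base + 3 * np.log(100))

    def test_zero_sse_flagged(self):
        aic, bic = information_criteria(0.0, 50, 2)
        assert aic == -np.inf and bic == -np.inf


class TestFisherCompare:
    def test_identical_samples(self):
        r = np.array([0.5, 0.6, 0.7, 0.4])
        t, p = fisher_compare(r, r)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_transform_identities(self):
        assert np.arctanh(0.0) == 0.0
        assert np.arctanh(0.5) == pytest.approx(0.5 * np.log(3.0))

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        a = np.tanh(rng.normal(1.0, 0.05, 50))
        b = np.tanh(rng.normal(0.5, 0.05, 50))
        t, p = fisher_compare(a, b)
        assert t > 10 and p < 1e-10

    def test_unit_correlations_clipped(self):
        t, p = fisher_compare([1.0, 0.9, 0.8], [0.5, 0.4, 0.6])
        assert np.isfinite(t) and 0 <= p <= 1


class TestFitGlobal:
    def test_noiseless_recovery(self):
        truth = NexisParams(gamma=2.48, alpha=0.25, beta=1.30, variant="global")
        ds = make_dataset(SyntheticSpec(rng_seed=8, noise_sd=0.0,
                                        quantified_frac=1.0, n_regions_per_hemi=10,
                                        true_params=truth))
        res = fit_global(ds.connectome, ds.data, rng_seed=1, n_boot=0)
        for k in ("gamma", "alpha", "beta"):
            assert getattr(res.point, k) == pytest.approx(getattr(truth, k), rel=0.01)
        assert res.r2 >= 0.999

    def test_ndm_variant_contract(self, desk_dataset):
        ds = desk_dataset
        res = fit_global(ds.connectome, ds.data, variant="NDM", rng_seed=1, n_boot=0)
        assert res.point.variant == "NDM"
        assert res.point.alpha == 0.0 and res.point.p == 0.0 and res.point.b == 0.0
        assert res.k_params == 2

    def test_deterministic(self, desk_dataset):
        ds = desk_dataset
        a = fit_global(ds.connectome, ds.data, rng_seed=7, n_boot=5)
        b = fit_global(ds.connectome, ds.data, rng_seed=7, n_boot=5)
        assert a.point == b.point
        pd.testing.assert_frame_equal(a.boot, b.boot)


class TestFitMicroglia:
    def test_noiseless_five_param_recovery(self, clean_dataset):
        ds = clean_dataset
        res = fit_microglia(ds.connectome, ds.gene, ds.data, None,
                            rng_seed=2, anchor=False, n_boot=0)
        for k in ("gamma", "alpha", "beta", "p", "b"):
            assert getattr(res.point, k) == pytest.approx(
                getattr(ds.params, k), rel=0.02), k
        assert res.r2 >= 0.999

    def test_anchor_requires_bootstrap_cis(self, desk_dataset):
        ds = desk_dataset
        glob = fit_global(ds.connectome, ds.data, rng_seed=1, n_boot=0)
        with pytest.raises(ValueError, match="bootstrap"):
            fit_microglia(ds.connectome, ds.gene, ds.data, glob, rng_seed=1)

    def test_anchored_within_global_ci(self, desk_dataset):
        ds = desk_dataset
        glob = fit_global(ds.connectome, ds.data, rng_seed=1, n_boot=20)
        res = fit_microglia(ds.connectome, ds.gene, ds.data, glob,
                            rng_seed=1, n_boot=0)
        for k in ("gamma", "alpha", "beta"):
            lo, hi = glob.ci95[k]
            val = getattr(res.point, k)
            assert lo - 1e-6 <= val <= hi + 1e-6
        assert res.k_params == 5

    def test_zero_modulator_collapses_to_global(self, clean_dataset):
        from nexis.datatypes import GeneVector

        ds = clean_dataset
        zero_u = GeneVector(np.zeros(ds.connectome.n), name="null", normalized=True)
        res = fit_microglia(ds.connectome, zero_u, ds.data, None,
                            rng_seed=3, anchor=False, n_boot=0)
        assert any("unidentifiable" in n for n in res.notes)
        # with u = 0, p and b drop out of the dynamics: the fit is exactly the
        # global model's fit of the same (gene-generated, hence misspecified) data
        glob = fit_global(ds.connectome, ds.data, rng_seed=3, n_boot=0)
        assert res.r2 == pytest.approx(glob.r2, abs=1e-6)
        assert res.point.gamma == pytest.approx(glob.point.gamma, rel=1e-3)
        assert res.point.alpha == pytest.approx(glob.point.alpha, abs=1e-3)
        assert res.point.beta == pytest.approx(glob.point.beta, rel=1e-2)

    def test_unnormalized_gene_rejected(self, desk_dataset):
        from nexis.datatypes import GeneVector

        ds = desk_dataset
        raw = GeneVector(ds.gene.values * 7.0, name="raw", normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            fit_microglia(ds.connectome, raw, ds.data, None,
                          rng_seed=0, anchor=False, n_boot=0)


class TestBootstrap:
    def test_full_fraction_degenerate_resample(self, desk_dataset):
        ds = desk_dataset
        est = NexisGlobal(ds.connectome, random_state=0).fit(ds.data)
        res = est.fit_bootstrap(ds.data, n_boot=3, frac=1.0, random_state=0)
        assert len(res.boot) == 3
        for col in ("gamma", "alpha", "beta", "r2"):
            assert res.boot[col].nunique() == 1

    def test_full_r2_within_bootstrap_range(self, desk_dataset):
        ds = desk_dataset
        res = fit_global(ds.connectome, ds.data, rng_seed=4, n_boot=30)
        assert res.boot.r2.min() <= res.r2 <= res.boot.r2.max()

    def test_ci_width_shrinks_with_noise(self):
        widths = {}
        for sd in (0.2, 0.1):
            ds = make_dataset(SyntheticSpec(rng_seed=13, noise_sd=sd,
                                            n_regions_per_hemi=12))
            res = fit_global(ds.connectome, ds.data, rng_seed=13, n_boot=25)
            widths[sd] = res.ci95["gamma"][1] - res.ci95["gamma"][0]
        assert widths[0.1] < widths[0.2]

    def test_bootstrap_resamples_regions_jointly(self, desk_dataset):
        ds = desk_dataset
        sub = ds.data.subset_regions(ds.data.quantified_regions()[:10])
        per_region = sub.quantified_mask.sum(axis=1)
        # a sampled region keeps all timepoints; others have none
        assert set(per_region) <= {0, ds.data.times.size}


class TestFitGammaOnly:
    def test_dilution_recovery(self):
        truth = SyntheticSpec().true_params
        half = replace(truth, gamma=truth.gamma / 2)
        ds = make_dataset(SyntheticSpec(rng_seed=11, true_params=half, noise_sd=0.05))
        res = fit_gamma_only(ds.connectome, ds.gene, ds.data, truth)
        assert res.point.gamma == pytest.approx(truth.gamma / 2, rel=0.02)
        assert res.fixed == ("alpha", "beta", "p", "b")
        assert res.k_params == 1

    def test_same_data_returns_original_gamma(self, clean_dataset):
        ds = clean_dataset
        res = fit_gamma_only(ds.connectome, ds.gene, ds.data, ds.params)
        assert res.point.gamma == pytest.approx(ds.params.gamma, rel=1e-6)
        assert res.r2 == pytest.approx(1.0)


class TestEstimatorAPI:
    def test_sklearn_params_roundtrip(self, desk_dataset):
        from sklearn.base import clone

        ds = desk_dataset
        est = NexisMicroglia(ds.connectome, ds.gene, anchor=False, n_starts=3,
                             random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["n_starts"] == 3
        cloned.set_params(n_starts=5)
        assert cloned.n_starts == 5

    def test_predict_and_score(self, clean_dataset):
        ds = clean_dataset
        est = NDM(ds.connectome, random_state=0).fit(ds.data)
        traj = est.predict([2.0, 4.0])
        assert traj.values.shape == (ds.connectome.n, 2)
        assert est.score(ds.data) == pytest.approx(est.r2_)

    def test_misaligned_regions_rejected(self, desk_dataset, clean_dataset):
        with pytest.raises(ValueError, match="aligned"):
            NDM(desk_dataset.connectome).fit(clean_dataset.data)
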