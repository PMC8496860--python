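"""Objective scoring, posterior, and the Metropolis-Hastings sampler."""
import math

import numpy as np
import pandas as pd
import pytest

from galvar import (
    FitConfig,
    GalPathwayModel,
    StrainTable,
    SyntheticStrainSpec,
    fit_strains,
    generate_strain_table,
    log_posterior,
    mh_sample,
    multi_strain_objective,
    objective,
)
from galvar.calibration import log_prior


def _table_from_rows(rows, strain_id="t", knockouts=()):
    return StrainTable(strain_id, pd.DataFrame(rows), knockouts)


@pytest.fixture(scope="module")
def noiseless_base_table(ref_params, small_grid):
    spec = SyntheticStrainSpec("base", {}, (), noise_sd=0.0, seed=1)
    return generate_strain_table(spec, ref_params, small_grid)


class TestObjective:
    def test_noiseless_self_fit_is_zero(
        self, ref_params, small_grid, noiseless_base_table
    ):
        obj = objective(ref_params, noiseless_base_table, small_grid)
        assert obj == pytest.approx(0.0, abs=1e-10)

    def test_single_condition_arithmetic(self, ref_params, small_grid):
        """Residuals 0.1 (high) and 0.2 (low) at one condition give 0.05."""
        from galvar import simulate_grid

        prof = simulate_grid(ref_params, small_grid)
        g = small_grid.glucose_levels[1]
        ga = small_grid.galactose_levels[1]
        i, j = 1, 1
        rows = [{
            "glucose": g, "galactose": ga,
            "on_peak": prof.normalized_high[i, j] + 0.1,
            "off_peak": max(prof.normalized_low[i, j] - 0.2, 0.0),
            "valid": True,
        }]
        # keep on >= off in the table
        assert rows[0]["on_peak"] >= rows[0]["off_peak"]
        expected = 0.1 ** 2 + (prof.normalized_low[i, j] - rows[0]["off_peak"]) ** 2
        obj = objective(ref_params, _table_from_rows(rows), small_grid)
        assert obj == pytest.approx(expected, abs=1e-9)

    def test_invalid_rows_are_excluded(self, ref_params, small_grid,
                                       noiseless_base_table):
        df = noiseless_base_table.data.copy()
        k = df.index[df["valid"]][0]
        df.loc[k, "on_peak"] = 1e6          # huge residual, masked out
        df.loc[k, "valid"] = False
        table = StrainTable("masked", df)
        obj = objective(ref_params, table, small_grid)
        assert obj == pytest.approx(0.0, abs=1e-10)

    def test_no_valid_conditions_raises(self, ref_params, small_grid,
                                        noiseless_base_table):
        df = noiseless_base_table.data.copy()
        df["valid"] = False
        with pytest.raises(ValueError):
            objective(ref_params, StrainTable("empty", df), small_grid)


class TestMultiStrain:
    def test_single_strain_reduces_to_objective(
        self, ref_params, small_grid, noiseless_base_table
    ):
        total, per = multi_strain_objective(
            ref_params, [(noiseless_base_table, (), {})], small_grid
        )
        assert total == pytest.approx(
            objective(ref_params, noiseless_base_table, small_grid)
        )

    def test_panel_generated_from_one_vector_scores_zero(
        self, ref_params, small_grid
    ):
        specs = [
            SyntheticStrainSpec("wt", {}, (), 0.0, 1),
            SyntheticStrainSpec("mig1", {}, ("MIG1",), 0.0, 2),
            SyntheticStrainSpec("gal80", {}, ("GAL80",), 0.0, 3),
        ]
        panel = [
            (generate_strain_table(s, ref_params, small_grid),
             s.knockouts, {})
            for s in specs
        ]
        total, per = multi_strain_objective(ref_params, panel, small_grid)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert set(per) == {"wt", "mig1", "gal80"}

    def test_empty_panel_raises(self, ref_params, small_grid):
        with pytest.raises(ValueError):
            multi_strain_objective(ref_params, [], small_grid)


class TestLogPosterior:
    def test_flat_prior_differences_equal_scaled_objective(
        self, ref_params, small_grid, noiseless_base_table
    ):
        """With identical priors, posterior differences are -dObj/sigma^2."""
        cfg = FitConfig(free=("kf83",), sigma=0.2)
        specs = [(noiseless_base_table, (), {})]
        p2 = ref_params.replace(kf83=ref_params["kf83"] * 2)
        lp1, o1 = log_posterior(ref_params, specs, cfg, small_grid)
        lp2, o2 = log_posterior(p2, specs, cfg, small_grid)
        dprior = log_prior(p2, cfg) - log_prior(ref_params, cfg)
        assert (lp2 - lp1) == pytest.approx(
            dprior - (o2 - o1) / cfg.sigma ** 2, rel=1e-9
        )

    def test_empty_tables_score_prior_only(self, ref_params):
        cfg = FitConfig(free=("kf83",))
        lp, obj = log_posterior(ref_params, [], cfg)
        assert obj == 0.0
        assert lp == pytest.approx(log_prior(ref_params, cfg))

    def test_prior_center_maximizes_oneparam_scan(
        self, ref_params, small_grid, noiseless_base_table
    ):
        """Noise-free self-generated data: the truth beats a coarse 1-D scan."""
        cfg = FitConfig(free=("kf83",))
        specs = [(noiseless_base_table, (), {})]
        lp0, _ = log_posterior(ref_params, specs, cfg, small_grid)
        for mult in (0.1, 0.3, 3.0, 10.0):
            p = ref_params.replace(kf83=ref_params["kf83"] * mult)
            lp, _ = log_posterior(p, specs, cfg, small_grid)
            assert lp < lp0


class TestSampler:
    @staticmethod
    def _gaussian_target(mu, sd):
        def fn(params):
            x = math.log10(params["kf83"])
            return -0.5 * ((x - mu) / sd) ** 2
        return fn

    def test_uphill_proposals_always_accepted(self, ref_params):
        calls = []

        def fn(params):
            calls.append(params["kf83"])
            return float(len(calls))        # strictly increasing posterior

        cfg = FitConfig(free=("kf83",), n_steps=50, step_decades=0.1, seed=3)
        chain = mh_sample(fn, ref_params, cfg)
        assert chain.accepted.all()

    def test_identical_seeds_identical_chains(self, ref_params):
        mu = math.log10(ref_params["kf83"])
        fn = self._gaussian_target(mu, 0.3)
        cfg = FitConfig(free=("kf83",), n_steps=200, step_decades=0.3, seed=11)
        c1 = mh_sample(fn, ref_params, cfg)
        c2 = mh_sample(fn, ref_params, cfg)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.accepted, c2.accepted)

    def test_gaussian_target_moments(self, ref_params):
        """Chain mean/sd of an analytic 1-D Gaussian target, 50k steps."""
        mu, sd = math.log10(ref_params["kf83"]), 0.25
        fn = self._gaussian_target(mu, sd)
        cfg = FitConfig(free=("kf83",), n_steps=50_000,
                        step_decades=0.5, seed=5)
        chain = mh_sample(fn, ref_params, cfg)
        xs = chain.samples[1000:, 0]        # drop warm-up
        # batch-means standard errors (autocorrelation-aware)
        nb = 50
        batches = xs[: len(xs) // nb * nb].reshape(nb, -1)
        bmeans = batches.mean(axis=1)
        se_mean = bmeans.std(ddof=1) / math.sqrt(nb)
        bsds = batches.std(axis=1, ddof=1)
        se_sd = bsds.std(ddof=1) / math.sqrt(nb)
        assert abs(xs.mean() - mu) < 3 * se_mean
        assert abs(xs.std(ddof=1) - sd) < 3 * se_sd

    def test_best_so_far_is_monotone(self, ref_params):
        fn = self._gaussian_target(math.log10(ref_params["kf83"]), 0.3)
        cfg = FitConfig(free=("kf83",), n_steps=2000, step_decades=0.4, seed=7)
        chain = mh_sample(fn, ref_params, cfg)
        best = chain.best_so_far()
        assert np.all(np.diff(best) <= 0)
        assert chain.best_objective == pytest.approx(best[-1])

    def test_zero_length_chain_raises(self, ref_params):
        with pytest.raises(ValueError):
            mh_sample(lambda p: 0.0, ref_params,
                      FitConfig(free=("kf83",), n_steps=0))

    def test_step_size_warning_outside_band(self, ref_params, caplog):
        fn = self._gaussian_target(math.log10(ref_params["kf83"]), 1e-4)
        cfg = FitConfig(free=("kf83",), n_steps=300, step_decades=5.0, seed=9)
        with caplog.at_level("WARNING"):
            chain = mh_sample(fn, ref_params, cfg)
        assert chain.acceptance_rate <= 0.05
        assert any("acceptance rate" in r.message for r in caplog.records)


class TestFitStrains:
    def test_empty_free_list_returns_init(
        self, ref_params, small_grid, noiseless_base_table
    ):
        cfg = FitConfig(free=())
        best, per, chain = fit_strains(
            [(noiseless_base_table, (), {})], ref_params, cfg, small_grid
        )
        assert chain is None
        assert best.values == ref_params.values
        assert per["base"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_perturbed_kf83_within_twofold(
        self, ref_params, small_grid, noiseless_base_table
    ):
        """Single free parameter, init 10x off the truth, noise-free table."""
        start = ref_params.replace(kf83=ref_params["kf83"] * 10)
        cfg = FitConfig(
            free=("kf83",), n_steps=250, step_decades=0.25,
            sigma=0.05, seed=13,
        )
        best, per, chain = fit_strains(
            [(noiseless_base_table, (), {})], start, cfg, small_grid
        )
        fold = best["kf83"] / ref_params["kf83"]
        assert 0.5 <= fold <= 2.0
        assert chain.best_objective < objective(start, noiseless_base_table,
                                                small_grid)

    def test_gal80_insensitivity_survives_fitting(
        self, ref_params, small_grid
    ):
        """A fitted model still renders gal80-deletion rows flat."""
        from galvar import simulate_grid

        specs = [
            SyntheticStrainSpec("wt", {}, (), 0.0, 21),
            SyntheticStrainSpec("gal80", {}, ("GAL80",), 0.0, 22),
        ]
        panel = [
            (generate_strain_table(s, ref_params, small_grid), s.knockouts, {})
            for s in specs
        ]
        cfg = FitConfig(free=("kf83", "kr83"), n_steps=60,
                        step_decades=0.05, seed=17)
        best, per, _ = fit_strains(panel, ref_params, cfg, small_grid)
        from galvar import apply_knockout

        prof = simulate_grid(apply_knockout(best, "GAL80"), small_grid)
        nh = prof.normalized_high
        for i, g in enumerate(small_grid.glucose_levels):
            row = nh[i, [j for j, ga in
                         enumerate(small_grid.galactose_levels) if ga > 0]]
            assert row.max() - row.min() < 0.05


class TestModelFacade:
    def test_fit_and_summary(self, ref_params, small_grid,
                             noiseless_base_table):
        model = GalPathwayModel([noiseless_base_table], grid=small_grid)
        cfg = FitConfig(free=("kf83",), n_steps=20, step_decades=0.02, seed=1)
        res = model.fit(start_params=ref_params, config=cfg)
        text = res.summary()
        assert "kf83" in text and "objective" in text
        assert res.objective >= 0.0
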