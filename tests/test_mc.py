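"""Monte Carlo engine: determinism, error propagation, batch behaviour."""

import numpy as np
import pandas as pd
import pytest

from forestagb.allometry import AGBModel, ErrorToggles, HeightModel, tree_agb
from forestagb.inventory import DiameterClassRecord, ManagementInventory, ReferencePlot
from forestagb.mc import PlotAGBModel, batch_estimate, estimate_plot_agb
from forestagb.simulate import DegradationScenario, degrade_plot


def _one_tree_plot(dbh=40.0, wd=0.6, wd_sd=0.12, area=0.1):
    trees = pd.DataFrame(
        {"dbh": [dbh], "taxon_id": ["tX"], "wd_mean": [wd], "wd_sd": [wd_sd],
         "x": [1.0], "y": [1.0]}
    )
    return ReferencePlot("one", area, trees)


class TestDeterministicBranch:
    def test_scientific_all_off_zero_variance(self, ref_plot):
        res = estimate_plot_agb(ref_plot, toggles=ErrorToggles.none(), n_iter=200, seed=0)
        assert res.variance == 0.0
        assert res.cv_pct == 0.0
        # mean equals the deterministic tree-AGB sum computed independently
        hm, am = HeightModel(), AGBModel()
        d = ref_plot.trees["dbh"].to_numpy()
        wd = ref_plot.trees["wd_mean"].to_numpy()
        oracle = tree_agb(wd, d, hm.predict(d), am).sum() / ref_plot.area_ha
        assert res.mean_agb == pytest.approx(oracle, rel=1e-12)

    def test_management_all_off_zero_variance(self, ref_plot):
        inv = degrade_plot(ref_plot, DegradationScenario(200.0), seed=0)
        res = estimate_plot_agb(inv, toggles=ErrorToggles.none(), n_iter=200, seed=0)
        assert res.variance == 0.0

    def test_same_seed_bit_identical(self, ref_plot):
        kw = dict(toggles=ErrorToggles.classical(), n_iter=100, seed=77)
        a = estimate_plot_agb(ref_plot, **kw)
        b = estimate_plot_agb(ref_plot, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_empty_inventory_flagged(self):
        empty = ReferencePlot(
            "e", 0.5,
            pd.DataFrame(columns=["dbh", "taxon_id", "wd_mean", "wd_sd", "x", "y"]),
        )
        res = estimate_plot_agb(empty, n_iter=50, seed=0)
        assert res.empty and res.mean_agb == 0.0 and res.variance == 0.0


class TestErrorPropagation:
    def test_cv_identity(self, ref_plot):
        res = estimate_plot_agb(ref_plot, toggles=ErrorToggles.classical(),
                                n_iter=300, seed=1)
        assert res.cv_pct == pytest.approx(100 * np.sqrt(res.variance) / res.mean_agb,
                                           rel=1e-12)
        assert res.mean_agb == pytest.approx(res.agb_ge20_mean + res.agb_10_20_mean,
                                             rel=1e-9)

    def test_single_tree_wd_cv_matches_brute_force_oracle(self):
        plot = _one_tree_plot()
        res = estimate_plot_agb(plot, toggles=ErrorToggles(wd=True),
                                n_iter=20_000, seed=2)
        # oracle: push truncated-normal wd draws through the AGB formula
        # directly, outside the engine
        orng = np.random.default_rng(999)
        raw = orng.normal(0.6, 0.12, size=500_000)
        wd = raw[(raw >= 0.08) & (raw <= 1.39)]
        hm, am = HeightModel(), AGBModel()
        agb = tree_agb(wd, 40.0, float(hm.predict(40.0)), am)
        oracle_cv = 100 * agb.std() / agb.mean()
        assert res.cv_pct == pytest.approx(oracle_cv, rel=0.05)

    def test_shared_coefficient_error_does_not_decay_with_tree_count(self, taxon_pool):
        # coefficient-only CV is ~constant in N; wd-only CV decays ~1/sqrt(N)
        def stand(n):
            trees = pd.DataFrame(
                {"dbh": np.full(n, 40.0), "taxon_id": ["t"] * n,
                 "wd_mean": [0.6] * n, "wd_sd": [0.12] * n,
                 "x": np.zeros(n), "y": np.zeros(n)}
            )
            return ReferencePlot("s", 1.0, trees)

        am = AGBModel(sigma_ln=0.0, coef_rel_sd=0.02)
        coef_small = estimate_plot_agb(stand(5), toggles=ErrorToggles(agb=True),
                                       n_iter=2000, seed=3, agb_model=am).cv_pct
        coef_large = estimate_plot_agb(stand(500), toggles=ErrorToggles(agb=True),
                                       n_iter=2000, seed=4, agb_model=am).cv_pct
        assert coef_large == pytest.approx(coef_small, rel=0.15)

        wd_small = estimate_plot_agb(stand(5), toggles=ErrorToggles(wd=True),
                                     n_iter=2000, seed=5).cv_pct
        wd_large = estimate_plot_agb(stand(500), toggles=ErrorToggles(wd=True),
                                     n_iter=2000, seed=6).cv_pct
        assert wd_large < wd_small / 5  # 1/sqrt(100) = 1/10 expected

    def test_adding_sources_never_decreases_mean_cv(self, plots20, correction_model):
        # nested toggle sets on the same degraded inventories, paired
        scenario = DegradationScenario(150.0, sampling_fraction_by_class={10.0: 0.25})
        invs = [degrade_plot(p, scenario, seed=i) for i, p in enumerate(plots20)]
        nested = [
            ErrorToggles(dbh_assign=True),
            ErrorToggles(dbh_assign=True, n_exp=True),
            ErrorToggles(dbh_assign=True, n_exp=True, wd=True),
            ErrorToggles(dbh_assign=True, n_exp=True, wd=True, height=True, agb=True),
        ]
        means = []
        for tog in nested:
            cvs = [estimate_plot_agb(inv, toggles=tog, n_iter=300, seed=j).cv_pct
                   for j, inv in enumerate(invs)]
            means.append(np.mean(cvs))
        assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))

    def test_missing_correction_model_rejected(self, ref_plot):
        inv = degrade_plot(
            ref_plot,
            DegradationScenario(120.0, census_threshold=20.0, drop_10_20=True),
            seed=0,
        )
        with pytest.raises(ValueError):
            PlotAGBModel(inv)

    def test_corrected_estimate_adds_10_20_component(self, ref_plot, correction_model):
        inv = degrade_plot(
            ref_plot,
            DegradationScenario(120.0, census_threshold=20.0, drop_10_20=True),
            seed=0,
        )
        res = estimate_plot_agb(inv, toggles=ErrorToggles.none(), n_iter=50, seed=0,
                                correction_model=correction_model)
        assert res.corrected
        assert res.agb_10_20_mean >= 0.0
        assert res.mean_agb == pytest.approx(res.agb_ge20_mean + res.agb_10_20_mean)


class TestBatch:
    def test_workers_do_not_change_results(self, plots20):
        kw = dict(toggles=ErrorToggles.classical(), n_iter=100, master_seed=5)
        seq, err1 = batch_estimate(plots20[:8], workers=1, **kw)
        par, err2 = batch_estimate(plots20[:8], workers=4, **kw)
        assert not err1 and not err2
        for a, b in zip(seq, par):
            assert a.mean_agb == b.mean_agb
            assert a.variance == b.variance

    def test_empty_list(self):
        results, errors = batch_estimate([])
        assert results == [] and errors == []

    def test_malformed_plot_isolated(self, plots20, ref_plot):
        bad = degrade_plot(
            ref_plot,
            DegradationScenario(120.0, census_threshold=20.0, drop_10_20=True),
            seed=0,
        )  # needs a correction model that we do not pass
        results, errors = batch_estimate([plots20[1], bad, plots20[2]],
                                         toggles=ErrorToggles.none(), n_iter=20)
        assert len(results) == 2
        assert len(errors) == 1 and errors[0].plot_id == bad.plot_id

    def test_invalid_dialect_rejected(self):
        with pytest.raises(ValueError):
            PlotAGBModel(object())

    def test_n_iter_validation(self, ref_plot):
        with pytest.raises(ValueError):
            PlotAGBModel(ref_plot).fit(n_iter=0)
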