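"""Synthetic stand generator and the degradation operators."""

import numpy as np
import pandas as pd
import pytest

from forestagb.distributions import WeibullDBHModel
from forestagb.inventory import (
    ReferencePlot,
    read_management_inventories,
    read_reference_plots,
    write_management_inventories,
    write_reference_plots,
)
from forestagb.simulate import (
    DegradationScenario,
    SyntheticForestConfig,
    degrade_plot,
    generate_plot,
    generate_taxon_table,
    split_plot,
)


class TestTaxonTable:
    def test_single_taxon_normalisation(self):
        pool = generate_taxon_table(1, seed=0)
        assert pool[0].rel_abundance == pytest.approx(1.0)

    def test_same_seed_identical(self):
        assert generate_taxon_table(20, seed=5) == generate_taxon_table(20, seed=5)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            generate_taxon_table(0, seed=0)

    def test_wd_mean_matches_rejection_oracle(self):
        pool = generate_taxon_table(10_000, seed=13)
        wd = np.array([t.wd_mean for t in pool])
        orng = np.random.default_rng(99)
        raw = orng.normal(0.62, 0.12, size=1_000_000)
        acc = raw[(raw >= 0.2) & (raw <= 1.0)]
        se = acc.std() / np.sqrt(wd.size)
        assert wd.mean() == pytest.approx(acc.mean(), abs=3 * se)
        assert wd.min() >= 0.2 and wd.max() <= 1.0

    def test_abundances_sum_to_one_and_decay(self):
        pool = generate_taxon_table(100, seed=1)
        ab = np.array([t.rel_abundance for t in pool])
        assert ab.sum() == pytest.approx(1.0)
        assert np.all(np.diff(ab) < 0)


class TestGeneratePlot:
    def test_zero_density_empty_plot(self, taxon_pool):
        cfg = SyntheticForestConfig(stem_density=0.0, taxon_pool=taxon_pool)
        assert generate_plot(cfg, seed=0).n_trees == 0

    def test_class_fraction_matches_closed_form_cdf(self, taxon_pool):
        # big plot => ~1e5 trees; share in [10, 20) vs the truncated-Weibull
        # class probability from the closed-form CDF
        cfg = SyntheticForestConfig(plot_area_ha=200.0, taxon_pool=taxon_pool)
        plot = generate_plot(cfg, seed=3)
        dbh = plot.trees["dbh"].to_numpy()
        p = WeibullDBHModel().class_prob(10.0, 20.0)
        frac = np.mean(dbh < 20.0)
        se = np.sqrt(p * (1 - p) / dbh.size)
        assert frac == pytest.approx(p, abs=3 * se)

    def test_deterministic_under_seed(self, forest_config):
        a = generate_plot(forest_config, seed=42)
        b = generate_plot(forest_config, seed=42)
        pd.testing.assert_frame_equal(a.trees, b.trees)


class TestDegradePlot:
    def test_lossless_binning_reconstructs_histogram(self, ref_plot):
        scenario = DegradationScenario(200.0)
        inv = degrade_plot(ref_plot, scenario, seed=0)
        dbh = ref_plot.trees["dbh"].to_numpy()
        assert not any(dbh >= 200.0), "fixture plot must not reach the open class"
        for c in inv.classes:
            expected = int(np.sum((dbh >= c.class_lo) & (dbh < c.class_lo + 10.0)))
            assert c.r == expected
            assert c.p == 1.0
        assert inv.n_observed == ref_plot.n_trees

    def test_binomial_thinning_mean(self, taxon_pool):
        # one class of 500 trees thinned at p=0.3: mean retained over seeds ~ n*p
        trees = pd.DataFrame(
            {
                "dbh": np.full(500, 25.0),
                "taxon_id": ["t0000"] * 500,
                "wd_mean": [0.6] * 500,
                "wd_sd": [0.05] * 500,
                "x": np.zeros(500),
                "y": np.zeros(500),
            }
        )
        plot = ReferencePlot("p", 0.5, trees)
        scenario = DegradationScenario(200.0, sampling_fraction_by_class={20.0: 0.3})
        retained = np.array(
            [degrade_plot(plot, scenario, seed=s).n_observed for s in range(300)]
        )
        se = np.sqrt(500 * 0.3 * 0.7 / 300)
        assert retained.mean() == pytest.approx(150.0, abs=3 * se)

    def test_worst_case_fractions_recorded(self, ref_plot):
        scenario = DegradationScenario(
            200.0, sampling_fraction_by_class={10.0: 0.125, 20.0: 0.125, 30.0: 0.25}
        )
        inv = degrade_plot(ref_plot, scenario, seed=1)
        p_by_class = {c.class_lo: c.p for c in inv.classes}
        assert p_by_class[10.0] == 0.125
        assert p_by_class[20.0] == 0.125
        assert p_by_class[30.0] == 0.25

    def test_census_threshold_drops_small_class(self, ref_plot):
        scenario = DegradationScenario(120.0, census_threshold=20.0, drop_10_20=True)
        inv = degrade_plot(ref_plot, scenario, seed=1)
        assert all(c.class_lo >= 20.0 for c in inv.classes)
        assert inv.drop_10_20

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            DegradationScenario(200.0, sampling_fraction_by_class={10.0: 0.0})
        with pytest.raises(ValueError):
            DegradationScenario(110.0)
        with pytest.raises(ValueError):
            DegradationScenario(200.0, drop_10_20=True)  # census floor stays 10


class TestSplitPlot:
    def test_area_conservation_and_partition(self, ref_plot):
        halves = split_plot(ref_plot)
        assert sum(h.area_ha for h in halves) == pytest.approx(ref_plot.area_ha)
        assert sum(h.n_trees for h in halves) == ref_plot.n_trees
        merged = sorted(
            np.concatenate([h.trees["dbh"].to_numpy() for h in halves]).tolist()
        )
        assert merged == sorted(ref_plot.trees["dbh"].tolist())

    def test_uniform_positions_split_evenly(self, taxon_pool):
        cfg = SyntheticForestConfig(plot_area_ha=20.0, taxon_pool=taxon_pool)
        plot = generate_plot(cfg, seed=8)  # ~1e4 trees, uniform positions
        left, _ = split_plot(plot)
        n = plot.n_trees
        se = np.sqrt(n * 0.25)
        assert left.n_trees == pytest.approx(n / 2, abs=3 * se)

    def test_only_two_way_supported(self, ref_plot):
        with pytest.raises(NotImplementedError):
            split_plot(ref_plot, n_parts=3)


class TestDialectRoundtrip:
    def test_reference_csv_roundtrip(self, plots20, tmp_path):
        write_reference_plots(plots20[:3], tmp_path / "t.csv", tmp_path / "m.csv")
        back = read_reference_plots(tmp_path / "t.csv", tmp_path / "m.csv")
        assert [p.plot_id for p in back] == [p.plot_id for p in plots20[:3]]
        for a, b in zip(plots20[:3], back):
            assert b.area_ha == a.area_ha
            np.testing.assert_allclose(
                b.trees["dbh"].to_numpy(), a.trees["dbh"].to_numpy()
            )

    def test_management_csv_roundtrip(self, plots20, tmp_path):
        scenario = DegradationScenario(150.0, sampling_fraction_by_class={10.0: 0.25})
        invs = [degrade_plot(p, scenario, seed=i) for i, p in enumerate(plots20[:3])]
        write_management_inventories(invs, tmp_path / "c.csv", tmp_path / "m.csv")
        back = read_management_inventories(tmp_path / "c.csv", tmp_path / "m.csv")
        for a, b in zip(invs, back):
            assert b.open_threshold == a.open_threshold
            assert {c.class_lo: c.r for c in b.classes} == {
                c.class_lo: c.r for c in a.classes
            }
            assert {c.class_lo: c.p for c in b.classes} == {
                c.class_lo: c.p for c in a.classes
            }
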