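# forestagb

Plot- and pixel-level **aboveground biomass (AGB) estimation from
forest-management inventories**, with full Monte Carlo uncertainty
propagation.

Management inventories from timber concessions cover areas orders of
magnitude larger than research plot networks, but they degrade the
tree record: diameters are binned into 10-cm classes, everything above
an opening threshold (120–200 cm) is pooled into one right-censored
"open class", and the smallest classes are censused on only a fraction
of the plot area — or not at all. `forestagb` turns such records into
research-grade AGB estimates (Mg ha⁻¹) with honest uncertainties, for
quantitative ecologists and carbon-mapping practitioners.

## The model

Tree AGB follows the pantropical power law

  AGB (kg) = α·(ρ·D²·H)^β,  α = 0.0673, β = 0.976,

with wood density ρ resolved from a reference table
(species → genus → family → dataset mean) and height from the
asymptotic regional model H = a_H·(1 − exp(−b_H·D^c_H)). Three
standardisation steps bridge the management dialect to tree lists:

* **diameter assignment** — inverse-transform sampling from a fitted
  size distribution (default: truncated Weibull, λ = 8.593, k = 0.737
  on [10, 400] cm) conditioned on each diameter class;
* **small-tree expansion** — a class counted r on a spatial fraction p
  is expanded by X ~ NegBin(r, p) (E[r + X] = r/p), the exact inverse of
  binomial thinning, with taxa assigned pro rata;
* **AGB₁₀₋₂₀ correction** — when the 10–20 cm class is absent:
  AGB₁₀₋₂₀ = a + b·AGB₌₂₀ + c·S + d·I + ε, with S, I the slope and
  intercept of the cumulated-biomass curve over classes 20–70 cm.

Each step, plus the wood-density, height- and AGB-model errors, is a
toggleable error source in a Monte Carlo chain (1000 iterations/plot);
plot estimates aggregate to 1-km pixels (EPSG:3395) with the variance
split into intra-plot (estimation) and inter-plot (sampling)
components, exported as a 5-band GeoTIFF.

## Worked example

```python
from forestagb import (
    SyntheticForestConfig, generate_taxon_table, generate_plots,
    degrade_plot, estimate_plot_agb, ErrorToggles, SCENARIOS,
)

pool = tuple(generate_taxon_table(50, seed=7))
forest = SyntheticForestConfig(plot_area_ha=0.5, stem_density=500.0, taxon_pool=pool)
plot = generate_plots(forest, 1, master_seed=11)[0]          # a reference plot

inv = degrade_plot(plot, SCENARIOS["best"], seed=3)          # management dialect
res = estimate_plot_agb(
    inv,
    toggles=ErrorToggles(wd=True, height=True, agb=True, dbh_assign=True, n_exp=True),
    n_iter=1000,
    seed=5,
)
print(res.summary())
```

```
Plot AGB estimate — p0000
----------------------------------------
mean AGB                  472.43 Mg/ha
variance                 1239.61 (Mg/ha)^2
CV                          7.45 %
AGB >= 20 cm              444.57 Mg/ha
AGB 10-20 cm               27.86 Mg/ha
iterations                  1000
DBH floor                     10 cm
```

The plot was degraded under the "best-case" management scenario
(open class at 200 cm, the 10–20 cm class sampled on 25% of the plot);
re-estimation with all applicable error sources recovers the plot's
biomass with a 7.5% coefficient of variation — the 472 Mg ha⁻¹ mean is
the plot AGB value, and 100·√variance/mean is its uncertainty. The
small-tree class contributes 27.9 Mg ha⁻¹, about 6% of the biomass
above 20 cm.

A command-line pipeline wraps the same library:

```sh
forestagb simulate  --config cfg.yml --out data/
forestagb estimate  --plots data/management_classes.csv \
                    --meta data/management_meta.csv --config cfg.yml --out est.csv
forestagb aggregate --estimates est.csv --out agb.tif --pixel-csv pixels.csv
forestagb validate  --scenario worst --config cfg.yml --out report.csv
```

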