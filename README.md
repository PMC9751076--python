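# divstab

Biodiversity-effect partitioning, temporal stability decomposition, and
path analysis for long-term grassland biodiversity experiments.

Grassland biodiversity experiments sow plots along a species-richness
gradient and harvest species-level biomass for years to decades. Two
questions drive their analysis: *why* do diverse mixtures out-produce
monocultures (complementarity vs. dominance by productive species), and
*why* is their productivity more stable from year to year (asynchronous
species fluctuations vs. stable populations)? `divstab` implements the
complete quantitative pipeline for these questions — from a synthetic
experiment generator with known ground truth, through the classical
additive partition and rolling-window stability indices, to power-law
slope decompositions and a recursive path model that links them — for
ecologists and biostatisticians analysing plot × year × species biomass
tables.

## The quantities

**Additive partition.** For a mixture of $N$ species with observed yields
$O_i$ and monoculture yields $M_i$, relative yields are
$\mathrm{RY}_i = O_i/M_i$ and $\mathrm{RYT} = \sum_i \mathrm{RY}_i$. The
net biodiversity effect splits exactly into complementarity and selection:

$$\mathrm{NE} = \sum_i O_i - \frac{\sum_i M_i}{N}, \qquad
\mathrm{CE} = (\mathrm{RYT}-1)\frac{\sum_i M_i}{N}, \qquad
\mathrm{SE} = (N-1)\,\mathrm{cov}(M_i,\ \mathrm{RY}_i - 1/N),$$

with $\mathrm{NE} = \mathrm{CE} + \mathrm{SE}$ identically. Species that
fail in monoculture ($M_i = 0$) are excluded; extreme CE/SE values are
flagged by quartile fences $Q_1 - 6\cdot\mathrm{IQR}$ /
$Q_3 + 6\cdot\mathrm{IQR}$. Windowed effects apply the same formulas to
biomass summed over multi-year windows, where interannually alternating
dominance scales up into multi-year complementarity.

**Stability and synchrony.** Over a window, the community series has mean
$\mu_{net}$ and SD $\sigma_{net}$; stability is
$\mathrm{CV}_{net}^{-1} = \mu_{net}/\sigma_{net}$. Synchrony is
$\theta = \sigma_{net} / \sum_i \sigma_i \in [0,1]$, asynchrony $1-\theta$,
population variability $\mathrm{CV}_{pop} = \sum_i\sigma_i / \mu_{net}$,
and $\mathrm{CV}_{net} = \theta\cdot\mathrm{CV}_{pop}$ exactly.

**Slope decompositions.** Power exponents $b$ of
$\log(\text{response}) \sim b\,\log(\text{richness})$ obey exact identities
on a common plot set: $b_{CV_{net}^{-1}} = b_{mean} - b_{SD}$ and
$b_{CV_{net}^{-1}} = b_{\theta^{-1}} + b_{CV_{pop}^{-1}}$. Trends of these
slopes across years or windows quantify whether diversity effects
strengthen with community age.

**Path analysis.** A recursive standardized path model (richness → CE/SE →
productivity → population stability; richness/CE/SE → asynchrony;
asynchrony + population stability → community stability) is estimated
equation-wise by least squares with bootstrap CIs, indirect effects as
products of chain coefficients, and between-window comparisons.

## Worked example

```python
from divstab import (build_default_design, simulate_experiment,
                     monoculture_index, partition_annual, flag_outliers,
                     yearly_richness_fits, slope_trend,
                     decompose_window_slopes)
from divstab.simulate import get_preset
from divstab.stability import rolling_window_metrics

design = build_default_design(seed=1)            # 78 mixture plots + 60 monocultures
table, truth = simulate_experiment(design, get_preset("jena_like", seed=3))

mono = monoculture_index(table, design)
effects = flag_outliers(partition_annual(table, mono, design))
fits = yearly_richness_fits(effects)
print(slope_trend(fits))

wm = rolling_window_metrics(table, design, width=5)
print(decompose_window_slopes(wm))
```

This prints (abridged) per-response trends of the yearly richness slopes:

```
    response  trend      p
        ANPP 0.1470 0.0005
          CE 7.6365 0.0000
          NE 8.0259 0.0000
         RYT 0.0214 0.0000
RY_community 0.0180 0.0000
          SE 0.3894 0.3541
```

Under the 17-year scenario with richness-dependent productivity decline,
the richness–CE slope strengthens by ≈ 7.6 g m⁻² per log-richness unit per
year (complementarity builds up over time), while the selection-effect
slope shows no trend. The window-slope decomposition shows the stabilizing
effect of richness growing from $b_{CV_{net}^{-1}} = 0.095$
($b_{mean}=0.135$, $b_{SD}=0.040$) in the first 5-year window to 0.129 in
the last, with identity gaps at machine precision (~1e-16).

The same stages are available from the shell:

```bash
divstab simulate  --seed 3 --out sim/
divstab partition --seed 3 --out effects.csv
divstab pipeline  --seed 3 --out run/      # everything end to end
```

## Layout

| module | contents |
| --- | --- |
| `divstab.design` | species pool, richness-gradient plot design |
| `divstab.io` | long-format biomass tables, harvest pooling, CSV round-trip |
| `divstab.simulate` | synthetic experiment generator + scenario presets |
| `divstab.partition` | additive NE/CE/SE partition, exclusions, outlier fences |
| `divstab.stability` | rolling windows, θ, asynchrony, CV decomposition |
| `divstab.slopes` | power-law slopes, b-identities, trend tests |
| `divstab.paths` | recursive path model, bootstrap, indirect effects |
| `divstab.cli` | `divstab` command-line entry point |

See `docs/methods.md` for the statistical model, parameter choices, and
known limitations.
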