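# treemort

Stage-stratified neighborhood analysis of tree mortality in stem-mapped
forest plots.

Whether a tree survives a census interval depends on who its neighbors
are: conspecific crowding can raise mortality (conspecific negative
density dependence), heterospecific crowding can lower it (herd
protection), and both effects change with the *life stage* of the
neighbors relative to the focal tree. `treemort` implements the full
analysis chain needed to quantify these effects in a two-census plot:
neighborhood crowding indices partitioned by relative life stage,
terrain and soil covariates at quadrat resolution, binomial mixed models
with crossed random intercepts, and exhaustive AIC model averaging. It
is aimed at forest ecologists working with ForestGEO-style forest
dynamics plot censuses.

## The model

For focal tree *i*, crowding by the neighbors *j* within radius *r* is

```
NI_i = Σ_j  BA_j / d_ij ,       BA_j = (DBH_j / 2)² · π
```

with basal area in cm² and distance in m. Neighbors are split into
conspecific vs heterospecific (CON / HET) and by relative stage —
earlier, same, later than the focal tree (EaCON, SaCON, LaCON, EaHET,
SaHET, LaHET). Absolute stages (sapling / juvenile / adult) come from
life-form-specific DBH thresholds: shrubs <2 / 2–4 / ≥4 cm, subtrees
<3 / 3–6 / ≥6 cm, canopy trees <5 / 5–10 / ≥10 cm.

Mortality of individual *i* of species *j* in 20 m grid cell *k* is
modeled as

```
Y_ijk ~ Bernoulli(p_ijk)
logit(p_ijk) = α + β'X_i + u_j + v_k ,   u_j ~ N(0, σ²_species),  v_k ~ N(0, σ²_grid)
```

where X holds standardized covariates: log initial DBH, the
neighborhood indices at the AIC-optimal radius (selected per life form
over 5–40 m), and per-5 m-quadrat environment (elevation, convexity,
slope, transformed aspect cos(α)+1.1, soil TN, TP, pH, moisture;
elevation and soil surfaces kriged from measured points). The model is
fitted by a Laplace approximation to the integrated likelihood
(cross-checked against lme4 in the test suite). Every subset of the
candidate covariates is fitted (2ⁿ models), each model gets an Akaike
weight `w_i ∝ exp(−ΔAIC_i/2)`, a variable's importance is the summed
weight of the models containing it, and effects are reported as
model-averaged estimators with unconditional standard errors over the
ΔAIC ≤ 2 optimal model group, flagged significant when the ±1.96 SE
interval excludes zero.

A synthetic-plot generator (Thomas-process species patterns, reverse-J
DBH distribution, smooth environmental surfaces, mortality drawn from
the mixed-logit model above with known coefficients) provides ground
truth for every stage of the pipeline.

## Worked example

```python
import numpy as np
import pandas as pd
from treemort import (PlotGeometry, SyntheticConfig, generate_plot,
                      exclude_edge, stratified_indices, AICModelAverager)

cfg = SyntheticConfig(parents_per_species=24.0, seed=1)   # 500 x 400 m plot
census, env, truth = generate_plot(cfg)

interior = exclude_edge(census, cfg.geometry)             # 25 m edge buffer
focal = interior[interior["stage"] == "juvenile"]
ni = stratified_indices(census, focal, radius=truth.radius)

cov = pd.DataFrame({
    "LaCON": ni["LaCON"], "EaCON": ni["EaCON"], "LaHET": ni["LaHET"],
    "DBH": np.log(focal["dbh"]),
    "ELEV": env.reindex(focal["quadrat_id"])["elev"].to_numpy(),
})
est = AICModelAverager().fit(cov, focal["dead"].to_numpy(),
                             species=focal["species"].to_numpy(),
                             grid=focal["grid_id"].to_numpy())
print(est.results_.round(3))
```

```
       importance  beta_avg  se_uncond  significant
var
LaCON       1.000     0.320      0.028         True
EaCON       0.984    -0.149      0.048         True
LaHET       1.000    -0.193      0.043         True
DBH         0.269    -0.001      0.052        False
ELEV        0.272     0.006      0.036        False
```

The generating truth was +0.3 per SD for conspecific later-stage
crowding, −0.2 for conspecific earlier-stage and heterospecific
later-stage crowding, and no DBH or elevation effect: the averaged
estimates recover the signs and significance, the null covariates stay
unimportant (importance well below 1) and non-significant.

A full pipeline run — census validation, focal-species selection
(≥50 stems per stage), edge exclusion, per-grid stage mortality with
Wilcoxon signed-rank comparisons, radius selection, and model averaging
per focal stage and stratification scheme — is available as
`treemort.run_analysis(RunConfig(...))` or from the shell:

```
treemort simulate --seed 1 --out demo
treemort all --config run.yaml
```

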