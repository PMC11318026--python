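# shellrank

Multivariate shelter-resource quality analysis for shell-dwelling cichlids.

`Neolamprologus multifasciatus` lives in social groups on Lake Tanganyika
shell beds; every independent fish occupies one empty `Neothauma
tanganyicense` snail shell from its group's limited supply. Shell "quality"
is multivariate — size (entrance diameter), wall intactness, surface vs
basement stratum, wall texture, sponge overgrowth, resident shrimp or crabs
— and this package implements the statistical machinery for asking which of
those characteristics drive shell choice, how shells are partitioned among
group members, and how to collapse all characteristics into a single
per-shell **resource attractiveness index**.

## Models

**Shell occupancy.** For shell *i* in group *g*, occupancy
`y_ig ~ Bernoulli(p_ig)` with

    logit p_ig = x_ig' beta + u_g,    u_g ~ N(0, sigma^2),

where `x` holds scaled intactness and entrance size, stratum, and the
binary shell traits, with two-way interactions among location, intactness
and entrance size screened by likelihood-ratio tests. The marginal
likelihood is maximized by adaptive Gauss–Hermite quadrature (15 nodes,
mode-centered and curvature-scaled per group), written in
`shellrank.glmm`. Wald contrasts, generalized VIFs and nested-model LRTs
ride on the same fit machinery.

**Occupant class.** Which class of group member (dominant male,
subordinate male, female, juvenile) holds a shell is a baseline-category
multinomial logit, `log[P(k)/P(baseline)] = x' gamma_k`, fit by
Newton–Raphson with step-halving (`shellrank.mnlogit`); releveling the
baseline via `gamma_{a|b} = gamma_{a|c} - gamma_{b|c}` (covariance
propagated through the same linear map) yields every pairwise comparison.

**Attractiveness index.** Per shell (`shellrank.index`):

    A_i = p_obs,i - mean_r p_rand,i(r),      z_i = (A_i - mean_g A) / sd_g A,

where `p_obs` is the occupancy model's conditional prediction and
`p_rand(r)` the prediction after permuting occupancy labels *within* each
group (preserving each group's occupied count — a group chooses only among
its own shells) and refitting the model, repeated `n_rand` times (1000 by
default). Positive `z`: occupied above random within-group choice — "the
best of what is available".

`shellrank.simulate` generates censuses matched to the study conditions
(41 groups, 25.8 ± 15.8 usable shells per group, entrance 2.00 ± 0.22 cm,
intactness 76.7 ± 23.0%, marginal occupancy 226/1057, generating slopes
equal to the occupancy-model estimates), so every stage is testable
without field data and fitted coefficients can be checked against the
generating truth.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on a
synthetic census into `results/run/`:

```
cd analysis
python 01_simulate.py && python 03_occupancy_model.py
```

prints (abridged):

```
census: 1030 shells collected, 1030 usable
groups: 41, occupied shells: 225, occupant records: 225

final occupancy model (log-odds):
  intactness_pct_s                          1.94 +/- 0.16  z=12.37  p=0.0000
  entrance_cm_s                             0.19 +/- 0.09  z= 2.01  p=0.0443
  location[surface]                         0.69 +/- 0.22  z= 3.08  p=0.0020
  shrimp                                   -1.19 +/- 0.54  z=-2.22  p=0.0264
  crab                                     -2.50 +/- 1.07  z=-2.34  p=0.0193
  sigma_group = 0.581
```

Intactness dominates occupancy (about 1.9 log-odds per SD here), entrance
size adds a smaller push, and shells holding crustaceans are avoided. At
this draw the intactness-by-location interaction was not retained
(screening LRT p = 0.12; its detection power at the generating effect size
is only ~60%, see `docs/methods.md`). `python 06_attractiveness.py` then
computes the index and refits the class model on it:

```
index over 1030 shells (300 within-group permutation refits):
  p_obs range 0.000-0.872; a_raw range -0.321-0.560

attractiveness coefficients by class pair:
  dominant_male vs juvenile:  -1.70 +/- 0.45  p=0.0001
  female vs juvenile:         -1.59 +/- 0.36  p=0.0000
```

Juveniles sit in significantly less attractive shells than adults, the
despotic-distribution signature the index is designed to expose.

The same pipeline is scriptable: `shellrank all --config run.yaml` with

```yaml
outdir: results/run
seed: 11
n_rand: 1000
simulate: {}          # or instead: shells_csv/occupants_csv paths
```

runs every stage (exit codes: 2 validation, 3 convergence, 4 missing
upstream artifact); real census CSVs (`shells.csv` / `occupants.csv`)
replace the simulate block.

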