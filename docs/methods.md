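# Methods

## Model

`wetstage` fits an additive two-scale decomposition of nutrient
concentration at sampled points,

    y = f1(d) + f2(c) + ε,

where `d` are discrete per-wetland attributes (morphometrics, land-use
percentages, 7-day trailing climate means) and `c` are continuous
per-pixel predictors read off quarterly mean composites of optical and
SAR imagery. Both `f1` and `f2` are random-forest regressions; `f2` is
trained on the stage-1 residuals `r = y − ŷ₁`, and the final prediction
is the sum `ŷ = ŷ₁ + r̂`. The approach assumes (a) additivity — the
satellite signal corrects, rather than interacts with, the site-level
baseline; (b) that a calendar quarter's mean composite is an adequate
stand-in for conditions on the sampling date; and (c) that residual
spatial structure is expressible in the composite's bands and indices.

### Residual definition

Training residuals use the stage-1 forest's **out-of-bag** predictions
on the training partition (`residual_source="oob"`, default). In-sample
random-forest predictions interpolate their training targets almost
perfectly, which would hand stage 2 near-zero targets and starve it of
signal; OOB predictions approximate leave-out behaviour at no extra
cost. `residual_source="insample"` is available for comparison.

### Model scope

The reference workflow fits one model per (year, quarter), mirroring
the seasonal importance heatmaps. With nine stations sampled monthly,
a (year, quarter) cell holds ~20 rows — too few for a 70/30 split — so
`fit_scoped` falls back (threshold: 20 training rows per group) to a
single pooled model whose stage-1 block gains four quarter one-hot
columns, making seasonality directly learnable. Seasonal importance
heatmaps are instead produced by `fit_quarterly_importance`, which fits
one model per (year, quarter) on all of that group's rows (no hold-out;
the fits exist only to read importances) and averages importances over
years per quarter, recording which years contributed.

### Validation

Hold-out metrics on the random 30 % test partition: r² = 1 − SS_res/SS_tot,
RMSE, MAE, and MBE with errors `e = predicted − observed` (positive MBE
= over-prediction). Three rows are reported: *stage1* scores `ŷ₁`
against observations; *stage2* scores `r̂` against the realized test
residuals `y − ŷ₁` (so its RMSE/MAE/MBE numerically equal the final
model's — the errors are identical — while its r² lives on the residual
scale); *final* scores `ŷ₁ + r̂` against observations. r² is undefined
(NaN) for zero-variance observations. The chain `rmse ≥ mae ≥ |mbe|`
holds for every input.

### Map prediction

`predict_map` renders three co-registered layers per quarter: a
baseline layer, constant within each wetland polygon (one stage-1
prediction per wetland, using the quarter-mean climate where a daily
series is supplied); a correction layer, the stage-2 prediction on each
pixel's composite features; and their pixelwise sum. Pixels outside all
polygons are nodata. Negative final concentrations are clipped to zero
(`clip_negative=True`), with the unclipped values retained in a
`final_raw` diagnostic layer; the additive identity is exact on the
unclipped layer.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| trees per forest | 500 | regression convention |
| mtry | ⌊p/3⌋ (min 1) | regression convention |
| max depth / min leaf | none / 1 | fully grown trees |
| importance | impurity, normalized to sum 1 | permutation optional |
| train fraction | 0.70 | hold-out = 30 % |
| residual_source | oob | see above |
| srvi_numerator | "vv" | the co-pol form 4·aVV/(aVV+aVH); "vh" gives the classical cross-pol RVI. The co-pol form is the package default and its complement identity (vv-form + vh-form = 4) is tested. |
| clip_negative | true | physical bound on concentrations |
| band set | B2–B8A, B11, B12 | config-driven; 60 m bands excluded |

Raster conventions: pixel-center registration, half-open cells
`[x, x + pixel_size)` (top/left edges inclusive); a single shared CRS
label, no reprojection; nodata carried as an explicit mask in memory
and as NaN on disk. Every elementwise division is guarded — zero
denominators produce nodata, never infinities. Indices are computed
from composited bands (mean-then-index), not as averages of per-scene
indices; the two differ for nonlinear indices and the composite-first
form matches treating the composite as "the mean environmental state".
SCI is reported in km/km² and is therefore scale-dependent; PPS is
dimensionless. Importance ties are broken by descending score then
lexicographic feature name.

## The synthetic study generator

No field or satellite data ship with the package, so
`wetstage.synthetic` emulates all inputs from a known additive model:

    y = intercept + Σ β_f·discrete_f + Σ γ_g·continuous_g(pixel, month)
        + seasonal(quarter) + trend·(year − year₀) + ε,   truncated at 0.

Defaults describe a nitrogen-like study: 3 wetlands, 3 stations each
(inlet/middle/outlet along the long chord), monthly visits March–
November over 2021–2024 (36 visit months × 9 stations = 324 samples),
a 200×200 grid at 10 m. Imagery consists of unit-variance Gaussian
random fields (correlation length 5 px) combined into band-specific
means and loadings: optical bands share latent "greenness" and
"brightness" fields per quarter (so NDVI varies smoothly and
realistically), SAR VV sits ~6.5 dB above VH. Within a quarter the
latent fields are fixed and monthly scenes add only a small jitter
(0.01 reflectance), so the quarterly composite the pipeline builds is a
faithful proxy for the monthly values the samples were drawn from —
deliberately, since recovery would otherwise be bounded by an
irreducible compositing mismatch.

Default coefficients partition the concentration variance the way the
two-stage design presumes: the discrete baseline (hay/pasture share
β = 0.08 mg/L per %, 7-day rain β = 0.05 mg/L per mm) plus a quarter
sinusoid (amplitude 0.45 mg/L, peaking Q2/Q3) dominate; a vegetation
term (γ_NDVI = 0.6 mg/L) supplies a genuine but secondary continuous
component; observation noise is 0.1 mg/L. Hay/pasture shares are drawn
on a stratified gradient across wetlands (survey-style site selection
spanning a land-use gradient); with plain uniform draws three sites
frequently land on nearly equal shares, which leaves the baseline with
almost no between-site contrast. The `bwg-like` land-use preset centres
developed/cultivated/forest shares on 26.2/38.2/14.7 %. A phosphorus
preset runs ~two orders of magnitude lower, stage-1-dominated, with a
small year-on-year decline that no predictor carries (deliberately
unexplainable drift emulating multi-year recovery). Truncation at zero
is reported and stays below 1 % under defaults. The exact decomposition
of every sample is stored in `SyntheticTruth`.

What the generator does **not** emulate: SAR speckle, clouds and
atmospheric effects, sensor revisit irregularity, within-wetland
land-use heterogeneity, and real hydrological routing. Passing recovery
tests therefore demonstrates the pipeline's correctness and the
method's behaviour under its own assumptions — not performance on real
wetlands.

### Importance identifiability

With only three wetlands, every site-level attribute is a perfect proxy
for site identity: any such feature can induce the same tree splits, so
impurity gain ties and the allocation of importance among discrete
features is arbitrary. Importance-recovery checks therefore use a
designed scenario with 12 wetlands and independently drawn land-use
mixes (`landuse_preset="independent"`), where threshold orderings
decouple and the feature that truly carries the signal (hay/pasture)
wins identifiably. Under the 3-wetland default, stage-1 importance
concentrates on the climate and quarter features — which genuinely vary
within sites — and this is expected, not a defect.

## Problem sizes in the test suite

Replicate-based checks run 20 seeded replicates of the default 324-
sample study (recovery at noise 0.05 mg/L; stage separation with γ ≡ 0)
and 20 replicates of the 12-wetland importance scenario; the noise
sweep uses σ ∈ {0.4, 0.2, 0.1, 0.05} on one fixed scene. CLI tests use
a miniature 60×60 grid over 6 months. The full suite runs in a few
minutes on one CPU.

## Known limitations

- No uncertainty quantification (prediction intervals) on maps.
- Simple random hold-out; spatial or grouped cross-validation is not
  implemented, so metrics can be optimistic under spatial
  autocorrelation shared between partitions.
- One shared CRS; no reprojection, cloud masking, or orbit bookkeeping
  (SAR passes are assumed pre-filtered to one orbital direction).
- The pooled model treats quarters as exchangeable categories; trends
  across years are not modelled by any feature.
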