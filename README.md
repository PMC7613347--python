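# prosailgpr

Hybrid radiative-transfer / machine-learning retrieval of rice leaf
area index (LAI) from Sentinel-2 band reflectance.

Monitoring LAI through the growth phases of irrigated rice (vegetative,
reproductive, ripening) is central to yield forecasting and irrigation/
fertilizer management, but field LAI campaigns are expensive. The
hybrid strategy implemented here needs no field training data: a
physical canopy reflectance model simulates what the satellite would
see across the plausible range of canopy states, and a probabilistic
regression is trained on those simulations to invert real imagery —
returning both an LAI estimate and a per-pixel uncertainty.

The package is aimed at quantitative remote-sensing practitioners and
agronomists working with Sentinel-2 Level-2A surface reflectance over
rice (or structurally similar cereal canopies).

## What it does

1. **Leaf optics (PROSPECT-4).** Directional-hemispherical leaf
   reflectance and transmittance over 400–2500 nm from four parameters:
   structure index N, chlorophyll Cab (µg/cm²), water Cw (cm), dry
   matter Cm (g/cm²), via the plate model with Stokes' extension to a
   real-valued number of plates.
2. **Canopy reflectance (4SAIL).** Top-of-canopy bidirectional
   reflectance of a turbid-medium canopy: LAI, mean leaf angle (ALA,
   ellipsoidal distribution), hot-spot parameter, diffuse fraction,
   Lambertian soil background and sun–target–sensor geometry.
3. **Training database.** 2000 parameter vectors (LAI ~ truncated
   𝒩(5.5, 4²) on [0.2, 9]; Cab ~ truncated 𝒩(35, 20²) on [10, 55];
   N, Cm, Cw, ALA, soil scaling and relative azimuth uniform), soil
   backgrounds from a wet/dry spectral library, spectra resampled to
   the ten Sentinel-2 20 m bands (B2–B8A, B11, B12) and perturbed with
   the four-component Gaussian noise model
   R\*(b) = R(b)(1 + md(b) + mi) + ad(b) + ai,
   with md, mi ~ 𝒩(0, (2 %)²) and ad, ai ~ 𝒩(0, 0.01²).
4. **Inversion (ARD-GPR).** Gaussian process regression
   ŷ(x) = Σᵢ aᵢ K(xᵢ, x) + α₀ with the automatic-relevance-determination
   squared-exponential kernel
   K(x, x′) = ν·exp(−Σ_b (x_b − x′_b)²/(2σ_b²)) + σ_n²δ,
   hyperparameters fitted by marginal-likelihood maximization. The
   per-band length-scales σ_b double as a band-relevance ranking; the
   posterior variance gives per-pixel uncertainty.
5. **Products.** LAI + uncertainty GeoTIFFs from reflectance rasters,
   per-plot phenology profiles on a days-after-sowing axis with
   vegetative / reproductive / ripening phase labels, and R²/RMSE
   validation reports. A synthetic-data module generates soil
   libraries, treatment-driven LAI trajectories (3 nitrogen rates ×
   3 irrigation regimes × 3 blocks = 27 plots) and fully rendered
   campaigns for end-to-end testing.

## Worked example

```python
from prosailgpr import gpr
from prosailgpr.lut import build_training_lut

clean, noisy = build_training_lut(n_samples=2000, seed=1)
report, _ = gpr.cross_validate(noisy.spectra, noisy.lai, k=10, seed=1,
                               restarts=2)
print(f"R2={report.r2:.3f} RMSE={report.rmse:.3f}")

model = gpr.fit(noisy.spectra, noisy.lai, restarts=2, seed=1,
                band_names=tuple(noisy.band_set.names))
print(gpr.band_relevance(model)[:4])
```

prints (about a minute for the cross-validation):

```
R2=0.847 RMSE=0.926
[('B7', 3.01), ('B6', 3.01), ('B8A', 3.03), ('B11', 4.15)]
```

The cross-validated model explains ~85 % of the LAI variance in the
noisy simulated database with an error just under 1 LAI unit, and the
most relevant bands are the red-edge (B6, B7), narrow NIR (B8A) and
SWIR (B11) channels — the blue/green visible bands contribute least,
as expected for an LAI signal dominated by canopy structure rather
than pigments.

The same pipeline is scriptable from the shell:

```bash
prosailgpr --seed 1 simulate-lut --out runs/lut
prosailgpr --seed 1 train --lut runs/lut/noisy --out runs/model
prosailgpr invert --model runs/model --image scene.tif \
    --out-lai lai.tif --out-sd lai_sd.tif
prosailgpr profiles --maps 2018-02-24=lai.tif --plots plots.geojson \
    --sowing-date 2017-12-24 --out profiles.csv
```

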