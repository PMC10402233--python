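# phossum

Analysis tools for **phosphene drawings** from epiretinal prosthesis
psychophysics.  Blind participants implanted with an Argus II array draw the
percepts ("phosphenes") elicited by stimulating one or two electrodes; the
scientific questions are whether paired-electrode percepts are the **linear
summation** of their single-electrode building blocks, and whether the
number of perceived phosphenes is governed by the **axon map** of the
retina — the distance *between* the stimulated nerve-fiber bundles rather
than the distance on the retinal surface.

The package provides:

- **Shape descriptors** (`phossum.drawing`): validated binary drawings and
  moment-based per-phosphene descriptors — area `A = M00`, centroid
  `(M10/M00, M01/M00)`, major/minor axis lengths `4·√λ` from the
  eigenvalues λ of the central-moment matrix
  `[[μ′20, μ′11], [μ′11, μ′02]]`, and the weighted border-pixel perimeter —
  plus the small-region prevalence filter and center-of-mass mean images.
- **Retinal geometry** (`phossum.geometry`): Argus II implant placement
  (6×10 grid, 575 µm pitch), the Jansonius nerve-fiber-bundle trajectory
  family `φ(r) = φ0 + b(r−r0)^c` about the optic disc, and the axonal
  decomposition of electrode-pair separations into **between-axon** and
  **along-axon** distances, with electrode–fovea distance (EFD) and the
  OCT shadow-width pixel→µm conversion.
- **Preprocessing** (`phossum.preprocessing`): standard-pulse
  normalization (2× threshold, 20 Hz), trial averaging, `1/n` power
  transforms (n = 3 for area, 2 otherwise), 2.5 SD outlier removal, and
  z-scored predictors assembled into a tidy design table.
- **Statistics** (`phossum.stats`): statsmodels-style models —
  `StandardizedOLS` (standardized β + partial correlations),
  `SummationRegression` (no-intercept slope of paired descriptors on
  summed singles), `MixedShapeModel` (participant random intercept) — plus
  Bonferroni correction, VIF, Welch's t from summary statistics, AIC/BIC
  model comparison with qualitative evidence bands, and Q-Q normality.
- **Synthetic data** (`phossum.synthetic`): a generator that renders
  drawings with the assumed statistical structure (axon-aligned elongated
  percepts, amplitude→size, frequency/eccentricity→elongation, sub-unit
  paired gain, participant drawing noise) so the entire pipeline is
  testable without clinical data.

## Worked example

```python
from phossum import AxonMapModel, GeneratorConfig, run_pipeline, sample_dataset

model = AxonMapModel()
cfg = GeneratorConfig(n_electrodes=8, trials_per_stim=3, n_pairs=10)
dataset = sample_dataset(cfg, seed=11, model=model)
result = run_pipeline(dataset.trials, dataset.layouts, model=model)

print(result.summation_fits["area"].summary())
print(result.count_comparison.summary())
```

```
paired area ~ 0 + sum of singles  (n = 25)
AIC = -9.715   BIC = -7.277
predictor                   beta         r           p     p(bonf)
sum_of_singles            0.6508    0.8279    5.28e-23    5.28e-23
paired percepts larger than the single-electrode average but smaller than their sum (0.5 < slope < 1)

AIC: A = 67.159, B = 65.946, dAIC = 1.213 (both supported)
BIC: A = 73.253, B = 72.040, dBIC = 1.213 (both supported)
preferred model: tie
```

The summation slope 0.65 says a paired percept's total area is about
two-thirds of the sum of its two single-electrode percepts — larger than
their average, smaller than their sum — with the simulated participants'
gains in the 0.58–0.73 range.  The second block compares predicting the
phosphene count from the along-axon distance (model A) versus the
between-axon distance (model B); at this miniature problem size the AIC
difference of 1.2 favors B but stays below the decision band, which is why
the model comparison is run over many seeded replicates (see below), where
B wins essentially always.

There is also a CLI mirroring the pipeline stages:

```bash
phossum simulate --out data/ --seed 42
phossum shapes --trials data/trials.csv --out shapes.csv
phossum distances --placement data/placement.yaml --pairs pairs.csv --out dist.csv
phossum prepare --shapes shapes.csv --distances dist.csv --out design.csv
phossum fit --data data/ --out results/
```

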