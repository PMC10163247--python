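# treecloud

Recognition of two deciduous tree species (*Quercus acutissima* vs
*Robinia pseudoacacia* type classes) from 4-band multispectral reflectance
using **cloud-model classifiers**, with spectral-index construction and
screening, GLCM texture features, and an RBF-SVM baseline — packaged as a
reusable, fully tested pipeline driven by a synthetic two-species scene
generator.

## The problem and the method

Mapping deciduous species from high-resolution multispectral imagery
(4 bands: blue 0.45–0.52, green 0.52–0.59, red 0.63–0.69, NIR
0.77–0.89 µm) is hard because class spectra overlap and vary with
phenology. The pipeline here:

1. **Spectral indices.** 22 formula categories over band reflectances
   R_i (single-band transforms such as R_i², ln R_i; two-band combinations
   such as R_i − R_j, R_i/R_j, (R_i − R_j)/(R_i + R_j), ln R_i/(R_i − R_j))
   are enumerated over all band combinations, giving **166 distinct
   indices** after algebraic deduplication.
2. **Screening.** Each index is scored against the binary species label
   with the point-biserial correlation r (a univariate logistic-regression
   scoring, sign(β)·√(pseudo-R²), is available as an alternative); the
   top-10 |r| indices are the *sensitive* indices, with strength categories
   micro / real / significant / high at |r| = 0.30 / 0.50 / 0.80.
3. **Cloud model.** For each species and feature, the *backward cloud
   generator* estimates three digital characteristics from the modelling
   samples x₁…xₙ:

       Ex = x̄,   En = √(π/2) · (1/n) Σ|xᵢ − x̄|,   He = √(S² − En²)

   (S² the unbiased sample variance; He clamped at 0). The *X-conditional
   generator* converts them into a membership degree for a query value x₀,
   CT(x₀) = exp(−(x₀ − Ex)²/(2 En′²)) with En′ ~ |N(En, He²)| (stochastic
   mode) or En′ = En (deterministic mode, the default). Multi-dimensional
   memberships multiply across features, and the *maximum determination*
   rule assigns each pixel to the species with the largest membership.
4. **Texture.** Eight Haralick parameters (mean, variance, homogeneity,
   contrast, dissimilarity, entropy, second moment, correlation) from
   gray-level co-occurrence matrices over 3×3 / 5×5 / 7×7 sliding windows
   feed the same cloud classifiers.
5. **Baseline.** A C-SVC RBF support vector machine (gamma 0.5, C 1) on
   standardized features, 1-D per sensitive index and 3-D on the optimal
   triple.

Samples are split 2/3 modelling / 1/3 validation by equidistant sampling
(every third pixel to validation); the three features for the 3-D models
are chosen by 1-D validation accuracy.

Because the original satellite scenes are not public, the package ships a
**synthetic scene generator** with two phenological presets (`autumn`,
`winter`) — truncated-normal class-conditional band reflectances plus
spatially correlated within-class texture — that reproduce the structure
the method assumes: winter classes more separable than autumn, separation
concentrated in the red/NIR bands, class-specific spatial autocorrelation.

## Worked example

```python
from treecloud import backward_generate, membership_1d

p = backward_generate([0, 1, 2, 3, 4])
print(f"Ex={p.Ex:.5f}  En={p.En:.5f}  He={p.He:.5f}")
print(f"membership at x0=3: {membership_1d(p, 3.0):.5f}")
```

prints

```
Ex=2.00000  En=1.50398  He=0.48791
membership at x0=3: 0.80168
```

Ex is the class prototype (the sample mean 2), En ≈ 1.504 measures the
concept's spread, He ≈ 0.488 the uncertainty of that spread; a pixel at
x₀ = 3 belongs to this concept with membership degree 0.80.

Running the full study on the winter preset (1,000 pixels per class,
96×96 raster):

```python
from treecloud.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(preset="winter", n_per_class=1000,
                                  raster_shape=(96, 96), seed=1))
print(res.sensitive.head(3).to_string(index=False))
print(res.comparison.groupby(["block", "model", "dimension"])["overall_pct"].max())
```

```
feature_id         r category  n_used
  F9_i3_j4  0.895926     high    1334
  F9_i4_j3 -0.895926     high    1334
 F19_i4_j3 -0.895552     high    1334

block     model  dimension
spectral  cloud  1            97.45
                 3            97.30
          svm    1            97.90
                 3            97.00
texture   cloud  1            91.50
                 3            92.06
```

The most sensitive indices are red/NIR difference forms (`F9_i4_j3` is
R₄ − R₃), as expected when class separation sits in bands 3–4; the best
1-D cloud model recognizes 97.45% of validation pixels, the 3-D model is
statistically indistinguishable from it, and spectral features outperform
texture features.

The same stages are available from the shell:

```
treecloud simulate --preset winter --n-per-class 1000 --raster 96x96 --seed 1 --out sim
treecloud indices --samples sim/samples.csv --out features.csv
treecloud screen --features features.csv --k 10 --out sensitive.csv
treecloud run --preset winter --seed 1 --out run_out
```

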