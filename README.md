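# wcbaseg

Lung tumor segmentation in CT slices with a **texture-dictionary
deformable model** whose curve update is driven by a **water-cycle/bat
(WCBA) hybrid optimizer**, plus the full pipeline around it: median-filter
preprocessing, Bayesian fuzzy clustering of the lung lobes, and overlap
metrics. A seeded phantom generator provides lung-like test images with
exact ground truth, so the whole pipeline is exercisable without any
clinical data.

## Who this is for

Researchers in medical image analysis who want a reproducible, pure-Python
reference implementation of dictionary-based level-set segmentation and of
the water-cycle/bat metaheuristic — either to study the methods themselves
or to use the pieces (patch dictionaries, label/probability transforms,
the optimizer) in their own pipelines.

## The model

**Level set.** The tumor boundary is the zero set of a field φ with the
inside region at φ < 0. A two-mean (Chan–Vese-type) warm-up evolves

    ∂φ/∂t = δ_ε(φ) [ (t_out − t_in)(2J − t_out − t_in) + w·κ ],

where `t_in`, `t_out` are the region mean intensities of image `J`,
`κ = div(∇φ/‖∇φ‖)` the curvature and `δ_ε` a smoothed Dirac factor.

**Texture dictionary.** All T×T patches are clustered by Euclidean
k-means into d atoms; a sparse binary biadjacency matrix `G`
(pixels × d·T² dictionary pixels) links each pixel to the dictionary
pixels of every patch covering it. Each iteration, the current labels
are pushed through `G` to per-dictionary-pixel frequencies `g`,
balanced for region area (`g̃ ∝ g_x/|ψ_x|`), pulled back as per-pixel
probabilities `E` by averaging, contrast-transformed to
`Ẽ_x = e_x/(e_x + max_{n≠x} e_n)`, and the curve moves with speed

    ∂φ_x/∂t = (1/2 − Ẽ_x + w·κ) ‖∇φ_x‖ .

**WCBA curve update.** The hybrid optimizer ranks a raindrop population
into sea/rivers/streams, blends the river flow with a bat-algorithm
frequency `l_b = l_min + (l_max − l_min)k`, and re-scatters members by
evaporation/raining with a decaying threshold `B_max`. The same
frequency/velocity blend, applied to φ as a single entity, gives the
stochastic curve update (`mode="wcba"`); `mode="plain"` is the explicit
Euler step.

**Metrics.** Confusion counts (A, B, K, I), accuracy `(A+B)/(A+B+K+I)`,
Jaccard `|M∩N|/|M∪N|` and Dice `2|Y∩Z|/(|Y|+|Z|)`.

## Worked example

```bash
wcbaseg pipeline --phantom easy --seed 1 --out demo/
```

writes the filtered image, lobe mask and tumor mask to `demo/` and prints

```
input: shape=(128, 128), seed=1 [0.00s]
median_filter: window=3, border=replicate [0.00s]
lobes: clusters=3, sweeps=50, smooth_sigma=2.0, prototypes=[0.06, 0.277, 0.518] [0.13s]
segment: mode=plain, patch_size=9, n_atoms=50, iterations=85, converged=True [0.66s]
tumor: accuracy=0.9973 dice=0.9794 jaccard=0.9597
```

The three prototypes are the recovered intensity classes (air background,
lung parenchyma, soft tissue); the final line compares the predicted tumor
mask with the phantom's exact ground truth: 97.9% Dice overlap here.

The same from Python:

```python
from wcbaseg import phantom, pipeline

spec, _ = phantom.default_suite(1)[0]          # "easy" suite member
result = pipeline.run_pipeline(spec, pipeline.PipelineConfig(seed=1))
print(result.tumor_metrics.dice)               # 0.9794...
```

Other entry points: `wcbaseg optimize --objective sphere` runs the
standalone optimizer and writes a convergence trace;
`wcbaseg benchmark --n-phantoms 5 --out bench.csv` emits a per-phantom
metrics table with a trailing mean row; `wcbaseg phantom` renders a
suite member with its ground-truth masks.

## Known limitation

On purely texture-defined contrast (tumor and parenchyma at identical
mean intensity) the dictionary's label/probability averaging blurs the
decision boundary over roughly the patch radius; the converged boundary
sits a 1.5–2 px shell inside the true one, which costs about 0.1 Dice at
a realistic nodule size. Intensity contrast sharpens the atoms and
removes the effect; see `docs/methods.md` for the analysis.
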