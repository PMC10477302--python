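# fuzzykld

Fuzzy-parameter probability distributions, the fuzzy extended
Kullback–Leibler divergence, and a leaf-image classification pipeline
built on them.

## The problem

Fitting a parametric distribution to a sample ends with a point estimate
θ̂, but with incomplete or noisy data (sub-samples of a mixture, image
descriptors pooled across photographs) the plausible parameter values
form a region around θ̂, not a point.  `fuzzykld` represents each
parameter as a **fuzzy number**: a membership function ξ(θ) ∈ [0, 1]
whose δ-cuts C_δ = {θ : ξ(θ) ≥ δ} are nested intervals.  The membership
function is obtained from Bayesian statistics — the posterior density
f(θ) is rescaled by its mode,

    f̃(θ) = f(θ) / f(θ_Mode),

so that its maximum is exactly 1 and its superlevel sets act as δ-cuts.

Distributions with fuzzy parameters are compared with the **fuzzy
extended Kullback–Leibler divergence**.  For crisp models the package
provides the classical divergence D(f‖g) = ∫ f log(f/g) dx and a
discretized *extended* divergence against the empirical distribution of
a sorted sample x₁ ≤ … ≤ x_n over the consecutive intervals
(x_{t−1}, x_t]:

    KLD(f‖emp) = Σ_t P_f((x_{t−1}, x_t]) · log ( P_f / P_emp ),

with x₀ = min(x) − ε.  When the parameters are fuzzy, the divergence
becomes a fuzzy number itself: its δ-cut is the [min, max] of the
divergence as the parameters range over the Cartesian box of their
δ-cuts.

The package exercises this machinery end to end as a plant-leaf
classifier: HOG and LBP texture descriptors are extracted per image,
each class's pooled descriptor values are fitted with the best family
(smallest extended divergence among normal/gamma/exponential/uniform/
lognormal), the fitted parameters are fuzzified through their grid
posteriors, and a query image is assigned to the class whose fuzzy
model is nearest (smallest defuzzified fuzzy divergence) to the query's
empirical descriptor distribution.  A Gaussian-mixture EM module covers
the mixture-decomposition stage for multimodal data, and a synthetic
leaf-image generator stands in for photographic data so that every
stage is testable offline.

## Worked example

```python
import numpy as np
import fuzzykld as fk

# 1. recover a two-component normal mixture N(-1, 1²) ⊕ N(2, 2²)
#    mixed 90/10, from 20 000 draws
x, _ = fk.gen_mixture_sample(fk.normal_mixture_spec(0.9), 20_000, seed=7)
params = fk.fit_em(x, 2, seed=7, restarts=10).params
print(np.round(params.weights, 3))    # [0.884 0.116]
print(np.round(params.means, 3))      # [-1.016  1.665]

# 2. fit a fuzzy gamma distribution to 50 000 G(3; 2) draws
g = fk.make_distribution("gamma", {"shape": 3, "scale": 2}).sample(50_000, seed=7)
fd = fk.fit_fuzzy_distribution(g)
print(fd.family)                                  # gamma
(a, b), = fd.params["shape"].delta_cut(0.05)
print(round(a, 3), round(b, 3))                   # 2.969 3.056

# 3. classify synthetic leaves by their descriptor distributions
specs = fk.default_leaf_classes()
feats = lambda im: fk.concat_features(fk.hog_descriptor(im.astype(float)),
                                      fk.lbp_descriptor(im.astype(float)))
imgs, labels = fk.gen_leaf_images(specs, 10, seed=1)
groups = {}
for im, lab in zip(imgs, labels):
    groups.setdefault(lab, []).append(feats(im))
models = fk.train(groups)
test_imgs, test_labels = fk.gen_leaf_images(specs, 5, seed=2)
acc, confusion = fk.evaluate(
    [(feats(im), lab) for im, lab in zip(test_imgs, test_labels)], models)
print(acc)                                        # 1.0
```

The recovered mixture weights (88.4 / 11.6 %) and component means
(−1.02, 1.67) sit at sampling-error distance from the generating values;
the δ=0.05 cut [2.97, 3.06] of the fuzzy gamma shape brackets the true
shape 3 and shrinks as the sample grows; and the four synthetic leaf
classes are separated perfectly on this small test split.

A `fuzzykld` console script exposes the same steps
(`fit-mixture`, `fit-family`, `kld`, `train`, `classify`,
`simulate-mixture`, `simulate-leaves`); run `fuzzykld --help`.

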