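# mrmrkit

Minimum-redundancy maximum-relevance (mRMR) feature selection with a
cross-validation stopping rule, confusion-matrix evaluation, and a
morphological region-of-interest (ROI) preprocessing chain for grayscale
medical-style images — plus seeded synthetic benchmarks with planted ground
truth so everything is testable offline.

## Who this is for

Feature tables extracted from images (for example the activations of a deep
network's final layer over lung-CT slices) routinely contain hundreds of
columns, many of which are irrelevant to the diagnostic label or near-copies
of one another. `mrmrkit` selects a small informative subset, scores it with
the standard confusion-matrix metrics, and provides the image-side ROI
masking step that narrows feature extraction to the anatomy of interest.

## The method

For a feature subset S and class label c, with mutual information I
estimated in bits from discretized joint histograms:

- **Max-Relevance** D(S, c) = (1/|S|) Σ_{x_i ∈ S} I(x_i; c)
- **Min-Redundancy** R(S) = (1/|S|²) Σ_{x_i, x_j ∈ S} I(x_i; x_j)
- combined objective Φ = D − R, maximized incrementally: the first pick is
  argmax I(x_j; c); each later step adds

  argmax_{x_j ∉ S} [ I(x_j; c) − (1/|S|) Σ_{x_i ∈ S} I(x_i; x_j) ]

After each addition, the stratified k-fold CV accuracy of a classifier
(Gaussian naive Bayes by default, pluggable) on S is compared with that of
S without its newest member on the *same* fold partition; a drop terminates
selection and discards the newest member.

Evaluation uses AC = (TP+TN)/N, PR = TP/(TP+FP), RE = TP/(TP+FN),
F1 = 2·PR·RE/(PR+RE) = 2TP/(FN+2TP+FP), FPR = FP/(FP+TN), via stratified
k-fold CV or a stratified 70/30 holdout.

The image chain — Otsu binarization, erosion, median filtering, dilation,
largest-component contour extraction, flood-filling of interior holes —
yields a binary ROI mask and the masked image, and an S×S grid partition
(a 640×640 image with S = 8 tiles into 64 cells of 80×80 pixels).

## Worked example

```sh
mrmrkit --seed 42 simulate table --n 500 --relevant 3 --copies 1 --noise 10 \
        --out T.csv --truth roles.json
mrmrkit --seed 42 select --input T.csv --folds 10 --output report.json
mrmrkit --seed 42 evaluate --input T.csv --subset report.json --holdout 0.7 \
        --output metrics.json
```

The simulated table has 3 informative ("relevant") columns at indices 0, 2, 4,
one correlated copy of each (ρ = 0.95) at indices 1, 3, 5, and 10 pure-noise
columns. `select` prints

```
selected 3 features (accuracy_drop): [4, 2, 0]
```

— exactly one member of each planted group, no copies, no noise; selection
stopped when adding a fourth feature lowered the paired 10-fold CV accuracy.
The per-step trace in `report.json`:

```
k=1 chosen= 4 J=0.3816 D=0.3816 R=3.3219 Phi=-2.9404 cv_acc=0.7920
k=2 chosen= 2 J=0.0858 D=0.3414 R=1.7687 Phi=-1.4273 cv_acc=0.8700
k=3 chosen= 0 J=0.0973 D=0.3419 R=1.2644 Phi=-0.9225 cv_acc=0.9260
```

J is the incremental criterion of the chosen feature (its relevance alone at
k=1); D, R and Φ = D − R describe the subset after each addition (R includes
the diagonal entropy terms, hence its scale); cv_acc is the stopping signal.
`evaluate` then prints

```
accuracy 0.9067 on 3 features
```

with per-class and macro AC/PR/RE/F1/FPR in `metrics.json`
(macro F1 ≈ 0.907, macro FPR ≈ 0.093 for this seed).

The image side works the same way:

```sh
mrmrkit --seed 1 simulate phantom --out img.png --roi roi.png
mrmrkit preprocess --input img.png --output-mask mask.png --grid 8 --grid-json cells.json
```

`mask.png` recovers the two elliptical lung fields of the phantom
(intersection-over-union vs the ground-truth mask > 0.99 at noise σ = 8) and
`cells.json` lists the 64 half-open 80×80 cell extents.

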