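# pancedge

Quantitative edge-irregularity scoring of parenchymal organ borders on CT
region-of-interest images, built around the **pancreatic margin score (PMS)**.

## The problem

The healthy pancreas has a lobulated, nodular margin against the surrounding
visceral fat. Pancreatic ductal adenocarcinoma, wrapped in a dense
desmoplastic stroma, presents an abnormally *smooth* margin. Quantifying the
irregularity of a short border fragment inside a fixed-size box therefore
separates tumor-bearing from healthy edge segments: low score → smooth edge →
tumor-like; high score → nodular edge → healthy parenchyma. The same idea
underlies the liver surface nodularity (LSN) score used for fibrosis staging.

`pancedge` is for researchers in quantitative imaging who want a transparent,
testable implementation of this measurement plus the statistics that go with
a paired tumor-vs-healthy study design.

## The measurement

Inside a constant-size ROI (default 40 × 40 px):

1. **Canny edge detection** — Gaussian smoothing (σ = 1 px), Sobel gradients,
   non-maximum suppression along the quantized gradient direction, hysteresis
   linking. Thresholds are quantiles of the ROI's nonzero gradient magnitudes
   (high = 0.90 quantile, low = 0.4 × high), so the edge map is exactly
   invariant under affine intensity rescaling.
2. **Border selection** — the graph-geodesic between the two farthest pixels
   of the largest 8-connected edge component, found by double BFS.
3. **Parameterization** — principal-axis coordinates: *u* along the border,
   *v* perpendicular to it.
4. **Average boundary line** — a stiff least-squares cubic spline v̂(u) with
   interior knots every ROI-width/4 pixels absorbs organ-scale curvature
   while leaving nodularity in the residuals.
5. **Score** — PMS = √(mean (v − v̂(u))²), in pixels.

A threshold on the score classifies segments (`classify`, published value
0.6855 px: *below* = cancer); `paired_t_test`, `roc_curve` and
`cohort_report` reproduce the paired-study statistics (two-sided paired *t*,
trapezoidal AUROC with the Mann-Whitney identity, Youden-optimal operating
point).

A **phantom generator** renders two-phase parenchyma/fat step images whose
border is a known base curve plus band-limited sinusoidal roughness of exact
RMS amplitude, with anti-aliased rasterization, Gaussian blur and noise —
giving every pipeline stage an exact ground-truth oracle.

## Worked example

Simulate a small paired cohort (each image holds a smooth tumor-like phantom
on the left, a rough healthy-like phantom on the right), then score one box
of each kind:

```bash
$ pancedge simulate --out-dir demo --n 4 --seed 7
demo/manifest.csv

$ pancedge score --image demo/P001.png --roi "12,12,40,40"    # tumor-side box
{
  "knots_used": 3,
  "n_points": 40,
  "params_fingerprint": "eddca3d37e25f6f7",
  "pms": 0.4657165629467672,
  "roi_label": ""
}

$ pancedge score --image demo/P001.png --roi "12,76,40,40"    # healthy-side box
{
  ...
  "pms": 0.8043582694952816
}
```

The smooth border scores 0.47 px, the rough one 0.80 px — the tumor-like
segment sits below the healthy one, as the biology predicts. Batch-score the
whole manifest and summarize:

```bash
$ pancedge batch --manifest demo/manifest.csv --out-dir demo/out
$ python -c "import json; print(json.load(open('demo/out/summary.json')))"
# n=4, tumor_mean=0.463, healthy_mean=0.883, auc=1.0,
# youden_threshold=0.636, p=0.0079, youden_sens=1.0, youden_spec=1.0
```

With only 4 pairs the groups already separate perfectly (AUROC 1.0) and the
Youden threshold (0.636 px) falls between the group means; the paired *t*-test
p-value of 0.008 reflects the small sample.

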