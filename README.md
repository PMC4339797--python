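# smfish3d

Quantification of single-molecule FISH (smFISH) dots in 3D confocal image
stacks of whole-mount samples — spot enhancement, per-cell masking,
threshold-sweep transcript counting, dot-intensity and conglomerate analysis,
two-channel detection efficiency, and transcript-count distribution model
selection.

## The problem

In smFISH, each mRNA molecule is bound by ~30–50 short fluorescently labeled
oligonucleotide probes and appears as one diffraction-limited dot in a
confocal z-stack.  Counting dots per cell gives absolute transcript numbers
in single cells — provided the dots can be separated from autofluorescent
background, assigned to cells, and counted at a threshold that is neither
drowning in noise nor eroding real signals.  This package implements that
quantification pipeline for anisotropic confocal grids (default voxel
0.04 × 0.04 × 0.3 µm) and ships a synthetic-stack generator with full ground
truth, so every stage is testable without any microscope data.

## The method

1. **Spot enhancement.**  The raw stack *I* is convolved with a negated 3D
   Laplacian-of-Gaussian kernel, *F = −(∇²G<sub>σ</sub>) ∗ I*, with σ
   specified in µm and converted per axis to voxels so the kernel is
   isotropic in physical space.  The kernel sums to zero (no DC response),
   so smooth background vanishes and dots become positive peaks.
2. **Normalization.**  Negative responses are clipped and the stack is
   divided by its global maximum, putting all equally filtered images on a
   common [0, 1] scale.
3. **Masking.**  Per-slice cell-border polygons (JSON) are rasterized into a
   3D binary mask; voxels outside the border are set to 0.
4. **Threshold sweep and plateau counting.**  The masked stack is binarized
   at 100 uniform thresholds *t<sub>k</sub> = k/100*; at each, connected
   components (26-connectivity) are counted.  The transcript number is the
   count on the widest stable plateau of the threshold → count curve
   (width measured in log-threshold; manual selection is also supported).
5. **Dot intensity and conglomerates.**  At a fixed threshold of 0.25, each
   dot's intensity is the mean of its member voxels.  Dots at ~2× the modal
   intensity are flagged as conglomerates (two unresolved transcripts).
6. **Two-channel efficiency.**  Dots detected in two spectral channels are
   matched greedily one-to-one within a radius; efficiency A→B is the
   fraction of A dots with a matched B dot.
7. **Distribution model selection.**  Per-cell counts are fitted by maximum
   likelihood to normal, gamma, logistic, Weibull and Poisson families and
   screened with a one-sample Kolmogorov–Smirnov test at α = 0.05; the
   non-rejected families form the verdict per gene.  A ΔΔCt helper computes
   relative qPCR expression, *ratio = E<sup>−ΔΔCt</sup>*.

Probe-set arithmetic is included: ⌊(L + g)/(p + g)⌋ probes of length *p* with
minimum gap *g* fit on a transcript of length *L*.

## Worked example

Simulate a small two-cell stack, filter it, and count transcripts per cell:

```sh
smfish3d simulate --out-dir demo --shape 16 160 160 \
    --n-cells 2 --spots-per-cell 8 --seed 3
smfish3d filter demo/channel_a.tif demo/filtered.tif
smfish3d count demo/filtered.tif demo/rois.json demo/counts
```

which prints

```
simulated 16 spots in 2 cells -> demo
filtered demo/channel_a.tif -> demo/filtered.tif
cell_01: 8 transcripts @ t=0.39
cell_02: 8 transcripts @ t=0.38
```

Both cells truly contain 8 transcripts; the plateau of the threshold sweep
sits at 0.38–0.39 on the normalized intensity scale and recovers the exact
count for each cell.  `demo/counts/cell_counts.csv` and `spots.csv` hold the
per-cell counts and per-dot centroids/intensities.  Probe arithmetic:

```
$ smfish3d tile --length 720
32 probes of 20 nt (gap ≥ 2) fit on 720 nt
```

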