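# chorosps

Supervised superpixel segmentation of the **choroid** in OCT B-scans, with
quantitative metrics and cohort statistics.

The choroid — the vascular layer between the retinal pigment epithelium
(RPE) and the sclera — shows structural changes in neurodegenerative
disease. Its boundary in an OCT B-scan is irregular and poorly served by
single-point thickness measurements. This package instead delimits the
whole choroidal cross-section by clustering the B-scan into superpixels
(a grayscale SLIC: grid-seeded local k-means in joint intensity/position
space) and grouping the superpixels that cover the choroid, either
interactively (an expert picks numbered superpixels from an overlay) or
by a band-criteria surrogate for batch runs. Three metrics summarize the
segmented region of one eye:

* **CA** — choroidal area: the pixel count of the region (px²);
* **COID** — choroidal optical image density: the mean 8-bit gray level
  over the region;
* **CD** — choroidal density: the ratio CA / COID (dimensionless).

Groups of eyes (e.g. controls vs. multiple sclerosis vs. Parkinson
disease) are compared metric-by-metric with a one-way ANOVA and pairwise
Welch t-tests under Bonferroni correction.

A seeded synthetic B-scan generator (layered retina, vessel lumina,
multiplicative gamma speckle, periodic stripe artifact, retinal tilt)
provides ground-truth masks, so the whole chain is testable without
clinical images.

## Worked example

Segment a synthetic speckled B-scan (496 × 496 px, 8 vessel lumina,
8-look speckle) with the recommended analysis configuration:

```python
import chorosps as c

scan = c.generate_bscan(c.SyntheticSpec(size=496, vessel_count=8,
                                        speckle_looks=8.0, seed=1))
cfg = c.PipelineConfig(
    superpixel=c.SuperpixelParams(n_superpixels=600, compactness=30.0),
    selection=c.SelectionConfig(mode="band", intensity_range=(40, 80),
                                depth_range=(5, 200)),
)
res = c.process_image(scan.image, cfg)
print("metrics:", res.metrics)
print("true CA:", scan.true_ca, "true COID:", round(scan.true_coid, 2))
```

prints

```
metrics: CA=49745 px^2, COID=59.93, CD=830.08
true CA: 49104 true COID: 59.06
```

The recovered area differs from the generator's ground truth by 1.3% and
the optical density by 0.9 gray levels: the band-criteria selection found
the choroid band without supervision. For a real device export, published
per-eye values behave the same way — an eye with CA = 154 940 px² and
COID = 51.22 has

```python
>>> c.choroid_density(154940, 51.22)
3024.990238188208
```

## Command line

```sh
chorosps synth -n 5 --seed 1 --output-dir scans/      # synthetic scans + truth
chorosps process scans/*.png --output-dir out/        # metrics.csv + sidecars
chorosps stats cohort_metrics.csv --output-dir stats/ # ANOVA + post hoc report
```

`process` accepts `--select-labels 12,13,27` for the supervised protocol
(pick label numbers from the overlay written by `--save-intermediates`),
or uses the band-criteria surrogate from the YAML config.

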