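# polarcap

Quantification of protein distributions on the periphery of single yeast
cells, spatially registered to the polar cap.

During the pheromone response, budding yeast concentrate polarity proteins
(active Cdc42, Bem1) at a cortical site — the polar cap — and the spatial
arrangement of signaling proteins such as the RGS Sst2 or the MAPK Fus3
around that site encodes how the pathway is regulated in space. `polarcap`
implements the standard analysis for two-channel time-lapse data of such
cells:

1. **Periphery line-scan.** The cell boundary is traced from a single-cell
   mask (sub-pixel iso-contour at 0.5, lightly smoothed) and the intensity
   of each channel is measured along it with a 5-pixel-wide band averaged
   along the local normal, giving an intensity profile per frame and a
   position × time kymograph per cell.
2. **Registration to the polar cap.** Each signal profile is circularly
   shifted so the reference-channel peak (peak Bem1) sits at the center,
   then min-subtracted and normalized to sum to 1. The values are the
   *fraction of protein* at each signed distance (µm) from the cap center.
3. **Nuclear masking ("Nucleinator").** For nucleo-cytoplasmic markers,
   pixels above the per-cell mean + 1 SD forming 8-connected objects larger
   than 25 px are masked, grown by 1 px, and replaced with the cell's mean
   fluorescence before the line-scan, removing spurious peripheral spikes
   caused by nuclei near the cell edge.
4. **Extrema statistics.** Per frame, the global maximum and minimum of the
   registered profile are located; their distances from the cap are
   summarized as histograms, empirical cumulative distance curves, and
   quantile readouts (distance containing 50% of maxima / 25% of minima).
5. **Inference.** Cohort averages carry 95% percentile-bootstrap bands
   (10,000 resamplings, resampling cells); strains are compared
   position-by-position with a sliding one-way ANOVA + Tukey HSD +
   Benjamini–Hochberg FDR, and distance distributions with two-sample
   Kolmogorov–Smirnov tests. Phenotype frequencies get bootstrapped CIs and
   a bootstrap difference-in-means test; gradient tracking is scored by the
   cosine of orientation between growth displacement and the gradient axis.

Because raw live-cell imaging data of this kind is rarely deposited, the
package ships a first-class synthetic-scene generator
(`polarcap.scenes`): circular cells with a wrapped-Gaussian membrane cap,
a second channel with a peak planted at a known arc-length offset plus
optional flanking minima, a bright nucleus, cytoplasmic background, and
per-frame Gaussian noise — with full ground truth, so every stage of the
pipeline is testable for exact recovery of planted parameters.

## Worked example

```python
import numpy as np
from polarcap import make_population
from polarcap.pipeline import analyze_cell, analyze_population

# 10 synthetic cells, channel-2 peak planted 1.0 µm from the polar cap,
# 29 frames each at membrane signal-to-noise 5
cells = make_population(n_cells=10, offset_sampler=1.0, seed=42)
results = [
    analyze_cell(stack, truth.cell_masks, f"cell{i:03d}", cfg.pixel_size_um)
    for i, (stack, truth, cfg) in enumerate(cells)
]
pop = analyze_population(results, grid_spacing_um=0.1, start_frame=9,
                         n_boot=2000, seed=42)
avg = pop.average
peak = avg.positions_um[np.argmax(avg.mean)]
print(f"cohort peak position: {peak:+.1f} um from the polar cap")
print(f"median |max| distance: {np.median([r.max_dist_um for r in pop.extrema]):.2f} um")
print(f"50% of maxima within:  {pop.maxima_q50_um:.2f} um")
print(f"25% of minima within:  {pop.minima_q25_um:.2f} um")
```

prints

```
cohort peak position: +1.0 um from the polar cap
median |max| distance: 1.05 um
50% of maxima within:  1.00 um
25% of minima within:  2.10 um
```

The cohort-average distribution peaks at the planted 1.0 µm offset; half of
the per-frame signal maxima fall within 1.0 µm of the cap, and a quarter of
the minima within 2.1 µm (the planted flanking dips sit at 0 and 2 µm from
the cap, and per-frame minima are the noisier readout).

There is also a CLI mirroring the stages
(`polarcap simulate | profile | nucmask | register | extrema | stats | all`);
`polarcap all --config run.yaml` executes the whole pipeline from a YAML
configuration and writes CSV/JSON results plus a reproducibility manifest.

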