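# lipidseg

Segmentation and lipid-fingerprint statistics for MALDI imaging mass
spectrometry (MSI) of demyelinating spinal-cord lesions.

Focal demyelination (e.g. lysophosphatidylcholine injection, a model of
multiple sclerosis lesions) produces spatially heterogeneous tissue: a
fully demyelinated lesion core, a peri-lesion ring of activated
microglia/macrophages, and uninvolved white and grey matter.  Bulk
lipidomics averages these compartments away.  `lipidseg` is for analysts
who want to recover compartment-resolved lipid fingerprints from
negative-ion MSI datacubes: it reduces per-pixel spectra to a pixels ×
peaks matrix, partitions the image by fingerprint correlation, extracts
per-region relative abundances, and tests, projects and classifies them.

## What it computes

* **Preprocessing** — per-pixel rigid ppm alignment against the cohort
  mean (cross-correlation, ±10 ppm), TIC normalization (each pixel's
  summed intensity → 1), average-spectrum peak picking (local maxima with
  intensity ≥ 0.5% of the base peak), and reduction to the maximum
  intensity within ±5 ppm of each peak centre.
* **DHC-RC segmentation** — divisive hierarchical clustering with
  rank-competing walkers.  The leaf with the lowest mean within-segment
  Pearson correlation r̄ is repeatedly bipartitioned by two walkers grown
  from a minimally correlated seed pair, keeping over restarts the split
  that maximizes r̄(within) − r̄(between).  Segments are coloured on a
  continuous bar: the least-correlated pair takes the two ends, the rest
  sit at d_a/(d_a+d_b), d_x = 1 − r(segment, extreme x).  Any segment
  subset can be isolated and re-segmented to resolve fine structure such
  as the peri-lesion ring.
* **Statistics** — region fingerprints (per-section relative abundances
  over annotated species), Welch t-tests across sections with star codes
  (* p<0.05, ** p<0.01, *** p<0.0001), mean-centred PCA, and a 500-tree
  random forest evaluated leave-one-section-out, reporting per-class
  precision, sensitivity and one-vs-rest specificity.
* **Annotation** — [M−H]⁻ matching at 5 ppm against a bundled 52-species
  library (PC, PC-E, PE, PE-E, PI, PS, PG, SM, sulfatides) with masses
  built from class backbone formulas; PS/PI fragment ambiguities flagged.
* **Synthetic data** — a ground-truth-labelled section generator (tissue
  phantom + region templates + Orbitrap-like noise model) emulating the
  lesioned-cord study design, so the full chain is testable end to end.

Formats: imzML/ibd (continuous and processed), an internal npz container,
TIFF label/segment rasters with JSON sidecars, CSV tables, plain-text
`key = value` configs.

## Worked example

Simulate the nine-section cohort and run the full analysis:

```python
from lipidseg import simulate_study
from lipidseg.pipeline import PipelineConfig, run_study_analysis

sections = simulate_study(n_sections=9, seed=1)
res = run_study_analysis(sections, PipelineConfig(seed=0))

print(res["classification"].per_class)
comp = res["comparisons"]
print(comp[comp.species.isin(["PI 38:4", "ST 42:2"])]
      [["species", "region_a", "region_b", "mean_a", "mean_b", "p", "stars"]]
      .round(4).to_string(index=False))
print(res["pca"].scores["PC1"].groupby(level="region").mean().round(3))
```

prints

```
              precision  sensitivity  specificity
class
lesion_core         1.0          1.0          1.0
peri_lesion         1.0          1.0          1.0
white_matter        1.0          1.0          1.0

species     region_a    region_b  mean_a  mean_b   p stars
PI 38:4 white_matter peri_lesion  0.0250  0.0529 0.0   ***
ST 42:2 white_matter peri_lesion  0.0893  0.0567 0.0   ***
PI 38:4 white_matter lesion_core  0.0250  0.0744 0.0   ***
ST 42:2 white_matter lesion_core  0.0893  0.0286 0.0   ***
PI 38:4  peri_lesion lesion_core  0.0529  0.0744 0.0   ***
ST 42:2  peri_lesion lesion_core  0.0567  0.0286 0.0   ***

region
lesion_core    -0.062
peri_lesion    -0.005
white_matter    0.067
```

Read: the leave-one-section-out random forest separates the three region
fingerprints perfectly; PI 38:4 (arachidonic-acid store) rises and
sulfatide ST 42:2 falls monotonically from white matter through the
peri-lesion into the core, both highly significant across the nine
sections; and the PC1 score centroids order the regions along a single
demyelination gradient.

The same run from the shell, with maps, tables and a re-run manifest:

```sh
lipidseg run --seed 0 --out-dir runs/demo
lipidseg simulate --width 48 --height 48 --seed 1 --n-sections 1 --out-dir runs/sim
lipidseg preprocess --in runs/sim/section0_cube.npz --out runs/pp
lipidseg segment --in runs/pp_features.npz --n-segments 5 --seed 0 --out runs/seg5
lipidseg resegment --features runs/pp_features.npz --in runs/seg5_segmap.npz \
    --select-ids 1,2,3 --n-segments 4 --out runs/seg4
```

## Layout

```
src/lipidseg/
  phantom.py     label-raster tissue phantom
  templates.py   per-region lipid abundance templates
  simulate.py    noise model and cohort simulator
  cube.py        SpectraCube container
  preprocess.py  align / normalize / average / pick / reduce
  segment.py     DHC-RC segmentation, colours, re-segmentation
  stats.py       fingerprints, Welch tests, PCA, random forest
  lipids.py      shorthand parsing, formulas, monoisotopic masses
  annotate.py    [M-H]- peak annotation
  io.py          imzML, containers, rasters, configs
  pipeline.py    orchestration + manifest
  cli.py         `lipidseg` subcommands
  plots.py       segment maps, abundance bars, score plots
```
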