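# hepamorph

3D morphometric analysis of hepatic fibrosis in whole-liver bright-field
(Nissl) volumes.

Whole-mount Nissl staining imaged in reflected bright field renders vessel
and sinusoid lumens bright and parenchyma dark, so a single grayscale
volume carries central veins, portal veins, arteries, bile ducts,
sinusoids, and steatotic (fat-laden) hepatocyte regions at once.
`hepamorph` implements the analysis chain that turns such a volume into
quantitative pathology:

- **phantom** — synthetic Nissl-like liver volumes with exact ground truth
  (branching vein trees, a connected sinusoid mesh, pericentral steatosis
  whose volume fraction decays with distance from the central-vein
  surface), so every downstream stage is testable without external data;
- **preprocess** — bias-field division, Fourier notch removal of periodic
  sectioning stripes, median denoising with percentile contrast
  normalization, and resampling to a 1 µm isotropic grid;
- **vessels** — seeded region growing for vein trees, thresholding with
  vessel subtraction and size filtering for sinusoids, and central-vs-
  portal branch classification by companion-structure (artery/bile-duct)
  proximity;
- **morphometry** — topology-preserving 3D thinning, a centreline branch
  graph with per-point distance-transform diameters, and the four vessel
  statistics: mean diameter d̄ (arc-length-weighted mean of 2·EDT),
  number of segments, length density L_V = L/V_ref (m·mm⁻³), and volume
  fraction V_V = V/V_ref; plus a two-sample Student's t comparison
  (mean ± s.e.m.);
- **steatosis** — a trainable voxel classifier (one hidden layer on
  multi-scale intensity/texture features) standing in for cloud-scale
  semantic segmentation, with loss/accuracy/IoU training curves,
  post-processing, overlap metrics, and mask × gray extraction;
- **spatial** — Euclidean distance fields from vessel surfaces, half-open
  perivascular distance bands (0–30–60–90–120 µm) with per-band steatotic
  percentages, 150 µm shells around individual branches, and
  stratification of shell steatosis by branch diameter class;
- **labelstats** — per-connected-component shape descriptors
  (Volume3d, EqDiameter = (6V/π)^(1/3), maximum Feret Length3d,
  inscribed-ball Thickness3d, per-slice Perimeter, sphericity index
  Shape_VA3d = A³/36πV²) and aggregate statistics with the overall volume
  fraction;
- **cli** — YAML-configured orchestration of the full pipeline with CSV/
  JSON reports and a seed-stamped manifest.

## Worked example

Run the full pipeline on a 96³ synthetic phantom:

```sh
hepamorph simulate --out demo_phantom --seed 5 --shape 96   # volumes only
python - <<'PY'
from hepamorph.cli import PipelineConfig, run_pipeline
import hepamorph.phantom as ph

cfg = PipelineConfig(output_dir="demo_out", seed=5,
                     phantom=ph.PhantomConfig(shape=(96, 96, 96), seed=5))
out = run_pipeline(cfg)
print(open(out / "band_report.csv").read())
PY
```

which prints the perivascular distance-band report:

```
band_um,region_volume_um3,steatotic_volume_um3,percent
0-30,486110.0,314020.0,64.5985476538232
30-60,282935.0,147249.0,52.04340219485041
60-90,15596.0,5172.0,33.16234932033855
90-120,0.0,0.0,
```

Each row is one 30 µm distance band around the segmented central-vein
surface: the volume of the band, the volume of predicted steatosis inside
it, and their percentage. The phantom programs steatotic coverage of
68/56/30/18 % in the four bands; the measured 65/52/33 % reflects the
full segmentation chain (region growing, classifier prediction) rather
than ground-truth masks, and the outer bands are truncated by the small
demo volume (the 90–120 µm band is empty at 96³, reported as an undefined
percentage). `demo_out/` also contains the vessel morphometry table,
classifier training curves, the per-component shape table with aggregate
statistics, and `manifest.json` recording the seed and config hash; a
rerun with the same config is byte-identical.

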