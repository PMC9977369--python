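# psdgold

Quantitative spatial analysis of immunogold-labeled receptors at postsynaptic
densities (PSDs) from freeze-fracture replica immunolabeling (FRIL) electron
microscopy.

In FRIL, membrane proteins retained on a carbon replica are tagged with
colloidal gold beads (5/10/15 nm), giving a two-dimensional map of receptors
— here AMPA-type (GluR1–4) and NMDA-type (GluN1 subunit) glutamate receptors
— across the PSDs of cortical layer 4 and layer 5 dendritic shaft and spine
synapses. Each PSD is a closed polygonal contour traced around the
intramembrane-particle cluster (nm coordinates, optional hole rings for
annular PSDs) plus the gold-grain coordinates. `psdgold` is for analysts of
such data: it counts grains within the contour, measures PSD geometry
(area *A*, centroid, maximum Feret diameter), builds pose-normalized 2D
receptor density maps (counts and exact cell∩region coverage on a 25 nm grid,
normalized as Σcounts/Σcoverage in grains/nm²), computes area-normalized
radial distribution profiles (20 nm annuli around the centroid,
count/area(annulus∩region)), simulates spatial null models that keep each
PSD's outline and grain count —

* `equal`: uniform over the region,
* `center_gaussian`: density ∝ exp(−d_c²/2σ²), d_c = distance to centroid,
* `border_gaussian`: density ∝ exp(−d_b²/2σ²), d_b = distance to the outer
  contour, with σ = ⅓·√(A/π)

— and tests measured profiles against each model with an exact Monte-Carlo
rank test (Dunnett-style control-vs-treatment comparisons; each of the 100
simulation iterations is held out as pseudo-measured data, giving an
exchangeable null and exact p-values). Descriptive group tables (mean, SD,
median, IQR, skewness, variance, CV), Mann–Whitney U / Kruskal–Wallis H
comparisons, grain-count vs area regression (R²) and per-animal AMPA/GluN1
ratio analysis round out the pipeline. A seeded synthetic-study generator
reproduces the reference populations (lognormal areas, Poisson counts
calibrated to a target count–area R², 80/10/5/5
macular/perforated/horseshoe/ring morphologies) so everything is testable
without raw EM data.

## Worked example

```python
from psdgold import (study_config, generate_study, select, region_area,
                     synaptic_count, summarize, count_area_r2, receptor_ratio)
from psdgold.validation import compare_against_models

cfg = study_config(seed=42, scale=0.25)      # quarter-size synthetic study
ds, truth = generate_study(cfg)              # 359 PSDs with ground truth

sub = select(ds, layer="L4", target="shaft", receptor="AMPA")
areas = [region_area(r.region) for r in sub.records]
s = summarize(areas, "AMPA L4 shaft areas")
fit = count_area_r2(sub.records)
row = receptor_ratio(ds, "L4", "shaft")
res = compare_against_models(sub, iterations=100, seed=7)
```

printed (via f-strings over the objects above):

```
records: 359
PSD area (um^2): mean 0.055 +/- 0.016, median 0.054, CV 0.28
grains/PSD: mean 23.8 +/- 7.5
count-area R^2 = 0.69 (slope 396 grains/um^2)
AMPA/GluN1 ratio L4 shaft: 0.70 +/- 0.18 over 15 animals
measured vs equal: discrepancy 51.9, p = 0.901
measured vs center_gaussian: discrepancy 127.2, p = 0.010
measured vs border_gaussian: discrepancy 153.3, p = 0.010
```

The generated L4-shaft population reproduces its configured structure (areas
around 0.06 µm², ~23 AMPA grains per PSD, count tightly coupled to area, an
AMPA/GluN1 ratio below 1 on shafts), and the profile comparison retains the
true uniform placement (p = 0.90) while rejecting both Gaussian alternatives
at the exact test's resolution (p = 1/101 ≈ 0.01).

## Command line

```sh
psdgold simulate -o study.json --seed 7            # synthetic study + truth CSV
psdgold analyze study.json -d results/             # full pipeline, manifest.json
psdgold density-map study.json -d maps/ --grid-size 20
psdgold radial study.json -d profiles/
```

`analyze` writes per-group summary tables (`summary_*.csv`), count–area fits,
AMPA/GluN1 ratios, density-map matrices (`map_*_{counts,coverage,normalized}.csv`),
tidy radial profiles with simulated conditions (`radial_*.csv`), profile test
results (`profile_tests.csv`) and a reproducibility manifest.

## Layout

```
src/psdgold/
  model.py       exchange data model, JSON I/O, filtering
  geometry.py    area, centroid, Feret diameter, pose normalization
  density.py     gridded density maps and population averaging
  radial.py      radial distribution profiles
  nulls.py       spatial null models and per-PSD simulations
  stats.py       descriptive and inferential statistics
  synth.py       synthetic-study generator
  tables.py      reference group statistics (generator targets)
  validation.py  calibration and power experiments
  reference.py   brute-force oracles (Monte-Carlo area, ray casting, ...)
  pipeline.py    end-to-end analysis orchestration
  cli.py         typer CLI (simulate / analyze / density-map / radial / ...)
docs/methods.md  model, parameters, numerical choices, limitations
```
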