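# cmscreen

Simulation and analysis toolkit for plate-based live-cell **nuclei-count
proliferation screens**, modelled on high-content screening of human
iPSC-derived cardiomyocytes (hiCMs).

## The problem

Postnatal mammalian cardiomyocytes barely divide, and the common proxies
for proliferation are ambiguous: cycling markers (Ki67, PCNA) and DNA
synthesis labels (BrdU/EdU) also flag endoreduplication and binucleation,
and even midbody markers appear in binucleating cells. A more direct
readout is simply to label every nucleus with a live-cell dye and count
nuclei per well over time: if a compound drives genuine hyperplastic
growth, the nuclei count rises faster than in vehicle controls.

`cmscreen` implements the full computational stack for such a screen:

* **platemodel** — 96/384-well plate maps (compound, concentration, role,
  plating density per well), well geometry, and per-well count time series;
* **simulate** — a seeded stochastic simulator of ground-truthed wells:
  density-dependent division, cytokinesis vs binucleation, drug-modulated
  division and death, and rendering of tiled nuclei images, cell-boundary
  label images, and marker channels;
* **imaging** — tile stitching, nucleus segmentation (smooth → threshold →
  label → watershed declumping), marker-positive scoring, and
  nuclei-per-cell assignment for binucleation measurement;
* **analytics** — control-normalized nuclear fold change, multi-screen
  aggregation, SEM-based hit ranking, time-of-death day binning, density
  curves, and dose–response tables;
* **cli** — `cmscreen simulate | quantify | screen | report`.

## The statistics at the core

For a well with nuclei counts $N(t)$, the **raw fold change** over the
analysis window (default 0–72 h) is $\mathrm{FC} = N(72)/N(0)$, and the
**normalized fold change** divides by the mean raw fold change of the
plate's vehicle-control wells:

$$\widetilde{\mathrm{FC}} = \frac{N(72)/N(0)}{\langle \mathrm{FC}\rangle_{\text{controls}}}$$

so 1 means control-like growth, 0 means total cell death, and 2 means a
doubling of the nuclei increase relative to control. Compounds are
aggregated over replicate screens (mean ± SEM, SEM = sd/√n); **hits** are
compounds with mean > 1, ranked by ascending SEM, because reproducibility
across screens — not magnitude alone — separates real modulators from
false positives. Wells whose counts collapse below a fraction of their
initial value (default 0.2, for ≥ 2 consecutive points) are called dead,
binned by day (`ceil(first-crossing hour / 24)`, with collapse at the
first image as day 0), and excluded from compound means, since dead wells
shed fluorescent debris that corrupts counts.

The simulator encodes the biology the screen relies on: division
probability falls linearly with plating density between 136 and
544 cells/mm² (saturating outside that range, hence the screening density
at the midpoint, (544+136)/2 = 340 cells/mm²), and each division resolves
as cytokinesis or binucleation with a density-independent binucleation
probability β.

## Worked example

Simulate four replicate screens of a toy plate carrying a GSK-3β-inhibitor-
like proliferative compound and a lethal kinase inhibitor, then aggregate:

```python
import pandas as pd
from cmscreen import (PlateMap, WellCondition, SimulationConfig, DrugEffect,
                      simulate_screen, fold_changes_for_plate, aggregate_screens,
                      rank_hits, call_death)
from cmscreen.simulate import ImagingParams

plate = PlateMap(plate_id="demo", plate_format=384, wells={
    "A01": WellCondition(role="control", compound_id="DMSO"),
    "A02": WellCondition(role="control", compound_id="DMSO"),
    "B01": WellCondition(role="treated", compound_id="SB216763", concentration_um=10.0),
    "B02": WellCondition(role="treated", compound_id="STAUR", concentration_um=10.0),
})
cfg = SimulationConfig(
    seed=1, n_timepoints=7,
    imaging=ImagingParams(tile_grid=(2, 2), tile_px=200, tile_overlap_px=16),
    drug_effects={
        "SB216763": DrugEffect(division_multiplier=4.0),
        "STAUR": DrugEffect(death_hazard=1.0, death_onset_h=24.0),
    },
)
rows = []
for scr in simulate_screen(plate, cfg, n_screens=4, seed=1):
    series = {w: sw.series for w, sw in scr.wells.items()}
    deaths = {w: call_death(ts) for w, ts in series.items()}
    results = {r.well: r for r in fold_changes_for_plate(series, plate)}
    for w, cond in plate.wells.items():
        if cond.role != "treated":
            continue
        died, day = deaths[w]
        rows.append({"compound": cond.compound_id, "screen": scr.screen,
                     "normalized_fc": results[w].normalized_fold_change if w in results else None,
                     "died": died, "death_day": day})
summaries = aggregate_screens(pd.DataFrame(rows))
for s in summaries:
    print(f"{s.compound_id:10s} mean={s.mean if s.mean is None else round(s.mean, 3)} "
          f"sem={s.sem if s.sem is None else round(s.sem, 3)} "
          f"dead_wells={s.n_excluded_dead} death_day={s.death_day}")
print("hits:", [h.compound_id for h in rank_hits(summaries)])
```

Output:

```
SB216763   mean=1.226 sem=0.02 dead_wells=0 death_day=None
STAUR      mean=None sem=None dead_wells=4 death_day=2.0
hits: ['SB216763']
```

SB216763 increased nuclei count ~23% over control, reproducibly
(SEM 0.02), so it ranks as a hit; the lethal compound killed all four
replicate wells (its counts collapsed by 36 h → death day 2), was excluded
from fold-change means, and appears only in the death table.

The same pipeline runs from the shell on rendered images:

```bash
cmscreen simulate --platemap plate.csv --config cfg.yaml --outdir run/ --images
cmscreen quantify --images run/images --config cfg.yaml --outdir run/
cmscreen screen --counts run/counts.csv --platemap plate.csv --outdir run/
cmscreen report --indir run/ --out run/report.txt
```

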