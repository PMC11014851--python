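# lving — Lagrangian velocimetry for intracellular net growth

`lving` turns time-lapse quantitative-phase movies of single cells into
spatially resolved maps of net biomass production and degradation, in
picograms per hour, at sub-micrometer resolution. It is aimed at
quantitative-phase-imaging (QPI) labs studying where a cell builds and
degrades mass — across the cell cycle, under synthesis inhibitors, or
during autophagy — without any fluorescent label.

## The method

A QPI frame measures optical path difference (OPD, µm), which converts to
areal dry-mass density via the specific refractive increment α
(0.18 µm³/pg):

    σ = OPD / α        [pg/µm²]

At a fixed location, mass change mixes transport and biosynthesis:

    ∂σ/∂t + ∇·(σv) = r

where **v** is the intracellular mass-transport velocity and *r* the net
local production rate — the quantity of interest. `lving` estimates *r*
Lagrangianly:

1. **Velocimetry** — window cross-correlation between consecutive mass
   frames (zero-mean NCC with gradient-based subpixel refinement,
   ~0.01 px accuracy) gives **v** on a node grid.
2. **Tracking** — small control volumes (0.7 µm² squares) seeded over the
   cell are advected and deformed with the flow; displacements are
   re-anchored against the window-start frame so tracking error does not
   accumulate. In the co-moving frame the transport term vanishes.
3. **Growth fitting** — the OLS slope of each volume's enclosed mass
   (exact polygon–pixel integration) versus time is its net rate *r* in
   pg/h; rates rasterized at the volumes' footprints form the growth map.
4. **Regions & puncta** — summed rates over a mask divided by the region's
   dry mass give the specific growth rate (1/h); connected regions of
   strong positive/negative rate are reported as growth/degradation
   puncta.

A forward simulator (`lving.synthetic`) renders noisy OPD movies from
prescribed velocity fields and source terms with exact ground truth, so the
whole pipeline is testable end to end without any experimental data.

## Worked example

Simulate a translating cell growing uniformly at 0.05/h for 30 minutes,
then run the full pipeline on the rendered movie:

```python
import pandas as pd
from lving import PipelineConfig, run_pipeline, simulate

scene = {
    "shape": [128, 128], "pixel_size": 0.25, "n_frames": 31,
    "velocity": {"kind": "uniform", "u": 0.05, "v": 0.02},
    "source": {"kind": "uniform_specific", "g": 0.05},
    "seed": 42,
}
simulate(scene, "demo/sim")
run_pipeline("demo/sim/movie.tif", "demo/sim/movie.json",
             PipelineConfig(window_min=30.0), "demo/out")
print(pd.read_csv("demo/out/regions.csv").to_string(index=False))
```

prints

```
 t_start_min  t_end_min region  total_rate_pg_per_h  region_mass_pg  specific_rate_per_h  n_volumes
         0.0       30.0   cell            19.241038      379.881584              0.05065        425
```

The cell carries 379.9 pg of dry mass; 425 tracked control volumes sum to
19.24 pg/h of net production, a specific growth rate of 0.0507/h against
the prescribed 0.05/h. `demo/out/` also contains the per-frame mass stack
(`mass.tif`), velocity tables (`velocity/field_*.csv`), per-volume tracks
and rates, the growth map (`growth_maps.tif`, NaN outside tracked volumes),
a puncta table, and a `manifest.json` with config hash and input/output
checksums — rerunning with the same inputs reproduces the tree
byte-for-byte.

The same pipeline is available from the shell:

```sh
lving simulate --scene scene.yaml --out demo/sim
lving run --opd demo/sim/movie.tif --metadata demo/sim/movie.json \
          --config pipeline.yaml --out demo/out
lving validate-config --config pipeline.yaml
```

Real data enter the same way: a multi-page 32-bit float TIFF of OPD (µm)
plus a JSON/YAML sidecar with `pixel_size_um` and `frame_interval_min`,
and optional cell/nucleus masks (TIFF/PNG, nonzero = inside).

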