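# blastosim

Agent-based simulation and track-level quantification of **syncytial
blastoderm formation** — the stage of early insect development in which
nuclei divide without cytokinesis and migrate through the shared cytoplasm
of a large egg until they form a single layer at its periphery. The
package targets the mode of development seen in the cricket *Gryllus
bimaculatus*, whose nuclei move *actively* and *asynchronously*: mitotic
cycle length, nuclear speed, and movement direction all co-vary with local
nuclear density rather than with position, lineage, or elapsed time.

It is intended for developmental biologists and biophysicists who want to
(a) test force models of syncytial nuclear positioning against tracking
data, and (b) compute the standard statistics of 3D+T nuclear lineage
tracks.

## The model

Each nucleus carries a **cloud origin** (abstracted microtubule-organizing
center) on its surface. After each division, a **cloud** (abstracted
astral microtubule array) grows geodesically from the origin at
`r_max/τ_grow` up to `r_max = 150 µm`, occluded by the eggshell, by every
nucleus body, and by neighboring clouds (first-arrival partition of
space). Uniformly distributed motors tug the origin toward every cloud
voxel with weight `v_vox / R²` (`R` = geodesic distance to the origin), so
the pull of a thin solid-angle sector is proportional to its length and
the net force

&nbsp;&nbsp;&nbsp;&nbsp;**F** = Σ_vox **û** · v_vox / R²

points toward open space. Motion is overdamped with a small constant
periplasm bias **b** (|b| = 0.4 µm/min, toward the nearest shell point):

&nbsp;&nbsp;&nbsp;&nbsp;**v** = µ **F** + **b**

During the slow pre-division state (Phase B) the cloud is absent and only
the bias acts. Cycle lengths are drawn from a lognormal law whose mean
rises linearly with local density (nuclei within a 150-µm ball),
`T(ρ) = 42.92 + 1.52·ρ` min, with constant-CV noise (SD 11 min at mean
87 min); Phase A lasts `clamp(0.6T, 20, 28)` min. Daughters are placed on
a uniformly random axis with antipodal cloud origins. The mobility µ is
calibrated so the 99th-percentile Phase A speed matches 4 µm/min.

Crowding therefore throttles both *movement* (occluded clouds shrink) and
*proliferation* (denser → longer cycles) with purely local rules — which
is sufficient to reproduce axial expansion, the exponential speed–density
law `y = y0·e^(−x/x0)`, biphasic speeds, space-seeking directionality,
and the behavior of physically constricted embryos.

Two rejected comparators run under the same harness: 3D mutual repulsion
and sign-reversed ("pushing") clouds. The metrics module implements the
track statistics: local density, instantaneous speed, division-pulse
detection, cycle lengths, local proliferation time, density–cycle
concordance, pairwise movement correlation, the Voronoi-based
space-seeking score, and the seeded-bootstrap exponential fit.

## Worked example

```python
import dataclasses
import blastosim as bs
from blastosim.pulling import SimConfig

shape = bs.ShapeSpec(kind="capsule", length_um=1200, width_um=450,
                     first_division_frac=0.6)
cfg = SimConfig(shape=shape, seed=11, voxel_um=15, n_start=4, n_end=350)
domain = bs.build_domain(shape, cfg.voxel_um)
mu = bs.calibrate_mobility(cfg, domain)
table = bs.run_simulation(dataclasses.replace(cfg, mu=mu), domain)

rec = bs.per_record_metrics(table)
A = rec[(rec.phase == "A") & ~rec.censored & rec.speed_um_min.notna()]
fit = bs.fit_density_scale(A.speed_um_min.to_numpy(),
                           A.density.to_numpy(), n_boot=200, seed=0)
```

Output of the full example (see the same numbers discussed in
`docs/methods.md`):

```
simulated 700 nuclei over 243 frames (363 min), 348 divisions
calibrated mobility mu = 0.01172
Phase A median speed (um/min) by density bin: low=1.73 medium=0.86 high=0.78
Phase B median speed: 0.40 um/min
Phase A density scale x0 = 29.9 density units (90% CI 28.4-31.6, n=5070)
early division-peak intervals (min): [43.5 52.5 48. ]
```

Reading the numbers: fast-phase speed falls monotonically across the
low/medium/high density bins (edges 11 and 29), the slow phase moves at
the bias speed and is density-independent, the fitted density scale says
Phase A speed drops e-fold per ~30 extra neighbors, and successive early
division pulses arrive roughly every 49 minutes — the early mitotic
rhythm of the cricket embryo.

The same workflow is scriptable from the shell:

```bash
blastosim simulate --config run.yaml --seed 11 --out tracks.csv
blastosim analyze  --tracks tracks.csv --out metrics/ --seed 0
blastosim compare  runA.csv runB.csv --counts 120,200,300 --out cohorts.csv
```

`simulate` accepts `--model pulling|repulsion|pushing` and writes a run
manifest (resolved config, seed, version) next to the tracks.

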