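# Methods

`blastosim` simulates and quantifies nuclear dynamics during syncytial
blastoderm formation in large insect eggs — the developmental mode of the
cricket *Gryllus bimaculatus*, in which nuclei divide without cytokinesis
and migrate through a shared cytoplasm until they line the egg periphery.
This note records the model, its assumptions, the parameter choices, and
what the synthetic tests do and do not establish.

## The pulling-cloud model

Each nucleus is a rigid sphere (radius 10 µm) carrying a body-fixed *cloud
origin* on its surface — an abstraction of the microtubule-organizing
center. The mitotic cycle alternates between two states:

* **Phase A** (fast, post-division): a *cloud* — the abstracted astral
  microtubule array — grows geodesically from the origin through the
  cytoplasm at speed `r_max / tau_grow` (default 150 µm / 5 min), to a
  maximum radius of 150 µm. Growth is occluded by the eggshell, by every
  nucleus body, and by other clouds: voxels belong to the first-arriving
  front, so clouds partition space ("first-arrival labeling"). Uniformly
  distributed motors tug the origin toward every voxel of its cloud with
  weight `v_voxel / R²` (`R` = geodesic voxel-to-origin distance). The
  `1/R²` scaling makes the pull of a thin solid-angle sector proportional
  to its length, so the net force measures *where the cloud could grow* —
  a nucleus beside open space is pulled into it.
* **Phase B** (slow, pre-division): the cloud is absent and only the
  periplasm bias acts. At the end of Phase B the nucleus divides: a
  uniformly random axis is drawn, daughters are placed at ±r on it and
  inherit antipodal cloud origins, so they are initially pulled apart.

Dynamics are overdamped: `velocity = mu * F + b`, where `b` is a constant
0.4 µm/min drift toward the nearest eggshell point (the unexplained
periphery bias of real nuclei; 0.4 µm/min equals the median empirical
Phase B speed, which in this model is bias-only). Positions are clamped to
stay one nucleus radius inside the shell. The mobility `mu` is not a free
choice: `calibrate_mobility` bisects it until the 99th-percentile Phase A
speed of a short pilot run matches the 4 µm/min "fast" end of the observed
speed range (tolerance 2%, deterministic given the seed).

### Cycle scheduling

Cycle lengths are drawn at birth from a lognormal law whose mean is linear
in local density (nuclei within a 150-µm ball): `T(ρ) = T0 + slope·ρ`.
The defaults anchor the line to the two reported observations of cricket
development — ≈49-min cycles at the four-nucleus stage (where the focal
nucleus has ρ ≈ 4 neighbors) and ≈87-min cycles in the high-density regime
(ρ = 29, the "high" bin edge) — giving `slope = 1.52 min per density unit`
and `T0 = 42.92 min`. Note the anchor at ρ = 4, not ρ = 0: a density of
zero never occurs once divisions begin, and anchoring `T(0) = 49` would
make every realized early cycle 52–56 min, contradicting the observed
early division rhythm.

The noise has constant coefficient of variation: SD = 11 min at the
reference mean of 87 min (the reported fourth-cycle dispersion), scaling
proportionally at other means. A constant absolute SD of 11 min would give
early 49-min cycles twice the relative spread of the reported cycle-4 value
and would smear the early division pulses, which are empirically sharp;
proportional noise reproduces both the reported dispersion and the observed
*decline* of division synchronicity as cycles lengthen.

Phase A lasts `clamp(0.6·T, 20, 28)` min (the observed fast-phase duration
range); the remainder of the cycle is Phase B.

### Numerical choices

* Geometry is voxelized (default 10 µm; scaled runs use 15 µm, which keeps
  the cloud radius at 10 voxels). Front propagation runs on a radius-2
  chamfer stencil (26 neighbors plus the coprime (2,1,0)/(2,1,1)/(2,2,1)
  offsets) via multi-source Dijkstra; this keeps the path-metric
  anisotropy to ~2% (plain 26-connectivity errs by ~8%, visibly shrinking
  "geodesic balls"). Staggered cloud start times are realized with
  per-source delay edges from virtual nodes; clouds that entered Phase A
  earlier are proportionally larger, and fully grown clouds compete as if
  synchronized (growth history beyond the radius cap is not retained).
  One consequence of node-based blocking with a radius-2 stencil is that
  single-voxel obstacles are permeable to knight-move edges; nucleus
  bodies at coarse voxel sizes therefore occlude slightly less than their
  nominal spheres. Tests that need impermeable walls use two-voxel-thick
  obstacles.
* Distance to the eggshell uses an exact Euclidean distance transform
  (`scipy.ndimage.distance_transform_edt`); the outward bias direction is
  the negative gradient of this field.
* Clouds are recomputed from scratch each 1.5-min step (the imaging frame
  interval, so simulated and empirical metrics share sampling).
* Voxels with `R` below one voxel are excluded from the force sum
  (singularity guard). Volume weighting (every cloud voxel) is the
  default; surface weighting (boundary voxels, area-weighted) is retained
  as an option but makes the pull of a sector length-independent, which
  contradicts the rod-proportionality property the force law is built on.
* Randomness: one root seed; each nucleus draws from its own
  `SeedSequence(seed, spawn_key=(id,))` stream, so a division in one
  lineage never perturbs draws elsewhere. Identical config + seed gives
  byte-identical track tables.

## Track statistics

All statistics consume the shared track-table schema
(`nucleus_id,parent_id,frame,t_min,x_um,y_um,z_um`; binary lineage forest;
root nuclei are *censored* — their birth is unobserved — and are excluded
from cycle-length statistics).

* **Local density**: count of *other* nuclei within a closed 150-µm ball
  (bins: low < 11, medium 11–28, high ≥ 29). A 2D disc variant exists for
  projection data and is never mixed with 3D values.
* **Speed**: per-frame displacement / 1.5 min, assigned to the later frame.
* **Phases for analysis**: sampled 3–13.5 min (A) and 33–39 min (B) after
  the last division.
* **Division synchronicity**: percent change in total count per frame,
  smoothed with a centered rolling mean (window 5 frames by default; a
  rolling median would erase a perfectly synchronous single-frame pulse).
  Peaks require prominence ≥ 25% of the series maximum and ≥ 30 min
  separation — closer maxima cannot be successive generation pulses, since
  no early cycle is that short; they are sub-structure of a single pulse.
* **Speed–density law**: nonlinear least squares of `y = y0·exp(−x/x0)`;
  the 90% CI for the density scale `x0` is a seeded case-resampling
  percentile bootstrap (nucleus-timepoints resampled i.i.d.).
* **Space-seeking score**: cosine between a nucleus's one-step
  displacement and the vector to the centroid of its Voronoi cell, the
  cell being the set of interior voxels nearest to it (exact geometric
  clipping against the curved shell would buy nothing at our voxel sizes).
  Undefined (NaN) when either vector is < 1e-6 µm.
  The per-phase summary (`space_seeking_phase_medians`) pools frames of
  the *axial-expansion epoch* — frames where at least half the nuclei are
  still interior (> 75 µm from the shell). In a scaled-down embryo the
  periplasm eventually swallows the interior; the few late "interior"
  nuclei are stragglers on the rim of the vacated core, whose cells all
  point inward, and they are not the cohort this statistic describes.
* **Proliferation time**: time until the 150-µm-ball count around a
  nucleus's moving position rises by 25% (ceiling on the integer target);
  NaN if its record ends first. Concordance between density and
  proliferation time is the percentage of strictly-ordered pairs that
  agree in sign.

## Comparator models

Two rejected alternatives run under the same stepping, scheduling, and
output harness:

* **Mutual repulsion** (soft exponential kernel by default, power-law
  optional, truncated at a cutoff; active in Phase A, bias always on).
  An isolated nucleus moves at the bias speed — the minimum — which
  inverts the observed density–speed relationship at the sparse end.
  Pooled Spearman correlations between Phase-A-window speed and density
  in our scaled sweep come out *weakly negative* at several settings
  (−0.02 to −0.45): nuclei in the densest neighborhoods sit where pair
  forces cancel by symmetry, while sparse cluster-edge nuclei feel
  coherent outward pushes, and early compact-cluster frames confound the
  pooled statistic. This differs from full-scale reports of
  no negative relation at any swept setting (the original 3D adaptation
  is not available in reconstructable detail); what the comparator does
  establish is that no repulsion setting approaches the observed strong
  exponential decay of speed with density.
* **Asymmetric pushing**: the pulling force with its sign reversed.
  Interior Phase A nuclei then move *away* from open space (negative
  space-seeking median), dramatically unlike real nuclei.

## Scaled run sizes and what the tests show

Test and acceptance runs use capsules of 900–1200 × 400–450 µm at 15-µm
voxels, run to ~350 nuclei — about half-scale in length and an order of
magnitude fewer nuclei than a real embryo, chosen as single-CPU problem
sizes that still populate all three density bins, produce four to six
division waves, and complete blastoderm formation. Emergent results on
these runs (Phase A density scale ≈ 24–29, space-seeking medians ≈ 0.76 /
0.08, early division-peak intervals ≈ 45–48 min, declining speed-peak
amplitudes, constriction effects) sit close to the reported full-scale
simulation values, but inherit sensitivity to the scaled geometry; the
capsule itself stands in for the real embryo surface mesh, which is not
available.

The synthetic fixtures emulate 3D+T tracking output (binary lineages,
90-s frames) with exact ground truth; they contain no detection dropouts,
tracking errors, or imaging noise, so passing metric tests demonstrates
correctness of the statistics, not robustness to segmentation artifacts.

## Known limitations

* Nuclear rotation is not modeled; the cloud origin is body-fixed between
  divisions.
* No periplasm anchoring: simulated nuclei that reach the periplasm keep
  space-seeking (a limitation shared by the reference model).
* No cytoplasmic flow, nucleus–nucleus contact mechanics, or
  cellularization.
* The constricted shape is a smooth cosine pinch; the physical hair
  profile is unknown.
* Empirical-data targets (the deposited tracking dataset) are outside the
  test surface; the metrics pipeline accepts any CSV in the track schema.
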