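# sarcotomo

Geometric and statistical analysis of sarcomere coordinate models from
muscle cryo-electron tomography.

Subtomogram studies of skeletal muscle produce, besides density maps, a
*coordinate model* of the sarcomere: traced thin and thick filament
axes, fitted myosin heads, annotated α-actinin cross-links.  This
package implements the analyses that operate on those coordinates —
for structural biologists who want to quantify filament organization
and cross-bridge statistics without re-running a full averaging
pipeline — together with a synthetic sarcomere generator so every stage
can be exercised and validated without tomographic data.

## What it computes

**Actin helix arithmetic** (`sarcotomo.helix`).  The thin filament is a
helix with twist φ = −166.6° and rise r = 27.9 Å per subunit; subunit
*k* has azimuth θ₀ + kφ (mod 360°).  Because φ is close to 180°, the
two long-pitch strands cross over every 180°/(180° − |φ|) ≈ 13.4
subunits ≈ 37 nm — the period of the myosin "target regions".
`estimate_helical_params` inverts this: it recovers (φ, r) from ordered
subunit coordinates by axis fitting plus circular averaging of azimuth
increments.

**Filament tracing** (`sarcotomo.tracing`).  An equatorial Fourier mask
on XY slices removes cross-bridge signal; filaments then appear as
dense dots in XZ cross-sections, found per plane by a
Laplacian-of-Gaussian detector with sub-voxel refinement and linked
into 3D traces by deterministic greedy nearest-neighbour linking.
`measure_lattice` reports nearest-neighbour spacings (45 nm thick–thick,
45/√3 ≈ 26 nm thin–thick in the hexagonal A-band) and a ψ₆
bond-orientational order score.

**A-band cross-bridge census** (`sarcotomo.binding`).  Heads are
assigned to their nearest actin subunit; occupancy is reported against
the theoretical budget of 6 heads per 14.3 nm crown of thick filament
(e.g. 2,734 fitted of 3,315 theoretical = 82.5%).  Myosins are
classified double / single / split-head; bound-subunit orientations are
gathered into per-thick-filament circular histograms (the orientation
gate confines each group to a ~120° arc); binding profiles over the
alphabet {R, G, B, E} are aligned by an affine-gap pairwise aligner
(Gotoh) with center-star progressive merging to expose binding
hotspots; and the bound-versus-free thin-to-thick distance populations
are compared (Welch or bootstrap CI, skewness checks), with every
subunit contributing exactly three measurements.

**Z-disc geometry** (`sarcotomo.zdisc`).  α-Actinin cross-links between
antiparallel thin filaments: rod length = axis-to-axis distance minus
the 6 nm actin diameter (~33 nm), obtuse angle to the pointed end,
consecutive-spacing histograms with the 5.58 nm (2 × rise) doublet
signature, Z-disc thickness from the outermost binding sites, and the
thickness–angle correlation that diagnoses the parallel-hinge
behaviour (~128° in thin ~80 nm discs, ~158° in thick ~100 nm ones).

**Tropomyosin states** (`sarcotomo.tpm`).  Filaments are cut into 37 nm
sections anchored at the A/I boundary and classified M / intermediate /
C from circular-mean azimuth offsets (the two states are ~21° apart),
locating the M→C transition.

**Synthetic generator** (`sarcotomo.synth`) builds ground-truth models
for all of the above — hexagonal lattice, helical filaments,
orientation-gated stochastic binding, antiparallel Z-disc arrays with
doublets, tropomyosin labels — and can rasterize them to MRC2014
volumes with noise and a missing-wedge mask.

## Worked example

```python
import numpy as np
from sarcotomo.specs import LatticeSpec
from sarcotomo.synth import build_aband_model
from sarcotomo import binding as B
from sarcotomo.helix import estimate_helical_params

model = build_aband_model(LatticeSpec(n_rows=5, n_cols=5), seed=1, n_thin=30)
heads, census = B.assign_heads(model.heads, model)
topo = B.classify_head_topology(heads, model)
orient = B.bound_orientations(model)
dist = B.angular_distribution(orient["rel_orientation"].to_numpy(),
                              orient["group"].to_numpy())
subs = model.subunits[model.subunits["filament_id"] == model.thin_ids()[0]]
helix = estimate_helical_params(subs[["x", "y", "z"]].to_numpy())
```

prints (via the obvious f-strings):

```
heads fitted / theoretical : 1510 / 1800  (occupancy 83.9%)
head topology              : 1386 double, 118 single (7.8%), 6 split (0.40%)
angular span per group     : B 119 deg, G 117 deg, R 116 deg
recovered helix            : twist -166.6 deg, rise 27.9 A
```

Reading: on a 30-filament synthetic A-band generated at the default
rigor-state parameters, 83.9% of the theoretical heads are bound
(binomial scatter around the 82.5% target), single and split heads
appear at roughly their configured rates, each thick filament's bound
subunits span ~120° of azimuth (the ±60° orientation gate), and the
helical parameters are recovered exactly from the coordinates.

The same stages run from the shell:

```bash
sarcotomo simulate --seed 1 --out-dir out/model --rasterize
sarcotomo trace out/model/volume.mrc --out out/traces.tsv
sarcotomo run-all --seed 1 --out out/run
```

`run-all` writes a single deterministic `report.json` plus figures
(circular orientation histogram, cross-link spacing histogram,
tropomyosin state strip).

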