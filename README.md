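# remodkit

Analysis and targeted structural remodeling of digitally reconstructed
neuronal morphologies.

Dendritic trees are not static: chronic stress retracts the arbors of
hippocampal CA3 pyramidal neurons while expanding those of the
basolateral amygdala; disease, learning and development reshape
dendrites in their own ways.  Testing how such structural changes affect
neuronal function requires imposing them *in silico* on real
reconstructions — without committing to any particular growth or
retraction rule.  `remodkit` is a toolkit for exactly that workflow,
aimed at computational neuroscientists and neuroanatomists who work with
SWC reconstructions (the NeuroMorpho interchange format):

* **Parse / write SWC** liberally on input, canonically on output
  (contiguous ids, parent-before-child, fixed precision), with full
  structural validation.
* **Morphometrics** per region (basal/apical/axon): total dendritic
  length, surface and volume (conical-frustum model per segment,
  lateral surface `π(r₁+r₂)·√(L² + (r₁−r₂)²)`, volume
  `(π/3)·L·(r₁²+r₁r₂+r₂²)`), branch-point and terminal counts,
  centrifugal branch order, path length to the soma, diameter taper,
  and Sholl profiles (intersections, branch points, or length per
  radial shell, with exact segment–sphere clipping so shell lengths sum
  to the total).
* **Remodeling actions** on selected dendrites (unbranched sections
  between branch points/tips): `shrink`, `remove`, `extend`, `branch`,
  `scale`.  Selections are manual, by region, or seeded random
  fractions; growth uses a stochastic kernel of short, somewhat randomly
  directed segments radiating away from the parent dendrite and the
  soma.  Achieved length changes match requests to 1e-6 μm.
* **Group comparison**: percent change of group means
  (`100·(treated − control)/control`), SEMs, and radial profiles of
  length or branch points.
* **Synthetic populations**: seeded NeuroMorpho-style pyramidal cells
  (distinct basal/apical subtrees, strict bifurcation, gamma section
  lengths, tapering diameters) so every workflow is testable and
  reproducible without downloads.

## Worked example

`examples/remodel_single_cell.py` generates a CA3-like synthetic cell,
shrinks all apical terminal dendrites by 60%, and branches one basal
terminal with daughters at 80% of the parent's length:

```text
cell: 2084 samples, 8319.9 μm total dendrite

shrink 60% of 30 apical terminals:
  apical length 4117.6 -> 2794.6 μm
  largest request/achieved mismatch: 4.97e-14 μm

branch a 51.2 μm basal terminal (fraction 0.8):
  daughter grown: 40.933 μm (requested 40.933)
  daughter grown: 40.933 μm (requested 40.933)
  branch points 54 -> 55

exported SWC: 2106 samples, ids contiguous and parent-before-child
```

Each apical terminal lost exactly 60% of its own length (the mismatch
line shows the worst per-section deviation); the branch action turned
one tip into a branch point carrying two new 40.9 μm daughters.  The
other examples cover single-cell analysis (`analyze_single_cell.py`),
the two chronic-stress population recipes
(`stress_recipes_population.py`) and group radial profiles
(`radial_profiles.py`).

The same workflows are available from the shell:

```sh
remodkit synth   --n 25 --seed 7 --preset ca3 --outdir cells/
remodkit analyze cells/cell_001.swc --out analysis/
remodkit apply   --in cells/cell_001.swc --out out/cell_001_mod.swc \
                 --recipe ca3-stress --seed 42
remodkit compare --group-a cells/ --group-b out/ --out comparison/
```

Multi-step pipelines can also be given as a YAML/JSON config of ordered
`select`/`action` steps (see `remodkit apply --help`); every run writes
a manifest with the seeds needed to reproduce its outputs byte for byte.

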