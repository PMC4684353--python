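# airwaygen

Patient-based **complete conducting airway tree models**: volume-filling
generation of the distal airways, Horsfield-order diameter assignment,
bronchial morphometry and nonlinear airflow resistance.

High-resolution CT resolves the bronchial tree only down to roughly
generation 6–10, but the conducting airways continue to about generation 16,
and the small airways beyond CT visibility dominate pathology in asthma and
COPD. `airwaygen` extends imaging-derived central airway centrelines into the
volumes bounded by the five lobar surfaces, producing a complete conducting
tree to the acinar level (~30 000 terminal bronchioles, one per 187 mm³ mean
acinar volume), and then asks the quantitative questions one would ask of a
real bronchial tree: its morphometry (branching angles, length and calibre
ratios, Horsfield/Strahler orders) and its resistance to airflow under a
nonlinear (Pedley) pressure-drop model.

It is intended for researchers in computational lung physiology who need
complete, subject-based airway geometries for reduced-dimensional ventilation
models — and for anyone who wants a self-contained, testable implementation
of the classic volume-filling airway generation algorithm.  A synthetic
anatomy generator (five watertight lobe-like volumes plus a central tree with
CT-like calibres and depths) replaces the imaging front end, so the entire
pipeline runs and is tested with no patient data.

## The model in brief

**Growth.**  A cubic grid of seed points (spacing `V_acinus^(1/3)`,
`V_acinus = 187 mm³`) fills each lobe; each seed stands for one acinus.
While seeds remain: each seed is assigned to the closest open branch end in
its lobe (seeds farther than the adaptive threshold
`T = max(V_b − n·V_b/N, 5 mm)` from every apex are discarded); each apex's
seed set is split in two by the plane through the set centroid and the apex
branch axis; a new branch grows 40 % of the way towards each half's centroid.
A pathway terminates — consuming its nearest remaining seed — when its set is
a single seed or its remaining reach falls below the 2 mm terminal-bronchiole
length.  Branching angles are limited to 60°, and endpoints are kept inside
the host lobe.

**Diameters.**  Generated airways get lumen diameters from their Horsfield
order x via

    log D(x) = (x − N) log(Rd_H) + log(D_N),      Rd_H = 1.15,

extrapolated either from the trachea (*tracheal* scheme) or from each
generated subtree's most distal measured branch (*parent* scheme, which
propagates measured luminal narrowing into the unseen periphery).

**Resistance.**  Each airway is a circular tube with Poiseuille resistance
`R_p = 128 μ l / (π d⁴)`, multiplied by the Pedley entrance-flow factor
`Z = (c/4)·√(Re·d/l)` when `Z > 1` (`c = 1.85`,
`Re = 4 ρ |Q| / (μ π d)`).  Mass conservation at every bifurcation, zero
pressure at every terminal bronchiole and a prescribed tracheal flow give a
nonlinear network solved by fixed-point iteration with a direct sparse solve
per step.  Longitudinal calibre heterogeneity of measured airways is kept by
summing per-segment Poiseuille resistances along each centreline.

## Worked example

```python
from airwaygen import (AnatomyConfig, GenerationConfig, DiameterScheme,
                       make_anatomy, generate_complete_tree, apply_scheme,
                       assign_generations, assign_horsfield_orders,
                       summarize, solve_flow, total_resistance)

lobes, central = make_anatomy(AnatomyConfig(rng_seed=1))
tree, stats = generate_complete_tree(central, lobes, GenerationConfig(rng_seed=1))
assign_generations(tree); assign_horsfield_orders(tree)
apply_scheme(tree, DiameterScheme(mode="parent"))

print(len(tree.branches), "branches,",
      sum(stats.consumed.values()), "seeds consumed")
m = summarize(tree).summary["mean"]
print(f"mean branching angle {m['theta']:.1f} deg, D/D_parent {m['D_over_D_parent']:.2f}")
state = solve_flow(tree, 0.17e-3, model="pedley")
print(f"R_total at 0.17 L/s: {total_resistance(state)/98066.5:.2f} cmH2O.s/L")
```

prints

```
58811 branches, 29361 seeds consumed
mean branching angle 42.3 deg, D/D_parent 0.83
R_total at 0.17 L/s: 0.66 cmH2O.s/L
```

— a complete conducting tree whose ~29 000 terminal bronchioles each serve
one acinus, with cast-study-like morphometry and a physiologically plausible
total airway resistance at quiet-breathing flow.

The same pipeline is scriptable from the shell:

```sh
airwaygen synth --seed 1 -o anatomy/
airwaygen generate --airways anatomy/central_tree.vtk --lobes 'anatomy/lobe_*.stl' \
                   --seed 1 -o complete.vtk
airwaygen diameters --tree complete.vtk --scheme parent -o complete_d.vtk
airwaygen morphometry --tree complete_d.vtk -o morpho.csv
airwaygen resistance --tree complete_d.vtk --flow 1.67 --decompose -o r.json
airwaygen run --seed 1 -o full_run/        # everything, plus a manifest
```

Centreline trees exchange as legacy-VTK ASCII polydata (`.vtk`, with a
`radius` point array and `origin`/`lobe` cell arrays) or as a
`nodes.csv`/`edges.csv` pair; lobar surfaces as STL/OFF/PLY.

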