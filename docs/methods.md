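# Methods

`airwaygen` builds complete conducting airway trees — trachea to terminal
bronchioles — by extending a central (imaging-derived) centreline tree into
the volumes bounded by the five lobar surfaces, and computes bronchial
morphometry and nonlinear airflow resistance on the result.  This note
documents the model, its assumptions, every tunable parameter, what the
synthetic anatomy does and does not emulate, and the numerical choices made
where the design was genuinely open.

## 1. Data model

An airway tree is a rooted, strictly bifurcating tree of *branches*; a branch
is a polyline of centreline nodes (proximal → distal) with a lumen radius per
node, spanning one bifurcation (or the inlet) to the next (or a tip).
Branches are tagged `ct` (measured) or `generated`.  Trifurcations are
rejected at load: the growth algorithm only ever bifurcates, and the
minor/major-child morphometry assumes child pairs.  Host volumes are closed
triangulated surfaces (validated watertight with consistent winding).

Conventions with algebraic consequences:

* **Generation**: trachea 0, child = parent + 1 (Weibel numbering).
* **Horsfield order**: terminals 1, parent = max(child orders) + 1.
* **Strahler order**: terminals 1, parent increments only on equal children.
* **Branch diameter D**: generated branches carry one assigned diameter; a
  measured branch's D is the mean of `2 × radius` over the nodes it *owns*
  (every path node past the junction shared with its parent; the root owns
  all of its nodes).  Owning the junction radius exactly once means scaling a
  branch's radii by `f` scales its D by `f` — which makes lumen-constriction
  and parent-scheme scaling arguments exact.
* **Units**: files and the tree are in mm (flows in L/s at the CLI); the
  resistance module converts to SI internally.

Point-in-lobe queries use ray casting: a point is inside iff a ray crosses
the closed surface an odd number of times.  Rays that graze a vertex or edge
(detected by near-degenerate barycentric coordinates or near-zero hit
distance) are retried against a fixed table of directions, so classification
is deterministic and independent of call order.  Points exactly on a face
classify as inside.

## 2. Volume-filling growth of the distal airways

A cubic lattice of seed points fills each lobe, anchored at the lobe
bounding-box minimum corner, with spacing `V_acinus^(1/3)` so that each seed
accounts for one mean acinar volume (`V_acinus = 187 mm³`; ≈ 29 400 seeds for
a 5.5 L lung).  Each seed will become one terminal bronchiole.  The distal
ends of the measured tree are the starting growth apices; every apex and
seed belongs to one lobe, and lobes grow independently.

Breadth-first over growth rounds `n = 0, 1, …`, while seeds remain:

1. Every remaining seed is assigned to the closest apex (Euclidean distance
   to the apex's distal node; ties to the lowest branch id).  Seeds farther
   than `T = max(V_b − n·V_b/N, 5 mm)` from every apex are discarded
   permanently (`V_b` = lobe bounding-box diagonal; `N` = 25 nominal maximum
   generations).  The threshold comparison is inclusive.  In practice this
   discards a handful of seeds per subject, suppressing spurious long late
   branches.
2. Each apex's seed set is split into two non-empty sets by the plane through
   the set centroid and the apex branch's two end nodes.  If centroid and
   branch axis are collinear, the fallback plane passes through the apex
   distal node normal to the branch axis; if all points lie on the plane,
   they are split in half along the projection.
3. For each half, a branch grows from the apex distal node 40 % of the way
   to the half's centroid.  A deviation from the apex direction beyond 60° is
   rotated back to 60° (the angle limit inherited from the base volume-filling
   algorithm; configurable, `None` disables).  An endpoint outside the lobe is
   pulled back by halving the branch towards the apex (after five halvings
   the branch closes as terminal).
4. A pathway terminates when its seed set holds a single point, or when its
   remaining reach (apex to set centroid) is below the prescribed terminal
   length (2 mm).  Each terminal branch removes the seed point closest to its
   distal end from the global set.  An apex assigned exactly one seed closes
   itself the same way (one point cannot be plane-split), and an apex
   assigned no seeds stays open for later rounds.

Seed accounting is exact: every seed is either consumed by a terminal branch
or discarded by the threshold rule, and the growth statistics
(`GrowthStats`) record both per lobe and per round.

**The 2 mm rule is compared against the pathway's remaining reach, not the
40 %-grown branch length.**  This is the one place the algorithm's prose
admits two readings, and they diverge dramatically on a lattice of
acinar-spaced seeds: compared against the grown length, the rule fires on
~70 % of terminals, each stranding its residual seed set one generation
deeper; the cascades inflate the mean terminal generation by ~2 and drive
sibling subtrees far out of balance (D_minor/D_major ≈ 0.77,
mean branching angle ≈ 54°).  Compared against the reach, the rule is a
rarely-triggered guard (the single-point rule does almost all termination),
clusters resolve by balanced recursive splitting, and the emergent
morphometry lands where bronchial trees of this construction are reported to
land (mean terminal generation ≈ 15.6, branching angle ≈ 42°).  The reach
reading is the package's choice.

The loop is deterministic for a fixed configuration; `rng_seed` only drives
the optional seed-lattice jitter (off by default — the grid is uniform).

## 3. Diameter assignment

Generated airways are 1-D line segments and need diameters before
simulation.  With Horsfield orders computed on the *complete* tree (a
measured branch's order depends on the generated subtree hanging from it),

    D(x) = D_N · Rd_H^(x − N),      Rd_H = 1.15,

extrapolates from a base airway of order `N` and diameter `D_N`:

* **tracheal** — the trachea is the base for all generated branches;
* **parent** (default) — each generated subtree's base is its most distal
  measured ancestor, so measured luminal narrowing (e.g. asthmatic
  constriction) propagates into the unseen periphery.

A floor (default 0.2 mm) guards against sub-physiological diameters in deep
asymmetric subtrees; it is rarely binding.  Measured branches keep their
per-point radii untouched, and the assignment is idempotent.

## 4. Morphometry

Angles use end-to-end branch chords (stable on noisy polylines): the
branching angle θ is the angle between parent and child chords; the rotation
angle ϕ is the angle between the parent-and-sibling plane and the plane of
the two children, folded into [0°, 90°], reported missing on degenerate
(collinear) planes.  The minor/major child is the smaller-/larger-diameter
child (ties to the lower branch id); `L1/L2` is shorter over longer child
length; θ is additionally stratified by parent diameter (>4, 4–3, 3–2,
2–1 mm, half-open downward).  Subject-level aggregation takes the mean of
per-branch values within each tree, then mean ± SD across trees.

## 5. Airflow resistance

Airways are circular tubes (consistent with centrelines carrying a single
radius per point).  Per airway,

    R = Z·R_p  if Z > 1,  else R_p
    R_p = 128 μ l / (π d⁴)
    Z   = (c/4) · √(Re · d / l),    Re = 4 ρ |Q| / (μ π d)

with air at body temperature (ρ = 1.15 kg/m³, μ = 1.92·10⁻⁵ Pa·s) and
c = 1.85.  Longitudinal heterogeneity of measured airways is kept by summing
per-segment Poiseuille resistances (segment diameter = mean of its endpoint
diameters); the entrance-flow factor Z develops once per airway and therefore
uses the full branch length, which makes a uniform branch's resistance exactly
independent of how finely its centreline is subdivided.  Only viscous
dissipation is modelled — no kinetic-energy pressure changes — and |Q| in Re
makes the model symmetric between inspiration and expiration (the reported
expiratory increase of c is not modelled).

The network solve prescribes the inlet flow at the trachea entrance and zero
pressure at every terminal bronchiole; conservation of mass holds at each
bifurcation.  Because R depends on Q the system is nonlinear: a fixed-point
iteration starts from the Poiseuille solution, alternates a direct sparse
nodal solve with resistance updates, and stops when the l∞ relative residual
of `R(Q)·Q = ΔP` (scaled by the inlet pressure) falls below 10⁻⁸ (at most
100 iterations; typically ~10–30 at high flow, exactly 1 for Poiseuille, and
1 when re-entered with a converged state's flows).

Two decompositions are provided.  Per-branch/per-generation contributions use
the viscous power fraction `R_b Q_b² / (R_total Q_in²)`, which always sums
to 1 and reduces to the pressure-drop share on symmetric trees.  The
generated-airway share of total resistance compares the measured-tree model
solved on its own against the complete model, `1 − R_central/R_complete` —
the two-model comparison that the fraction is defined by.  Totals are SI
internally; the CLI also prints cmH₂O·s/L (= 98 066.5 Pa·s/m³).

## 6. Synthetic anatomy: what it emulates, and what it does not

The generator stands in for the imaging front end and is calibrated to the
statistics reported for CT cohorts, not to any one anatomy:

* **Lobes** — five ellipsoids flattened against oblique fissure planes
  (projection preserves mesh connectivity, hence watertightness), scaled to
  the exact target volumes: 5.5 L adult inspiratory lung, fractions
  RUL/RML/RLL/LUL/LLL = 0.20/0.10/0.25/0.20/0.25, arranged in
  left/right–upper/lower slots with disjoint bounding boxes.
* **Central tree** — trachea (18 mm diameter, 100 mm long) descending to a
  carina, then recursive bisection of per-lobe point clouds using the same
  plane-splitting rule as the growth algorithm.  Calibres are inherited
  asymmetrically: the child feeding the larger subtree narrows by 0.78 per
  generation, its sibling by 0.63 (matching measured central-airway
  D_major/D_parent, D_minor/D_parent and their 0.70 mean); setting
  `child_diameter_ratio` forces a symmetric homothety instead.  Branch
  lengths take the volume-filling 40 % step floored at 3.7 diameters (the
  measured central L/D).  The tree stops where the child calibre falls below
  the CT visibility limit (2 mm) or at the depth cap (10): terminal segmented
  generations then span ~4–7 with mean ≈ 6 and tip diameters 2.3–3.3 mm.
  Every tip is placed strictly inside a lobe — a tip outside lobar tissue
  would act as a wide-open outlet in the ventilation solve and shunt most of
  the inlet flow.
* **Constriction (asthma-like)** — an optional heterogeneous narrowing: a
  random 30 % of measured branches have their owned radii multiplied by a
  factor drawn uniformly from [0.4, 0.8].  With fraction 1 and a constant
  factor f every branch diameter scales by f exactly (Poiseuille resistance
  by f⁻⁴), and narrowing always increases total resistance.

Not emulated: real lobe shapes and fissure anatomy (only volumes, positions
and watertightness matter downstream); airway curvature (branches are
straight, subdivided polylines); the minimum-radius bias and noise of real
CT segmentations; cartilage rings, wall thickness, or any dynamic behaviour.
Tests passing on this anatomy therefore validate the algorithms and their
emergent statistics, not anatomical realism per se.

## 7. Emergent statistics and known limitations

On the default anatomy (~29 400 seeds, ~58 800 branches; built in ~40 s and
solved in a few seconds on one CPU — the problem sizes used throughout the
test suite, with a ~150 mL miniature for unit tests), the pipeline yields
mean terminal generation ≈ 15.6, mean branching angle ≈ 42.3°,
D/D_parent ≈ 0.83, L1/L2 ≈ 0.66, L/D ≈ 4.6, total resistance ≈ 0.66
cmH₂O·s/L at 0.17 L/s, and a generated-airway resistance share of ≈ 0.62
(vanishing flow) falling to ≈ 0.36 at 1.67 L/s, with a seed-to-seed spread
of a few hundredths.

Two per-bifurcation statistics sit outside the ranges reported for CT-based
cohorts and are documented rather than adjusted: sibling calibre symmetry
(our D_minor/D_major ≈ 0.91 versus reported ≈ 0.97 — under the log-linear
diameter law, 0.97 would require near-perfectly height-balanced sibling
subtrees, which plane-splitting of a seed lattice does not enforce) and the
length-contraction ratio (our per-bifurcation mean L/L_parent ≈ 0.95 versus
reported ≈ 0.89; the ratio-of-means variant is ≈ 0.86, bracketing it).

## 8. Defaults

| Parameter | Default | Meaning |
|---|---|---|
| `acinar_volume` | 187 mm³ | seed-lattice cell volume (one acinus per seed) |
| `growth_fraction` | 0.40 | fraction of apex→centroid distance grown |
| `min_branch_length` | 2 mm | terminal reach limit (terminal-bronchiole length) |
| `threshold_floor` | 5 mm | floor of the adaptive assignment threshold |
| `max_generations` (N) | 25 | sets the threshold decrement V_b/N |
| `angle_clamp` | 60° | maximum branching angle (None disables) |
| `rd_h` | 1.15 | diameter anti-log slope per Horsfield order |
| `diameter_floor` | 0.2 mm | minimum assigned diameter |
| `total_lung_volume` | 5500 mL | adult inspiratory volume |
| `trachea_diameter` / `length` | 18 / 100 mm | inlet geometry |
| `major/minor_diameter_ratio` | 0.78 / 0.63 | central calibre inheritance |
| `length_to_diameter` | 3.7 | central branch L/D target |
| `min_segmentable_diameter` | 2 mm | CT visibility limit ending the central tree |
| `central_generations` | 10 | hard cap on central-tree depth |
| `density` / `viscosity` | 1.15 kg/m³ / 1.92e-5 Pa·s | air at body temperature |
| `pedley_c` | 1.85 | entrance-flow dissipation constant |
| solver `tol` / `max_iter` | 1e-8 / 100 | l∞ relative residual / iteration cap |
| flow rates | 0.17, 0.83, 1.67 L/s | low / moderate / high tracheal flows |

Every default is exposed in configuration dataclasses and printable with
`airwaygen config`.
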