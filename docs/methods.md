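# Methods

`ligmem` studies how small lignin-derived solutes (guaiacyl and syringyl
units and a trimeric derivative) adhere to, insert into, and aggregate on a
ceramide bilayer — the dominant lipid of the stratum corneum, the skin's
outermost permeability barrier. Because desk-scale re-analysis cannot rerun
microsecond all-atom MD, the package pairs every analyzer with a synthetic
generator whose ground truth is known exactly, and implements the
forward–reverse (FR) nonequilibrium estimator used to obtain the insertion
free-energy profile. Units are fixed throughout: Å, ns, kcal/mol, K, with
kB = 1.9872041e-3 kcal/mol/K.

## 1. One-dimensional solute dynamics

The solute centre-of-mass coordinate along the bilayer normal z moves on a
membrane potential U(z) (`PotentialSpec`: flat, linear, harmonic, quartic
double-well, or cubic-spline tabulated — the spline keeps the gradient
continuous). Dynamics are overdamped Langevin, integrated by
Euler–Maruyama:

    z ← z − D U′(z)/(kB T) dt + sqrt(2 D dt) η,  η ~ N(0,1),

with reflecting boundaries at the domain edges. Euler–Maruyama with a
stability guard was chosen over higher-order schemes because the guard
makes the discretisation error controllable and the scheme trivially
reproducible: the check dt·D·max|U″|/(kB T) < 0.1 is enforced wherever a
potential meets a parameter set (for pulls the spring constant is added to
the curvature bound, since the spring is part of the effective potential).
Inside the integrator the gradient is evaluated from a dense uniform lookup
table (4097 nodes, linear interpolation); at the mandated step sizes the
table error is orders of magnitude below the discretisation error. A single
integer seed fixes the entire path bit-for-bit.

Typical parameters: D = 20–100 Å²/ns (small-molecule diffusivity near a
lipid–water interface), T = 300/310/320 K matching the study's thermal
conditions, dt set by the stability guard (2–10 × 10⁻⁵ ns at D = 100 and
spring k = 10).

## 2. Steered pulls and work accumulation

A harmonic guide λ(t) moving at constant speed v drags the coordinate; the
spring force on the particle is f = k(λ − z) and the external work is
accumulated per step by the trapezoidal rule W += ½(f_i + f_{i+1}) v dt
(signed v, so downhill reverse pulls accumulate negative work). Records
(t, λ, z, f, W) are kept every `record_stride` steps; with stride 1 the
stored W re-integrates exactly from the stored f; at coarser strides the
re-integration is a resolution-limited consistency check because f is an
instantaneous, thermally fluctuating quantity.

Initial states are drawn from the Boltzmann distribution of U(z) plus the
spring pinned at z_start (discrete inverse-CDF sampling on a dense grid).
This matches the stiff-spring assumption, is exactly reproducible, and
replaces the original protocol's "variety of initial conformations from
fast pre-pulls", which is not reproducible from the text.

The default spring constant k = 10 kcal/mol/Å² is not printed in the source
protocol; at v = 0.1 Å/ns and D ≥ 50 Å²/ns the steady-state guide–particle
lag (kB T/D)·v/k is below 0.05 Å, comfortably inside the stiff-spring
regime, while keeping the stability guard satisfiable at desk-scale step
counts.

**Domain padding.** The coordinate domain must extend a few Å beyond the
pulled interval. If a reflecting edge coincides with a pull endpoint, the
wall performs unaccounted work on the particle near the turnaround and the
estimator inherits a kBT-scale artefact concentrated at the edges; padding
by ~3–5 Å (with the potential's own tails acting as soft walls) removes it.
This was measured directly on the flat-potential null.

## 3. Forward–reverse PMF estimation

Forward pulls traverse z = 0 → 19 Å (bilayer centre to surface), reverse
pulls the same interval backwards, at the same |v|. Let a denote the
forward start. On a uniform z grid (default 0.5 Å, fine enough to resolve
the few-Å features of membrane insertion profiles):

* forward traces contribute W_F(z), the cumulative work interpolated at the
  grid nodes (work is treated as a function of guide position λ — the
  stiff-spring reading — which makes the F and R spatial axes commensurate);
* reverse traces are re-indexed to the same axis as the *segment* work
  between z and a: W_R(z) = W_total − W(λ = z).

In the overdamped linear-response regime the dissipation over a given
segment is the same in both traversal senses, so it cancels in the
half-difference and adds in the half-sum:

    ΔU(z) = ½(⟨W_F(z)⟩ − ⟨W_R(z)⟩),   W_d(z) = ½(⟨W_F(z)⟩ + ⟨W_R(z)⟩) ≥ 0.

ΔU is shifted so ΔU(anchor) = 0 (default anchor z = 19 Å, the bulk-adjacent
endpoint); its standard error is ½·sqrt(SE_F² + SE_R²). Grid nodes may
exceed the recorded λ range by at most one recording step (the guide ends
within one step of z_end when dt does not divide the traversal time
exactly); anything farther is an error.

A note on direction relabelling: because the reverse re-indexing is what
recovers U(z), swapping the F/R labels of the *traces* changes only the
reference endpoint — the anchored profile is invariant, not negated.  The
exact antisymmetry lives one level up: swapping the mean-work columns of a
`MeanWorkProfile` negates the unanchored ΔU identically. Both properties
are tested.

The optional diffusivity profile D(z) = kB T v / W_d′(z) follows from the
same linear-response framework (it is reconstructed from the method the
work bookkeeping is based on, not an independently published result of this
analysis). The slope of W_d is taken by central differences and reported
only where positive and statistically significant; the significance test
uses standard errors of per-pull work *increments*, because cumulative-work
standard errors are strongly correlated between nodes and would mask real
slopes. Non-significant or non-positive-slope nodes are NaN — never a
negative D.

Default ensemble size is 20 pulls per direction ("several pulls" in the
original protocol is not a number); at v = 0.1 Å/ns, D = 100 Å²/ns the
dissipation over 19 Å is ≈ 0.01 kcal/mol, giving a statistical error of
ΔU ≈ 0.02 kcal/mol and an RMSE against the generator's double-well truth
of < 0.1 kcal/mol.

## 4. Synthetic bilayer scenes

The scene builder emulates the *geometry* the analyzers consume, not the
physics of a real bilayer:

* **Lipids** — 400 per leaflet by default (800 total, matching the study
  composition), each a 5-pseudo-atom rod: headgroup nitrogen NF on the
  ±20 Å leaflet planes (Gaussian lattice jitter, default 0.4 Å) and four
  chain carbons pointing to the bilayer centre. The toy lipid is the
  smallest topology that supports leaflet assignment, density profiles and
  any-atom clustering.
* **Water** — single-site pseudo-atoms filling the |z| > leaflet_z slabs
  uniformly at a requested number density (default 0.0334 Å⁻³, bulk water).
* **Solutes** — an m×m lateral grid (3×3 and 5×5 are the study's two
  concentrations; with 800 lipids these give the printed 1:89 and 1:32
  molar ratios). Each solute is a hinged two-arm pseudo-molecule whose
  end-to-end distance (terminal oxygens O4–O9) and arm dihedral are drawn
  per frame from plantable mixtures. Defaults follow the observed
  conformers: compact ≈ 5.5 Å / extended ≈ 8.0 Å end-to-end, dihedral modes
  at 15° and 90° (midpoints of the observed 0–30° and 75–105° ranges).
  Solute COM z-trajectories come from the Langevin generator.
* **Planted features** — exact ground truth for closing the
  generator→analyzer loop: hydrogen-bond geometries as (d_DA, angle_HDA)
  pairs realised literally (donor–H at 1 Å, acceptor placed at the
  requested distance/angle, pairs isolated beyond any criterion); clusters
  as molecule groups placed in 3.2 Å corresponding-atom contact with ≥ 8 Å
  clearance between groups.

Randomness uses named substreams (scene, conformers, dynamics, planting) of
one seed, so identical specs give bit-identical coordinates. What the
scenes do **not** emulate: atomistic packing, water structure and hydrogen
atom detail, lipid conformational disorder, electrostatics, and any
coupling between solutes and lipids. A passing analyzer test therefore
certifies the *measurement*, not membrane physics.

Known mismatches carried deliberately: ion counts are metadata only; total
atom counts of the original systems are not reproduced (the source table's
totals are internally inconsistent); solutes are 8 pseudo-atoms, not
all-atom monolignols.

## 5. Observables

All pair distances use orthorhombic minimum-image in x and y only; z is
non-periodic (slab geometry). Defaults and conventions, all configurable
and logged in each output's JSON sidecar:

* **COM z-distance** — mass-weighted solute COM z minus the mean z of the
  reference atoms (default: upper-leaflet nitrogens). Negative = inserted
  below the plane. Pseudo-atoms default to unit mass.
* **Profiles** — density axis is z minus the per-frame bilayer centre
  (mean z of lipid atoms; leaflets are assigned per frame by the sign of
  z − centre, so flip-flopping lipids would change leaflet membership).
  Counts mode satisfies Σρ = N exactly; number-density mode divides by
  area × bin width. Symmetrisation (±z averaging) is off by default. Bin
  widths: 0.5 Å (density), 1.0 Å (distance distributions), 15° (dihedral).
* **Hydrogen bonds** — geometric criterion d(D,A) ≤ 3.5 Å and
  angle(H–D–A) ≤ 30°, a widely used MD-analysis default; the original
  analysis does not print its criterion, so absolute counts are
  criterion-dependent and every output records the criterion used.
* **Clustering** — single linkage over molecules with an any-atom cutoff,
  default 3.5 Å (consistent with the hydrogen-bond length scale that
  drives aggregation); connected components via the sparse graph solver.
  Per-species normalised count = clusters containing the species /
  molecules of the species.
* **SASA** — Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points, probe 1.4 Å), occluders = all non-water atoms;
  radii from a Bondi-style element table, overridable and logged. The
  two-sphere analytic-cap error at 960 points is < 2 %.
* **Conformations** — end-to-end distance of named terminal atoms; signed
  dihedral in (−180°, 180°] by the standard convention; 2-D maps are
  normalised to unit total mass.

## 6. Numerical choices and degenerate inputs

Probability densities renormalise the histogram sum exactly, so the unit
integral holds to 1e-9 regardless of float rounding. Empty selections,
zero-atom files, truncated trajectory frames, mixed pull protocols, grids
outside the traversed interval, donors without bonded hydrogens, and
non-positive cutoffs are hard errors naming the offending frame/line where
applicable; unknown selection names degrade to empty matches with a logged
warning (useful in sweeps where a species is legitimately absent). PMF
minima in reports are refined by a local quadratic fit through the three
nodes around the grid minimum.

## 7. Problem sizes used in the shipped checks

The test suite and the acceptance script run the chain at desk scale,
chosen so each stage completes in seconds while keeping statistical
tolerances honest: 20 pulls per direction at dt = 4×10⁻⁵ ns (≈ 4.8×10⁶
steps per pull), Langevin equilibrium runs of 2–4×10⁶ steps, scenes of
16–400 lipids per leaflet with up to 400 frames, and oracle comparisons on
100 randomised frames of ≤ 300 atoms. Statistical assertions use fixed
seeds; tolerances follow from the propagated standard errors at these
ensemble sizes, not the other way around.

## 8. Limitations

* The FR estimator assumes overdamped linear response and a stiff spring;
  strongly curved potentials (U″ comparable to k) bias the profile near
  steep regions, and the shipped defaults keep max|U′| ≲ 2 kcal/mol/Å.
* The diffusivity profile is meaningful only where dissipation dominates
  noise; at the default slow-pull conditions most nodes are legitimately
  reported as NaN.
* Scenes are static in lipids/water across frames; observables that would
  depend on lipid dynamics (order parameters, area per lipid, H-bond
  lifetimes) are out of scope.
* Absolute hydrogen-bond counts depend on the geometric criterion, which
  the original analysis does not specify; only criterion-tagged numbers
  are comparable.
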