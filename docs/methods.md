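# Methods

## Particle-energy model

The energy per molecule of a faceted nanocrystal is modelled as the bulk
term plus a surface penalty:

```
E_particle(r, phi) = E_latt-inter + dE_intra + sum_f x_f(r, phi) * (-0.5 * E_att,f)
```

`E_latt-inter` is the intermolecular lattice energy, `dE_intra` the
intramolecular conformational penalty (both kJ/mol per molecule;
`dE_intra` defaults to 0 so a single combined bulk energy can be supplied).
`E_att,f <= 0` is the attachment energy of facet family `f`; half its
magnitude is the energy a surface molecule is missing relative to a bulk
molecule, which is why the per-molecule surface penalty is `-0.5 * E_att`.
The model assumes idealized convex habits and neglects surface relaxation
and edge/corner energies, so it is a first-order (1/r) surface correction:
reliable for sizes well above the interplanar spacings, and flagged invalid
(`x_total > 1`) when the particle becomes thinner than its own surface
layer.

### Surface fractions

A habit is a centrosymmetric convex polyhedron stored in half-space form
(one unit normal and origin-plane distance per facet family, expanded to
the Friedel pair).  scipy's `HalfspaceIntersection`/`ConvexHull` construct
and measure it.  The fraction of molecules in the surface layer of family
`f` is taken as the one-interplanar-slab estimate

```
x_f = A_f * d_f / V
```

with the facet-family area `A_f` (both faces of the +/- pair) in nm^2, the
d-spacing `d_f` converted from angstroms (10 A = 1 nm), and the hull
volume `V` in nm^3; the molecular number density cancels.  An alternative
`shell` mode shrinks every plane by its own d-spacing and apportions the
outer-minus-inner hull volume by `A*d` weights; both modes agree as
`r -> infinity` and `slab` is the default.  The slab estimate differs from
the literally counted shell by an `O(d/L)` edge term (largest for small
facets, a few percent at PED 60 nm for the synthetic pair); the test suite
pins this against a brute-force point-in-slab Monte Carlo oracle at two
sizes.

Sizes are reported as PED, the diameter of the equal-volume sphere
(`V = (pi/6) PED^3`).  For a fixed shape `x_f * PED` is exactly constant,
so the surface penalty is `c / PED` with a shape-dependent coefficient `c`
(kJ/mol nm); the package computes `c` once per shape and uses the closed
form `PED* = (c_A - c_B) / (E_bulk,B - E_bulk,A)` for stability crossings,
verified against bisection on the directly evaluated curves.  Crossings
below 1e-6 nm are reported as "none": they are far below the model's
validity and arise only from round-off when the coefficients tie.

### Habits and aspect ratios

The attachment-energy habit places each family's plane at a distance
proportional to `|E_att|` and normalises the volume.  Shape sweeps reshape
a habit by diagonal scaling along its bounding-box axes (relabelled so
L >= W >= T) until the box ratios match the requested (L/T, W/T); the
half-spaces transform covariantly (`n -> Lambda^{-1} n`, renormalised) so
facet identities survive and per-family areas are re-measured on the
rebuilt hull.  The canonical sweep uses 24 evenly spaced levels on
[1, 14], giving the standard 300 canonical pairs with W/T <= L/T.
Bounding-box axes were chosen as the reference frame because they are
shape-intrinsic and reproducible; no crystallographic axis convention is
implied.

### Switch statistics

Random habits are drawn uniformly on the canonical triangle
{1 <= W/T <= L/T <= 14}, independently for each polymorph, and the switch
probability at a size is the fraction of pairs in which the
bulk-metastable form has strictly lower particle energy (ties and
equal-bulk-energy pairs count as no switch).  The default sample size is
100,000 pairs with an explicit seed.

Evaluating 2 x 100,000 hulls is avoided by an exact shortcut: under a
diagonal scaling `Lambda`, a face's area vector maps as
`det(Lambda) * Lambda^{-1} * A` and the combinatorial face structure of a
convex polytope is unchanged, so every aspect-ratio transform of a base
habit has per-family areas available in closed form.  The vectorised path
is cross-checked in the tests against explicit hull reconstruction to
1e-8 relative, and the Monte Carlo statistics against exhaustive
enumeration on a fine aspect-ratio grid.

The crossing-size distribution has a broad, flat mode, so both the mode
(most likely switch size) and the full histogram are reported; the mode of
a 100,000-sample histogram with 60 bins over [0, 200] nm is reproducible
to about one bin.

## Synthetic polymorph pair

The fixture generator emulates a conformational-polymorph drug system with
a nanoscale stability switch: the bulk-stable form (bulk energy
-400 kJ/mol) carries more expensive surfaces than the metastable form
(-395 kJ/mol, gap 5 kJ/mol).  Cells are low-symmetry (monoclinic /
orthorhombic) at drug-molecule dimensions.  Facet families were chosen so
each form's d-spacings sit within a ~15 % band; with comparable slab
thicknesses the attachment-energy habit sits near the optimum of the
penalty landscape and the surface-penalty minimum falls on the most equant
habit of the sweep, as observed for the drug-crystal case being emulated.

Attachment energies are drawn from a seeded uniform band (+/-25 % around
130 kJ/mol).  Because the two cells differ in d-spacings and habit
geometry, raw `|E_att|` ratios do not control the penalty ratio; the
generator therefore rescales the metastable form's energies — which leaves
its habit unchanged and scales its penalty exactly linearly — so that the
ratio of the two forms' attachment-energy-habit penalty coefficients
equals `penalty_contrast` (default 0.68).  These defaults put the
attachment-energy-habit crossing near 28 nm, the switch-probability curve
near zero at 100 nm rising to ~0.6 at 20 nm, and the switch-size mode in
the tens of nanometres — the phenomenology of the emulated system.  The
fixture demonstrates the machinery; quantitative statements about any real
polymorph pair require its DFT facet energies, for which validating
templates are shipped with every `E_att` left null.

What the synthetic pair does *not* emulate: real facet sets with symmetry
multiplicities, solvent-dependent surface stabilisation, thermal/entropic
corrections, and any kinetic (nucleation) effect.  Passing tests therefore
show the geometry, the energy model and the statistics are computed
correctly — not that any particular real system switches at these sizes.

## Milling population balance

State: number density `n(y)` over the dimensionless diameter `y` on a
uniform finite-volume grid, plus the supersaturation `S`.  Defaults:
`y` in [0.01, 10] with 300 cells.  Mechanisms:

* **Breakage.** Selection `k_b * y^q` (default q = 3: large particles
  break much faster) with binary uniform-in-volume daughters
  `b(y|y') = 6 y^2 / y'^3`.  The discrete kernel applies a per-source
  two-parameter moment correction (weights scaled by
  `alpha_j + gamma_j y^3`) so each event creates exactly two daughters and
  conserves volume to machine precision; the smallest cell cannot break.
  Both the selection law and the daughter distribution are pluggable
  config choices; the defaults are the minimal standard forms.
* **Ostwald ripening.** Gibbs-Thomson velocity
  `G* = k_g (S - exp(beta/y))` with capillary parameter `beta`
  (default 0.02), giving a critical size `y_n = beta / ln S` below which
  particles dissolve.  The default `beta` keeps the exponential at the
  smallest grid cell moderate, so explicit time stepping remains efficient
  while the critical size stays inside the grid for the supersaturations
  the runs reach.
* **Solute balance.** `S` changes by exactly the solid volume the
  advection step creates or destroys, scaled by `Da_m * (pi/6)`; this
  includes the dissolution flux of particles shrinking past the left grid
  edge (their remaining mass returns to solution, the number loss is
  tracked), making total mass `M = S + Da_m (pi/6) m3` conserved to
  machine precision by construction.  The right boundary is closed; runs
  are configured so no mass reaches it.

Advection uses a van Leer flux-limited upwind finite-volume scheme,
stepped with Heun's explicit two-stage method at CFL 0.5 (the admissible
step also respects an explicit-breakage stability limit `cfl / max
selection rate`).  Negative densities from round-off are clipped at zero
and physically meaningless densities below 1e-200 are flushed (they
otherwise denormalise and slow the arithmetic).  Initial conditions are
log-normal densities evaluated on the grid (deterministic, so runs are
bit-reproducible).

Scenario defaults (A: pure breakage of a coarse population; B: pure
ripening of a fines-rich one, median 0.3; C: both, coarse start) follow
the qualitative milling phenomenology: A grinds the mean size down and
multiplies the particle count at constant solid volume; B dissolves the
fines and coarsens; C reaches a steady state in mean size and
supersaturation, with lower milling intensity or higher initial
supersaturation giving a larger steady size.  `Da_m` is set per scenario
so the dissolved-mass budget is order-unity against `S` (0.02 for the
coarse initial condition with `m3 ~ 54`, 20 for the fines-rich one with
`m3 ~ 0.06`); steady state is declared when both `|d(mean)/dtau|` and
`|dS/dtau|` stay below 1e-6 for ten consecutive output intervals.

The model deliberately omits nucleation and treats a single solid phase;
it answers where the size/supersaturation steady state sits, not which
polymorph forms there — that is the particle-energy model's question.

## Numerical choices and limitations

* Geometry comparisons at 1e-9 relative; aspect-ratio attainment is exact
  (diagonal scaling scales axis-aligned extents exactly).
* Hull degeneracies: volumes below 1e-12 nm^3 and unbounded intersections
  raise geometry errors rather than returning junk.
* Tests run the population balance on reduced grids (>= 100 cells,
  shorter horizons) and the switch statistics at 20,000-100,000 samples;
  these sizes resolve every behaviour asserted while keeping the suite
  quick.
* Facet families are expanded only to Friedel pairs; symmetry-equivalent
  facets must be listed explicitly (no space-group machinery).
* The free energy is approximated by the lattice-energy surface: no
  vibrational/entropic terms, no solvent stabilisation of surfaces, no
  kinetics.
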