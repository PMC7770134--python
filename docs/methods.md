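# Methods

This note records the models implemented in `uaaff`, the defaults and
their rationale, the numerical choices, and what the synthetic test
systems do and do not establish.

## Scope and units

The package covers the desk-scale portion of a UAA force-field
development workflow: charge derivation and benchmarking, and end-point
binding analysis. Quantum-chemical calculations, general force-field
atom typing and molecular dynamics are upstream of this package; their
outputs (ESP grids, bonded/LJ parameters, snapshot series) are inputs
here.

Coordinates are Cartesian Ångström and energies kcal/mol throughout,
except ESP fitting, which runs in atomic units (Bohr, hartree/e) with a
single fixed conversion of 0.52917721 Å/Bohr applied at the call
boundary. The electrostatic constant is the Amber code value
k_e = 332.0637 kcal·Å/(mol·e²), chosen so energies are bit-comparable
with Amber-family implementations.

## Geometry

Torsions use the IUPAC sign convention via the atan2 formulation, which
is stable near 0° and 180°; collinear central bonds raise a
degenerate-geometry error rather than returning noise. Superposition is
the least-squares Kabsch fit (via scipy's rotation alignment, always a
proper rotation); the residual RMSD is recomputed directly from the
transformed coordinates because the solver's internal residual loses
precision near zero. RMSDs are fit and measured on the same atom
selection (heavy or all); pairing is by atom index.

Van der Waals radii default to the Bondi table with one exception:
iodine uses the Pauling radius 2.15 Å, the standard choice for
heavy-halogen amino-acid analogs whose Bondi entry is unreliable for
surface construction. The table is configurable per call.

## Restrained ESP fitting

The fit minimizes

    Σ_k (V_k − Σ_j q_j/|r_k − r_j|)²  +  a Σ_{restrained j} (√(q_j² + b²) − b)

subject to Σ q_j = Q (exact, via a KKT row), equality within declared
equivalence classes, and frozen per-atom values. The hyperbolic
restraint is handled by iteratively reweighted linear solves
(linearizing the penalty derivative around the current charges), the
standard approach; convergence is max |Δq| below a tolerance of
1e-10 e, usually within ten iterations. With a = 0 the first solve is
the exact constrained ordinary-least-squares solution.

Restraint constants are the canonical two-stage values — a = 0.0005
hartree in stage 1, 0.001 in stage 2, width b = 0.1 e, hydrogens
unrestrained — all configurable. Stage 2 freezes every charge at its
stage-1 value except declared refit sets (typically methyl groups) and
applies their equivalences. Equivalence classes are supplied explicitly
rather than detected from graph symmetry; automatic symmetry perception
is out of scope and the explicit form keeps fits reproducible.

Each backbone conformer is fitted independently; the blending stage
(below) is what couples the two states. A joint multi-conformer fit
would be a reasonable variant but is not what the per-state blending
scheme consumes.

Grids follow the Merz–Kollman construction: near-uniform (golden-spiral)
points on spheres at 1.4, 1.6, 1.8 and 2.0 × the van der Waals radius of
every atom, about one point per Å², each atom/shell set randomly rotated
by a seeded generator, and candidates culled inside any atom's scaled
sphere. Grids are deterministic given the seed.

## Amber-form energy and minimization

The five-term potential uses harmonic bonds and angles K(x − x_eq)²,
cosine dihedrals (V_n/2)(1 + cos(nφ − γ)), Coulomb and 12-6
Lennard-Jones with Lorentz–Berthelot combining, no cutoff (gas phase).
1-2 and 1-3 pairs are excluded; 1-4 pairs are scaled by 1/1.2
(electrostatics) and 1/2.0 (van der Waals), the ff14SB convention that
the charge sets are meant to be compatible with. Analytic Cartesian
gradients are implemented for every term and verified against central
finite differences to 1e-6 relative error in the test suite.

Minimization is quasi-Newton (L-BFGS) with a gradient tolerance of
1e-6 kcal/(mol·Å) and a 5,000-step ceiling. Backbone states are
maintained during relaxation with periodic harmonic torsion restraints
k·wrap(φ − φ₀)², default k = 100 kcal/(mol·rad²); the reported energy
is always the unrestrained force-field energy at the relaxed geometry.
Whether published α/β relative energies were evaluated at relaxed MM
geometries or fixed QM geometries is generally under-specified in this
field, so both modes are exposed (`minimized`, the default, and
`single_point`).

## Charge blending and benchmark statistics

A production charge set per residue is the convex combination
w_α·q_α + w_β·q_β on backbone and side-chain atoms, with acetyl and
N-methyl cap charges frozen at their protein-force-field reference
values (blending is affine, so the integer net charge is preserved
exactly). The blend weight is selected per system by a deterministic
grid search minimizing |RE_model − RE_QM| over the fraction set
{β, β·7/8+α/8, β/2+α/2, β/3+α·2/3, β/5+α·4/5, β/6+α·5/6, α}, the
proportions that occur across the published optimization cycles; ties
break toward the larger β weight. This formalizes what is in practice a
manual, per-system adjustment procedure.

Two RMS conventions exist for the benchmark statistic
√(Σ(RE_QM − RE_model)²/D): the printed 18-system RMS row of the
benchmark table is reproduced only with D = N − 1 (4.86, 5.68, 2.33,
0.33, 1.08 kcal/mol), while the published four-system literature
comparison (2.25 and 0.38 kcal/mol over systems 7, 9, 11, 13) requires
D = N. Both are implemented behind an explicit `denominator` flag and
both reproductions are asserted in the acceptance tests, including the
negative control that swapping flags does not reproduce the printed
values. R² is the squared Pearson product-moment correlation, which
reproduces the printed 0.9407 for the final cycle to four decimals.

## MM/PBSA

Single-trajectory convention: receptor and ligand coordinates are
extracted from each complex frame, so bonded terms cancel identically
and ΔE_MM reduces to receptor–ligand cross terms (no 1-4 scaling —
the parts share no bonds). ΔG_bind = ΔE_vdW + ΔE_ele + ΔG_pb + ΔG_np;
the entropy term −TΔS is declared in the options but never computed,
following common practice for relative comparisons. Components are
averaged over snapshots with the population SD √(Σ(xᵢ − x̄)²/N) —
interpreted as a spread (with the square root), which is the only
reading consistent with typical printed ± values.

### Poisson–Boltzmann solver

Finite-difference linearized PB on a regular grid:
∇·(ε∇φ) − ε_s κ² λ(r) φ = −4π k_e ρ. Charges spread to nodes by
trilinear interpolation; Dirichlet boundaries from the Debye–Hückel
monopole superposition; red–black successive over-relaxation with the
textbook optimal ω and a mean-residual stopping tolerance of 1e-6.
Defaults: solute dielectric 1, solvent 80, 300 K, 0.5 Å spacing,
10 Å padding, 0.1 M monovalent salt with Na⁺/Cl⁻ radii 0.95/1.81 Å
defining per-species ion-exclusion (Stern) layers in the screening map.
The screening prefactor 8π·k_e·(I·N_A·10⁻²⁷)/RT gives a Debye length of
9.7 Å at 0.1 M and 300 K, consistent with the textbook 9.6 Å at 298 K.

The dielectric boundary is the union-of-spheres (van der Waals) surface
with harmonic smoothing: each face midpoint gets an inside fraction
f = clip(1/2 − d/h, 0, 1) from its signed surface distance d, and the
face dielectric is the harmonic mixture 1/ε = f/ε_in + (1−f)/ε_out.
The solvation energy is ½Σ qᵢ φ_reac(rᵢ), with φ_reac the difference
between the solvated solve and a uniform-solute-dielectric reference
solve on the identical grid — same-grid subtraction cancels the
discretized Coulomb self-energy without analytic corrections. On the
Born ion (q = 1 e, R = 2 Å, ε 1→80, analytic −81.98 kcal/mol) the
solver lands within 0.8% at 0.5 Å spacing, converging monotonically
under refinement (1.8% → 0.8% → 0.4% at 0.8/0.5/0.35 Å).

For binding energies the three solves (complex, receptor, ligand) share
one grid box derived from the complex frame, which keeps per-atom
self-energy contributions aligned across the three states.

### SASA and nonpolar term

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points/atom) on each expanded sphere rᵢ + 1.4 Å; the accessible
fraction is the share of points outside every neighbour's expanded
sphere. The isolated-sphere error is below 0.1%; doubling the point
count moves toy-complex totals by less than 0.1%. The nonpolar term is
γ·SASA + b with γ = 0.00542 kcal/(mol·Å²) and b = 0.92 kcal/mol, so the
binding difference is ΔG_np = γ·ΔSASA − b (the intercept enters once
per state).

### Per-residue decomposition

ΔG_res = ΔE_MM,res + ΔG_pb,res + ΔG_np,res. Cross-pair MM energies are
split half to each partner's residue; the polar part attributes
½qᵢφ_reac per atom in each state and differences complex minus isolated
part; the nonpolar part assigns γ·ΔSASA per atom, with the state
intercept −b spread evenly over residues (it belongs to no residue, and
the even split is the convention that keeps residue sums exactly equal
to the global terms — asserted to 1e-6 kcal/mol in the tests).

## Synthetic systems

The fixtures module generates all test inputs:

- **Toy dipeptide** (13 atoms): an acetyl-capped single residue with a
  two-carbon side chain and two side-chain hydrogens, built in internal
  coordinates so the α copy has (φ, ψ) = (−60°, −40°) and the β copy
  (180°, 180°) exactly; equilibrium bond/angle values are measured from
  the built geometry so both states start finite and near-relaxed. The
  backbone torsion path carries no hydrogens, so heavy-atom and
  all-atom selections differ meaningfully.
- **ESP recovery problem**: well-separated random atoms with zero-sum
  hidden charges; the grid is the seeded shell construction and the
  target values are the exact Coulomb potential, so an unrestrained fit
  must recover the hidden charges to numerical precision (~1e-14 e
  observed).
- **Binding complex**: 2–4 three-atom pseudo-residues on an arc plus a
  three-atom ligand, with seeded coordinate jitter across snapshots.
  Interactions are few-charge/sphere systems chosen to be
  analytically checkable, not chemically realistic.

These fixtures validate the machinery — constraint handling, oracle
agreement, conservation, convergence — not chemical accuracy for real
UAAs, which depends on the quality of the upstream QM data and
GAFF/ff14SB parameters that enter as inputs. The embedded 18-system
benchmark table is transcribed data, used to verify the statistics
pipeline against its printed summary rows.

## Problem sizes

Test and acceptance runs use the toy systems above, PB grids at
0.35–0.8 Å spacing (up to ~70³ nodes), ~1,000–1,500-point ESP grids and
3–5 snapshots; these sizes make the full suite run in well under a
minute apart from the PB refinement study, while exercising every code
path at production grid spacing (0.5 Å) in the Born oracle.

## Known limitations

- Linearized PB only; no nonlinear PB and no generalized-Born fallback.
- No periodic boundary conditions, cutoffs or dynamics; energies are
  gas-phase and exact-pairwise.
- Equivalence classes and ligand selections are explicit inputs; no
  graph-symmetry or bond perception.
- The per-residue polar attribution (½qφ charge weighting) and the even
  spread of the nonpolar intercept are conventions; other decomposition
  schemes redistribute between residues while preserving the same
  totals.
- The blend optimizer searches a finite fraction grid; it formalizes a
  manual procedure and does not gradient-refine charges beyond convex
  combination.
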