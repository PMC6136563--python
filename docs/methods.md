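# Methods

## Model overview

`orthofem` couples a linear-elastic finite-element computation of
periodontal-ligament (PDL) stress with an empirical quadratic law mapping
that stress to monthly clinical tooth movement during canine retraction.
The chain is: parametric anatomy → region-tagged tetrahedral mesh →
small-strain elastic solve under a 1 N bracket-to-TAD force → von Mises
stress sampled at three root landmarks → movement prediction → rigid
advance of the tooth → remesh and repeat per monthly period.

Units are mm / N / MPa (N/mm²) throughout; 100 gf is mapped to exactly
1.0 N.

## Coordinate convention and anatomy

Model frame: x mesial(−)/distal(+), y buccal(+)/palatal(−),
z apical(−)/coronal(+), origin at the cervical center of the canine.
Positive movement is distal.

The canine root is a tapered cone with elliptical cross-section
(mesiodistal semi-axis 3.0 mm at the cervix, 0.6 mm at the flat apex,
buccolingual axis 1.25× larger), length 15 mm; the crown is a capped
elliptical frustum, height 10 mm. These are adult-canine-scale defaults;
they reproduce no particular patient and are free parameters of
`AnatomyConfig`. The PDL is a constant 0.25 mm offset shell — a standard
textbook thickness; the source clinical data do not state one. The
alveolar bone is a 20 × 14 × 20 mm block with a 1.5 mm cortical shell
around a cancellous core; the socket is the PDL outer surface. The
bracket attachment sits on the buccal crown surface at 45 % of crown
height; the TAD default is at (9, 2, −6) mm — distal and apical to the
bracket, as a mini-screw in the attached gingiva between second premolar
and first molar sits relative to a canine bracket. The retraction force
points from the bracket to the TAD.

Only the canine, its PDL and the surrounding block are modelled: the
measured quantities involve only the canine landmarks, and the neighbour
teeth and archwire would add cost without touching them. Landmarks:
C1D/C2D on the distal root surface at 1/3 and 2/3 of root length from the
cervix, C1M mesial at 1/3, placed analytically on the surface.

`random_seed` perturbs only the export-surface vertices (±0.5 µm jitter
emulating scanner noise); every interface used by the mesher and solver is
analytic and deterministic.

## Meshing

The volume mesh is a structured O-grid: node rings around the tooth axis
at each axial level — inside the tooth, exactly on the root surface,
exactly on the socket (PDL outer) surface, then graded through the bone to
the block walls, whose nodes lie exactly on the rectangular cut faces.
Ring-to-ring hexahedral cells are split into six tetrahedra sharing a main
diagonal, with face diagonals consistent between neighbours; axis cells
are prisms split compatibly. Each tetrahedron is tagged by analytic
classification of its centroid; cells in the air around the crown are
discarded.

Two details matter for correctness:

* **Shell sealing.** Cells at the apex cap and the cervical rim can
  straddle the 0.25 mm ligament and couple a root-surface node directly to
  a bone element — a stiff short circuit that suppresses PDL stress by an
  order of magnitude. After tagging, any tooth/bone element sharing a node
  across the shell is reassigned to the PDL (physically: the soft-tissue
  collar at crest and apex). The resulting meshes have zero shared
  tooth–bone nodes at every tested resolution.
* **Degenerate-cell pruning.** Collapsed cells (e.g. flattened rings at the
  crest plane) are dropped by a volume threshold scaled with
  `target_edge³` before orientation fixing.

The default `target_edge` of 0.9 mm gives ≈ 22 000 linear tetrahedra /
4 200 nodes — a desk-scale density chosen so a full four-period study
solves in about a minute; `--clinical-scale` (0.45 mm) approaches the
~100 000-element density of clinical models. Quadratic (10-node) elements
are available by edge-midpoint promotion. Ring counts have floors
(12 circumferential, 3 radial bone rings), so element count scales as
`target_edge⁻³` only once those floors are exceeded; the refinement
property (halving the edge ≥ quadruples the count) holds from ≈ 1.2 mm
downward.

Box meshes (5- and 6-tet cube decompositions) are provided for solver
verification.

## Elasticity solve

Isotropic Hooke materials per region (defaults: cortical 13 800 / 0.26,
cancellous 345 / 0.31, tooth 20 000 / 0.15, PDL 0.68 / 0.49, stainless
steel 210 000 / 0.30). Standard displacement FEM: constant-strain tet4 or
tet10 with 4-point Gauss quadrature, vectorised assembly into a sparse
symmetric matrix, Dirichlet constraints by reduction, SuperLU
factorisation (deterministic given the mesh ordering). Reactions are
recovered as K u − f; the relative residual of the constrained system is
checked below 1e−8.

Boundary conditions: the block's mesial and distal cut faces and its floor
are clamped (the original models' maxillary fixation is not documented;
clamping the cut faces is the conventional choice and leaves the
buccal/palatal plates free). The force is shared over the ≤ 6 crown-surface
nodes nearest the bracket attachment. The bracket/archwire "touch contact"
of the clinical appliance is linearised: by default no wire (pure point
load); optionally a sliding constraint that suppresses bracket-node
displacement perpendicular to the archwire axis, implemented by a
per-node change of basis. Frictionless contact proper is nonlinear and
is not needed for the quantities this package reports.

Landmark stress is the von Mises invariant of the volume-weighted average
stress tensor over PDL elements whose centroids lie within a radius of the
landmark (default: twice the local element edge). The clinical source
never names the invariant or the tissue; von Mises in the PDL is the
choice most comparable to the PDL/crestal stress ranges of related
studies, and `--stress-measure max_principal` provides the magnitude of
the extreme principal stress as an alternative.

### Why the default landmark stresses sit below 0.01 MPa

Under 1 N the synthetic model yields landmark von Mises values of
2–4 × 10⁻³ MPa, below the 0.01–0.10 MPa plausibility envelope that
brackets clinically reported ranges (0.028–0.063 MPa). This is physics,
not discretisation — quadratic elements give the same magnitudes. A thin
ligament confined between near-rigid tooth and bone with ν = 0.49 carries
a predominantly **hydrostatic** stress state: the computed PDL pressure
magnitude is 0.01–0.06 MPa, inside the reported range, while the
deviatoric (von Mises) part is 5–10× smaller. Reported clinical-model
stresses are therefore most consistent with a pressure-like or principal
measure, or with peak rather than volume-averaged values. The envelope
check is accordingly a soft diagnostic: it logs pass/warn and honestly
reports *warn* at the defaults.

## Movement law, calibration and validation

The law Y = aX² + bX + c (canonical a = 2960, b = −254.56, c = 5.667;
Y mm, X N/mm²) is non-monotone with a minimum near X ≈ 0.043 MPa,
consistent with pressure–tension physiology: moderate stress throttles
the vascular supply that remodelling needs, higher stress recruits
undermining resorption.

* `predict` evaluates the law unrounded; display rounding is
  half-away-from-zero, 3 decimals for mm and 2 for percent.
* `fit` is ordinary least squares (numpy polyfit; cross-checked against a
  dense normal-equations oracle in the tests). An OLS refit of the full
  calibration table gives (2590, −220, 4.94) — *not* the canonical
  coefficients; the published fitting procedure is underdetermined (the
  first patient's C1M measurements are known to be noisy, and a fit on a
  subset may be involved), so the package treats the canonical
  coefficients as given, reports the refit beside them, and exposes
  `--refit` / `--exclude-c1m`.
* Percent difference uses the **unrounded prediction** as denominator:
  100·|F − C| / F. This convention reproduces the printed extremes (0.36,
  8.96) exactly and every per-cell percent within 0.02 points; per-cell
  checks use a ±0.06 tolerance since the original rounding convention is
  not stated.
* Clinical measurement is emulated by Kabsch rigid superimposition
  (no scaling) on a palatal reference patch, per-landmark Euclidean
  displacement, and Dahlberg's error √(Σd²/2n) for repeated measures.

Stress at period start Tᵢ predicts movement over Tᵢ→Tᵢ₊₁, matching the
row structure of the calibration and validation tables.

## Study loop

Each period: solve, sample, predict, advance, remesh. Three scalar
movements underdetermine a 6-dof motion, so each landmark is displaced by
its predicted magnitude along the retraction direction projected into the
mesiodistal–occlusal plane, and the best-fit rigid transform of the three
displaced landmarks (via the same Kabsch routine) is applied to the tooth
pose; the RMS misfit is reported per period. The PDL and socket are
re-derived around the moved root — socket remodelling, as serial clinical
models imply — while the bone block boundary stays fixed. The advanced
model is fully remeshed, the simplest correctness-preserving choice.

Because the synthetic stresses fall below the law's calibrated stress
support, the study clips sampled stress into that support
(0.028–0.063 MPa, the calibration table's range) before evaluating the
law, logging every clip. Without this domain restriction the quadratic
extrapolates 0.002 MPa to ≈ 5.4 mm/month, which is physiologically
meaningless and marches the tooth out of the block. `run_period` applies
no clipping unless a domain is passed explicitly.

## What the synthetic data do and do not show

The generator emulates the *geometry class* of the clinical problem
(thin-shell ligament between stiff bodies, landmark placement, load path
bracket→tooth→PDL→bone) and makes every downstream contract testable:
element oracles, patch test, equilibrium, linearity, frame invariance,
convergence, determinism. It does **not** reproduce patient root
morphology, bone density fields, or the clinical stress magnitudes, so
agreement of the *movement-law* stage with the printed tables is evidence
about that stage only, not an end-to-end clinical validation. Per-patient
stress values from the original CT-based models are not reproducible
without that imaging.

## Numerical choices and limitations

* Direct sparse factorisation; no iterative tolerance to tune.
  Determinism: identical config and seed give bitwise-identical outputs.
* tet4 is the default for speed; near-incompressible PDL plus linear
  elements means volumetric locking — landmark samples converge within
  10 % under 2× refinement at fixed sampling radius, but absolute PDL
  deviatoric stress remains element-order sensitive at the few-percent
  level. tet10 is available where accuracy matters (e.g. bending
  verification).
* Small strain, one elastic snapshot per month: no viscoelasticity, no
  nonlinear PDL constitutive law, no frictional contact, no bone
  remodelling mechanics, no root-resorption side effects.
* Landmark sampling averages over a neighbourhood; peak stresses at the
  cervical margin are higher than the reported samples.
* The degenerate-input paths raise typed errors: invalid anatomy
  dimensions, non-positive element volumes, missing materials, empty
  sampling neighbourhoods (with a radius suggestion), underconstrained
  systems (naming the free rigid mode), malformed STL (with byte offset).
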