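# Methods

## Scope and design philosophy

hingekit implements the *computational* core of two-state hinge design and
analysis: backbone-level geometry and a quantitative kinetic model. It
deliberately excludes everything that requires a sequence-design or
structure-prediction stack (interface redesign, sequence optimisation,
structure prediction filters, loop rebuilding) and everything that requires
laboratory data (real titrations, dipolar EPR traces, crystallography).
Within that scope every operation is exact, deterministic, and testable
against analytic oracles on synthetic scaffolds.

## Backbone geometry

### Structures and helices

Structures are backbone-only (N, CA, C, O, optional CB), in ångströms,
1-based residue numbering per chain. Helices are detected from CA geometry
alone: a four-residue window is α-helical when d(CAᵢ, CAᵢ₊₃) ∈ [4.5, 5.7] Å
and the four-CA virtual torsion ∈ [40°, 60°]; maximal runs of qualifying
windows ≥ 6 residues become segments. This is coarser than hydrogen-bond
based assignment but robust on backbone-only models and exactly right on
the ideal fixtures. Helix axes, rise and twist come from superposing
CA[0:n−1] onto CA[1:n] and decomposing the per-residue screw operator
(Chasles); the decomposition is exact for ideal helices and a least-squares
compromise otherwise. The axis is oriented N→C so the rise is positive; a
one-step superposition RMSD above 1.0 Å flags the segment as non-helical.

### Ideal CB placement

Every residue receives an ideal CB from its N/CA/C frame (bond length
1.521 Å, standard tetrahedral direction, L-chirality). All contact,
label-site, staple and DEER-surrogate distances use these CBs, which makes
every geometric result sequence-independent.

### Pivot-shift state generation

The state-Y transform superposes the pivot-helix CA window shortened by |s|
residues onto the window shifted by s; positive s slides the copy toward
the C-terminal end of the pivot axis. On an ideal pivot this is exactly a
screw of s × twist degrees and s × rise Å. The screw decomposition reports
the rotation angle in [0, 360) with the axis oriented so the slide is
non-negative; angles below 0.1° are treated as degenerate (pure
translation, axis undefined). State Y keeps domain 1 (helices 1..p with
internal loops) verbatim — coordinate-identical to state X by construction,
asserted in tests — and applies the transform to domain 2 (helices p+1..n
with internal loops). The loop between the domains is severed; no loop
atoms are fabricated. Instead the report records the C→N gap and a
feasibility bound gap ≤ 3.8 × (n_loop + 1), the fully extended CA virtual
bond length times the number of bridging bonds.

### Surrogate two-state gate

The selection energy is a contact count, not a physical potential:
E = −(# inter-segment CB–CB pairs < 8 Å) + 25 × (# heavy-atom pairs
< 3.2 Å, excluding residues within 2 positions in sequence). Segments are
rigid bodies (helices, with loops merged into the preceding helix, and the
peptide), so rigid-body-internal contacts cancel between states and the
gate compares exactly what changes: the inter-domain and peptide
interfaces. The gate reproduces the *selection logic* of two-state design —
closed state favoured in isolation, complex favoured with peptide — and no
energy value should be compared with any physical scoring function. The
clash weight of 25 simply guarantees that any steric overlap dominates any
achievable contact reward.

### Site selection

Label-site pairs take one residue per domain, require both CBs to have at
most 14 CB neighbours within 10 Å in both states (a burial proxy standing
in for SASA), and rank by |Δd| = |d_Y − d_X| descending. Staple candidates
require the CB–CB distance inside a disulfide-compatible window
(3.5–5.5 Å) in the state to lock and above 10 Å in the other state, making
the crosslink geometrically possible in only one conformation.

## Synthetic scaffolds

The fixture generator emulates a designed helical repeat protein: two
ideal, exactly screw-symmetric α-helices per repeat (default 20 residues,
rise 1.5 Å/res, twist 100°/res), antiparallel up-down, packed on a
two-layer hexagonal lattice with adjacent axes 10 Å apart, consecutive
repeats related by one rigid repeat operator (optionally curved via a
repeat twist). Backbone atoms sit in a per-residue frame that co-rotates
with the CA helix; the frame offsets were solved once against standard
bond lengths and angles, with the carbonyl O placed so the O···N(i+4)
separation stays above the clash cutoff. All helices share one azimuthal
phase (80°), which keeps repeats congruent and maximises the inter-helix
steric margin across helix lengths. Loops are geometric CA-path
placeholders bulged onto circular arcs so virtual bonds stay in range; they
carry no torsional realism, which is acceptable because no operation scores
loops.

What passing tests on these fixtures shows: the register-shift/screw
identity, the two-state compatibility invariants, the gate logic, and the
site-selection contracts all behave exactly as specified on regular
scaffolds. What it does not show: behaviour on real DHR backbones with
supercoiling, irregular loops, or non-ideal helix geometry — there the
helix detector and pivot superposition degrade gracefully (flags, warning
RMSDs) but the analytic identities hold only approximately.

## Kinetic model

Species X, Y, YP and free peptide P evolve under mass-action kinetics with
the four microscopic constants (k₁, k₋₁ in s⁻¹; k₂ in M⁻¹s⁻¹; k₋₂ in s⁻¹).
Key derived quantities: K_conf = k₁/k₋₁, F_Y = k₁/(k₁+k₋₁),
K_D,intr = k₋₂/k₂, K_D,app = K_D,intr/F_Y.

- **Equilibrium** is computed in closed form: eliminating X via K_conf
  reduces the system to single-site binding with K_D,app, solved with the
  cancellation-free root of the depletion quadratic.
- **Dynamics** use scipy's LSODA (adaptive, switches to implicit stepping
  in stiff regimes) at rtol 1e-8; both conservation laws are enforced
  exactly by projection afterwards.
- **Oracle**: with P constant (large excess) the three-species system is
  linear and solved exactly by eigendecomposition (matrix exponential
  fallback for defective matrices). The nonlinear ODE agrees with this
  solution to < 1e-6 of the hinge total across random rate sets; the
  comparison requires genuine excess (hinge ≪ peptide), since peptide
  depletion is a real nonlinear effect the frozen-P oracle cannot show.
- **Pre-equilibrium**: the slow relaxation eigenvalue approaches
  k₂F_Y·[P] + k₋₂ as (k₁+k₋₁)/(k₂[P]+k₋₂) → ∞ (within 1% at ratio 100),
  which is why single-exponential fits and a linear k_app-vs-[P] regression
  identify k_on = k₂F_Y and k_off = k₋₂.
- **Stability shifts** multiply K_conf by exp(ΔΔG/RT)
  (R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K). Positive ΔΔG favours
  state Y. Because kinetic data constrain only the ratio, the barrier
  position is unknown; the default convention rescales k₋₁ only, with
  k₁-scaling exposed as an alternative. Binding rates are untouched
  (perturbations modelled are away from the interface).
- **Locks** (disulfide staples) zero one conformational rate: lock X sets
  k₁ = 0 (binding-incompetent), lock Y sets k₋₁ = 0 (F_Y = 1). Whether a
  real locked-Y variant also perturbs k₂ or k₋₂ cannot be resolved from
  on-rates alone; F_Y inference assumes identical k₂ and surfaces that
  assumption as a flag on every result.
- **Competition** adds a second hinge sharing the free-peptide pool, with
  stepwise injections at scheduled times (species are introduced at their
  own conformational equilibrium).

## Observables and fitting

- **FRET**: E = 1/(1+(r/R₀)⁶), population-weighted over states; YP reuses
  the state-Y inter-label distance, so FRET is blind to the Y→YP step —
  association experiments on locked-Y variants must therefore use the
  bound-fraction (FP-style) observable, and the analysis chain does.
  Default R₀ = 51 Å represents a typical long-range dye pair and is
  configurable; amplitude and background are free fit parameters because
  absolute FRET amplitudes are not comparable across constructs.
- **Titrations** default to the depletion-exact quadratic isotherm (probe
  concentrations near or below K_D make the hyperbolic form biased; the
  tests quantify the >20% bias in a 10× depletion regime). K_D is fitted
  on a log scale for positivity.
- **Exponential fits** initialise from a semilog regression on the
  plateau-subtracted signal; flat traces are flagged unidentifiable rather
  than fitted.
- **Pseudo-first-order regression** is weighted by inverse variance when
  per-trace standard errors are available; a fitted k_off below zero by
  more than 2 SE flags a model violation.
- **DEER surrogate**: state distance distributions are Gaussians centred on
  CB–CB distances with σ = 3 Å, standing in for spin-label rotamer clouds;
  they are not comparable to rotamer-library simulations of real labels.
  Mixture decomposition is non-negative least squares with weights
  renormalised to the simplex; bases closer than cosine similarity 0.99
  are declared unidentifiable.
- **Noise** is additive i.i.d. Gaussian with a mandatory seed; all
  simulators are bit-reproducible given the seed.

## Problem sizes

The test suite runs the geometric pipeline on 4-repeat (8-helix) scaffolds
with 20–24-residue helices (181–213 residues), kinetic oracle comparisons
over 100 random rate sets, Monte-Carlo fitting checks with 200–300
replicates, and association pipelines with five concentrations of 200-point
traces; these sizes make every identity testable to tight tolerances while
keeping the whole suite in seconds.

## Known limitations

- The gate energy is ordinal only; it cannot rank two passing designs.
- No loop atoms are built; feasibility is a necessary, not sufficient,
  condition for a closable loop.
- Helix detection assumes right-handed α-geometry; π/3₁₀ segments and
  heavily supercoiled helices fall outside the windows.
- The kinetic model has exactly two hinge conformations; intermediates,
  unfolding, and temperature dependence of rates are out of scope.
- Surface exposure is a CB-neighbour-count proxy, not SASA.
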