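# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one convention exists.

## Structures and subunit mapping

Models are read with biotite (mmCIF and PDB), keeping all ATOM/HETATM
records with author chain IDs and residue numbers; waters and ligands are
retained and flagged by residue name. Altloc handling keeps the first
conformer, so all geometry is single-conformer and deterministic.
Multi-model files contribute model 1 for static measurements; trajectory
readers take all models. Missing elements are inferred from the leading
characters of the atom name (needed for van-der-Waals radii downstream).

A `SubunitMap` fixes the tetramer convention: positions A–D map to
chains, A/C share one subunit identity and B/D the other (GluA1 and GluA2
in the packaged default). All residue labels are mature-protein numbering
with a per-chain `offset` (default 0) to reach a model's author
numbering; this keeps selections explicit instead of silently wrong when
deposited numbering differs.

**D1/D2 lobe boundaries.** No authoritative residue split of the LBD
clamshell exists. The packaged convention assigns most of segment S1 plus
the C-terminal helices of S2 to the upper lobe D1 (GluA2: 392–495 and
732–775) and the remainder to D2 (496–506 and 632–731), with GluA1
numbering 4 lower throughout. The YAML config is editable and the
validation step reports exactly which ranges fail to resolve.

## Superposition and angles

`superpose` is a plain Kabsch solver (SVD with a determinant guard
against reflections), returning the rotation, translation, angle/axis and
RMSDs. The rotation angle comes from the trace, the axis from the
skew-symmetric part with an eigenvector fallback near 180°. Tests hold it
against an independent quaternion-eigenvalue (Horn) solver.

**β (two-fold-symmetry deviation).** Defined intrinsically: superpose
protomer 1 of an LBD dimer onto protomer 2 over a 1:1 Cα correspondence
and take β = |180° − θ|. This needs no external symmetric reference and
is zero exactly when the dimer is C2-symmetric over the paired atoms.
Hetero-dimers (GluA1 vs GluA2) are paired by global sequence alignment
(BLOSUM62) keeping non-gap Cα pairs; identical numberings pair directly.
Reports give per-dimer β values and their mean, since conventions differ
on whether to average.

**Clamshell closure / hinge angle.** The two states are superposed on
their D1 lobes; the reported angle is the full rotation angle of the
residual optimal transform of D2, not its projection onto a hinge plane.
This is simpler and deterministic; it can differ by a few degrees from
hinge-projection conventions (e.g. DynDom-style analyses), which is why
cross-convention comparisons should use a ±3° margin.

Report rounding: distances to 0.1 Å, angles to 0.1°.

## Pore profiling

At each slice z along the axis the profiler maximizes the clearance
c(p) = min over atoms (|p − x_i| − r_i) over in-plane positions p. The
search is a coarse grid (0.5 Å spacing, 5 Å extent) followed by bounded
Nelder–Mead; every slice after the first is constrained within a 2 Å
continuity bound of the previous centre, which keeps the probe inside the
pore rather than letting it escape around the outside of the protein.
This makes the profiler deterministic, unlike simulated-annealing
profilers; on analytic tube fixtures it agrees with a dense brute-force
search to ±0.05 Å. Radii are capped (default 10 Å) and empty slices are
reported at the cap with a flag.

Axis choice: lab z, an explicit (origin, direction), or automatic from
the centroids of the T617 and T625 gate-residue Cα tetrads (the receptor
pseudo-symmetry axis approximates the pore axis). Default radius set is
Bondi; an AMBER-flavoured set is available, and an exact inflation
property holds: adding δ to every radius lowers every profile radius by
exactly δ.

√area uses the four gate-residue Cα atoms: project onto the best-fit
plane (SVD), order by angle about the centroid, shoelace area, square
root. Collinear quadrilaterals are rejected.

## Water permeation

Crossing semantics (the literature is usually silent on these details):
a three-state tracker per water oxygen (below/inside/above the gate
slab). A completed event enters through one boundary and exits through
the opposite one, with any dwell length; re-exit through the entry
boundary cancels the pending event; a single-frame jump across the whole
slab counts. Both directions count. These rules are time-reversible
(reversing the trajectory preserves the count and flips directions) and
chunk-stable (the tracker carries state across contiguous pieces).
`entry_frame` is the first frame inside the slab, `exit_frame` the first
frame beyond the far boundary.

Gate planes are the mean axial Cα coordinate of the two gate-residue
tetrads per frame (defaults T617 and T625, GluA2 numbering); reversed
labels are swapped with a warning. Waters are identified by oxygen only.
With a periodic box length supplied, coordinates are unwrapped first so
wrap jumps (> box/2) are never counted as crossings. Rates are events per
ns; the cumulative average at window k is the mean of windows 1..k.

## Kinetics

Sign convention: inward currents are negative. All detection operates on
the baseline-subtracted current flipped by the sign of its largest
deflection — deliberately not a pointwise absolute value, which would
fold zero-mean tail noise into a positive floor and bias exponential fits
toward shorter τ (a ~5% effect at 2% noise in simulation).

τ fits use trust-region least squares of A·e^(−t/τ) + C with an analytic
Jacobian, from the peak to the end of the application (auto window) or an
explicit window; non-decaying windows raise instead of returning a
meaningless τ.

The Hodgkin–Huxley recovery equation is evaluated literally; it implies
I(0) = 1 and I(∞) = I_max ≥ 1, i.e. peaks normalized to the residual
non-desensitized response. A two-pulse envelope normalized to the
conditioning peak instead starts near 1/I_max and saturates at 1;
`fit_recovery(..., normalized_to="conditioning")` fits I(t)/I_max for
that convention. The literal normalization is the default and the
tension between the two conventions is documented rather than resolved.
The fit is a fixed multi-start (m ∈ {0.5, 1, 2, 4}) trust-region least
squares with bounds (I_max ≥ 1, 0.05 ≤ m ≤ 50); the best residual wins,
so results are deterministic.

I_SS is the mean magnitude over the final 10% of the glutamate
application; I_max is the peak magnitude of the desensitization-blocked
(CTZ) trace.

## Correlation

Pearson r and the least-squares line come from scipy.stats; the optional
two-sided p-value (t-transform) is reported but never used as a gate.
τ_RecDes values for literature complexes are user-supplied configuration
(a template with citation slots ships with the package); nothing numeric
is hard-coded for quantities the package cannot measure itself.

## Synthetic generators: what a green test establishes

- **C2 dimers** are random rank-3 point clouds; protomer 2 is protomer 1
  rotated 180° about z and then by the injected deviation about a chosen
  axis, all about the dimer centre. The recorded β oracle comes from
  quaternion composition, independent of the superposition code under
  test. Note that a deviation about an axis perpendicular to the flip
  axis composes to another 180° rotation about a tilted axis, so its
  oracle β is 0 — the fixtures test agreement with the oracle, not with
  the injected number. These clouds have no protein-like covariance, so
  they validate the estimator, not its robustness to real coordinate
  error (a separate noise-degradation test covers that up to 0.5 Å).
- **Pore tubes** are atom rings on a cylinder with a known analytic
  minimal clearance; they validate the probe search, not performance on
  irregular, partially occluded protein pores.
- **Water trajectories** script monotone traversals and confine the
  remaining waters by reflected Gaussian steps (σ = 0.5 Å/frame) in a
  band clear of the slab, so the ground-truth event list is exactly the
  script; consecutive same-direction scripts for one water are rejected
  (they would require a teleport). Diffusive recrossing statistics of
  real MD are not emulated.
- **Current traces** are generated from the same closed-form kinetics the
  fitters assume, plus additive Gaussian noise scaled to the peak —
  defaults are the measured GluA1/A2 values (τ_Des 7.64 ms, τ_Deact
  3.45 ms, τ_RecDes 75 ms with m = 1.02 from the representative two-pulse
  fit, I_SS/I_max 0.032). The envelope generator's default I_max = 30 is
  chosen so the residual starting fraction 1/I_max ≈ 0.033 matches the
  measured steady-state fraction. Solution-exchange artefacts, drift and
  series-resistance errors are not modelled, so green fits establish
  estimator correctness, not acquisition robustness.

## Known limitations

- The deposited-model reproduction test needs coordinate files the
  package cannot ship or download offline; it fails with instructions
  until they are provided locally.
- The hinge angle deviates from hinge-projection conventions by design
  (documented above).
- The pore profiler's continuity constraint assumes the pore does not
  jump more than 2 Å laterally per 0.5 Å slice; genuinely discontinuous
  channels need a larger bound or an explicit axis.
- Permeation counting assumes the axial coordinate alone decides
  inside/outside; strongly tilted pores should be rotated to the axis
  first.
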