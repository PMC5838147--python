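# Methods

## The SAPSA descriptor

The package computes the **solvent-accessible polar surface area (SAPSA)**
of a conformational ensemble.  For one conformer, each atom is modeled as a
sphere of van der Waals radius `r` (Bondi values: C 1.70, N 1.55, O 1.52,
H 1.20, S 1.80 Å), and the surface of interest is the **probe-center
(accessible) surface**: the locus traced by the center of a solvent probe
of radius 1.4 Å rolling over the van der Waals spheres, i.e. area measured
on spheres of radius `r + 1.4 Å`.  An atom is **polar** if it is nitrogen,
oxygen, or a hydrogen bonded to either; SAPSA is the accessible area summed
over the polar atoms, and the ensemble SAPSA is the arithmetic mean over
frames.  Every atom — polar or not — occludes its neighbors, which is the
mechanism that lets an apolar side chain shield backbone amides and lower
SAPSA without changing the 2D polar-atom count.  This is exactly what
separates SAPSA from the topological PSA, which is a sum of fragment
contributions independent of conformation.

Ensemble statistics report the per-frame mean and the population standard
deviation (divisor `n`), plus block statistics over consecutive windows of
`block_size` frames (default 1000 frames — 1 ns when 20 000 frames span
20 ns; the last block may be short).  Since the literature is ambiguous
about whether a "±" on an ensemble surface area denotes the frame spread or
the spread of block means, both are exposed (`sd` and `block_sd_of_means`).

### Surface integration

Areas are estimated by Shrake–Rupley point counting with a deterministic
golden-spiral point set.  Per atom `i`, test points on the expanded sphere
`R_i = r_i + probe` are kept if they lie outside every neighboring expanded
sphere; the exposed fraction times `4πR_i²` is the atom's area.  Candidate
occluders are atoms with center distance `< R_i + R_j` (a KD-tree prunes
the pair list).  A point lying exactly on a neighbor sphere counts as
exposed — a measure-zero tie broken for determinism.

Two refinements matter for the invariants the test suite checks:

* **Canonical orientation.**  The point set is oriented in the
  principal-axes frame of the *polar* atoms (eigenvectors of their
  coordinate covariance, signs fixed covariantly by third moments, the
  weakest axis rebuilt from the cross product of the other two).  The frame
  co-rotates with the molecule, so areas are exactly invariant under
  rigid-body motion; and because it depends only on polar atoms, edits that
  touch only apolar atoms (side-chain truncation) leave every test
  direction unchanged — which makes per-frame truncation monotonicity an
  exact property rather than a statistical one.  Limitation: when the polar
  atoms are nearly collinear or symmetric the frame is ill-conditioned;
  results remain deterministic but exact rotational invariance can degrade
  to discretization level.
* **Per-atom decorrelation.**  Each atom's point set receives a
  deterministic rotation derived from its coordinates in the canonical
  frame, decorrelating discretization errors between atoms so that summed
  areas converge faster than any single atom's.

The default point count is 1920: on the bundled fixtures doubling it
changes totals by ≤0.1%, and agreement with an independent Monte-Carlo
surface integration (10⁶ random directions per atom) is well within 1% on
random clusters.  `n_sphere_points` and the probe radius are configurable
(`SurfaceConfig`).

### Permeability classification

For cyclic hexapeptides of this scaffold class, an ensemble-mean SAPSA
below 80 Å² indicates expected high passive permeability and above 150 Å²
expected low permeability; values in between (boundaries included) are
classed intermediate.  The thresholds are configuration constants, not
fitted quantities.

### Atom typing and I/O

Multi-model PDB files are read and written through Biopython; one MODEL is
one conformer, and all models must share the atom count.  Bond sources are
used in precedence order CONECT records → explicit bond file → distance
inference (`d ≤ 0.6 (r_i + r_j) + tol`, vdW radii, tol = 0 Å): truncation
editing and hydrogen-polarity typing need reliable bonds.  A hydrogen that
ends with anything other than exactly one bond is a hard error, and
structures without hydrogens are rejected rather than protonated —
protonation is out of scope.  Radii ship in an explicit, overridable YAML
config; there are no silent defaults at compute time.  Side-chain hydroxyl
hydrogens follow the same polar-H rule as amide hydrogens.

## Side-chain truncation decomposition

To separate *why* a terminal group (e.g. the extra methyl that turns Ala
into Abu) changes SAPSA, the group is edited away on the parent molecule's
own trajectory: the target carbon's hydrogens are deleted, the carbon
becomes a hydrogen repositioned along the old bond vector at 1.09 Å
(standard C–H; the geometry rule is a package choice), and all other
coordinates stay fixed.  With ensembles A (parent), B (comparator, its own
ensemble) and A′ (A's frames, edited topology):

* `direct shielding = mean(A′) − mean(A)` — pure steric occlusion, since
  the scaffold geometry is frozen;
* `conformational  = mean(B) − mean(A′)` — the group's effect on which
  conformations are populated.

The two components sum to `mean(B) − mean(A)` identically.  Because the
replacement hydrogen's expanded sphere is geometrically contained in the
removed carbon's (0.45 Å closer along the bond, 0.5 Å smaller radius),
per-frame SAPSA can never decrease under the edit — asserted exactly in the
tests thanks to the shared point orientation described above.

## Conformer generators

`sample_ensemble` is a torsional Metropolis Monte-Carlo chain: one random
rotation per step about a user-declared rotatable bond (ring torsions are
rejected), acceptance `min(1, exp(−ΔE/kT))`.  The energy is deliberately
minimal and non-physical — a soft-sphere clash penalty
`Σ max(0, 0.8(r_i+r_j) − d)²·scale` minus a reward per donor-H···acceptor
contact under 2.5 Å.  Its only contract is to produce topologically valid,
seeded, conformationally diverse ensembles for pipeline testing; it makes
no claim about force-field fidelity, and the implicit-solvent Langevin
molecular-dynamics protocol it stands in for is recorded in metadata only.

`make_two_state_fixture` builds a four-atom mini-molecule whose single
polar N–H is occluded by a mobile apolar carbon in a "shielded" state and
clear of it in an "exposed" state, with states drawn i.i.d. with
probability `p_exposed`.  The expected ensemble mean is the closed-form
mixture `p·A_exposed + (1−p)·A_shielded` with both state areas computable
directly, so ensemble averaging can be validated against an analytic
target.  `delta_area` sets the shielded-state occluder distance through the
spherical-cap area it removes from the nitrogen's expanded sphere; the
realized gap also includes partial occlusion of the hydrogen, so tests
always compute state areas with the engine.  The geometry is synthetic, not
chemically sensible.  `make_decomposition_pair` extends this with a remote
terminal ethyl arm to emulate a substituent whose entire SAPSA effect is
conformational (the two ensembles differ in state populations, 0.2 vs 0.8
exposed by default).

What these generators do **not** emulate: real force fields, Boltzmann
weighting, hydrogen-bond networks, ring flexibility, or solvent models.
Passing tests therefore demonstrate the correctness of the surface/ensemble
machinery, not the reproduction of any published absolute SAPSA value —
those depend on the original trajectories, which are not available.

## Non-compartmental pharmacokinetics

`NCA(profile).fit()` computes model-free parameters from a
concentration–time profile:

* **BLQ rule** (LLOQ-aware): values below the assay LLOQ before the first
  quantifiable sample are set to 0; embedded and trailing BLQ samples are
  dropped with a logged note.  Alternative rules (`drop_all`, `zero_all`)
  are selectable.
* **Time-zero anchor**: oral profiles get C(0) = 0; i.v. bolus profiles get
  C(0) back-extrapolated log-linearly from the first two positive samples.
* **AUC / AUMC**: trapezoidal, default linear-up/log-down (the log
  trapezoid `(C₁−C₂)/ln(C₁/C₂)·Δt` is exact on exponential decay); a pure
  linear method is available.
* **λ_z**: log-linear least squares over the terminal window (excluding
  T_max) with the best adjusted r²; a flat or rising tail yields an
  "unreliable" flag instead of an extrapolated AUC.
* **Derived**: `AUC_inf = AUC_last + C_last/λ_z`, `t½ = ln2/λ_z`,
  `MRT = AUMC_inf/AUC_inf`, and for i.v. bolus `CL = dose/AUC_inf`
  (mL/min/kg) and `V_ss = CL·MRT` (L/kg).  Converting molar concentrations
  to mass units requires an explicit molecular weight — never guessed.

Absolute oral bioavailability is `100 × AUC_dn(oral)/AUC_dn(iv)` from
dose-normalized AUCs; the function accepts result objects or bare published
means, which reproduces the published integer percentages (30/7/39/23) from
the printed table values.

### Hepatic first-pass analysis

`FirstPass(portal, jugular).fit()` compares AUCs from simultaneous
portal-vein and jugular-vein sampling after an oral dose:
`first_pass_% = 100·(1 − AUC_jugular/AUC_portal)`.  AUCs are `AUC_last`
over the common quantifiable window, with no terminal extrapolation —
matching how such dual-cannulation studies are evaluated.  A jugular AUC
exceeding the portal AUC is reported as a flagged negative extraction, not
clipped.  The result contextualizes the implied hepatic extraction against
a reference hepatic blood flow (default 90 mL/min/kg, the rodent-scale
value).

### Synthetic PK generator

One-compartment closed forms with first-order absorption: i.v.
`C(t) = (dose/V)e^{−kt}` with `k = CL/V`; oral systemic concentration uses
bioavailability `F = f_abs(1−E_H)`; the portal concentration adds the
absorption flux over portal flow, `k_a·f_abs·dose·e^{−k_a t}/Q_pv` — a
well-stirred-consistent additive-flux approximation that is a test
harness, not a physiological model.  Analytic identities used as oracles:
`AUC_inf(jugular) = f_abs(1−E_H)·dose/CL` and
`AUC(portal) − AUC(jugular) = f_abs·dose/Q_pv`.  When elimination is purely
hepatic and portal flow equals hepatic flow (`CL = E_H·Q_pv`), the AUC
ratio identifies E_H exactly; otherwise it estimates `CL/(Q_pv(1−E_H)+CL)`.

Defaults (chosen once as a realistic high-extraction scenario): dose
3 mg/kg, V 2.8 L/kg, E_H 0.77, Q_pv 90 mL/min/kg, hence CL 69.3 mL/min/kg
(t½ ≈ 0.47 h), f_abs 1, k_a 1.0 h⁻¹ (first-order absorption of a suspension
dose), sampling at 0.25, 0.5, 1, 2, 4, 7, 24 h (plus 0.08 h for i.v.),
LLOQ 0.4 ng/mL, multiplicative log-normal noise at a configurable CV
(mean-preserving), censored values reported as 0.  On that sparse schedule
the recovered first-pass is ≈75% for a true 77% — the deficit is the
portal AUC missed before the first sample; it vanishes as sampling
densifies (asserted as a convergence test).

## Problem sizes and tolerances

Test fixtures use 4–9-atom synthetic molecules and ensembles of 10²–2·10³
frames, sizes at which every assertion runs in seconds while the sampling
error of the two-state mean (≈0.2 Å² at 2000 frames) is far below the
state separation (≈19 Å²).  Engine-vs-oracle comparisons use 10⁶ Monte-
Carlo samples per atom (sampling sd ≈0.1% of an atom's area) against the
1% tolerance.  Exact identities (decomposition sum, first-pass complement)
are asserted to 10⁻⁹.

## Known limitations

* No analytic (LCPO/power-diagram) surface; accuracy is discretization-
  bound.  No mmCIF or binary trajectory formats; no protonation logic.
* Absolute SAPSA values for real peptides depend on the conformational
  ensemble supplied; the bundled samplers cannot reproduce published
  force-field trajectories, only exercise the machinery.
* The NCA assumes the standard sparse-sampling conventions above; no
  compartmental fitting, allometry, or inter-animal statistics beyond what
  callers compute from per-profile results.
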