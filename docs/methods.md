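# Methods

This note records the models, conventions and numerical choices behind
dendrikit, and what its synthetic-data tests do and do not establish.

## Units and containers

Coordinates are stored in nm, times in ns, masses in amu, charges in e,
energies in kJ/mol — the Gromacs unit system. XYZ and PDB files are
assumed to be in Å and converted on read (XYZ can be declared as nm).
Binding cutoffs and RDF bins are expressed in Å, the field's habit for
contact criteria; the conversion happens internally. Atom groups are
0-based index sets; a system is a dendrimer set plus disjoint ligand
molecules, and atoms outside both (solvent, ions) are ignored by every
analysis. Frame times come from a per-frame `t=<ns>` comment when the
file carries one, else `index × dt`; on conflict beyond 1e-6 ns the file
field wins with a warning. A declared orthorhombic box switches binding
distances to the minimum-image convention but never re-images
coordinates — the intended geometry is a single carrier centered in the
box, where re-imaging is unnecessary.

## Shape descriptors

Per frame, for group coordinates r_i with masses m_i about the group
COM R:

- gyration tensor `S = Σ m_i (r_i−R)(r_i−R)^T / Σ m_i` (tr S = Rg²),
- inertia tensor `I = Σ m_i (|r_i−R|² E − (r_i−R)(r_i−R)^T)`.

The asphericity factor is

    A = 1 − 3⟨I₂⟩ / ⟨I₁²⟩,   I₁ = λ₁+λ₂+λ₃,  I₂ = λ₁λ₂+λ₂λ₃+λ₁λ₃,

with λ the **gyration** eigenvalues and ⟨·⟩ a per-frame average of I₂
and I₁² separately, as the definition is written — not an average of
per-frame A values. The gyration basis is a deliberate choice: with
inertia eigenvalues the supremum of A over physical shapes is 0.25 (a
rod has I = (0, I, I)), which cannot realize the 0 (sphere) … 1 (stick)
range the classification relies on. In the gyration basis a collinear
rod has two eigenvalues that vanish *identically*, so I₂ = 0 and A = 1
exactly, with no clamping anywhere (A ∈ [0, 1] is a theorem, asserted as
a property test on random clouds). Both tensors are exposed
(`tensor="inertia"` reproduces the other convention), and the reported
I_x ≤ I_y ≤ I_z and aspect ratios use the inertia eigenvalues, which is
how such tables are conventionally printed.

Time averaging in `shape_report`: Rg and the moments are averaged per
frame; aspect ratios are ratios of *mean* moments (stable when moments
nearly cross, consistent with reporting "mean values"); A follows its
own averaging rule above. The equivalent-sphere radius is
r = √(5/3)·⟨Rg⟩, exact for a uniform solid sphere.

Eigenvalues come from `numpy.linalg.eigvalsh` (symmetric solver, real
spectrum), sorted ascending; exact ties keep solver order, which cannot
affect the symmetric functions used downstream.

## Binding analyses

A ligand is bound at a frame iff its minimum any-atom distance to the
dendrimer set is **strictly** below the cutoff (default 3.5 Å);
exact-boundary configurations are unbound. Minimum distances use a k-d
tree over the dendrimer atoms (with toroidal topology when a box is
declared).

Residence runs are segmented on the *full* series — a merge requires
consecutive bound frames, with no gap tolerance — then filtered by
window intersection: a ligand is persistent if any run touching the
window lasts more than τ (default 10 ns), transient if it was bound in
the window only in runs of at most τ, and excluded if never bound in the
window. Persistent + transient therefore partition the distinct binders
(property-tested on random series). Letting runs that begin before the
window count is the only semantics under which "bound for more than
10 ns, determined within a 10 ns window" is satisfiable at all. Run
duration is t_last − t_first of the run's frames, compared against
τ + 1e-9 ns: the guard makes the strict "more than τ" comparison robust
to floating-point time grids, and classifies a run spanning exactly τ as
transient, which the strict reading demands anyway.

The COM RDF histograms dendrimer-COM→ligand-COM distances over a frame
window, normalized by spherical-shell volume and by the mean ligand
density inside the analysis sphere of radius r_max — not the box
volume — so a uniform population in that sphere gives g ≈ 1 and the
far tail sits at the bulk level. Rebinning conserves total counts
(tested). Inner bins have tiny shell volumes; their g values are
correspondingly noisy at realistic occupancies.

Pair energies are plain cutoff-truncated sums over dendrimer×ligand
atom pairs within 1.2 nm: 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with
Lorentz–Berthelot mixing (σ arithmetic, ε geometric) plus f·q_iq_j/r
with f = 138.935458 kJ·mol⁻¹·nm·e⁻². This is a configuration-analysis
energy, not a dynamics energy: no reciprocal-space (PME) term, no
exclusions, no tail corrections; absolute Coulomb values for charged
systems therefore differ from an Ewald treatment and should be read
comparatively. The vectorized sum is verified against an all-pairs
double loop to 1e-9 relative, and the constant f against an independent
derivation from CODATA constants (e²N_A/4πε₀). The per-ligand mean of
the trajectory-level helper divides by the *bound* ligand count per
frame by default (flag `averaging="all"` divides by all ligands); which
population such printed per-molecule energies refer to is genuinely
ambiguous in practice, so the choice is explicit.

## Solution observables

**Guinier.** Ordinary least squares of ln I on q² after optional
pointwise background subtraction (backgrounds on a different grid are
linearly interpolated onto the sample grid). Rg = √(−3·slope),
I₀ = exp(intercept); a non-negative slope is an error, and q_max·Rg >
1.3 raises a validity warning. The `"auto"` range expands from the three
lowest-q points and keeps the longest prefix with qRg ≤ 1.3 and
r² ≥ 0.99 — a reproducible stand-in for the manual region choice of
instrument software; prefixes that fail (noisy short windows) are
skipped rather than fatal, and the scan stops once qRg is far past the
regime.

**Stokes–Einstein.** R_H = k_BT/6πηD with k_B from scipy.constants.
Viscosity is a *required* input: reported diffusion data rarely state
it, and guessing silently would corrupt R_H. `solvent_viscosity()` ships
handbook H₂O/D₂O values with linear interpolation in T and linear
mixing in D₂O fraction, clearly labeled approximate (real mixtures
deviate by a few percent; e.g. diffusion data consistent with
R_H ≈ 2.97 nm at 30 °C imply η ≈ 0.92 mPa·s for a 50:50 mixture, inside
but not at the linear-mix value).

**Shape ratio.** R_g/R_H rounded half-to-even to 3 decimals;
"sphere-like" on the closed band [0.7, 0.8] (a homogeneous sphere sits
at √(3/5) ≈ 0.775). Percent changes round to 2 decimals. The rounding
precisions match how such values are conventionally reported.

**DOSY.** The fitted model is the Stejskal–Tanner mono-exponential
I = I₀·exp(−D·b), b = (γδg)²(Δ−δ/3), with γ defaulting to ¹H. The
experiment's named sequence (BPPLED) determines pulse bookkeeping, not
the functional form, so the standard form is adopted; all timings are
user inputs. The nonlinear fit is initialized from the log-linear
regression and refined by Levenberg–Marquardt; non-convergence reports
the residual. Monoexponentiality assumes a monodisperse diffusing
species — polydisperse decays need multi-component models out of scope
here.

## Synthetic data: the stated world

Generator defaults encode the scenario the analyses are meant for; they
are fixed, not tuning knobs.

- **Ellipsoid clouds**: uniform sampling inside the ellipsoid;
  analytic truth Rg² = (a²+b²+c²)/5, gyration eigenvalues a²/5 ….
- **Binding scripts**: single-bead ligands placed, while bound, at
  3.0 Å from a seeded random dendrimer atom (exercising the any-atom
  rule, not COM proximity) and, while unbound, radially outside the
  whole cloud with clearance ≥ 10 Å; a cutoff between the two radii
  must reproduce the script exactly, which is the generator-as-oracle
  property tested over 100 random scripts. Intervals are half-open
  [t_on, t_off).
- **Scenarios S1/S2/S3** mirror a 100-ligand carrier at 0/10/20%
  protonation over 100 ns with dt = 0.1 ns (the frame stride is a free
  parameter; 0.1 ns is a typical save interval): final-window (90–100
  ns) mean occupancies 5/16/25 and persistent/transient splits (0, 8),
  (6, 12), (12, 13). Persistent ligands bind at 40 ns and stay (runs of
  60 ns > τ); transient ligands tile the window in runs of ≤ 10 ns so
  the occupancy is exact at every frame.
- **SAXS**: homogeneous-sphere form factor
  I₀[3(sin qR − qR cos qR)/(qR)³]², series-expanded below qR = 1e-4;
  multiplicative Gaussian noise.
- **DOSY**: default δ = 2.8 ms (bipolar pair total), Δ = 350 ms,
  25-step linear ramp over 2–95% of g_max = 0.5 T/m — chosen inside the
  standard operating ranges of such experiments so that a
  D ≈ 8×10⁻¹¹ m²/s species is attenuated to a 2–5% residual.

Every generator is a pure function of (parameters, seed) via a local
`numpy.random.Generator`; no global state.

What green tests establish: the analysis layer recovers scripted truth
exactly and matches independent oracles (analytic shapes, brute-force
energies, closed-form scattering). What they do not: agreement with real
MD output (flexible carriers, multi-atom drugs, solvent-mediated
dynamics, PME electrostatics) or with real instrument data (smearing,
polydispersity, concentration effects). Published trajectory-derived
quantities can only be reproduced from the original trajectories, which
are not deposited.

## Known limitations

- Binary trajectory formats (XTC/TRR/DCD) are not read; convert to
  multi-frame XYZ or multi-model PDB first.
- No PBC unwrapping; molecules split across a box boundary would need
  pre-imaging (minimum-image distances remain correct).
- RDF normalization assumes the analysis sphere fits the sampled region;
  r_max beyond the populated volume deflates the reference density.
- Pair energies are O(N_dendrimer × N_ligand) per frame with a plain
  distance matrix; fine for 10⁴-atom groups, not for much larger ones.
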