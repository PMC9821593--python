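# dendrikit

Analysis toolkit for dendrimer–drug complexation studies. It targets the
workflow of characterizing a polymeric nanocarrier (e.g. a generation-4
poly(amidoamine) dendrimer) loaded with a small anionic drug (e.g.
5-fluorouracil): molecular-trajectory analyses of size, shape and ligand
binding on one side, and the matching solution-scale observables from
SAXS, DLS and NMR diffusometry on the other. A synthetic-data module
generates every input with known ground truth, so the whole analysis
layer is testable without running molecular dynamics or owning a
scattering instrument.

## What it computes

**Trajectory side** (coordinates in nm, times in ns):

- radius of gyration, ordered principal moments of inertia
  *I_x ≤ I_y ≤ I_z* and their aspect ratios *I_z/I_x*, *I_z/I_y*;
- the asphericity factor
  *A = 1 − 3⟨I₂⟩/⟨I₁²⟩* with *I₁ = λ₁+λ₂+λ₃*, *I₂ = λ₁λ₂+λ₂λ₃+λ₁λ₃*
  built from the **gyration-tensor** eigenvalues λ, so that *A* runs from
  0 (sphere) to exactly 1 (rod); the equivalent-sphere radius
  *r = √(5/3)·R_g*;
- ligand binding by an any-atom distance cutoff (bound iff the minimum
  ligand–dendrimer atom distance is **strictly below** 3.5 Å),
  bound-count time series, residence-time statistics (persistent binders
  have a contiguous bound run longer than τ = 10 ns touching the analysis
  window), COM–COM radial distribution functions, and cutoff-truncated
  Lennard-Jones + Coulomb pair interaction energies
  (Lorentz–Berthelot mixing, *f* = 138.935458 kJ·mol⁻¹·nm·e⁻²).

**Solution side**:

- Guinier fits *ln I(q) ≈ ln I₀ − (R_g²/3) q²* with an automatic low-q
  window (*qR_g* ≤ 1.3, *r²* ≥ 0.99) or an explicit range;
- Stokes–Einstein *R_H = k_B T / (6πηD)* and the *R_g/R_H* shape
  classification (sphere-like band 0.7–0.8);
- Stejskal–Tanner DOSY fits
  *I(g) = I₀·exp(−D(γδg)²(Δ−δ/3))* for self-diffusion coefficients.

**Synthetic inputs**: uniform ellipsoid bead clouds (analytic
*R_g² = (a²+b²+c²)/5*), scripted binding trajectories whose exact
bound/unbound truth is returned alongside, homogeneous-sphere SAXS
curves and Stejskal–Tanner decays, all bit-reproducible per seed.

## Worked example

`examples/binding_pipeline.py` scripts the most-protonated scenario
(100 ligands, 100 ns, final-10 ns occupancy 25 with 12 persistent
binders), then recovers those numbers from coordinates alone:

```
classifier reproduces scripted truth: True
mean bound ligands in 90-100 ns: 25.0
persistent binders N(t>10 ns): 12
transient binders  N(t<10 ns): 13
```

`examples/hydrodynamics.py` turns measured solution data into shape and
swelling descriptors:

```
RH = 2.97 nm from D = 8.10e-11 m^2/s (T = 303.15 K, eta = 9.231e-04 Pa s)
pH  10.2: Rg/RH = 0.763 -> sphere-like
pH   7.0: Rg/RH = 0.790 -> sphere-like
pH   4.3: Rg/RH = 0.778 -> sphere-like
RH swelling pH 10.2 -> 4.3: 13.88%
Rg swelling pH 10.2 -> 4.3: 16.04%
```

The *R_g/R_H* ratios inside 0.7–0.8 identify a compact sphere-like
particle; the percent changes quantify electrostatic swelling upon
protonation at acidic pH. The other examples cover shape reports,
RDF profiles, pair energies, Guinier fitting and DOSY fitting; each
prints the numbers it computes and one line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated inputs, the two asphericity-limit
benchmarks: the asphericity factor of a dense uniformly sampled
solid-sphere bead cloud (N = 10 000, seeded) and of a perfectly collinear
100-bead rod, writing both to the JSON file given by `--out`.
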