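# Methods

`hopcrystal` implements the hopping (Marcus) picture of charge transport in
molecular crystals: charge carriers are localized on single molecules and
move by thermally activated hops between neighbors. The pipeline goes from
a crystal structure to carrier mobilities in five stages — neighbor-dimer
enumeration, electronic coupling, reorganization energy, hop rates, and
diffusion/mobility — each usable on its own through the library API.

## Transport model

For a hop between two molecules with electronic coupling *J*, total
reorganization energy *λ*, site-energy difference ΔE = E_initial − E_final
and temperature *T*, the rate is

    k = (2π/ħ) · J² · (4πλk_BT)^(−1/2) · exp(−(ΔE − λ)² / (4λk_BT))

With this sign convention a downhill hop (ΔE > 0) is accelerated and
detailed balance k(ΔE)/k(−ΔE) = exp(ΔE/k_BT) holds identically; for
identical molecules on equivalent sites ΔE = 0, the regime in which all
crystal-level results here are computed. Assumptions: non-adiabatic
(small-J) limit, classical treatment of nuclear modes, site-independent
rates (perfect crystal, no energetic disorder), no polaron or nuclear
tunneling corrections, no electric field.

The hop rates of one central molecule define a random walk. Its diffusion
tensor is summed exactly over transport directions (the MSD convention):

    D = ½ Σ_i k_i (r_i ⊗ r_i),    D_iso = tr(D)/3,

where **r**_i are centroid-to-centroid hop vectors. A second, widely used
"rate-weighted" isotropic form, D_iso = (1/6) Σ_i r_i² k_i P_i with
P_i = k_i/Σ_j k_j, is available as a labeled option because published
hopping-mobility studies use both. The two are not equivalent: on a simple
cubic 6-neighbor lattice the MSD form gives k·r² and the rate-weighted form
k·r²/6, and on a two-channel (±r) chain they differ by exactly a factor of
2. Every report names the convention it used; the MSD form is the default
because it is the one validated by the kinetic Monte Carlo oracle. Mobility
follows from the Einstein–Smoluchowski relation μ = eD/(k_BT), i.e.
dividing D in cm²/s by k_BT/e in volts (25.85 mV at 300 K).

Multi-molecule cells are handled in the single-site approximation: rates
are assembled per central molecule and D is averaged uniformly over the
inequivalent sites.

## Transfer integrals (dimer projection)

The coupling for a dimer is extracted by projecting each monomer's frontier
orbital (HOMO for holes, LUMO for electrons) into the dimer Fock/overlap
problem: with φ_A, φ_B the embedded orbitals,

    e_a = ⟨φ_A|F|φ_A⟩,  J_raw = ⟨φ_A|F|φ_B⟩,  s_ab = ⟨φ_A|S|φ_B⟩,
    J_eff = (J_raw − s_ab (e_a + e_b)/2) / (1 − s_ab²),

the symmetric-orthogonalization correction of the 2×2 frontier block.
|J_eff| feeds the rate (which depends on J²); the signed value is retained
for diagnostics. The classic energy-splitting-in-dimer estimate (half the
gap of the two frontier-dominated dimer levels) is implemented as an
independent cross-check: for homodimers it agrees with the projection to
numerical precision, while for inequivalent sites it overestimates |J| as
√(Δe²/4 + J²) — the reason projection is the default. If a monomer's
frontier level is degenerate within 10 meV the full coupling block between
the degenerate sets is evaluated and its root-mean-square attached, with
the scalar frontier-pair value still reported (the molecules this package
targets are non-degenerate; acene HOMO/LUMO levels are isolated).

Couplings come from any backend satisfying one contract: a tight-binding
(Hückel) toy model with one π-type function per heavy atom (defaults
α_C = −6.55 eV, α_N = −8.55 eV, β = −2.7 eV; intermolecular hopping
t(d) = t0·e^(−η(d−d0)) with t0 = −0.3 eV, η = 1 Å⁻¹, d0 = 3.5 Å, cut at
6 Å — literature-typical π-system magnitudes that yield tens-of-meV
couplings at van der Waals stacking distances), planted matrices with known
couplings for validation, or a plain-text adapter that ingests externally
computed Fock/overlap/Hessian/state-energy matrices. The package never runs
a self-consistent electronic-structure method itself; full-fidelity numbers
require feeding DFT matrices through the adapter.

## Reorganization energy

The inner-sphere reorganization energy is computed by the 4-point
adiabatic-potential scheme from the energies of the neutral and charged
states at both relaxed geometries:

    λ = (E_N* − E_N) + (E_C* − E_C).

For two equal-curvature harmonic surfaces whose minima are displaced by Δq
along a mode of frequency ω, this equals ω²Δq² — it counts the relaxation
of both molecules participating in a self-exchange hop. The normal-mode
decomposition uses the same two-surface convention: after Eckart alignment
(mass-weighted removal of net translation and rotation, required for
rigid-motion invariance), the mass-weighted neutral→charged displacement is
projected on the neutral-state modes, and each mode is assigned
λ_i = ω_i²Δq_i² so that Σλ_i reproduces the 4-point λ exactly in the
harmonic limit. The Huang–Rhys factor is reported as S_i = λ_i/(ħω_i) with
that (two-surface) λ_i; it is therefore twice the single-surface textbook
factor, a deliberate consistency choice documented here. Modes are taken
from the neutral-state Hessian by default; only the inner-sphere term is
treated (no outer-sphere/polarization contribution).

The Raman proxy report tabulates λ_i against I_i/ω_i for Raman lines
matched to modes within a ±10 cm⁻¹ window, with a Spearman rank correlation
and the spectrally integrated proxy. It is a monitoring statistic, not a
causal model; unmatched modes and lines are listed, never dropped.

## Crystal handling

CIF input (cell, symmetry triplets or space-group symbol, fractional
sites) is parsed with gemmi; fractional coordinates are converted once to
Cartesian Å with the standard crystallographic convention (a along x, b in
the xy-plane) and all downstream geometry is Cartesian. Sites with
occupancy < 1 are rejected by default (the crystals of interest are
ordered); a flag keeps them. Symmetry is expanded to a P1 cell; molecules
are identified as connected components of the bond graph (covalent-radius
sum + 0.4 Å) over periodic images and unwrapped across boundaries, with an
infinite covalent network reported as an error. Neighbor dimers are found
by scanning lattice images over at least a 3×3×3 supercell (auto-grown when
the cutoff exceeds the guaranteed search radius) with a default
centroid–centroid cutoff of 10 Å, which covers all nearest-neighbor shells
of acene-like crystals; symmetry-equivalent pairs are grouped by a
rigid-motion-invariant fingerprint (the sorted list of intermolecular
heavy-atom distances, compared within 10⁻³ Å) and each unique pair carries
the full set of equivalent hop directions, which matters for the tensor
(±r pairs share r⊗r, general symmetry mates do not).

Close contacts are classified by a distance criterion — two atoms of
different molecules closer than the Bondi van-der-Waals radius sum
(C 1.70, N 1.55, H 1.20 Å) + 0.2 Å — and tallied by unordered element
pair. Pairs of heavy π-atoms (C⋯C, C⋯N, N⋯N) are classed conductive,
anything involving H insulating. This is deliberately a proxy for
Hirshfeld-surface contact analysis: absolute fractions are contact counts,
not surface areas, so only trends across related structures should be
compared (every report header says so).

## Synthetic data and what it does (not) show

The generators provide every input at desk scale: idealized linear acene
templates (regular 1.40 Å hexagons, 1.09 Å C–H) with configurable CH→N
substitution; one-molecule π-stack crystals with chosen spacing/slip and an
optional lateral edge-gap; a two-molecule herringbone toy with opposite
tilts; planted dimer matrices with known frontier couplings rotated into
random AO bases; displaced-harmonic molecules with planted per-mode
curvatures and displacements (hence exact λ ground truth); and planted hop
networks (chain, cubic, anisotropic, random). All generators are
deterministic given spec and seed.

These fixtures validate the machinery — projection algebra, alignment,
summation, Monte Carlo — exactly, but they do not emulate real crystal
chemistry: tight-binding couplings are not DFT couplings, idealized
geometries carry no thermal disorder, and the harmonic models have no
anharmonicity or Duschinsky rotation. Passing tests demonstrate
correctness of the analysis, not accuracy of any specific material
prediction; material-specific numbers require external structures and
electronic-structure matrices through the adapter.

## Numerical choices

- Constants: ħ = 6.582119569×10⁻¹⁶ eV·s, k_B = 8.617333262×10⁻⁵ eV/K
  (CODATA); energies in eV internally, couplings reported in meV.
- Vibrational bookkeeping in natural units √(eV/(amu·Å²)) (≈ 521.5 cm⁻¹),
  so λ_i = κΔq² holds without conversion factors; cm⁻¹ only at interfaces.
- MO orthonormality (C†SC = 1), Fock symmetry, overlap positivity and mode
  orthonormality are enforced at construction/load time (tolerances 1e-8 /
  1e-10); the generalized eigenproblem is solved with `scipy.linalg.eigh`.
- Eckart alignment residuals above 1e-6 (relative to the displacement
  norm) raise an error rather than silently contaminating Δq.
- KMC: residence-time algorithm; per-trajectory estimator Δr⊗Δr/(2Δt)
  over the second half of each trajectory; D_iso stderr from per-trajectory
  isotropic samples (tensor components of low-dimensional networks are
  strongly correlated, so component-wise quadrature would understate it).
  Default problem size 200 trajectories × 2000 hops, and 50 random networks
  in the cross-validation — sizes chosen so the full validation runs in
  seconds while leaving Monte Carlo error well below the 3σ acceptance
  band.
- Degenerate frontier levels: 10 meV window, rms block coupling attached.
- Empty hop lists yield D = 0 with a warning; mixed temperatures in one
  hop set are an error.

## Known limitations

Hopping-model assumptions exclude bandlike and transient-localization
transport; mobilities for high-J materials are therefore lower bounds in
spirit. ΔE ≠ 0 (heterodimer) rates depend on the stated sign convention;
the (ΔE − λ)² form coincides with the conventional (ΔG° + λ)² expression at
ΔE = 0, the only regime exercised by the crystal pipeline. The contact
classifier is not a Hirshfeld analysis. The CIF reader covers the core
dictionary subset (cell, symmetry, fractional sites) — no disorder
assemblies, no charge/spin metadata. Open-shell monomers are unsupported.
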