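# hopcrystal

Hopping charge-transport analysis for molecular organic semiconductor
crystals: from a crystal structure to hole/electron transfer integrals
(dimer projection), reorganization energies (4-point adiabatic scheme with
normal-mode decomposition), Marcus hop rates, and isotropic charge
mobilities — with synthetic toy crystals, planted electronic-structure
matrices and a kinetic Monte Carlo diffusion oracle so the whole analysis
is testable without any electronic-structure code or database access.

It is aimed at people studying structure–mobility relationships in
π-conjugated crystals (acenes, azaacenes and relatives): how N-substitution
shifts frontier levels, how packing motifs (herringbone vs π-stacking)
shape intermolecular couplings, and what that does to carrier mobility.

## The model

Carriers hop between neighboring molecules with the Marcus rate

    k = (2π/ħ) J² (4πλk_BT)^(−1/2) exp(−(ΔE − λ)²/(4λk_BT)),

where *J* is the electronic coupling between the frontier orbitals of the
pair (HOMOs for holes, LUMOs for electrons), *λ* the reorganization energy,
and ΔE the site-energy difference (0 for identical molecules). The
diffusion tensor sums over all transport directions from a central
molecule, D = ½ Σᵢ kᵢ (rᵢ ⊗ rᵢ), and the isotropic mobility follows from
the Einstein–Smoluchowski relation μ = eD/(k_BT). Couplings are computed by
projecting monomer frontier orbitals into the dimer Fock/overlap problem
(the dimer-projection / DIPRO construction, with overlap correction);
reorganization energies come from the four state/geometry energies
λ = (E_N* − E_N) + (E_C* − E_C) and can be decomposed into per-mode
contributions λᵢ = ωᵢ²Δqᵢ² with Huang–Rhys factors Sᵢ = λᵢ/(ħωᵢ).
See `docs/methods.md` for conventions, assumptions and limitations.

Electronic structure enters through one backend contract: a tight-binding
(Hückel) toy model for desk-scale work, planted matrices for validation,
or a plain-text adapter for matrices computed externally (e.g. by DFT).

## Worked example

A cofacial anthracene π-stack (spacing 3.5 Å) with the Hückel backend and
chosen reorganization energies, via the CLI:

```yaml
# run.yaml
input:
  kind: stack
  spec: {n_rings: 3, spacing: 3.5}
lambda: {hole: 0.2, electron: 0.25}
cutoff: 5.0
```

```
$ hopcrystal run --config run.yaml
structure: toy-stack
HOMO -7.668 eV   LUMO -5.432 eV   gap 2.237 eV
electron: λ = 250 meV | largest J: 57.9 meV @ 3.50 Å, 57.9 meV @ 3.50 Å | μ = 0.1583 cm²/(V·s) [msd convention]
    hole: λ = 200 meV | largest J: 113.9 meV @ 3.50 Å, 113.9 meV @ 3.50 Å | μ = 1.109 cm²/(V·s) [msd convention]
conductive contact fraction: 1.000
```

Reading this: the stack has one unique neighbor dimer (the two ±c stack
images at 3.50 Å); the tight-binding HOMO–HOMO coupling at van der Waals
contact is ≈114 meV and the LUMO–LUMO coupling ≈58 meV, so with
λ_h = 200 meV the hole channel reaches μ_h ≈ 1.1 cm²V⁻¹s⁻¹ — hopping-model
magnitudes typical of good π-stacked organic semiconductors. The contact
table classifies every intermolecular atom pair within the van der Waals
threshold; a perfectly cofacial carbon stack is 100 % C⋯C ("conductive")
contacts.

The same run through the library API:

```python
from hopcrystal.pipeline import RunConfig, run_pipeline

cfg = RunConfig(input_kind="stack", input_spec={"n_rings": 3, "spacing": 3.5},
                lambdas={"hole": 0.2, "electron": 0.25}, cutoff=5.0)
result = run_pipeline(cfg)
print(result.reports["hole"].mu)        # 1.1092240951637202
```

Other entry points: `hopcrystal dimers --cif X.cif --cutoff 10` (neighbor
enumeration for any CIF), `hopcrystal lambda --fourpoint file.dat`
(4-point λ from an adapter file), `hopcrystal kmc --network net.json`
(Monte Carlo diffusion for a planted hop network).

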