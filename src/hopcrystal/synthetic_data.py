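"""Synthetic inputs: toy crystals, planted electronic-structure matrices and
displaced-harmonic molecules with known reorganization energy.

Everything here is generated programmatically and deterministically (given
spec and seed); no downloads, no external files.  The acene-like templates
carry configurable nitrogen substitution so the qualitative trends of
N-substituted π-stacks (LUMO lowering, growing conductive-contact share)
are testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import natural_to_wavenumber
from .crystal_model import CrystalStructure, Molecule, SymmetryOp, UnitCell
from .errors import GeometryError
from .mobility import HopSpec
from .qc_backend import (
    DimerMatrices,
    ElectronicStructureResult,
    FourPointEnergies,
    NormalModeSet,
)

RING_BOND = 1.40   # Å, aromatic C–C
CH_BOND = 1.09     # Å


# ---------------------------------------------------------------------------
# Molecular templates
# ---------------------------------------------------------------------------

def make_acene_template(n_rings: int) -> Molecule:
    """Idealized linear acene (anthracene for n_rings=3): fused regular
    hexagons in the xy-plane, long axis along x, H on every CH carbon."""
    if n_rings < 1:
        raise ValueError("need at least one ring")
    hx = RING_BOND * math.sqrt(3.0) / 2.0
    verts = []
    for j in range(n_rings):
        cx = j * RING_BOND * math.sqrt(3.0)
        for ang in (0, 60, 120, 180, 240, 300):
            a = math.radians(ang)
            verts.append((cx + RING_BOND * math.sin(a), RING_BOND * math.cos(a)))
    # Merge shared fusion carbons.
    unique: list[tuple[float, float]] = []
    for v in verts:
        if not any(math.hypot(v[0] - u[0], v[1] - u[1]) < 0.1 for u in unique):
            unique.append(v)
    unique.sort(key=lambda p: (round(p[0], 3), round(p[1], 3)))
    coords = np.array([(x, y, 0.0) for x, y in unique])
    n_c = len(coords)

    bonds = [
        (i, j)
        for i in range(n_c)
        for j in range(i + 1, n_c)
        if np.linalg.norm(coords[i] - coords[j]) < RING_BOND + 0.1
    ]
    elements = ["C"] * n_c
    neighbor_count = np.zeros(n_c, dtype=int)
    for i, j in bonds:
        neighbor_count[i] += 1
        neighbor_count[j] += 1

    all_coords = [tuple(c) for c in coords]
    all_bonds = list(bonds)
    for i in range(n_c):
        if neighbor_count[i] < 3:  # CH position
            vec = np.zeros(3)
            for a, b in bonds:
                if a == i:
                    vec += coords[i] - coords[b]
                elif b == i:
                    vec += coords[i] - coords[a]
            vec /= np.linalg.norm(vec)
            elements.append("H")
            all_coords.append(tuple(coords[i] + CH_BOND * vec))
            all_bonds.append((i, len(all_coords) - 1))
    _ = hx
    return Molecule(elements=elements, coords=np.array(all_coords), bonds=all_bonds)


def ch_positions(template: Molecule) -> list[int]:
    """Indices of CH carbons (candidates for N substitution), by geometry:
    sorted by (x, y) for a deterministic substitution order."""
    bonded_h = {min(i, j) for i, j in template.bonds
                if "H" in (template.elements[i], template.elements[j])}
    ch = [i for i in range(template.n_atoms)
          if template.elements[i] == "C" and any(
              (i in (a, b)) and "H" in (template.elements[a], template.elements[b])
              for a, b in template.bonds)]
    _ = bonded_h
    return sorted(ch, key=lambda i: (round(template.coords[i][0], 3),
                                     round(template.coords[i][1], 3)))


def edge_ch_positions(template: Molecule) -> list[int]:
    """CH carbons ordered by decreasing |y| (long-edge first): substituting
    these converts the lateral edge-to-edge contacts of a stack from
    H-mediated to N-mediated."""
    return sorted(
        ch_positions(template),
        key=lambda i: (-abs(template.coords[i][1]), round(template.coords[i][0], 3)),
    )


def substitute_nitrogens(template: Molecule, positions: list[int]) -> Molecule:
    """Replace the CH unit at each given carbon index by N (drop its H)."""
    elements = list(template.elements)
    drop = set()
    for p in positions:
        if elements[p] != "C":
            raise ValueError(f"substitution site {p} is {elements[p]}, not C")
        elements[p] = "N"
        for a, b in template.bonds:
            if p in (a, b):
                other = b if a == p else a
                if template.elements[other] == "H":
                    drop.add(other)
    keep = [i for i in range(template.n_atoms) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [(remap[a], remap[b]) for a, b in template.bonds
             if a not in drop and b not in drop]
    return Molecule(
        elements=[elements[i] for i in keep],
        coords=template.coords[keep],
        bonds=bonds,
    )


# ---------------------------------------------------------------------------
# Toy crystals
# ---------------------------------------------------------------------------

@dataclass
class StackSpec:
    """One-molecule-per-cell π-stack: stacking axis c = (slip, 0, spacing)."""

    template: Molecule
    spacing: float = 3.5          # Å along the stacking normal
    slip: float = 0.0             # Å along the long molecular axis
    padding: float = 12.0         # Å of lateral vacuum
    edge_gap: float | None = None  # Å edge-to-edge along b; None = padded vacuum
    n_nitrogens: int = 0
    pattern: list[int] = field(default_factory=list)
    name: str = "toy-stack"

    def __post_init__(self):
        if self.spacing <= 2.8:
            raise ValueError("stacking spacing must exceed 2.8 Å")
        if self.slip < 0:
            raise ValueError("slip must be ≥ 0")


def _resolve_molecule(spec: StackSpec) -> Molecule:
    if spec.n_nitrogens == 0:
        return spec.template
    pattern = spec.pattern or ch_positions(spec.template)
    if spec.n_nitrogens > len(pattern):
        raise ValueError("more nitrogens requested than CH positions available")
    return substitute_nitrogens(spec.template, list(pattern[: spec.n_nitrogens]))


def make_stack_crystal(spec: StackSpec) -> CrystalStructure:
    """P1 crystal whose only close neighbors are the ±c stack images."""
    mol = _resolve_molecule(spec)
    ext = mol.coords.max(axis=0) - mol.coords.min(axis=0)
    a = ext[0] + spec.padding
    b = ext[1] + (spec.edge_gap if spec.edge_gap is not None else spec.padding)
    c_len = math.hypot(spec.slip, spec.spacing)
    beta = math.degrees(math.acos(spec.slip / c_len))
    cell = UnitCell(a=a, b=b, c=c_len, alpha=90.0, beta=beta, gamma=90.0)

    if spec.spacing < 2.8:
        raise GeometryError("stack images clash")
    m = cell.frac_to_cart
    centered = mol.coords - mol.centroid + m @ np.array([0.5, 0.5, 0.5])
    frac = centered @ np.linalg.inv(m).T
    return CrystalStructure(
        cell=cell,
        symmetry=[SymmetryOp.identity()],
        site_elements=list(mol.elements),
        site_frac=frac,
        name=spec.name,
    )


def make_herringbone_crystal(
    template: Molecule,
    tilt_deg: float = 50.0,
    b: float = 7.4,
    c: float = 5.2,
    padding: float = 12.0,
    name: str = "toy-herringbone",
) -> CrystalStructure:
    """Two molecules per cell with opposite tilts ±tilt/2 about the long
    axis: one edge-to-face contact class and one same-tilt translation
    class within a ~6 Å centroid cutoff."""
    ext = template.coords.max(axis=0) - template.coords.min(axis=0)
    a = ext[0] + padding
    cell = UnitCell(a=a, b=b, c=c)
    m = cell.frac_to_cart

    def tilted(angle_deg: float) -> np.ndarray:
        t = math.radians(angle_deg)
        rot = np.array(
            [[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]]
        )
        return (template.coords - template.centroid) @ rot.T

    center_a = m @ np.array([0.5, 0.25, 0.25])
    center_b = m @ np.array([0.5, 0.75, 0.75])
    coords = np.vstack([tilted(+tilt_deg / 2) + center_a, tilted(-tilt_deg / 2) + center_b])
    frac = coords @ np.linalg.inv(m).T
    return CrystalStructure(
        cell=cell,
        symmetry=[SymmetryOp.identity()],
        site_elements=list(template.elements) * 2,
        site_frac=frac,
        name=name,
    )


def write_cif(structure: CrystalStructure, path) -> None:
    """Emit a P1 CIF that round-trips through read_cif to 1e-6 Å."""
    if not structure.site_elements:
        raise ValueError("cannot write a CIF with no atom sites")
    cell = structure.cell
    with open(path, "w") as fh:
        fh.write(f"data_{structure.name or 'hopcrystal'}\n")
        for tag, val in (
            ("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
            ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
            ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma),
        ):
            fh.write(f"{tag} {val:.10f}\n")
        fh.write("loop_\n_space_group_symop_operation_xyz\n'x, y, z'\n")
        fh.write(
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
        )
        for k, (el, f) in enumerate(zip(structure.site_elements, structure.site_frac)):
            fh.write(f"{el}{k + 1} {el} {f[0]:.15g} {f[1]:.15g} {f[2]:.15g}\n")


# ---------------------------------------------------------------------------
# Planted electronic structure
# ---------------------------------------------------------------------------

@dataclass
class PlantedDimer:
    dimer: DimerMatrices
    mon_a: ElectronicStructureResult
    mon_b: ElectronicStructureResult
    carrier: str
    planted_J_raw: float
    planted_s_ab: float
    expected_J_eff: float


def make_planted_dimer(
    n_basis: int = 6,
    coupling: float = 0.05,
    s_ab: float = 0.0,
    site_split: float = 0.0,
    carrier: str = "hole",
    seed: int = 0,
) -> PlantedDimer:
    """Dimer Fock/overlap with a known frontier-frontier coupling.

    Monomer MO energies are evenly spaced and non-degenerate; the coupling
    (and optionally a frontier overlap s_ab and a site-energy split) is
    planted between the two frontier MOs, then everything is rotated into
    a random AO basis per monomer.
    """
    if n_basis % 2:
        raise ValueError("n_basis must be even (closed shell)")
    rng = np.random.default_rng(seed)
    e_a = np.linspace(-10.0, -2.0, n_basis)
    e_b = e_a + site_split
    n_el = n_basis  # half filled
    fi = n_el // 2 - 1 if carrier == "hole" else n_el // 2

    n = 2 * n_basis
    f_mo = np.diag(np.concatenate([e_a, e_b]))
    s_mo = np.eye(n)
    ia, ib = fi, n_basis + fi
    f_mo[ia, ib] = f_mo[ib, ia] = coupling
    s_mo[ia, ib] = s_mo[ib, ia] = s_ab

    def random_orthogonal(k):
        q, r = np.linalg.qr(rng.normal(size=(k, k)))
        return q * np.sign(np.diag(r))

    qa, qb = random_orthogonal(n_basis), random_orthogonal(n_basis)
    q = np.zeros((n, n))
    q[:n_basis, :n_basis] = qa
    q[n_basis:, n_basis:] = qb
    dimer = DimerMatrices(
        fock=q @ f_mo @ q.T, overlap=q @ s_mo @ q.T, block_sizes=(n_basis, n_basis)
    )

    def monomer(qm, energies):
        return ElectronicStructureResult(
            orbital_energies=energies,
            mo_coefficients=qm,
            overlap=np.eye(n_basis),
            n_electrons=n_el,
        )

    ea_f, eb_f = e_a[fi], e_b[fi]
    expected = (coupling - s_ab * (ea_f + eb_f) / 2.0) / (1.0 - s_ab**2)
    return PlantedDimer(
        dimer=dimer,
        mon_a=monomer(qa, e_a),
        mon_b=monomer(qb, e_b),
        carrier=carrier,
        planted_J_raw=coupling,
        planted_s_ab=s_ab,
        expected_J_eff=expected,
    )


# ---------------------------------------------------------------------------
# Displaced-harmonic molecules
# ---------------------------------------------------------------------------

@dataclass
class HarmonicModel:
    """Ground truth for the reorganization machinery.

    Curvatures κ_i are mass-weighted (eV/(amu·Å²)) and displacements Δq_i
    mass-weighted (√amu·Å); the 4-point reorganization energy of two
    equal-curvature displaced surfaces is λ_true = Σ κ_i·Δq_i².
    """

    four_point: FourPointEnergies
    modes: NormalModeSet
    neutral_geom: np.ndarray
    charged_geom: np.ndarray
    lambda_true: float
    lambda_modes: np.ndarray      # per-mode, descending-free (mode order)
    elements: list[str]


def make_displaced_harmonic(
    n_modes: int,
    force_constants,
    displacements,
    seed: int = 0,
) -> HarmonicModel:
    """Molecule with ``n_modes`` planted harmonic modes.

    A random non-linear reference geometry is drawn (seeded); mode vectors
    are random orthonormal directions in the mass-weighted space orthogonal
    to rigid translations/rotations, so Eckart-aligned projection recovers
    the planted Δq_i exactly.
    """
    kappa = np.atleast_1d(np.asarray(force_constants, dtype=float))
    dq = np.atleast_1d(np.asarray(displacements, dtype=float))
    if kappa.size == 1:
        kappa = np.full(n_modes, kappa[0])
    if dq.size == 1:
        dq = np.full(n_modes, dq[0])
    if kappa.size != n_modes or dq.size != n_modes:
        raise ValueError("force_constants/displacements must match n_modes")
    if np.any(kappa <= 0):
        raise ValueError("force constants must be positive")

    rng = np.random.default_rng(seed)
    n_atoms = max(4, (n_modes + 6 + 2) // 3)
    element_pool = ["C", "N", "H"]
    elements = [element_pool[i % 3] for i in range(n_atoms)]
    from .elements import atomic_mass

    masses = np.array([atomic_mass(e) for e in elements])
    geom = rng.normal(scale=1.5, size=(n_atoms, 3))

    from .reorganization import _rigid_body_basis

    rigid = _rigid_body_basis(geom, masses)
    dim = 3 * n_atoms
    if n_modes > dim - rigid.shape[0]:
        raise ValueError("too many modes for this molecule size")
    raw = rng.normal(size=(n_modes, dim))
    raw -= (raw @ rigid.T) @ rigid
    q, r = np.linalg.qr(raw.T)
    vectors = (q[:, :n_modes] * np.sign(np.diag(r)[:n_modes])).T

    freqs_cm = natural_to_wavenumber(np.sqrt(kappa))
    modes = NormalModeSet(frequencies=freqs_cm, displacement_vectors=vectors, masses=masses)

    disp_mw = (dq[:, None] * vectors).sum(axis=0)
    charged = geom + (disp_mw / np.sqrt(np.repeat(masses, 3))).reshape(n_atoms, 3)

    lam_modes = kappa * dq**2
    relax = float(0.5 * lam_modes.sum())  # one-surface relaxation Σ ½κΔq²
    four = FourPointEnergies(E_N=0.0, E_N_star=relax, E_C=-1.0, E_C_star=-1.0 + relax)
    return HarmonicModel(
        four_point=four,
        modes=modes,
        neutral_geom=geom,
        charged_geom=charged,
        lambda_true=float(lam_modes.sum()),
        lambda_modes=lam_modes,
        elements=elements,
    )


# ---------------------------------------------------------------------------
# Planted hop networks
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """Direct hop definitions: (r_vec Å, J eV, ΔE eV) per direction."""

    hops: list[tuple]             # (r_vec, J, delta_E)
    lambda_: float = 0.2
    T: float = 300.0


def make_planted_network(spec: PlantedNetwork) -> list[HopSpec]:
    return [
        HopSpec(J=float(J), lambda_=spec.lambda_, r_vec=np.asarray(r_vec, dtype=float),
                delta_E=float(dE), T=spec.T)
        for r_vec, J, dE in spec.hops
    ]


def chain_network(r: float = 4.0, J: float = 0.05, lambda_: float = 0.2,
                  T: float = 300.0) -> list[HopSpec]:
    """1D chain: two opposite neighbors at ±r along z."""
    return make_planted_network(PlantedNetwork(
        hops=[((0, 0, r), J, 0.0), ((0, 0, -r), J, 0.0)], lambda_=lambda_, T=T))


def cubic_network(r: float = 4.0, J: float = 0.05, lambda_: float = 0.2,
                  T: float = 300.0) -> list[HopSpec]:
    """Simple-cubic 6-neighbor network."""
    hops = []
    for axis in range(3):
        for sign in (+1, -1):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * r
            hops.append((tuple(v), J, 0.0))
    return make_planted_network(PlantedNetwork(hops=hops, lambda_=lambda_, T=T))


def anisotropic_network(
    J_stack: float = 0.100,
    J_side: float = 0.020,
    r_stack: float = 3.5,
    r_side: float = 6.0,
    lambda_: float = 0.2,
    T: float = 300.0,
) -> list[HopSpec]:
    """Quasi-one-dimensional regime: a strong π-stacking channel along z
    plus weak (~20 meV) side channels along x and y."""
    hops = [((0, 0, r_stack), J_stack, 0.0), ((0, 0, -r_stack), J_stack, 0.0)]
    for axis in range(2):
        for sign in (+1, -1):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * r_side
            hops.append((tuple(v), J_side, 0.0))
    return make_planted_network(PlantedNetwork(hops=hops, lambda_=lambda_, T=T))


def random_network(
    rng: np.random.Generator,
    n_directions: int | None = None,
    lambda_range=(0.1, 0.4),
    J_range=(0.005, 0.12),
    r_range=(3.0, 10.0),
    T: float = 300.0,
) -> list[HopSpec]:
    """Random ± direction pairs (site-independent rates, zero ΔE) for
    analytic-vs-KMC cross validation."""
    if n_directions is None:
        n_directions = int(rng.integers(1, 5))
    lam = float(rng.uniform(*lambda_range))
    hops = []
    for _ in range(n_directions):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r_vec = direction * rng.uniform(*r_range)
        J = float(rng.uniform(*J_range))
        hops.append((tuple(r_vec), J, 0.0))
        hops.append((tuple(-r_vec), J, 0.0))
    return make_planted_network(PlantedNetwork(hops=hops, lambda_=lam, T=T))
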