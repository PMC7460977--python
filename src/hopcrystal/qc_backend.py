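"""Electronic-structure backends behind one contract.

Three routes provide the quantities the transport analysis consumes
(orbital energies/coefficients, Fock/overlap matrices, four-point state
energies, normal modes):

* a tight-binding (Hückel) toy backend with one π-type basis function per
  heavy atom — deterministic, download-free, used for end-to-end tests;
* planted matrices with known couplings (see :mod:`hopcrystal.synthetic_data`);
* a plain-text adapter that ingests externally computed matrices (e.g. from
  a DFT code) without running any electronic-structure method itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .crystal_model import Molecule
from .errors import GeometryError, ValidationError

ORTHONORMALITY_TOL = 1e-8


@dataclass
class HuckelParams:
    """Tight-binding parameters (eV, Å).

    On-site energies α per element and a single bonded hopping β define
    the monomer Hamiltonian; intermolecular hopping decays exponentially,
    t(d) = t0·exp(−η(d−d0)) for heavy-atom pairs with d ≤ d_max.  Default
    magnitudes are literature-typical for π systems and give couplings in
    the tens of meV at van der Waals stacking distances.
    """

    alpha: dict = field(default_factory=lambda: {"C": -6.55, "N": -8.55})
    beta: float = -2.7
    t0: float = -0.3
    eta: float = 1.0
    d0: float = 3.5
    d_max: float = 6.0


@dataclass
class ElectronicStructureResult:
    """Single-molecule orbitals from any backend."""

    orbital_energies: np.ndarray        # ascending, eV
    mo_coefficients: np.ndarray         # (n_basis, n_orbitals), columns = MOs
    overlap: np.ndarray                 # (n_basis, n_basis)
    n_electrons: int
    basis_labels: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.orbital_energies = np.asarray(self.orbital_energies, dtype=float)
        self.mo_coefficients = np.asarray(self.mo_coefficients, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.n_electrons % 2:
            raise ValidationError("open-shell systems unsupported (odd electron count)")
        if np.any(np.diff(self.orbital_energies) < -1e-10):
            raise ValidationError("orbital energies must be non-decreasing")
        gram = self.mo_coefficients.T @ self.overlap @ self.mo_coefficients
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=ORTHONORMALITY_TOL):
            raise ValidationError("MO coefficients not S-orthonormal (C†SC ≠ 1)")

    @property
    def homo_index(self) -> int:
        return self.n_electrons // 2 - 1

    @property
    def lumo_index(self) -> int:
        return self.homo_index + 1

    def frontier_index(self, carrier: str) -> int:
        if carrier == "hole":
            return self.homo_index
        if carrier == "electron":
            if self.lumo_index >= len(self.orbital_energies):
                raise ValidationError("no virtual orbital available (LUMO undefined)")
            return self.lumo_index
        raise ValueError(f"carrier must be 'hole' or 'electron', got {carrier!r}")


@dataclass
class DimerMatrices:
    """Fock and overlap matrices of a molecular dimer in block layout."""

    fock: np.ndarray
    overlap: np.ndarray
    block_sizes: tuple[int, int]

    def __post_init__(self):
        self.fock = np.asarray(self.fock, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=float)
        n = sum(self.block_sizes)
        if self.fock.shape != (n, n):
            raise ValidationError(
                f"Fock dimension {self.fock.shape} inconsistent with blocks {self.block_sizes}"
            )
        if self.overlap.shape != (n, n):
            raise ValidationError(
                f"overlap dimension {self.overlap.shape} inconsistent with blocks {self.block_sizes}"
            )
        if not np.allclose(self.fock, self.fock.T, atol=1e-10):
            raise ValidationError("Fock matrix not symmetric within 1e-10")
        if np.linalg.eigvalsh(self.overlap).min() <= 0:
            raise ValidationError("overlap matrix not positive definite")


@dataclass(frozen=True)
class FourPointEnergies:
    """Total energies (eV) of the four state/geometry combinations.

    E_N: neutral state at its own optimized geometry; E_N_star: neutral
    state at the charged-state geometry; E_C: charged state at its own
    geometry; E_C_star: charged state at the neutral geometry.
    """

    E_N: float
    E_N_star: float
    E_C: float
    E_C_star: float

    def __post_init__(self):
        for v in (self.E_N, self.E_N_star, self.E_C, self.E_C_star):
            if not np.isfinite(v):
                raise ValidationError("four-point energies must be finite")


@dataclass
class NormalModeSet:
    """Vibrational modes at a reference geometry.

    Frequencies in cm⁻¹ (translations/rotations projected out, so all
    positive); displacement vectors are orthonormal in the mass-weighted
    metric, shape (n_modes, 3·n_atoms).
    """

    frequencies: np.ndarray
    displacement_vectors: np.ndarray
    masses: np.ndarray                 # per-atom, amu

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.displacement_vectors = np.asarray(self.displacement_vectors, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValidationError("retained mode frequencies must be positive")
        gram = self.displacement_vectors @ self.displacement_vectors.T
        if not np.allclose(gram, np.eye(len(self.frequencies)), atol=ORTHONORMALITY_TOL):
            raise ValidationError("mode vectors not orthonormal in mass-weighted metric")


# ---------------------------------------------------------------------------
# Hückel backend
# ---------------------------------------------------------------------------

def _heavy(molecule: Molecule):
    idx = molecule.heavy_indices()
    return idx, molecule.coords[idx], [molecule.elements[i] for i in idx]


def _monomer_hamiltonian(molecule: Molecule, params: HuckelParams) -> tuple[np.ndarray, list]:
    idx, _, elems = _heavy(molecule)
    pos = {int(a): k for k, a in enumerate(idx)}
    n = len(idx)
    h = np.zeros((n, n))
    for k, el in enumerate(elems):
        try:
            h[k, k] = params.alpha[el]
        except KeyError:
            raise ValidationError(f"no on-site Hückel energy for element {el!r}")
    for i, j in molecule.bonds:
        if int(i) in pos and int(j) in pos:
            h[pos[int(i)], pos[int(j)]] = params.beta
            h[pos[int(j)], pos[int(i)]] = params.beta
    labels = [(int(a), "pz") for a in idx]
    return h, labels


def huckel_monomer(molecule: Molecule, params: HuckelParams | None = None) -> ElectronicStructureResult:
    """Tight-binding π-system solution: one basis function and one electron
    per heavy atom (C, N); orthogonal basis (overlap = identity)."""
    params = params or HuckelParams()
    h, labels = _monomer_hamiltonian(molecule, params)
    if len(labels) % 2:
        raise ValidationError(
            f"{len(labels)} π electrons: open-shell systems unsupported"
        )
    energies, coeffs = np.linalg.eigh(h)
    return ElectronicStructureResult(
        orbital_energies=energies,
        mo_coefficients=coeffs,
        overlap=np.eye(len(labels)),
        n_electrons=len(labels),
        basis_labels=labels,
    )


def intermolecular_hopping(d: np.ndarray, params: HuckelParams) -> np.ndarray:
    """Distance-decayed hopping t(d) = t0·exp(−η(d−d0)), zero beyond d_max."""
    t = params.t0 * np.exp(-params.eta * (np.asarray(d) - params.d0))
    return np.where(np.asarray(d) <= params.d_max, t, 0.0)


def huckel_dimer(mol_a: Molecule, mol_b: Molecule, params: HuckelParams | None = None) -> DimerMatrices:
    """Block tight-binding dimer: monomer Hamiltonians on the diagonal,
    distance-decayed hoppings between heavy atoms off-diagonal."""
    params = params or HuckelParams()
    ha, labels_a = _monomer_hamiltonian(mol_a, params)
    hb, labels_b = _monomer_hamiltonian(mol_b, params)
    _, pa, _ = _heavy(mol_a)
    _, pb, _ = _heavy(mol_b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    if d.size and d.min() < 0.5:
        raise GeometryError(f"overlapping atoms between monomers (d = {d.min():.3f} Å)")
    off = intermolecular_hopping(d, params)
    na, nb = ha.shape[0], hb.shape[0]
    fock = np.block([[ha, off], [off.T, hb]])
    return DimerMatrices(fock=fock, overlap=np.eye(na + nb), block_sizes=(na, nb))


# ---------------------------------------------------------------------------
# Plain-text matrix adapter
# ---------------------------------------------------------------------------
#
# Format: one or more sections, each starting with
#     #kind fock|overlap|coeffs|energies|hessian|fourpoint|masses
#     #dim n [m]
#     #blocks n_a n_b        (dimer matrices only)
# followed by whitespace-separated rows at full precision.

_KINDS = {"fock", "overlap", "coeffs", "energies", "hessian", "fourpoint", "masses"}


def write_adapter_file(path, sections: dict[str, np.ndarray], blocks: tuple[int, int] | None = None) -> None:
    """Write matrices in the adapter exchange format (≥ 15 significant digits)."""
    with open(path, "w") as fh:
        for kind, arr in sections.items():
            if kind not in _KINDS:
                raise ValueError(f"unknown section kind {kind!r}")
            a = np.atleast_2d(np.asarray(arr, dtype=float))
            fh.write(f"#kind {kind}\n")
            if a.shape[0] == 1:
                fh.write(f"#dim {a.shape[1]}\n")
            else:
                fh.write(f"#dim {a.shape[0]} {a.shape[1]}\n")
            if blocks is not None and kind in ("fock", "overlap"):
                fh.write(f"#blocks {blocks[0]} {blocks[1]}\n")
            for row in a:
                fh.write(" ".join(format(x, ".17g") for x in row) + "\n")


def _parse_sections(path):
    sections: dict[str, np.ndarray] = {}
    blocks = None
    kind = None
    dims: tuple[int, ...] = ()
    rows: list[list[float]] = []

    def flush():
        nonlocal kind, rows
        if kind is None:
            return
        arr = np.array(rows, dtype=float)
        expect = dims if len(dims) == 2 else (1, dims[0])
        if arr.shape != expect:
            raise ValidationError(
                f"section '{kind}': declared dimension {dims} but read shape {arr.shape}"
            )
        sections[kind] = arr if len(dims) == 2 else arr.ravel()
        kind, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#kind"):
                flush()
                kind = line.split()[1]
                if kind not in _KINDS:
                    raise ValidationError(f"unknown section kind {kind!r} in {path}")
            elif line.startswith("#dim"):
                dims = tuple(int(x) for x in line.split()[1:])
            elif line.startswith("#blocks"):
                blocks = tuple(int(x) for x in line.split()[1:3])
            elif line.startswith("#"):
                continue
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return sections, blocks


def load_external_matrices(path):
    """Load adapter file(s) into validated records.

    Returns, depending on the sections present:
    :class:`FourPointEnergies` (fourpoint), :class:`NormalModeSet`
    (hessian + masses), :class:`DimerMatrices` (fock + overlap + #blocks),
    :class:`ElectronicStructureResult` (energies + coeffs + overlap), or
    the raw section dict otherwise.  Invariants are enforced at load time
    with errors naming the offending matrix.
    """
    sections, blocks = _parse_sections(path)
    if "fourpoint" in sections:
        vals = np.asarray(sections["fourpoint"]).ravel()
        if vals.size != 4:
            raise ValidationError("fourpoint section must hold exactly 4 energies")
        return FourPointEnergies(*[float(v) for v in vals])
    if "hessian" in sections:
        if "masses" not in sections:
            raise ValidationError("hessian section requires an accompanying masses section")
        return modes_from_hessian(sections["hessian"], np.asarray(sections["masses"]).ravel())
    if "fock" in sections and "overlap" in sections and blocks is not None:
        return DimerMatrices(fock=sections["fock"], overlap=sections["overlap"],
                             block_sizes=(blocks[0], blocks[1]))
    if "energies" in sections and "coeffs" in sections:
        n_basis = sections["coeffs"].shape[0]
        overlap = sections.get("overlap", np.eye(n_basis))
        n_el = 2 * ((len(np.asarray(sections["energies"]).ravel()) + 1) // 2)
        return ElectronicStructureResult(
            orbital_energies=np.asarray(sections["energies"]).ravel(),
            mo_coefficients=sections["coeffs"],
            overlap=overlap,
            n_electrons=n_el,
        )
    return sections


def modes_from_hessian(hessian: np.ndarray, masses: np.ndarray,
                       rigid_tol: float = 1e-6) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian (eV/(amu·Å²)); eigenpairs with
    |eigenvalue| below ``rigid_tol`` (translations/rotations) are dropped."""
    from .constants import natural_to_wavenumber

    h = np.asarray(hessian, dtype=float)
    if not np.allclose(h, h.T, atol=1e-8):
        raise ValidationError("mass-weighted Hessian not symmetric")
    evals, evecs = np.linalg.eigh(h)
    keep = evals > rigid_tol
    if np.any(evals < -rigid_tol):
        raise ValidationError("Hessian has imaginary modes (negative curvature)")
    freqs = natural_to_wavenumber(np.sqrt(evals[keep]))
    return NormalModeSet(
        frequencies=freqs,
        displacement_vectors=evecs[:, keep].T,
        masses=masses,
    )


def solve_generalized(fock: np.ndarray, overlap: np.ndarray):
    """FC = SCε for a Hermitian pencil; returns (energies, coefficients)."""
    return scipy.linalg.eigh(fock, overlap)
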