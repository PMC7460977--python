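"""Crystal structures: CIF input, symmetry expansion to P1, whole-molecule
identification across periodic boundaries, and neighbor-dimer enumeration.

All geometry downstream of CIF reading is Cartesian Å.  The fractional →
Cartesian transformation follows the standard crystallographic convention
(a along x, b in the xy-plane).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .elements import BOND_TOLERANCE, covalent_radius
from .errors import FormatError, NotMolecularError, SupercellError, SymmetryError

DEFAULT_DIMER_CUTOFF = 10.0  # Å, centroid–centroid
_SITE_MERGE_TOL = 1e-3       # Å, for deduplicating symmetry-generated sites


@dataclass(frozen=True)
class UnitCell:
    """Lattice parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def _cosines(self):
        return tuple(math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))

    @property
    def volume(self) -> float:
        ca, cb, cg = self._cosines
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    @property
    def frac_to_cart(self) -> np.ndarray:
        ca, cb, cg = self._cosines
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg, 0.0))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def cart_to_frac(self) -> np.ndarray:
        return np.linalg.inv(self.frac_to_cart)

    def heights(self) -> np.ndarray:
        """Perpendicular interplanar distances along a, b, c (Å).

        These bound the minimum image separation; a 3×3×3 supercell
        guarantees completeness of a neighbor search up to min(heights).
        """
        m = self.frac_to_cart
        av, bv, cv = m[:, 0], m[:, 1], m[:, 2]
        vol = abs(np.dot(av, np.cross(bv, cv)))
        return np.array(
            [
                vol / np.linalg.norm(np.cross(bv, cv)),
                vol / np.linalg.norm(np.cross(cv, av)),
                vol / np.linalg.norm(np.cross(av, bv)),
            ]
        )


@dataclass(frozen=True)
class SymmetryOp:
    """Crystallographic symmetry operation acting on fractional coordinates."""

    rotation: np.ndarray   # 3×3, integer entries
    translation: np.ndarray  # fractional, components in [0, 1)

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        if abs(abs(np.linalg.det(rot)) - 1.0) > 1e-9:
            raise ValueError("symmetry rotation must have |det| = 1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float) % 1.0)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        """Parse an xyz-style operation string such as '-x, y+1/2, -z+1/2'."""
        try:
            op = gemmi.Op(triplet.strip())
        except Exception as exc:  # gemmi raises RuntimeError on bad strings
            raise SymmetryError(f"cannot parse symmetry operation {triplet!r}: {exc}")
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        return cls(rotation=rot, translation=tran)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.rotation.T + self.translation


@dataclass
class Molecule:
    """A whole molecule in the Cartesian crystal frame."""

    elements: list[str]
    coords: np.ndarray         # (n, 3) Å
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.elements), 3)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of atomic positions."""
        return self.coords.mean(axis=0)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def translated(self, vec: np.ndarray) -> "Molecule":
        return Molecule(list(self.elements), self.coords + np.asarray(vec), list(self.bonds))

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Molecule":
        return Molecule(list(self.elements), self.coords @ np.asarray(rot).T + trans, list(self.bonds))


@dataclass
class CrystalStructure:
    """Unit cell + symmetry + sites; molecules filled by identify_molecules."""

    cell: UnitCell
    symmetry: list[SymmetryOp]
    site_elements: list[str]
    site_frac: np.ndarray          # (n, 3) asymmetric-unit fractional coords
    molecules: list[Molecule] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.site_frac = np.asarray(self.site_frac, dtype=float).reshape(len(self.site_elements), 3)
        if not self.symmetry:
            self.symmetry = [SymmetryOp.identity()]


@dataclass
class DimerPair:
    """A symmetry-unique pair of neighboring molecules.

    ``r_vec`` is the centroid→centroid vector for the representative
    instance; ``equivalent_r_vecs`` lists all symmetry-equivalent hop
    directions around the central molecule (their count is ``multiplicity``).
    """

    mol_a: Molecule
    mol_b: Molecule
    r_vec: np.ndarray
    multiplicity: int
    fingerprint: np.ndarray        # sorted intermolecular heavy-atom distances
    equivalent_r_vecs: list[np.ndarray] = field(default_factory=list)
    central_index: int = 0

    def __post_init__(self):
        self.r_vec = np.asarray(self.r_vec, dtype=float)
        if not self.equivalent_r_vecs:
            self.equivalent_r_vecs = [self.r_vec]

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.r_vec))

    def fingerprint_hash(self, tol: float = 1e-3) -> str:
        quantized = tuple(int(round(d / tol)) for d in self.fingerprint)
        return format(abs(hash(quantized)), "x")


# ---------------------------------------------------------------------------
# CIF input
# ---------------------------------------------------------------------------

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SG_NAME_TAGS = (
    "_space_group_name_H-M_alt",
    "_symmetry_space_group_name_H-M",
    "_space_group_name_Hall",
)


def read_cif(path, keep_partial_occupancy: bool = False) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Requires cell parameters and fractional atom sites; symmetry may be
    given as operation triplets or a recognized space-group symbol (P1 is
    assumed if absent).  Sites with occupancy < 1 are rejected unless
    ``keep_partial_occupancy`` is set, in which case the site is kept as-is.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
        block = doc.sole_block()
    except Exception as exc:
        raise FormatError(f"cannot parse CIF {path}: {exc}")

    def cell_value(tag):
        raw = block.find_value(tag)
        if raw is None:
            raise FormatError(f"CIF {path} missing required tag {tag}")
        return gemmi.cif.as_number(raw)

    cell = UnitCell(
        a=cell_value("_cell_length_a"),
        b=cell_value("_cell_length_b"),
        c=cell_value("_cell_length_c"),
        alpha=cell_value("_cell_angle_alpha"),
        beta=cell_value("_cell_angle_beta"),
        gamma=cell_value("_cell_angle_gamma"),
    )

    symmetry: list[SymmetryOp] = []
    for tag in _SYMOP_TAGS:
        loop = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in loop]
        if triplets:
            symmetry = [SymmetryOp.from_triplet(t) for t in triplets]
            break
    if not symmetry:
        for tag in _SG_NAME_TAGS:
            raw = block.find_value(tag)
            if raw is None:
                continue
            name = gemmi.cif.as_string(raw)
            sg = gemmi.find_spacegroup_by_name(name)
            if sg is None:
                raise SymmetryError(f"unrecognized space-group symbol {name!r}")
            for op in sg.operations():
                rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
                tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
                symmetry.append(SymmetryOp(rotation=rot, translation=tran))
            break
    if not symmetry:
        symmetry = [SymmetryOp.identity()]

    sym_col = block.find_loop("_atom_site_type_symbol")
    label_col = block.find_loop("_atom_site_label")
    fx = block.find_loop("_atom_site_fract_x")
    fy = block.find_loop("_atom_site_fract_y")
    fz = block.find_loop("_atom_site_fract_z")
    occ_col = block.find_loop("_atom_site_occupancy")

    xs = [gemmi.cif.as_number(v) for v in fx]
    ys = [gemmi.cif.as_number(v) for v in fy]
    zs = [gemmi.cif.as_number(v) for v in fz]
    if not xs or len(xs) != len(ys) or len(xs) != len(zs):
        raise FormatError(f"CIF {path} has no consistent _atom_site_fract_* loop")

    symbols = [gemmi.cif.as_string(v) for v in sym_col]
    if not symbols:
        labels = [gemmi.cif.as_string(v) for v in label_col]
        if not labels:
            raise FormatError(f"CIF {path} lacks atom type symbols and labels")
        symbols = ["".join(ch for ch in lab if ch.isalpha())[:2].capitalize() for lab in labels]
        symbols = [s if s in ("Br", "Cl", "Si") else s[0] for s in symbols]

    occupancies = [gemmi.cif.as_number(v) for v in occ_col] or [1.0] * len(xs)
    for sym, occ in zip(symbols, occupancies):
        if occ < 1.0 - 1e-6 and not keep_partial_occupancy:
            raise FormatError(
                f"site {sym} has occupancy {occ} < 1; disordered structures are "
                "rejected by default (pass keep_partial_occupancy=True to keep)"
            )

    name = block.name if block.name and block.name != "#" else ""
    return CrystalStructure(
        cell=cell,
        symmetry=symmetry,
        site_elements=[s.capitalize() if len(s) > 1 else s.upper() for s in symbols],
        site_frac=np.column_stack([xs, ys, zs]),
        name=name,
    )


# ---------------------------------------------------------------------------
# Symmetry expansion and molecule identification
# ---------------------------------------------------------------------------

def expand_to_p1(structure: CrystalStructure) -> tuple[list[str], np.ndarray]:
    """Apply all symmetry operations; return unique unit-cell sites.

    Duplicate images (special positions, redundant operators) are merged
    when closer than a small Cartesian tolerance under minimum image.
    """
    m = structure.cell.frac_to_cart
    elements: list[str] = []
    fracs: list[np.ndarray] = []
    for el, frac in zip(structure.site_elements, structure.site_frac):
        for op in structure.symmetry:
            f = op.apply(frac) % 1.0
            duplicate = False
            for g in fracs:
                delta = f - g
                delta -= np.round(delta)
                if np.linalg.norm(m @ delta) < _SITE_MERGE_TOL:
                    duplicate = True
                    break
            if not duplicate:
                elements.append(el)
                fracs.append(f)
    return elements, np.array(fracs).reshape(len(elements), 3)


_SHIFTS_27 = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])


def identify_molecules(structure: CrystalStructure) -> CrystalStructure:
    """Partition the P1 cell contents into whole molecules.

    Bonding criterion: interatomic distance ≤ covalent-radius sum + 0.4 Å,
    evaluated over periodic images.  Molecules straddling cell boundaries
    are reassembled by unwrapping lattice shifts along the bond graph; a
    component that does not close under translation (an infinite covalent
    network) raises :class:`NotMolecularError`.
    """
    elements, fracs = expand_to_p1(structure)
    n = len(elements)
    m = structure.cell.frac_to_cart
    cart = fracs @ m.T
    radii = np.array([covalent_radius(e) for e in elements])

    # Bonds (i, j, shift): atom j in image cell `shift` bonded to atom i.
    bonds: list[tuple[int, int, np.ndarray]] = []
    thresh = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    for shift in _SHIFTS_27:
        offset = m @ shift.astype(float)
        d = np.linalg.norm(cart[None, :, :] + offset - cart[:, None, :], axis=2)
        ii, jj = np.nonzero(d <= thresh)
        for i, j in zip(ii, jj):
            if i == j and not shift.any():
                continue
            if i == j:
                raise NotMolecularError(
                    f"atom {elements[i]}{i} bonds to its own periodic image"
                )
            if i < j or shift.any():
                bonds.append((int(i), int(j), shift))

    # Connected components on the quotient graph (shifts ignored).
    if bonds:
        bi = np.array([b[0] for b in bonds])
        bj = np.array([b[1] for b in bonds])
        adj = coo_matrix((np.ones(len(bonds)), (bi, bj)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    # Unwrap each component: BFS assigning an integer lattice offset per atom.
    neighbor_map: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    for i, j, s in bonds:
        neighbor_map[i].append((j, s))
        neighbor_map[j].append((i, -s))

    offsets = {}
    molecules = []
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        root = int(members[0])
        offsets[root] = np.zeros(3, dtype=int)
        queue = [root]
        while queue:
            i = queue.pop()
            for j, s in neighbor_map[i]:
                cand = offsets[i] + s
                if j in offsets:
                    if not np.array_equal(offsets[j], cand):
                        raise NotMolecularError(
                            "bond network does not close into a finite molecule "
                            "(infinite covalent chain detected)"
                        )
                else:
                    offsets[j] = cand
                    queue.append(int(j))
        idx = {int(a): k for k, a in enumerate(members)}
        coords = np.array([cart[a] + m @ offsets[int(a)].astype(float) for a in members])
        mol_bonds = sorted(
            {tuple(sorted((idx[i], idx[j]))) for i, j, _ in bonds if labels[i] == comp}
        )
        molecules.append(
            Molecule(elements=[elements[int(a)] for a in members], coords=coords,
                     bonds=[tuple(b) for b in mol_bonds])
        )

    return replace(structure, molecules=molecules)


# ---------------------------------------------------------------------------
# Dimer enumeration
# ---------------------------------------------------------------------------

def _pair_fingerprint(mol_a: Molecule, mol_b: Molecule) -> np.ndarray:
    ha, hb = mol_a.heavy_indices(), mol_b.heavy_indices()
    d = np.linalg.norm(
        mol_a.coords[ha][:, None, :] - mol_b.coords[hb][None, :, :], axis=2
    )
    return np.sort(d.ravel())


def _same_fingerprint(fa: np.ndarray, fb: np.ndarray, tol: float) -> bool:
    return fa.shape == fb.shape and bool(np.all(np.abs(fa - fb) <= tol))


def enumerate_dimers(
    structure: CrystalStructure,
    cutoff: float = DEFAULT_DIMER_CUTOFF,
    tol: float = 1e-3,
    auto_grow: bool = True,
) -> list[DimerPair]:
    """Enumerate symmetry-unique neighbor dimers around each central molecule.

    Every image molecule (lattice translations over at least a 3×3×3
    supercell, grown automatically when the cutoff demands it) whose
    centroid lies within ``cutoff`` of a home-cell molecule's centroid
    yields a candidate pair; candidates are grouped into unique entries by
    their intermolecular heavy-atom distance fingerprint.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.molecules:
        raise ValueError("molecules not identified; call identify_molecules first")

    cell = structure.cell
    m = cell.frac_to_cart
    n_img = int(np.ceil(cutoff / cell.heights().min()))
    if n_img > 1 and not auto_grow:
        raise SupercellError(
            f"cutoff {cutoff} Å exceeds the 3×3×3 supercell guarantee "
            f"(min cell height {cell.heights().min():.2f} Å); enable auto_grow"
        )
    n_img = max(n_img, 1)
    rng = range(-n_img, n_img + 1)
    shifts = np.array([(i, j, k) for i in rng for j in rng for k in rng], dtype=float)

    centroids = np.array([mol.centroid for mol in structure.molecules])
    uniques: list[DimerPair] = []
    for ci, central in enumerate(structure.molecules):
        for mj, other in enumerate(structure.molecules):
            disp = shifts @ m.T + centroids[mj] - centroids[ci]
            dist = np.linalg.norm(disp, axis=1)
            for s_idx in np.nonzero((dist > 1e-6) & (dist <= cutoff))[0]:
                r_vec = disp[s_idx]
                image = other.translated(shifts[s_idx] @ m.T)
                fp = _pair_fingerprint(central, image)
                for u in uniques:
                    if u.central_index == ci and _same_fingerprint(u.fingerprint, fp, tol):
                        u.multiplicity += 1
                        u.equivalent_r_vecs.append(r_vec)
                        break
                else:
                    uniques.append(
                        DimerPair(
                            mol_a=central,
                            mol_b=image,
                            r_vec=r_vec,
                            multiplicity=1,
                            fingerprint=fp,
                            equivalent_r_vecs=[r_vec],
                            central_index=ci,
                        )
                    )
    return uniques


def deduplicate_dimers(pairs: list[DimerPair], tol: float = 1e-3) -> list[DimerPair]:
    """Merge pairs with equal fingerprints (across central molecules).

    Multiplicities are summed and the representative geometry of the first
    occurrence kept.  The fingerprint is invariant under swapping the two
    molecules and under rigid motion, so translation- and symmetry-related
    duplicates coalesce.
    """
    merged: list[DimerPair] = []
    for p in pairs:
        for u in merged:
            if _same_fingerprint(u.fingerprint, p.fingerprint, tol):
                u.multiplicity += p.multiplicity
                u.equivalent_r_vecs.extend(p.equivalent_r_vecs)
                break
        else:
            merged.append(
                DimerPair(
                    mol_a=p.mol_a,
                    mol_b=p.mol_b,
                    r_vec=p.r_vec.copy(),
                    multiplicity=p.multiplicity,
                    fingerprint=p.fingerprint,
                    equivalent_r_vecs=list(p.equivalent_r_vecs),
                    central_index=p.central_index,
                )
            )
    return merged


# ---------------------------------------------------------------------------
# Inspection output
# ---------------------------------------------------------------------------

def write_xyz(molecules: list[Molecule], path, comment: str = "") -> None:
    """Concatenated-XYZ dump of molecules for visual inspection."""
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(mol.elements, mol.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def dimer_table(pairs: list[DimerPair]) -> list[dict]:
    return [
        {
            "fingerprint": p.fingerprint_hash(),
            "r": round(p.r, 6),
            "r_vec": [round(x, 6) for x in p.r_vec],
            "multiplicity": p.multiplicity,
            "central_index": p.central_index,
        }
        for p in pairs
    ]


def write_dimer_json(pairs: list[DimerPair], path) -> None:
    with open(path, "w") as fh:
        json.dump(dimer_table(pairs), fh, indent=2, sort_keys=True)
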