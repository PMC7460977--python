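"""Distance-based intermolecular close-contact classification.

For every atom of each home-cell molecule, each atom of a different
molecule (including periodic images) within r_vdW(A) + r_vdW(B) +
tolerance counts as one contact, tallied by unordered element pair
(C⋯C, C⋯N, N⋯N, C⋯H, N⋯H, H⋯H, ...).  Contacts between pairs of heavy
π-system atoms (C⋯C, C⋯N, N⋯N) are classed "conductive" — geometry
compatible with frontier-orbital overlap — while any contact involving H
is "insulating".

This is a van-der-Waals distance proxy, not a Hirshfeld-surface
fingerprint: absolute fractions differ from surface-area partitions,
but relative trends across related crystals are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import CrystalStructure
from .elements import vdw_radius

DEFAULT_CONTACT_TOLERANCE = 0.2  # Å beyond the vdW-radius sum
CONDUCTIVE_PAIRS = {("C", "C"), ("C", "N"), ("N", "N")}
PROXY_NOTE = (
    "distance/van-der-Waals proxy for contact classification; fractions are "
    "contact counts, not Hirshfeld surface areas"
)


@dataclass
class ContactTable:
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    note: str = PROXY_NOTE

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[tuple[str, str], float]:
        t = self.total
        return {pair: c / t for pair, c in self.counts.items()} if t else {}

    @property
    def conductive_fraction(self) -> float:
        t = self.total
        if not t:
            return 0.0
        return sum(c for pair, c in self.counts.items() if pair in CONDUCTIVE_PAIRS) / t

    def to_dict(self) -> dict:
        return {
            "note": self.note,
            "total": self.total,
            "counts": {"...".join(p): c for p, c in sorted(self.counts.items())},
            "fractions": {"...".join(p): f for p, f in sorted(self.fractions.items())},
            "conductive_fraction": self.conductive_fraction,
        }

    def long_rows(self, structure_name: str = "") -> list[dict]:
        """Stacked-bar-ready long format (one row per element pair)."""
        return [
            {
                "structure": structure_name,
                "pair": "...".join(pair),
                "count": count,
                "fraction": self.fractions[pair],
                "class": "conductive" if pair in CONDUCTIVE_PAIRS else "insulating",
            }
            for pair, count in sorted(self.counts.items())
        ]


def contact_fractions(
    structure: CrystalStructure,
    tolerance: float = DEFAULT_CONTACT_TOLERANCE,
    n_images: int = 1,
) -> ContactTable:
    """Tally close contacts for all home-cell molecules over a supercell.

    Counting every (central atom, external atom) ordered pair from every
    home-cell molecule symmetrizes reciprocal contacts automatically.
    ``n_images`` = 1 means a 3×3×3 supercell; fractions converge once all
    vdW-touching neighbors are inside (tested 2×2×2 vs 3×3×3).
    """
    if not structure.molecules:
        raise ValueError("molecules not identified; call identify_molecules first")
    m = structure.cell.frac_to_cart
    rng = range(-n_images, n_images + 1)
    shifts = np.array([(i, j, k) for i in rng for j in rng for k in rng], dtype=float)

    counts: dict[tuple[str, str], int] = {}
    mols = structure.molecules
    for ci, central in enumerate(mols):
        c_radii = np.array([vdw_radius(e) for e in central.elements])
        for mj, other in enumerate(mols):
            o_radii = np.array([vdw_radius(e) for e in other.elements])
            cut = c_radii[:, None] + o_radii[None, :] + tolerance
            for shift in shifts:
                if mj == ci and not shift.any():
                    continue
                d = np.linalg.norm(
                    other.coords + m @ shift - central.coords[:, None, :], axis=2
                )
                ii, jj = np.nonzero(d <= cut)
                for i, j in zip(ii, jj):
                    pair = tuple(sorted((central.elements[i], other.elements[j])))
                    counts[pair] = counts.get(pair, 0) + 1
    if not counts:
        warnings.warn("no intermolecular contacts within threshold; empty table",
                      stacklevel=2)
    return ContactTable(counts=counts)
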