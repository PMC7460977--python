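"""Reorganization energy: 4-point adiabatic scheme and normal-mode
decomposition with Huang–Rhys factors, plus the Raman I_i/ω_i proxy.

The intramolecular (inner-sphere) reorganization energy for a charge hop
combines the relaxation of the molecule that receives the charge and of
the one that loses it.  The 4-point scheme evaluates both on one molecule:

    λ = (E_N* − E_N) + (E_C* − E_C)

For two equal-curvature harmonic surfaces whose minima are displaced by Δq
along a mode of frequency ω this gives λ = ω²Δq² — twice the single-surface
relaxation ½ω²Δq².  The per-mode contributions reported here use the same
two-surface (equal-curvature) convention, λ_i = ω_i²Δq_i², so that
Σλ_i equals the 4-point λ exactly in the harmonic limit; the Huang–Rhys
factor is S_i = λ_i/(ħω_i) with that λ_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.spatial.transform import Rotation

from .constants import mode_quantum_ev, wavenumber_to_natural
from .errors import AlignmentError, ValidationError
from .qc_backend import FourPointEnergies, NormalModeSet

COMPONENT_TOL = -1e-6      # eV; more negative ⇒ geometry not optimal for its state
ECKART_TOL = 1e-6          # residual trans/rot amplitude after alignment
RAMAN_MATCH_WINDOW = 10.0  # cm⁻¹


@dataclass(frozen=True)
class ReorgEnergies:
    lambda_total: float              # eV
    carrier: str
    component_neutral: float         # E_N* − E_N, eV
    component_charged: float         # E_C* − E_C, eV


@dataclass(frozen=True)
class ModeContribution:
    omega_i: float        # cm⁻¹
    delta_q_i: float      # mass-weighted displacement, √amu·Å
    lambda_i: float       # eV, two-surface convention ω²Δq²
    huang_rhys: float     # S_i = λ_i/(ħω_i)


@dataclass(frozen=True)
class RamanLine:
    omega_i: float        # cm⁻¹
    intensity: float      # arbitrary units, ≥ 0

    @property
    def proxy(self) -> float:
        return self.intensity / self.omega_i


def lambda_four_point(energies: FourPointEnergies, carrier: str = "hole") -> ReorgEnergies:
    """λ = (E_N* − E_N) + (E_C* − E_C), components kept separately."""
    comp_n = energies.E_N_star - energies.E_N
    comp_c = energies.E_C_star - energies.E_C
    for label, comp in (("neutral", comp_n), ("charged", comp_c)):
        if comp < COMPONENT_TOL:
            raise ValidationError(
                f"{label}-surface component {comp:.3e} eV < 0: the supplied geometry "
                "is not the optimum of its own state"
            )
    return ReorgEnergies(
        lambda_total=comp_n + comp_c,
        carrier=carrier,
        component_neutral=comp_n,
        component_charged=comp_c,
    )


# ---------------------------------------------------------------------------
# Normal-mode decomposition
# ---------------------------------------------------------------------------

def _rigid_body_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation+rotation vectors at coords."""
    n = len(masses)
    sq = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    x = coords - com
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sq
        vecs.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        r = np.cross(np.broadcast_to(axis, (n, 3)), x) * sq[:, None]
        vecs.append(r.ravel())
    basis = np.array(vecs)
    # Orthonormalize; rank-deficient rows (linear molecules) are dropped.
    q, rmat = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(rmat)) > 1e-8
    return q[:, keep].T


def eckart_align(
    reference: np.ndarray, geometry: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Remove net translation and rotation of ``geometry`` relative to
    ``reference`` in the mass-weighted (Eckart) frame."""
    masses = np.asarray(masses, dtype=float)
    ref_com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    geo_com = (masses[:, None] * geometry).sum(axis=0) / masses.sum()
    ref = reference - ref_com
    geo = geometry - geo_com
    rot, _ = Rotation.align_vectors(ref, geo, weights=masses)
    return geo @ rot.as_matrix().T + ref_com


def normal_mode_decomposition(
    neutral_geom: np.ndarray,
    charged_geom: np.ndarray,
    modes: NormalModeSet,
    check_eckart: bool = True,
) -> list[ModeContribution]:
    """Project the neutral→charged geometry displacement onto normal modes.

    Geometries are Eckart-aligned first; the mass-weighted displacement is
    projected onto each mode vector giving Δq_i, and λ_i = ω_i²Δq_i² (see
    module docstring for the convention).  Modes are returned ordered by
    frequency.
    """
    neutral = np.asarray(neutral_geom, dtype=float)
    charged = np.asarray(charged_geom, dtype=float)
    if neutral.shape != charged.shape:
        raise ValidationError("neutral and charged geometries differ in shape")
    if modes.displacement_vectors.shape[1] != neutral.size:
        raise ValidationError(
            f"mode vectors of length {modes.displacement_vectors.shape[1]} do not "
            f"match geometry with {neutral.size} Cartesian degrees of freedom"
        )

    aligned = eckart_align(neutral, charged, modes.masses)
    dq = ((aligned - neutral) * np.sqrt(modes.masses)[:, None]).ravel()

    if check_eckart:
        rigid = _rigid_body_basis(neutral, modes.masses)
        residual = np.abs(rigid @ dq)
        scale = max(np.linalg.norm(dq), 1.0)
        if residual.size and residual.max() > ECKART_TOL * scale + ECKART_TOL:
            raise AlignmentError(
                f"Eckart residual {residual.max():.2e} above tolerance; net "
                "rotation/translation not removed"
            )

    contribs = []
    for omega_cm, vec in zip(modes.frequencies, modes.displacement_vectors):
        delta_q = float(vec @ dq)
        omega_nat = wavenumber_to_natural(omega_cm)
        lam = omega_nat**2 * delta_q**2
        contribs.append(
            ModeContribution(
                omega_i=float(omega_cm),
                delta_q_i=delta_q,
                lambda_i=lam,
                huang_rhys=lam / mode_quantum_ev(omega_cm),
            )
        )
    contribs.sort(key=lambda c: c.omega_i)
    return contribs


# ---------------------------------------------------------------------------
# Raman proxy
# ---------------------------------------------------------------------------

@dataclass
class RamanProxyReport:
    """Comparison of per-mode λ_i against the Raman proxy I_i/ω_i.

    A rank correlation, not a causal claim: the proxy tracks which modes
    carry electron–vibrational coupling, with prefactors outside this
    package's scope.
    """

    matched: list[tuple[ModeContribution, RamanLine]]
    unmatched_modes: list[ModeContribution]
    unmatched_lines: list[RamanLine]
    rank_correlation: float
    integrated_proxy: float

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "omega_cm": c.omega_i,
                    "lambda_i_meV": c.lambda_i * 1e3,
                    "proxy_I_over_omega": line.proxy,
                }
                for c, line in self.matched
            ]
        )


def raman_proxy_report(
    contribs: list[ModeContribution],
    raman: list[RamanLine],
    window: float = RAMAN_MATCH_WINDOW,
) -> RamanProxyReport:
    """Match Raman lines to modes by frequency (±window cm⁻¹), rank-correlate
    λ_i with I_i/ω_i, and integrate the proxy over the matched spectrum.
    Unmatched modes/lines are reported, never silently dropped."""
    lines = sorted(raman, key=lambda l: l.omega_i)
    used = set()
    matched = []
    unmatched_modes = []
    for c in contribs:
        best, best_gap = None, window
        for k, line in enumerate(lines):
            gap = abs(line.omega_i - c.omega_i)
            if k not in used and gap <= best_gap:
                best, best_gap = k, gap
        if best is None:
            unmatched_modes.append(c)
        else:
            used.add(best)
            matched.append((c, lines[best]))
    unmatched_lines = [l for k, l in enumerate(lines) if k not in used]

    if len(matched) >= 2:
        lam = [c.lambda_i for c, _ in matched]
        proxy = [l.proxy for _, l in matched]
        rho = scipy.stats.spearmanr(lam, proxy).statistic
    else:
        rho = float("nan")
    return RamanProxyReport(
        matched=matched,
        unmatched_modes=unmatched_modes,
        unmatched_lines=unmatched_lines,
        rank_correlation=float(rho),
        integrated_proxy=float(sum(l.proxy for _, l in matched)),
    )
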