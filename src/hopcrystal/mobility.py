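"""Marcus hop rates, diffusion by summation over transport directions, and
the Einstein–Smoluchowski mobility.

Rate for one hop (semiclassical nonadiabatic limit):

    k = (2π/ħ) · J² · (4πλk_BT)^(−1/2) · exp(−(ΔE − λ)² / (4λk_BT))

with ΔE = E_initial − E_final (0 for identical molecules), so a downhill
hop (ΔE > 0) is accelerated and detailed balance k(ΔE)/k(−ΔE) = exp(ΔE/k_BT)
holds.  The diffusion tensor sums over all hop directions from one central
site (MSD-exact convention):

    D = ½ Σ_i k_i (r_i ⊗ r_i),   D_iso = tr(D)/3

with the literature-common rate-weighted isotropic form
D_iso = (1/6) Σ_i r_i² k_i P_i, P_i = k_i/Σk_j, available as a labeled
option.  Mobility: μ = e·D/(k_BT) = D / (k_BT expressed in volts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_CM, HBAR_EV_S, KB_EV_K
from .errors import DomainError, ValidationError
from .qc_backend import ElectronicStructureResult

DEFAULT_TEMPERATURE = 300.0  # K
CONVENTIONS = ("msd", "rate-weighted")


@dataclass
class HopSpec:
    """One transport direction from the central molecule."""

    J: float                      # eV
    lambda_: float                # eV, > 0
    r_vec: np.ndarray             # Å
    delta_E: float = 0.0          # eV, E_initial − E_final
    T: float = DEFAULT_TEMPERATURE
    multiplicity: int = 1

    def __post_init__(self):
        self.r_vec = np.asarray(self.r_vec, dtype=float).reshape(3)
        if self.lambda_ <= 0:
            raise DomainError(f"reorganization energy must be positive, got {self.lambda_}")
        if self.T <= 0:
            raise DomainError(f"temperature must be positive, got {self.T}")
        if self.multiplicity < 1:
            raise DomainError("multiplicity must be ≥ 1")

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.r_vec))


@dataclass
class MobilityReport:
    per_direction: list[dict]     # r_vec, r, J_meV, k_s, P
    D_tensor: np.ndarray          # cm²/s
    D_iso: float                  # cm²/s
    mu: float                     # cm²·V⁻¹·s⁻¹
    carrier: str
    temperature: float
    convention: str
    warnings: list[str] = field(default_factory=list)


def marcus_rate(spec: HopSpec) -> float:
    """Hop rate in s⁻¹ for one direction (multiplicity not applied)."""
    kbt = KB_EV_K * spec.T
    prefactor = (2.0 * math.pi / HBAR_EV_S) * spec.J**2
    gaussian = (4.0 * math.pi * spec.lambda_ * kbt) ** -0.5
    exponent = -((spec.delta_E - spec.lambda_) ** 2) / (4.0 * spec.lambda_ * kbt)
    return prefactor * gaussian * math.exp(exponent)


def hopping_diffusion(
    hops: list[HopSpec],
    convention: str = "msd",
    carrier: str = "hole",
) -> MobilityReport:
    """Assemble the diffusion tensor from hop rates and convert to mobility.

    All hops must share one temperature (they describe one central site).
    ``multiplicity`` multiplies a hop's contribution; use it only when the
    equivalent directions share r⊗r (e.g. ±r pairs), otherwise list each
    direction explicitly.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    warns = []
    if not hops:
        warns.append("empty hop list: D = 0")
        return MobilityReport(
            per_direction=[], D_tensor=np.zeros((3, 3)), D_iso=0.0, mu=0.0,
            carrier=carrier, temperature=DEFAULT_TEMPERATURE,
            convention=convention, warnings=warns,
        )
    temps = {h.T for h in hops}
    if len(temps) > 1:
        raise ValidationError(f"mixed temperatures in one hop set: {sorted(temps)}")
    temperature = hops[0].T

    rates = np.array([marcus_rate(h) for h in hops])
    mults = np.array([h.multiplicity for h in hops], dtype=float)
    weights = rates * mults
    total = weights.sum()
    probs = weights / total if total > 0 else np.zeros_like(weights)

    r_cm = np.array([h.r_vec for h in hops]) * ANGSTROM_CM
    if convention == "msd":
        d_tensor = 0.5 * np.einsum("i,ij,ik->jk", weights, r_cm, r_cm)
        d_iso = float(np.trace(d_tensor) / 3.0)
    else:
        r2 = np.einsum("ij,ij->i", r_cm, r_cm)
        # P for an individual direction is k/Σ(mk); each of the m equivalent
        # directions contributes r²·k·P.
        p_individual = rates / total if total > 0 else np.zeros_like(rates)
        d_iso = float((r2 * weights * p_individual).sum() / 6.0)
        d_tensor = np.eye(3) * d_iso  # isotropic by construction
    mu = einstein_mobility(d_iso, temperature)

    per_direction = [
        {
            "r_vec": [round(x, 6) for x in h.r_vec],
            "r_angstrom": round(h.r, 6),
            "J_meV": h.J * 1e3,
            "delta_E_meV": h.delta_E * 1e3,
            "multiplicity": h.multiplicity,
            "k_per_s": float(k),
            "P": float(p),
        }
        for h, k, p in zip(hops, rates, probs)
    ]
    return MobilityReport(
        per_direction=per_direction, D_tensor=d_tensor, D_iso=d_iso, mu=mu,
        carrier=carrier, temperature=temperature, convention=convention,
        warnings=warns,
    )


def einstein_mobility(d_iso: float, temperature: float) -> float:
    """μ = D/(k_BT/e): D in cm²/s, k_BT/e in volts → μ in cm²·V⁻¹·s⁻¹."""
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    if d_iso < 0:
        raise DomainError(f"diffusion coefficient must be ≥ 0, got {d_iso}")
    return d_iso / (KB_EV_K * temperature)


def frontier_levels(result: ElectronicStructureResult) -> tuple[float, float, float]:
    """(HOMO, LUMO, gap) in eV; warns on a (near-)zero-gap toy input."""
    homo = float(result.orbital_energies[result.homo_index])
    if result.lumo_index >= len(result.orbital_energies):
        raise ValidationError("all orbitals occupied: LUMO undefined")
    lumo = float(result.orbital_energies[result.lumo_index])
    gap = lumo - homo
    if gap <= 1e-9:
        warnings.warn(f"zero or negative HOMO–LUMO gap ({gap:.3e} eV)", stacklevel=2)
    return homo, lumo, gap


def report_to_dict(report: MobilityReport) -> dict:
    return {
        "carrier": report.carrier,
        "temperature_K": report.temperature,
        "convention": report.convention,
        "D_iso_cm2_per_s": report.D_iso,
        "D_tensor_cm2_per_s": [[float(x) for x in row] for row in report.D_tensor],
        "mu_cm2_per_Vs": report.mu,
        "per_direction": report.per_direction,
        "warnings": report.warnings,
    }
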