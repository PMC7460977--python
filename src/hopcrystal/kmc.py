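"""Kinetic Monte Carlo random walk on a hop network.

Independent brute-force oracle for the analytic diffusion summation:
standard residence-time (Gillespie) algorithm — waiting times exponential
with the total escape rate, directions drawn with probability k_i/Σk —
with the diffusion tensor estimated from mean-squared-displacement growth
over the second half of each trajectory (the first half is discarded as a
guard against transients; hops are Markovian so this is conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_CM
from .errors import DomainError
from .mobility import HopSpec, marcus_rate


@dataclass
class KMCResult:
    D_tensor_est: np.ndarray   # 3×3, cm²/s
    stderr: np.ndarray         # 3×3 per-component standard error
    D_iso_est: float           # cm²/s
    D_iso_stderr: float        # from per-trajectory isotropic estimates
    n_trajectories: int
    n_hops: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "D_tensor_cm2_per_s": self.D_tensor_est.tolist(),
            "stderr_cm2_per_s": self.stderr.tolist(),
            "D_iso_cm2_per_s": self.D_iso_est,
            "D_iso_stderr": self.D_iso_stderr,
            "n_trajectories": self.n_trajectories,
            "n_hops": self.n_hops,
            "seed": self.seed,
        }


def simulate_random_walk(
    hops: list[HopSpec],
    n_traj: int = 200,
    n_hops: int = 2000,
    seed: int = 0,
    trajectory_dump=None,
) -> KMCResult:
    """Estimate the diffusion tensor of a single-site hop network.

    Site-independent rates are assumed (every site sees the same hop
    menu), which is exactly the regime the analytic summation covers.
    Per-trajectory tensor estimates Δr_aΔr_b/(2Δt) over the second half
    are averaged; stderr is the standard error across trajectories.
    """
    if n_traj < 1 or n_hops < 2:
        raise DomainError("need n_traj ≥ 1 and n_hops ≥ 2")
    expanded: list[HopSpec] = []
    for h in hops:
        expanded.extend([h] * h.multiplicity)
    rates = np.array([marcus_rate(h) for h in expanded])
    total = rates.sum()
    if total <= 0:
        raise DomainError("all hop rates are zero; random walk is degenerate")
    probs = rates / total
    steps_cm = np.array([h.r_vec for h in expanded]) * ANGSTROM_CM

    rng = np.random.default_rng(seed)
    choices = rng.choice(len(expanded), size=(n_traj, n_hops), p=probs)
    dts = rng.exponential(scale=1.0 / total, size=(n_traj, n_hops))

    pos = np.cumsum(steps_cm[choices], axis=1)        # (n_traj, n_hops, 3)
    times = np.cumsum(dts, axis=1)                     # (n_traj, n_hops)

    half = n_hops // 2
    r0 = pos[:, half, :]
    t0 = times[:, half]
    disp = pos[:, -1, :] - r0                          # displacement over 2nd half
    dt = times[:, -1] - t0

    # Unbiased per-trajectory estimator: E[Δr_a Δr_b] = 2 D_ab Δt.
    est = disp[:, :, None] * disp[:, None, :] / (2.0 * dt[:, None, None])
    d_tensor = est.mean(axis=0)
    stderr = est.std(axis=0, ddof=1) / np.sqrt(n_traj) if n_traj > 1 else \
        np.full((3, 3), np.inf)
    # Isotropic estimate and its stderr from the per-trajectory traces, so
    # correlations between tensor components are handled exactly.
    iso_samples = np.einsum("taa->t", est) / 3.0
    d_iso = float(iso_samples.mean())
    iso_stderr = float(iso_samples.std(ddof=1) / np.sqrt(n_traj)) if n_traj > 1 \
        else float("inf")

    if trajectory_dump is not None:
        import csv

        with open(trajectory_dump, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trajectory", "time_s", "x_cm", "y_cm", "z_cm"])
            for t_idx in range(min(n_traj, 10)):
                for h_idx in range(n_hops):
                    writer.writerow(
                        [t_idx, times[t_idx, h_idx], *pos[t_idx, h_idx]]
                    )

    return KMCResult(
        D_tensor_est=d_tensor,
        stderr=stderr,
        D_iso_est=d_iso,
        D_iso_stderr=iso_stderr,
        n_trajectories=n_traj,
        n_hops=n_hops,
        seed=seed,
    )
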