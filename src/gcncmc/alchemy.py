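"""Alchemical machinery for nonequilibrium switches.

One tagged molecule's intermolecular interactions are scaled by a pair of
coupling parameters (lambda_LJ, lambda_elec).  Insertions switch the
Lennard-Jones interactions fully on before the electrostatics (so no naked
charges appear at partial steric coupling); deletions run the reverse path.
The Lennard-Jones term uses the Beutler-style 1-1-6 soft core, which is
finite at r = 0 for lambda < 1 and reduces to the plain potential at
lambda = 1; electrostatics scale linearly on the truncated Coulomb term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NCMCProtocol",
    "switching_time",
    "lambda_schedule",
    "softcore_pair_energy",
]


@dataclass
class NCMCProtocol:
    """Definition of one nonequilibrium switching protocol.

    n_pert perturbation steps take the tagged molecule between the fully
    decoupled and fully coupled end states, with n_prop Langevin steps of
    time step dt_fs between (and bracketing) the perturbations, for a total
    switching time tau = (n_pert + 1) * n_prop * dt.  n_prop = 0 encodes
    frozen relaxation, i.e. instantaneous GCMC.
    """

    n_pert: int = 99
    n_prop: int = 50
    dt_fs: float = 2.0
    direction: str = "insert"
    softcore_alpha: float = 0.5
    stage_split: float = 0.5

    def __post_init__(self):
        if self.n_pert < 1:
            raise ValueError("n_pert must be >= 1")
        if self.n_prop < 0:
            raise ValueError("n_prop must be >= 0")
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be positive")
        if self.direction not in ("insert", "delete"):
            raise ValueError("direction must be 'insert' or 'delete'")
        if not 0.0 < self.stage_split <= 1.0:
            raise ValueError("stage_split must be in (0, 1]")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    def reversed(self) -> "NCMCProtocol":
        other = "delete" if self.direction == "insert" else "insert"
        return NCMCProtocol(self.n_pert, self.n_prop, self.dt_fs, other,
                            self.softcore_alpha, self.stage_split)


def switching_time(protocol: NCMCProtocol) -> float:
    """Switching time tau = (n_pert + 1) * n_prop * dt, in ps."""
    return (protocol.n_pert + 1) * protocol.n_prop * protocol.dt_ps


def lambda_schedule(protocol: NCMCProtocol) -> np.ndarray:
    """The (n_pert + 1, 2) array of (lambda_LJ, lambda_elec) waypoints.

    Insertion runs (0,0) -> (1,1) with the LJ stage completed before the
    electrostatic stage begins; the split of perturbation steps between the
    stages is ``stage_split`` (rounded, at least one LJ step).  A deletion
    schedule is exactly the reversed insertion schedule.
    """
    n = protocol.n_pert
    n_lj = min(n, max(1, round(protocol.stage_split * n)))
    n_el = n - n_lj
    lam_lj = np.concatenate([np.linspace(0.0, 1.0, n_lj + 1),
                             np.ones(n_el)])
    if n_el > 0:
        lam_el = np.concatenate([np.zeros(n_lj),
                                 np.linspace(0.0, 1.0, n_el + 1)])
    else:
        lam_el = lam_lj.copy()  # single combined stage; no partial charges
    sched = np.column_stack([lam_lj, lam_el])
    if protocol.direction == "delete":
        sched = sched[::-1].copy()
    return sched


def softcore_pair_energy(
    r: float | np.ndarray,
    lam_lj: float,
    epsilon: float,
    sigma: float,
    alpha: float = 0.5,
) -> float | np.ndarray:
    """Beutler 1-1-6 soft-core Lennard-Jones pair energy.

    U = 4 eps lam [ (alpha(1-lam) + (r/sigma)^6)^-2
                  - (alpha(1-lam) + (r/sigma)^6)^-1 ]

    Finite at r = 0 for lam < 1; plain LJ at lam = 1.
    """
    if not 0.0 <= lam_lj <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    r = np.asarray(r, dtype=float)
    x6 = (r / sigma) ** 6
    A = alpha * (1.0 - lam_lj) + x6
    with np.errstate(divide="ignore"):
        u = 4.0 * epsilon * lam_lj * (A**-2 - A**-1)
    out = np.where(A > 0, u, np.inf)
    return float(out) if out.ndim == 0 else out
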