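"""The GCNCMC Markov chain.

Insertion and deletion moves are selected per a species move pattern, the
tagged molecule is switched on/off through a nonequilibrium alchemical
protocol with Langevin relaxation between perturbations, and the accumulated
protocol work w enters a grand canonical Metropolis test.  For moves confined
to a spherical GCMC region the acceptance probabilities are

    P_insert = min[1, e^B  e^{-beta w} / N_T]
    P_delete = min[1, N_0 e^{-B} e^{-beta w}]

with N_0 the number of region molecules at the start of the move and N_T the
number at the end.  A move whose switched molecule ends outside the sphere is
rejected automatically (the reverse move could not be proposed, so detailed
balance would break).  Rejected moves restore the pre-move state; the chain
then continues with freshly resampled Maxwell-Boltzmann velocities, which is
valid under Langevin dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alchemy import NCMCProtocol, lambda_schedule
from .toy_systems import (
    SystemState,
    ToySystem,
    maxwell_boltzmann_velocities,
    molecule_interaction_energy,
    propagate,
)

__all__ = [
    "GCMCRegion",
    "MoveRecord",
    "ChainSchedule",
    "ChainResult",
    "GCNCMCSampler",
    "acceptance_insert",
    "acceptance_delete",
    "instantaneous_protocol",
]


@dataclass
class GCMCRegion:
    """Region open to insertion/deletion moves: a sphere or the whole box."""

    mode: str = "whole_box"
    center: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self):
        if self.mode not in ("sphere", "whole_box"):
            raise ValueError("mode must be 'sphere' or 'whole_box'")
        if self.mode == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere region needs a positive radius")
            if self.center is None:
                raise ValueError("sphere region needs a center")
            self.center = np.asarray(self.center, dtype=float)

    def volume(self, box) -> float:
        if self.mode == "sphere":
            return 4.0 / 3.0 * math.pi * self.radius**3
        return box.volume

    def contains(self, points: np.ndarray, box) -> np.ndarray:
        """Membership of points (minimum-image distance in sphere mode)."""
        pts = np.atleast_2d(points)
        if self.mode == "whole_box":
            return np.ones(pts.shape[0], dtype=bool)
        d = box.min_image(pts - self.center)
        return np.sum(d * d, axis=1) <= self.radius**2

    def random_point(self, box, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "whole_box":
            return rng.uniform(size=3) * box.edge_lengths
        while True:  # rejection sampling: uniform in the sphere
            p = rng.uniform(-1.0, 1.0, size=3)
            if p @ p <= 1.0:
                return self.center + self.radius * p


@dataclass
class MoveRecord:
    """Per-move bookkeeping sufficient to replay the accept/reject decision."""

    move_type: str
    species: str
    work: float = 0.0
    n0: int = 0
    nt: int = 0
    b_used: float = 0.0
    acceptance_probability: float = 0.0
    accepted: bool = False
    auto_rejected_out_of_sphere: bool = False
    skipped: bool = False
    rng_uniform: float = float("nan")
    rng_state_tag: str = ""


@dataclass
class ChainSchedule:
    """Cycle structure of a GCNCMC/MD run."""

    n_cycles: int
    md_steps_per_cycle: int = 10
    species_move_pattern: list[str] = field(default_factory=list)
    n_equil_cycles: int = 0
    consecutive_reject_limit: int | None = None

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.n_cycles > 0 and not 0 <= self.n_equil_cycles < max(self.n_cycles, 1):
            raise ValueError("n_equil_cycles must be < n_cycles")


@dataclass
class Frame:
    positions: np.ndarray
    mol_species: list[str]
    ghost_flags: list[bool]
    cycle: int


@dataclass
class ChainResult:
    frames: list[Frame]
    records: list[MoveRecord]
    occupancy: dict[str, np.ndarray]  # per-cycle N in region per species
    n_cycles_run: int
    n_equil_cycles: int
    terminated_early: bool = False

    def mean_occupancy(self, species: str) -> float:
        series = self.occupancy[species][self.n_equil_cycles:]
        return float(np.mean(series)) if series.size else float("nan")


def acceptance_insert(w: float, b: float, nt: int, beta: float) -> float:
    """min[1, e^B e^{-beta w} / N_T]; N_T counts the switched molecule."""
    if nt < 1:
        raise ValueError("N_T must be >= 1 (the switched molecule counts)")
    log_p = b - beta * w - math.log(nt)
    return 1.0 if log_p >= 0 else math.exp(log_p)


def acceptance_delete(w: float, b: float, n0: int, beta: float) -> float:
    """min[1, N_0 e^{-B} e^{-beta w}]."""
    if n0 < 1:
        raise ValueError("N_0 must be >= 1 for a deletion")
    log_p = math.log(n0) - b - beta * w
    return 1.0 if log_p >= 0 else math.exp(log_p)


def instantaneous_protocol(alpha: float = 0.5) -> NCMCProtocol:
    """Single-perturbation, zero-relaxation protocol: instantaneous GCMC.

    The work reduces to the bare energy change of the single switch, so a
    GCNCMC chain with this protocol is definitionally equal to classic
    instantaneous GCMC on the same random stream.
    """
    return NCMCProtocol(n_pert=1, n_prop=0, softcore_alpha=alpha)


class GCNCMCSampler:
    """Drives the GCNCMC chain for one toy system.

    Parameters
    ----------
    system, state : the toy model and its initial configuration.
    region : GCMCRegion open to moves.
    b_values : per-species Adams value.
    protocols : per-species NCMCProtocol.
    rng : seeded generator; all move randomness and the thermostat stream
        derive from it.
    md_dt, md_friction : Langevin parameters for both relaxation and the
        MD segments between moves (ps, 1/ps).
    ghost_capacity : hard cap on the ghost pool (grown lazily; exceeding
        it raises, mirroring fixed-pool ghost bookkeeping).
    """

    def __init__(
        self,
        system: ToySystem,
        state: SystemState,
        region: GCMCRegion,
        b_values: dict[str, float],
        protocols: dict[str, NCMCProtocol],
        rng: np.random.Generator,
        md_dt: float = 0.002,
        md_friction: float = 1.0,
        ghost_capacity: int = 10_000,
    ):
        self.system = system
        self.state = state
        self.region = region
        self.b_values = dict(b_values)
        self.protocols = dict(protocols)
        self.rng = rng
        self.md_dt = md_dt
        self.md_friction = md_friction
        self.ghost_capacity = ghost_capacity
        self._move_counter = 0

    # -- region bookkeeping (always recomputed from geometry) -------------

    def molecules_in_region(self, species: str) -> list[int]:
        mols = self.state.real_molecules(species)
        if not mols:
            return []
        centers = np.array([self.state.molecule_center(i) for i in mols])
        inside = self.region.contains(centers, self.system.box)
        return [m for m, ok in zip(mols, inside) if ok]

    def _get_ghost(self, species: str) -> int:
        for i in range(self.state.n_molecules):
            if self.state.ghost_flags[i] and self.state.mol_species[i] == species:
                return i
        if self.state.n_molecules >= self.ghost_capacity:
            raise RuntimeError("ghost pool capacity exhausted")
        park = np.zeros(3)
        return self.state.add_molecule(species, park, ghost=True, rng=self.rng)

    # -- moves -------------------------------------------------------------

    def attempt_move(
        self, species: str, move_type: str | None = None,
        frozen_dynamics: bool = False,
    ) -> MoveRecord:
        """One GCNCMC insertion or deletion attempt (random type by default)."""
        if move_type is None:
            move_type = "insert" if self.rng.random() < 0.5 else "delete"
        self._move_counter += 1
        tag = f"move-{self._move_counter}"
        b = self.b_values[species]
        protocol = self.protocols[species]

        if move_type == "delete" and not self.molecules_in_region(species):
            return MoveRecord("delete", species, n0=0, nt=0, b_used=b,
                              skipped=True, accepted=False, rng_state_tag=tag)

        saved = self.state.copy()
        beta = self.system.beta
        n_prop = 0 if frozen_dynamics else protocol.n_prop

        n0 = len(self.molecules_in_region(species))
        if move_type == "insert":
            imol = self._get_ghost(species)
            point = self.region.random_point(self.system.box, self.rng)
            self.state.move_molecule_to(imol, point, rng=self.rng)
            maxwell_boltzmann_velocities(self.state, self.rng, [imol])
            sched = lambda_schedule(
                NCMCProtocol(protocol.n_pert, protocol.n_prop, protocol.dt_fs,
                             "insert", protocol.softcore_alpha,
                             protocol.stage_split))
        else:
            candidates = self.molecules_in_region(species)
            imol = candidates[self.rng.integers(len(candidates))]
            sched = lambda_schedule(
                NCMCProtocol(protocol.n_pert, protocol.n_prop, protocol.dt_fs,
                             "delete", protocol.softcore_alpha,
                             protocol.stage_split))

        work = 0.0
        scaling = {imol: tuple(sched[0])}
        if n_prop:
            self.state = propagate(self.state, n_prop, self.md_dt,
                                   self.md_friction, self.rng, scaling)
        for k in range(1, sched.shape[0]):
            u_old = molecule_interaction_energy(self.state, imol, sched[k - 1])
            u_new = molecule_interaction_energy(self.state, imol, sched[k])
            work += u_new - u_old
            scaling = {imol: tuple(sched[k])}
            if n_prop:
                self.state = propagate(self.state, n_prop, self.md_dt,
                                       self.md_friction, self.rng, scaling)

        if move_type == "insert":
            self.state.ghost_flags[imol] = False
        else:
            self.state.ghost_flags[imol] = True

        nt = len(self.molecules_in_region(species))
        record = MoveRecord(move_type, species, work=work, n0=n0, nt=nt,
                            b_used=b, rng_state_tag=tag)
        self._finalize(saved, record, imol, beta)
        return record

    def _finalize(self, saved: SystemState, record: MoveRecord,
                  imol: int, beta: float) -> None:
        center = self.state.molecule_center(imol)
        in_region = bool(self.region.contains(center[None, :],
                                              self.system.box)[0])
        if not math.isfinite(record.work):
            record.auto_rejected_out_of_sphere = False
            record.acceptance_probability = 0.0
        elif not in_region:
            record.auto_rejected_out_of_sphere = True
            record.acceptance_probability = 0.0
        elif record.move_type == "insert":
            record.acceptance_probability = acceptance_insert(
                record.work, record.b_used, max(record.nt, 1), beta)
        else:
            record.acceptance_probability = acceptance_delete(
                record.work, record.b_used, max(record.n0, 1), beta)

        record.rng_uniform = float(self.rng.random())
        record.accepted = record.rng_uniform < record.acceptance_probability
        if not record.accepted:
            self.state = saved
            mols = self.state.real_molecules()
            if mols:
                maxwell_boltzmann_velocities(self.state, self.rng, mols)

    # -- chains ------------------------------------------------------------

    def run_chain(
        self,
        schedule: ChainSchedule,
        store_frames: bool = True,
        frozen_dynamics: bool = False,
    ) -> ChainResult:
        """Alternate MD segments and GCNCMC moves for n_cycles cycles.

        Emits the per-cycle region occupancy for every species in the move
        pattern, and optionally a trajectory frame per cycle.  The
        consecutive-reject limit (a convergence heuristic) counts
        post-equilibration move attempts, with skipped deletions counting
        as rejections.
        """
        species_list = list(dict.fromkeys(schedule.species_move_pattern))
        occ: dict[str, list[int]] = {sp: [] for sp in species_list}
        frames: list[Frame] = []
        records: list[MoveRecord] = []
        consecutive = 0
        terminated = False
        cycles_run = 0
        for cycle in range(schedule.n_cycles):
            if schedule.md_steps_per_cycle and not frozen_dynamics:
                self.state = propagate(self.state, schedule.md_steps_per_cycle,
                                       self.md_dt, self.md_friction, self.rng)
            for sp in schedule.species_move_pattern:
                rec = self.attempt_move(sp, frozen_dynamics=frozen_dynamics)
                records.append(rec)
                if cycle >= schedule.n_equil_cycles:
                    consecutive = 0 if rec.accepted else consecutive + 1
                    if (schedule.consecutive_reject_limit is not None
                            and consecutive >= schedule.consecutive_reject_limit):
                        terminated = True
                        break
            for sp in species_list:
                occ[sp].append(len(self.molecules_in_region(sp)))
            if store_frames:
                frames.append(Frame(self.state.positions.copy(),
                                    list(self.state.mol_species),
                                    list(self.state.ghost_flags), cycle))
            cycles_run = cycle + 1
            if terminated:
                break
        return ChainResult(
            frames=frames,
            records=records,
            occupancy={sp: np.array(v) for sp, v in occ.items()},
            n_cycles_run=cycles_run,
            n_equil_cycles=schedule.n_equil_cycles,
            terminated_early=terminated,
        )
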