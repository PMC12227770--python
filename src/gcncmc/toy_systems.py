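"""Self-contained toy particle systems and their dynamics.

The systems here (ideal gas, soft-core Lennard-Jones fluid, single- and
double-well "hosts") are deliberately minimal: rigid (by default single-site)
molecules in a periodic box interacting through truncated Lennard-Jones and
optionally truncated Coulomb terms, plus external binding wells.  They stand
in for solvated protein/host systems so that grand canonical moves can be
validated against closed-form and enumerable grand-canonical oracles.

Energies are kcal/mol, lengths Angstrom, times ps, masses amu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ACCEL_UNIT, COULOMB_K, R_KCAL, kT, beta as beta_fn

__all__ = [
    "SimulationBox",
    "SpeciesSpec",
    "BindingWell",
    "MutualExclusion",
    "ToySystem",
    "SystemState",
    "potential_energy",
    "forces",
    "insertion_energy",
    "molecule_interaction_energy",
    "propagate",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
    "widom_mu_ex",
]


@dataclass
class SimulationBox:
    """Orthorhombic periodic box.

    Parameters
    ----------
    edge_lengths : (3,) array-like
        Box edges in Angstrom; all must be positive.
    periodic : (3,) bool
        Periodicity per axis (toys are fully periodic by default).
    """

    edge_lengths: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float)
        if self.edge_lengths.shape != (3,) or np.any(self.edge_lengths <= 0):
            raise ValueError("edge_lengths must be 3 positive values")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary image [0, L)."""
        pos = np.array(positions, dtype=float)
        for ax in range(3):
            if self.periodic[ax]:
                pos[..., ax] %= self.edge_lengths[ax]
        return pos

    def min_image(self, dvec: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors."""
        d = np.array(dvec, dtype=float)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.edge_lengths[ax]
                d[..., ax] -= L * np.round(d[..., ax] / L)
        return d


@dataclass
class SpeciesSpec:
    """A rigid (by default single-site) molecular species."""

    name: str
    lj_epsilon: float = 0.0
    lj_sigma: float = 3.0
    charge: float = 0.0
    mass: float = 40.0
    site_local_coords: np.ndarray = field(
        default_factory=lambda: np.zeros((1, 3))
    )

    def __post_init__(self):
        self.site_local_coords = np.atleast_2d(
            np.asarray(self.site_local_coords, dtype=float)
        )
        if self.site_local_coords.shape[0] < 1:
            raise ValueError("species needs at least one site")
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.site_local_coords.shape[0]


@dataclass
class BindingWell:
    """External attractive well standing in for an occluded binding pocket.

    ``gaussian`` wells, U(r) = -depth * exp(-r^2 / 2 width^2), have smooth
    forces and are the default for chains that interleave Langevin dynamics.
    ``square`` wells (U = -depth for r <= width, else 0) exert no force and
    are reserved for enumeration fixtures sampled by pure Monte Carlo.
    """

    center: np.ndarray
    depth: float
    width: float
    form: str = "gaussian"
    species: str | None = None  # None: acts on every species

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.depth < 0:
            raise ValueError("well depth must be >= 0")
        if self.width <= 0:
            raise ValueError("well width must be > 0")
        if self.form not in ("gaussian", "square"):
            raise ValueError(f"unknown well form {self.form!r}")

    def energy(self, r2: np.ndarray) -> np.ndarray:
        if self.form == "gaussian":
            return -self.depth * np.exp(-r2 / (2.0 * self.width**2))
        return np.where(r2 <= self.width**2, -self.depth, 0.0)

    def force(self, dvec: np.ndarray, r2: np.ndarray) -> np.ndarray:
        """Force on a site at center + dvec (square wells exert none)."""
        if self.form == "gaussian":
            g = np.exp(-r2 / (2.0 * self.width**2))
            return -(self.depth / self.width**2) * g[..., None] * dvec
        return np.zeros_like(dvec)


@dataclass
class MutualExclusion:
    """Hard pair repulsion enforcing single occupancy for a species.

    A flat penalty between every pair of real molecules of ``species``;
    if ``radius`` is set the penalty applies only when both molecules lie
    within ``radius`` of ``center`` (the well-radius variant), otherwise it
    is global so the species' grand partition function is exactly two-state.
    """

    species: str
    penalty: float = 1.0e4
    center: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self):
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)


@dataclass
class ToySystem:
    """Description of a toy model: box, species, wells, global parameters."""

    box: SimulationBox
    species: dict[str, SpeciesSpec]
    wells: list[BindingWell] = field(default_factory=list)
    temperature: float = 298.0
    cutoff: float = 12.0
    softcore_alpha: float = 0.5
    exclusion: MutualExclusion | None = None

    @property
    def kT(self) -> float:
        return kT(self.temperature)

    @property
    def beta(self) -> float:
        return beta_fn(self.temperature)


class SystemState:
    """Mutable configuration: positions/velocities plus molecule bookkeeping.

    Molecules are contiguous site ranges; ``ghost_flags[i]`` marks molecule i
    as fully decoupled (zero intermolecular energy, frozen in dynamics).
    Toy species are single-site by default, for which all energy routines take
    a fully vectorized path.
    """

    def __init__(self, system: ToySystem):
        self.system = system
        self.positions = np.zeros((0, 3))
        self.velocities = np.zeros((0, 3))
        self.mol_species: list[str] = []
        self.mol_start: list[int] = []
        self.ghost_flags: list[bool] = []

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    def sites_of(self, imol: int) -> slice:
        start = self.mol_start[imol]
        n = self.system.species[self.mol_species[imol]].n_sites
        return slice(start, start + n)

    def add_molecule(
        self,
        species_name: str,
        position: np.ndarray,
        ghost: bool = False,
        rng: np.random.Generator | None = None,
        orientation: np.ndarray | None = None,
    ) -> int:
        """Append a molecule with its center of geometry at ``position``."""
        spec = self.system.species[species_name]
        local = spec.site_local_coords - spec.site_local_coords.mean(axis=0)
        if spec.n_sites > 1:
            if orientation is None:
                orientation = _random_rotation(rng or np.random.default_rng())
            local = local @ orientation.T
        sites = np.asarray(position, dtype=float)[None, :] + local
        imol = self.n_molecules
        self.mol_start.append(self.positions.shape[0])
        self.mol_species.append(species_name)
        self.ghost_flags.append(bool(ghost))
        self.positions = np.vstack([self.positions, sites])
        self.velocities = np.vstack([self.velocities, np.zeros_like(sites)])
        return imol

    def molecule_center(self, imol: int) -> np.ndarray:
        """Membership point: center of geometry of the molecule's sites."""
        return self.positions[self.sites_of(imol)].mean(axis=0)

    def molecule_centers(self) -> np.ndarray:
        if self._all_single_site():
            return self.positions
        return np.array([self.molecule_center(i) for i in range(self.n_molecules)])

    def move_molecule_to(
        self,
        imol: int,
        position: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> None:
        spec = self.system.species[self.mol_species[imol]]
        local = spec.site_local_coords - spec.site_local_coords.mean(axis=0)
        if spec.n_sites > 1 and rng is not None:
            local = local @ _random_rotation(rng).T
        self.positions[self.sites_of(imol)] = (
            np.asarray(position, dtype=float)[None, :] + local
        )

    def real_molecules(self, species: str | None = None) -> list[int]:
        return [
            i
            for i in range(self.n_molecules)
            if not self.ghost_flags[i]
            and (species is None or self.mol_species[i] == species)
        ]

    def copy(self) -> "SystemState":
        new = SystemState(self.system)
        new.positions = self.positions.copy()
        new.velocities = self.velocities.copy()
        new.mol_species = list(self.mol_species)
        new.mol_start = list(self.mol_start)
        new.ghost_flags = list(self.ghost_flags)
        return new

    def site_masses(self) -> np.ndarray:
        m = np.empty(self.positions.shape[0])
        for i in range(self.n_molecules):
            spec = self.system.species[self.mol_species[i]]
            m[self.sites_of(i)] = spec.mass / spec.n_sites
        return m

    def _all_single_site(self) -> bool:
        return self.positions.shape[0] == self.n_molecules

    def _per_molecule_params(self):
        eps = np.array(
            [self.system.species[s].lj_epsilon for s in self.mol_species]
        )
        sig = np.array([self.system.species[s].lj_sigma for s in self.mol_species])
        q = np.array([self.system.species[s].charge for s in self.mol_species])
        return eps, sig, q


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Energies and forces
# ---------------------------------------------------------------------------


def _lambda_arrays(state: SystemState, scaling) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule (lambda_LJ, lambda_elec); ghosts 0, real 1, overrides win."""
    n = state.n_molecules
    lam_lj = np.array(
        [0.0 if g else 1.0 for g in state.ghost_flags], dtype=float
    )
    lam_el = lam_lj.copy()
    if scaling:
        for imol, lam in scaling.items():
            if np.ndim(lam):
                lam_lj[imol], lam_el[imol] = float(lam[0]), float(lam[1])
            else:
                lam_lj[imol] = lam_el[imol] = float(lam)
    return lam_lj, lam_el


def _softcore_lj(r2, lam, eps, sig, alpha):
    x6 = (r2 / sig**2) ** 3
    A = alpha * (1.0 - lam) + x6
    with np.errstate(divide="ignore"):
        u = 4.0 * eps * lam * (A**-2 - A**-1)
    return np.where(A > 0, u, np.inf)


def _softcore_lj_force_over_r(r2, lam, eps, sig, alpha):
    """-(dU/dr)/r so that F_vec = result * dvec."""
    x6 = (r2 / sig**2) ** 3
    A = alpha * (1.0 - lam) + x6
    with np.errstate(divide="ignore", invalid="ignore"):
        dU_dA = 4.0 * eps * lam * (-2.0 * A**-3 + A**-2)
        out = -dU_dA * 6.0 * x6 / r2
    return np.where(r2 > 0, out, 0.0)


def _exclusion_mask(state: SystemState, centers: np.ndarray) -> np.ndarray:
    """Boolean (n,n) mask of molecule pairs subject to the exclusion penalty."""
    exc = state.system.exclusion
    n = state.n_molecules
    if exc is None:
        return np.zeros((n, n), dtype=bool)
    is_sp = np.array([s == exc.species for s in state.mol_species])
    mask = is_sp[:, None] & is_sp[None, :]
    if exc.radius is not None:
        d = state.system.box.min_image(centers - exc.center)
        inside = np.sum(d * d, axis=1) <= exc.radius**2
        mask &= inside[:, None] & inside[None, :]
    return mask


def _well_energy(state: SystemState, lam_lj: np.ndarray) -> float:
    sys_ = state.system
    if not sys_.wells:
        return 0.0
    total = 0.0
    if state._all_single_site():
        sp = np.array(state.mol_species)
        for well in sys_.wells:
            sel = lam_lj > 0
            if well.species is not None:
                sel &= sp == well.species
            if not np.any(sel):
                continue
            d = sys_.box.min_image(state.positions[sel] - well.center)
            r2 = np.sum(d * d, axis=1)
            total += float(np.sum(lam_lj[sel] * well.energy(r2)))
        return total
    for i in range(state.n_molecules):
        if lam_lj[i] == 0:
            continue
        pos_i = state.positions[state.sites_of(i)]
        for well in sys_.wells:
            if well.species is not None and well.species != state.mol_species[i]:
                continue
            d = sys_.box.min_image(pos_i - well.center)
            r2 = np.sum(d * d, axis=1)
            total += lam_lj[i] * float(np.sum(well.energy(r2)))
    return total


def potential_energy(state: SystemState, scaling: dict | None = None) -> float:
    """Total potential energy under a per-molecule lambda map.

    Pairwise soft-core LJ plus cutoff-truncated Coulomb under the
    minimum-image convention, external well terms, and the optional
    single-occupancy exclusion penalty.  Ghosts and lambda=0 molecules
    contribute nothing; the pair coupling is the product of the two
    molecules' lambdas (only one molecule is fractional at a time, so at
    full coupling this reduces to plain truncated LJ/Coulomb).
    """
    sys_ = state.system
    lam_lj, lam_el = _lambda_arrays(state, scaling)
    energy = _well_energy(state, lam_lj)
    n = state.n_molecules
    if n < 2:
        return energy
    if not state._all_single_site():
        return energy + _pair_energy_generic(state, lam_lj, lam_el)

    pos = state.positions
    eps, sig, q = state._per_molecule_params()
    d = sys_.box.min_image(pos[:, None, :] - pos[None, :, :])
    r2 = np.sum(d * d, axis=2)
    iu = np.triu_indices(n, k=1)
    r2u = r2[iu]
    within = r2u <= sys_.cutoff**2
    llj = (lam_lj[:, None] * lam_lj[None, :])[iu]
    lel = (lam_el[:, None] * lam_el[None, :])[iu]

    eps_ij = np.sqrt(eps[:, None] * eps[None, :])[iu]
    sig_ij = (0.5 * (sig[:, None] + sig[None, :]))[iu]
    act = within & (llj > 0) & (eps_ij > 0)
    if np.any(act):
        u = _softcore_lj(r2u[act], llj[act], eps_ij[act], sig_ij[act],
                         sys_.softcore_alpha)
        energy += float(np.sum(u))

    qq = (q[:, None] * q[None, :])[iu]
    actc = within & (lel > 0) & (qq != 0)
    if np.any(actc):
        with np.errstate(divide="ignore"):
            uc = COULOMB_K * qq[actc] / np.sqrt(r2u[actc])
        uc = np.where(r2u[actc] > 0, uc, 1.0e6)
        energy += float(np.sum(lel[actc] * uc))

    exc = sys_.exclusion
    if exc is not None:
        mask = _exclusion_mask(state, pos)[iu]
        energy += exc.penalty * float(np.sum(llj[mask]))
    return energy


def _pair_energy_generic(state, lam_lj, lam_el) -> float:
    """Site-resolved double loop for multi-site molecules (small systems)."""
    sys_ = state.system
    rc2 = sys_.cutoff**2
    energy = 0.0
    centers = state.molecule_centers()
    excl = _exclusion_mask(state, centers)
    for i in range(state.n_molecules):
        if lam_lj[i] == 0 and lam_el[i] == 0:
            continue
        spec_i = sys_.species[state.mol_species[i]]
        pos_i = state.positions[state.sites_of(i)]
        for j in range(i + 1, state.n_molecules):
            if lam_lj[j] == 0 and lam_el[j] == 0:
                continue
            spec_j = sys_.species[state.mol_species[j]]
            pos_j = state.positions[state.sites_of(j)]
            d = sys_.box.min_image(pos_i[:, None, :] - pos_j[None, :, :])
            r2 = np.sum(d * d, axis=2)
            within = r2 <= rc2
            llj = lam_lj[i] * lam_lj[j]
            lel = lam_el[i] * lam_el[j]
            if llj > 0 and spec_i.lj_epsilon > 0 and spec_j.lj_epsilon > 0:
                e = np.sqrt(spec_i.lj_epsilon * spec_j.lj_epsilon)
                s = 0.5 * (spec_i.lj_sigma + spec_j.lj_sigma)
                u = _softcore_lj(r2, llj, e, s, sys_.softcore_alpha)
                energy += float(np.sum(u[within]))
            if lel > 0 and spec_i.charge != 0 and spec_j.charge != 0:
                with np.errstate(divide="ignore"):
                    uc = COULOMB_K * spec_i.charge * spec_j.charge / np.sqrt(r2)
                uc = np.where(r2 > 0, uc, 1.0e6)
                energy += lel * float(np.sum(uc[within]))
            if excl[i, j]:
                energy += llj * sys_.exclusion.penalty
    return energy


def insertion_energy(
    state: SystemState, species_name: str, position: np.ndarray,
) -> float:
    """Energy change of inserting one fully coupled molecule at ``position``.

    O(N) shortcut used by Widom insertion; equivalent to the difference of
    two :func:`potential_energy` calls.
    """
    sys_ = state.system
    spec = sys_.species[species_name]
    pos = np.asarray(position, dtype=float)
    du = 0.0
    for well in sys_.wells:
        if well.species is not None and well.species != species_name:
            continue
        d = sys_.box.min_image(pos - well.center)
        du += float(well.energy(np.sum(d * d)))
    real = state.real_molecules()
    if real:
        centers = state.positions if state._all_single_site() else None
        if centers is None:
            raise NotImplementedError("insertion_energy needs single-site states")
        idx = np.array(real)
        d = sys_.box.min_image(centers[idx] - pos)
        r2 = np.sum(d * d, axis=1)
        within = r2 <= sys_.cutoff**2
        eps, sig, q = state._per_molecule_params()
        eps_ij = np.sqrt(eps[idx] * spec.lj_epsilon)
        sig_ij = 0.5 * (sig[idx] + spec.lj_sigma)
        sel = within & (eps_ij > 0)
        if np.any(sel):
            du += float(np.sum(_softcore_lj(r2[sel], 1.0, eps_ij[sel],
                                            sig_ij[sel], sys_.softcore_alpha)))
        qq = q[idx] * spec.charge
        selc = within & (qq != 0)
        if np.any(selc):
            with np.errstate(divide="ignore"):
                uc = COULOMB_K * qq[selc] / np.sqrt(r2[selc])
            du += float(np.sum(np.where(r2[selc] > 0, uc, 1.0e6)))
        exc = sys_.exclusion
        if exc is not None and species_name == exc.species:
            partners = np.array(
                [state.mol_species[i] == exc.species for i in real]
            )
            if exc.radius is not None:
                dc = sys_.box.min_image(pos - exc.center)
                if float(dc @ dc) <= exc.radius**2:
                    dp = sys_.box.min_image(centers[idx] - exc.center)
                    partners &= np.sum(dp * dp, axis=1) <= exc.radius**2
                else:
                    partners[:] = False
            du += exc.penalty * float(np.sum(partners))
    return du


def molecule_interaction_energy(
    state: SystemState, imol: int, lam: tuple[float, float]
) -> float:
    """Interaction energy of molecule ``imol`` at coupling (lam_LJ, lam_el).

    All other molecules are at their resting coupling (real = 1, ghost = 0).
    The protocol work of a switch only needs this term: everything not
    involving the tagged molecule cancels in the perturbation differences.
    Single-site fast path; falls back to full energy differences otherwise.
    """
    lam_lj, lam_el = float(lam[0]), float(lam[1])
    if lam_lj == 0.0 and lam_el == 0.0:
        return 0.0
    sys_ = state.system
    if not state._all_single_site():
        base = {imol: (0.0, 0.0)}
        return potential_energy(state, {imol: (lam_lj, lam_el)}) - \
            potential_energy(state, base)

    sp_name = state.mol_species[imol]
    spec = sys_.species[sp_name]
    pos = state.positions[imol]
    du = 0.0
    for well in sys_.wells:
        if well.species is not None and well.species != sp_name:
            continue
        d = sys_.box.min_image(pos - well.center)
        du += lam_lj * float(well.energy(np.sum(d * d)))
    others = [i for i in state.real_molecules() if i != imol]
    if not others:
        return du
    idx = np.array(others)
    d = sys_.box.min_image(state.positions[idx] - pos)
    r2 = np.sum(d * d, axis=1)
    within = r2 <= sys_.cutoff**2
    eps, sig, q = state._per_molecule_params()
    eps_ij = np.sqrt(eps[idx] * spec.lj_epsilon)
    sig_ij = 0.5 * (sig[idx] + spec.lj_sigma)
    sel = within & (eps_ij > 0)
    if lam_lj > 0 and np.any(sel):
        du += float(np.sum(_softcore_lj(r2[sel], lam_lj, eps_ij[sel],
                                        sig_ij[sel], sys_.softcore_alpha)))
    qq = q[idx] * spec.charge
    selc = within & (qq != 0)
    if lam_el > 0 and np.any(selc):
        with np.errstate(divide="ignore"):
            uc = COULOMB_K * qq[selc] / np.sqrt(r2[selc])
        du += lam_el * float(np.sum(np.where(r2[selc] > 0, uc, 1.0e6)))
    exc = sys_.exclusion
    if exc is not None and sp_name == exc.species and lam_lj > 0:
        partners = np.array(
            [state.mol_species[i] == exc.species for i in others]
        )
        if exc.radius is not None:
            dc = sys_.box.min_image(pos - exc.center)
            if float(dc @ dc) <= exc.radius**2:
                dp = sys_.box.min_image(state.positions[idx] - exc.center)
                partners &= np.sum(dp * dp, axis=1) <= exc.radius**2
            else:
                partners[:] = False
        du += lam_lj * exc.penalty * float(np.sum(partners))
    return du


def forces(state: SystemState, scaling: dict | None = None) -> np.ndarray:
    """Forces (kcal/mol/A) per site, consistent with :func:`potential_energy`.

    Square wells and the exclusion penalty are flat away from their
    discontinuity and contribute no force.
    """
    sys_ = state.system
    lam_lj, lam_el = _lambda_arrays(state, scaling)
    F = np.zeros_like(state.positions)
    single = state._all_single_site()

    # wells
    if sys_.wells:
        if single:
            sp = np.array(state.mol_species)
            for well in sys_.wells:
                sel = lam_lj > 0
                if well.species is not None:
                    sel &= sp == well.species
                if np.any(sel):
                    d = sys_.box.min_image(state.positions[sel] - well.center)
                    r2 = np.sum(d * d, axis=1)
                    F[sel] += lam_lj[sel, None] * well.force(d, r2)
        else:
            for i in range(state.n_molecules):
                if lam_lj[i] == 0:
                    continue
                sl = state.sites_of(i)
                for well in sys_.wells:
                    if (well.species is not None
                            and well.species != state.mol_species[i]):
                        continue
                    d = sys_.box.min_image(state.positions[sl] - well.center)
                    r2 = np.sum(d * d, axis=1)
                    F[sl] += lam_lj[i] * well.force(d, r2)

    n = state.n_molecules
    if n >= 2 and single:
        pos = state.positions
        eps, sig, q = state._per_molecule_params()
        d = sys_.box.min_image(pos[:, None, :] - pos[None, :, :])
        r2 = np.sum(d * d, axis=2)
        np.fill_diagonal(r2, np.inf)
        within = r2 <= sys_.cutoff**2
        llj = lam_lj[:, None] * lam_lj[None, :]
        lel = lam_el[:, None] * lam_el[None, :]
        f_over_r = np.zeros_like(r2)
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        act = within & (llj > 0) & (eps_ij > 0)
        if np.any(act):
            f_over_r[act] = _softcore_lj_force_over_r(
                r2[act], llj[act], eps_ij[act], sig_ij[act], sys_.softcore_alpha
            )
        qq = q[:, None] * q[None, :]
        actc = within & (lel > 0) & (qq != 0)
        if np.any(actc):
            with np.errstate(divide="ignore"):
                f_over_r[actc] += lel[actc] * COULOMB_K * qq[actc] / (
                    r2[actc] * np.sqrt(r2[actc])
                )
        F += np.sum(f_over_r[..., None] * d, axis=1)
    elif n >= 2:
        F += _pair_forces_generic(state, lam_lj, lam_el)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite force encountered")
    return F


def _pair_forces_generic(state, lam_lj, lam_el) -> np.ndarray:
    sys_ = state.system
    rc2 = sys_.cutoff**2
    F = np.zeros_like(state.positions)
    for i in range(state.n_molecules):
        if lam_lj[i] == 0 and lam_el[i] == 0:
            continue
        spec_i = sys_.species[state.mol_species[i]]
        sl_i = state.sites_of(i)
        pos_i = state.positions[sl_i]
        for j in range(i + 1, state.n_molecules):
            if lam_lj[j] == 0 and lam_el[j] == 0:
                continue
            spec_j = sys_.species[state.mol_species[j]]
            sl_j = state.sites_of(j)
            pos_j = state.positions[sl_j]
            d = sys_.box.min_image(pos_i[:, None, :] - pos_j[None, :, :])
            r2 = np.sum(d * d, axis=2)
            within = r2 <= rc2
            f_over_r = np.zeros_like(r2)
            llj = lam_lj[i] * lam_lj[j]
            lel = lam_el[i] * lam_el[j]
            if llj > 0 and spec_i.lj_epsilon > 0 and spec_j.lj_epsilon > 0:
                e = np.sqrt(spec_i.lj_epsilon * spec_j.lj_epsilon)
                s = 0.5 * (spec_i.lj_sigma + spec_j.lj_sigma)
                f_over_r += _softcore_lj_force_over_r(
                    r2, llj, e, s, sys_.softcore_alpha
                )
            if lel > 0 and spec_i.charge != 0 and spec_j.charge != 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fc = lel * COULOMB_K * spec_i.charge * spec_j.charge / (
                        r2 * np.sqrt(r2)
                    )
                f_over_r += np.where(r2 > 0, fc, 0.0)
            f_over_r = np.where(within, f_over_r, 0.0)
            fij = f_over_r[..., None] * d
            F[sl_i] += np.sum(fij, axis=1)
            F[sl_j] -= np.sum(fij, axis=0)
    return F


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def maxwell_boltzmann_velocities(
    state: SystemState,
    rng: np.random.Generator,
    molecules: list[int] | None = None,
) -> None:
    """Draw site velocities from the Maxwell-Boltzmann distribution in place."""
    kT_ = state.system.kT
    masses = state.site_masses()
    if molecules is None:
        idx = np.arange(state.positions.shape[0])
    elif molecules:
        idx = np.concatenate(
            [np.arange(state.positions.shape[0])[state.sites_of(m)]
             for m in molecules]
        )
    else:
        return
    sigma = np.sqrt(ACCEL_UNIT * kT_ / masses[idx])
    state.velocities[idx] = rng.normal(size=(idx.size, 3)) * sigma[:, None]


def propagate(
    state: SystemState,
    n_steps: int,
    dt: float = 0.002,
    friction: float = 1.0,
    rng: np.random.Generator | None = None,
    scaling: dict | None = None,
) -> SystemState:
    """Langevin dynamics with the BAOAB splitting.

    dt in ps (default 2 fs), friction in 1/ps.  Ghost molecules are frozen:
    they feel no forces and are not moved.  Returns a new state; raises
    FloatingPointError with the offending state attached on non-finite
    forces.
    """
    if n_steps == 0:
        return state.copy()
    if rng is None:
        rng = np.random.default_rng()
    sys_ = state.system
    new = state.copy()
    lam_lj, lam_el = _lambda_arrays(new, scaling)
    mobile = [i for i in range(new.n_molecules)
              if lam_lj[i] > 0 or lam_el[i] > 0]
    if not mobile:
        return new
    idx = np.concatenate(
        [np.arange(new.positions.shape[0])[new.sites_of(m)] for m in mobile]
    )
    masses = new.site_masses()[idx][:, None]
    kT_ = sys_.kT
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * ACCEL_UNIT * kT_ / masses)

    try:
        F = forces(new, scaling)[idx]
        for _ in range(n_steps):
            v = new.velocities[idx]
            v = v + 0.5 * dt * ACCEL_UNIT * F / masses
            x = new.positions[idx] + 0.5 * dt * v
            v = c1 * v + c2 * rng.normal(size=v.shape)
            x = x + 0.5 * dt * v
            new.positions[idx] = x
            F = forces(new, scaling)[idx]
            new.velocities[idx] = v + 0.5 * dt * ACCEL_UNIT * F / masses
    except FloatingPointError as err:
        err.state = new  # diagnostic dump for the caller
        raise
    new.positions = sys_.box.wrap(new.positions)
    return new


def kinetic_temperature(state: SystemState, molecules: list[int]) -> float:
    """Instantaneous kinetic temperature (K) of the given molecules' sites."""
    idx = np.concatenate(
        [np.arange(state.positions.shape[0])[state.sites_of(m)]
         for m in molecules]
    )
    m = state.site_masses()[idx]
    v2 = np.sum(state.velocities[idx] ** 2, axis=1)
    return float(np.mean(m * v2) / (3.0 * ACCEL_UNIT * R_KCAL))


# ---------------------------------------------------------------------------
# Widom test-particle insertion
# ---------------------------------------------------------------------------


def widom_mu_ex(
    frames,
    species: str,
    n_trials: int,
    rng: np.random.Generator,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """Excess chemical potential by Widom insertion over equilibrated frames.

    mu' = -kT ln <exp(-beta dU)> with trial positions uniform in the box.
    The standard error comes from block averages over frames.  Returns
    (mu', se); (inf, inf) with a warning if every trial overlaps.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("widom_mu_ex needs at least one frame")
    sys_ = frames[0].system
    b = sys_.beta
    per_frame = max(1, n_trials // len(frames))
    cap = 700.0 / b  # overflow guard for very favourable insertions only
    frame_means = np.empty(len(frames))
    for k, frame in enumerate(frames):
        pts = rng.uniform(size=(per_frame, 3)) * sys_.box.edge_lengths
        w = np.empty(per_frame)
        for t, p in enumerate(pts):
            du = insertion_energy(frame, species, p)
            w[t] = np.exp(-b * max(du, -cap))
        frame_means[k] = w.mean()
    overall = float(frame_means.mean())
    if overall == 0.0:
        warnings.warn("all Widom trials overlapped; mu_ex is +inf")
        return np.inf, np.inf
    kT_ = sys_.kT
    mu = -kT_ * np.log(overall)
    nb = min(n_blocks, len(frames))
    if nb > 1:
        blocks = np.array_split(frame_means, nb)
        bm = np.array([blk.mean() for blk in blocks])
        se = kT_ * float(np.std(bm, ddof=1) / np.sqrt(nb)) / overall
    else:
        se = float("nan")
    return float(mu), se
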