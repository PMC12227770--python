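"""Energies against a brute-force oracle, Langevin sampling, and Widom."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from conftest import block_se
from gcncmc.constants import ACCEL_UNIT, COULOMB_K, R_KCAL
from gcncmc.toy_systems import (
    BindingWell,
    MutualExclusion,
    SimulationBox,
    SpeciesSpec,
    SystemState,
    ToySystem,
    insertion_energy,
    kinetic_temperature,
    maxwell_boltzmann_velocities,
    molecule_interaction_energy,
    potential_energy,
    propagate,
    widom_mu_ex,
)


def _make_system(epsilon=0.5, sigma=3.0, charge=0.0, box=20.0, wells=(),
                 exclusion=None, cutoff=12.0):
    sp = SpeciesSpec("a", lj_epsilon=epsilon, lj_sigma=sigma, charge=charge)
    return ToySystem(SimulationBox(np.full(3, box)), {"a": sp},
                     wells=list(wells), cutoff=cutoff, exclusion=exclusion)


def _state_with(system, points, ghosts=None):
    st = SystemState(system)
    for k, p in enumerate(points):
        st.add_molecule("a", np.asarray(p, float),
                        ghost=bool(ghosts[k]) if ghosts else False)
    return st


def brute_force_energy(state):
    """Independent O(N^2) double loop: plain truncated LJ + Coulomb + wells."""
    sys_ = state.system
    e = 0.0
    mols = state.real_molecules()
    for ai, i in enumerate(mols):
        spec_i = sys_.species[state.mol_species[i]]
        pi = state.positions[i]
        for w in sys_.wells:
            if w.species in (None, state.mol_species[i]):
                d = sys_.box.min_image(pi - w.center)
                r2 = float(d @ d)
                if w.form == "gaussian":
                    e += -w.depth * math.exp(-r2 / (2 * w.width**2))
                else:
                    e += -w.depth if r2 <= w.width**2 else 0.0
        for j in mols[ai + 1:]:
            spec_j = sys_.species[state.mol_species[j]]
            d = sys_.box.min_image(pi - state.positions[j])
            r = math.sqrt(float(d @ d))
            if r > sys_.cutoff:
                continue
            if spec_i.lj_epsilon > 0 and spec_j.lj_epsilon > 0:
                eps = math.sqrt(spec_i.lj_epsilon * spec_j.lj_epsilon)
                sig = 0.5 * (spec_i.lj_sigma + spec_j.lj_sigma)
                e += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
            if spec_i.charge and spec_j.charge:
                e += COULOMB_K * spec_i.charge * spec_j.charge / r
    return e


class TestPotentialEnergy:
    def test_ideal_gas_pair_is_zero(self):
        sys_ = _make_system(epsilon=0.0)
        st = _state_with(sys_, [[1, 1, 1], [3, 3, 3]])
        assert potential_energy(st) == 0.0

    def test_lj_zero_crossing_at_sigma(self):
        sys_ = _make_system(epsilon=0.5, sigma=3.0)
        st = _state_with(sys_, [[5, 5, 5], [8, 5, 5]])
        assert potential_energy(st) == pytest.approx(0.0, abs=1e-12)

    def test_particle_at_gaussian_well_center(self):
        well = BindingWell(np.array([5.0, 5.0, 5.0]), depth=2.0, width=1.0)
        sys_ = _make_system(epsilon=0.0, wells=[well])
        st = _state_with(sys_, [[5, 5, 5]])
        assert potential_energy(st) == pytest.approx(-2.0)

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized energy equals the double-loop oracle on 50 particles."""
        well = BindingWell(np.array([10.0, 10.0, 10.0]), 1.5, 2.0)
        sys_ = _make_system(epsilon=0.4, sigma=3.0, box=22.0, wells=[well])
        # keep particles from overlapping so the reference LJ is well scaled
        pts = rng.uniform(0, 22, size=(50, 3))
        st = _state_with(sys_, pts)
        e_fast = potential_energy(st)
        e_ref = brute_force_energy(st)
        assert e_fast == pytest.approx(e_ref, rel=1e-10, abs=1e-8)

    def test_translation_and_image_invariance(self, rng):
        sys_ = _make_system(epsilon=0.4, box=20.0)
        pts = rng.uniform(0, 20, size=(12, 3))
        st = _state_with(sys_, pts)
        e0 = potential_energy(st)
        shift = np.array([3.7, -11.2, 40.0])  # includes whole-box images
        st2 = _state_with(sys_, sys_.box.wrap(pts + shift))
        assert potential_energy(st2) == pytest.approx(e0, rel=1e-9)

    def test_ghosts_contribute_nothing(self, rng):
        sys_ = _make_system(epsilon=0.4)
        pts = rng.uniform(0, 20, size=(8, 3))
        st = _state_with(sys_, pts)
        e0 = potential_energy(st)
        st.add_molecule("a", pts[0] + 0.1, ghost=True)  # overlapping ghost
        assert potential_energy(st) == pytest.approx(e0)

    def test_overlap_is_finite_under_softcore(self):
        sys_ = _make_system(epsilon=1.0)
        st = _state_with(sys_, [[5, 5, 5], [5, 5, 5]])
        # partially coupled overlap is capped by the soft core
        e = potential_energy(st, {1: (0.5, 0.5)})
        assert np.isfinite(e)

    def test_exclusion_penalty(self):
        exc = MutualExclusion("a", penalty=1e4)
        sys_ = _make_system(epsilon=0.0, exclusion=exc)
        st = _state_with(sys_, [[2, 2, 2], [15, 15, 15]])
        assert potential_energy(st) == pytest.approx(1e4)

    def test_tagged_interaction_energy_matches_difference(self, rng):
        """The O(N) tagged-molecule energy equals the full-energy difference."""
        well = BindingWell(np.array([10.0, 10, 10]), 1.0, 2.0)
        sys_ = _make_system(epsilon=0.4, wells=[well])
        st = _state_with(sys_, rng.uniform(0, 20, size=(10, 3)))
        for lam in [(0.3, 0.0), (1.0, 0.5), (1.0, 1.0)]:
            direct = molecule_interaction_energy(st, 4, lam)
            diff = potential_energy(st, {4: lam}) - potential_energy(
                st, {4: (0.0, 0.0)})
            assert direct == pytest.approx(diff, rel=1e-9, abs=1e-9)

    def test_insertion_energy_matches_difference(self, rng):
        sys_ = _make_system(epsilon=0.4)
        st = _state_with(sys_, rng.uniform(0, 20, size=(10, 3)))
        p = rng.uniform(0, 20, size=3)
        e0 = potential_energy(st)
        du_fast = insertion_energy(st, "a", p)
        st.add_molecule("a", p)
        assert du_fast == pytest.approx(potential_energy(st) - e0, rel=1e-9)


class TestPropagate:
    def test_zero_steps_identity(self, rng):
        sys_ = _make_system()
        st = _state_with(sys_, [[1, 1, 1], [4, 4, 4]])
        out = propagate(st, 0, rng=rng)
        assert np.array_equal(out.positions, st.positions)

    def test_ghosts_frozen(self, rng):
        sys_ = _make_system(epsilon=0.0)
        st = _state_with(sys_, [[1, 1, 1], [4, 4, 4]], ghosts=[False, True])
        maxwell_boltzmann_velocities(st, rng)
        out = propagate(st, 50, rng=rng)
        assert np.array_equal(out.positions[1], st.positions[1])
        assert not np.array_equal(out.positions[0], st.positions[0])

    def test_ideal_gas_equipartition(self, rng):
        """Kinetic temperature equilibrates to the thermostat setpoint."""
        sys_ = _make_system(epsilon=0.0)
        st = _state_with(sys_, rng.uniform(0, 20, size=(30, 3)))
        maxwell_boltzmann_velocities(st, rng)
        # high friction so samples decorrelate well within the run
        temps = []
        for _ in range(150):
            st = propagate(st, 10, friction=100.0, rng=rng)
            temps.append(kinetic_temperature(st, list(range(30))))
        mean_t = np.mean(temps)
        se = block_se(temps, 15) + 1e-9
        assert abs(mean_t - 298.0) < 3 * se

    def test_maxwell_boltzmann_speed_distribution(self, rng):
        """Langevin dynamics preserves the MB speed distribution (KS test)."""
        sys_ = _make_system(epsilon=0.0)
        st = _state_with(sys_, rng.uniform(0, 20, size=(40, 3)))
        maxwell_boltzmann_velocities(st, rng)
        speeds = []
        for _ in range(300):
            st = propagate(st, 10, friction=100.0, rng=rng)
            speeds.extend(np.linalg.norm(st.velocities, axis=1))
        scale = math.sqrt(ACCEL_UNIT * R_KCAL * 298.0 / 40.0)
        res = stats.kstest(speeds, stats.maxwell(scale=scale).cdf)
        assert len(speeds) >= 10_000
        assert res.pvalue > 0.01

    def test_gaussian_well_position_variance(self, rng):
        """Sampled in-well variance matches the Gibbs-measure quadrature."""
        depth_kt = 12.0
        kT = R_KCAL * 298.0
        s = 0.8
        well = BindingWell(np.array([5.0, 5.0, 5.0]), depth_kt * kT, s)
        sys_ = _make_system(epsilon=0.0, box=10.0, wells=[well])
        st = _state_with(sys_, [[5, 5, 5]])
        maxwell_boltzmann_velocities(st, rng)
        r0 = 3.0  # condition on staying within the well basin
        w = lambda r: r * r * math.exp(
            depth_kt * math.exp(-r * r / (2 * s * s)))
        num = quad(lambda r: r * r * w(r), 0, r0, limit=200)[0]
        den = quad(w, 0, r0, limit=200)[0]
        exact_r2 = num / den
        samples = []
        st = propagate(st, 200, dt=0.001, rng=rng)  # settle into the well
        for _ in range(2500):
            st = propagate(st, 6, dt=0.001, friction=30.0, rng=rng)
            d = sys_.box.min_image(st.positions[0] - well.center)
            r2 = float(d @ d)
            if r2 <= r0 * r0:
                samples.append(r2)
        mean_r2 = np.mean(samples)
        se = block_se(samples, 25)
        assert abs(mean_r2 - exact_r2) < max(3 * se, 0.05 * exact_r2)


class TestWidom:
    def _frames(self, sys_, n_mol, n_frames, rng, equil=300):
        st = _state_with(sys_, rng.uniform(0, sys_.box.edge_lengths[0],
                                           size=(n_mol, 3)))
        maxwell_boltzmann_velocities(st, rng)
        st = propagate(st, equil, rng=rng)
        frames = []
        for _ in range(n_frames):
            st = propagate(st, 5, rng=rng)
            frames.append(st)
        return frames

    def test_ideal_gas_mu_zero(self, rng):
        sys_ = _make_system(epsilon=0.0)
        frames = self._frames(sys_, 10, 20, rng, equil=10)
        mu, se = widom_mu_ex(frames, "a", 500, rng)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_repulsive_system_positive_mu(self, rng):
        # truncating LJ at r = sigma keeps only its repulsive branch
        sp = SpeciesSpec("a", lj_epsilon=1.0, lj_sigma=4.0)
        sys_ = ToySystem(SimulationBox(np.full(3, 14.0)), {"a": sp},
                         cutoff=4.0)
        frames = self._frames(sys_, 20, 10, rng, equil=200)
        mu, _ = widom_mu_ex(frames, "a", 400, rng)
        assert mu > 0.0

    def test_dilute_lj_second_virial(self, rng):
        """mu' ~ 2 B2 rho kT at low density (truncated-LJ virial oracle)."""
        eps, sig, cutoff, box, n = 0.5, 3.0, 12.0, 30.0, 6
        sys_ = _make_system(epsilon=eps, sigma=sig, box=box, cutoff=cutoff)
        beta = 1.0 / (R_KCAL * 298.0)

        def mayer(r):
            u = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
            return (math.exp(-beta * u) - 1.0) * r * r

        b2 = -2 * math.pi * quad(mayer, 1e-3, cutoff, limit=400)[0]
        rho = n / box**3
        pred = 2 * b2 * rho / beta
        frames = self._frames(sys_, n, 150, rng)
        mu, se = widom_mu_ex(frames, "a", 60_000, rng)
        assert mu == pytest.approx(pred, abs=max(3 * se, 0.25 * abs(pred)))

    def test_all_overlap_warns_inf(self, rng):
        exc = MutualExclusion("a", penalty=1e9)
        sys_ = ToySystem(SimulationBox(np.ones(3)), {"a": SpeciesSpec("a")},
                         exclusion=exc)
        st = _state_with(sys_, [[0.5, 0.5, 0.5]])
        with pytest.warns(UserWarning):
            mu, _ = widom_mu_ex([st], "a", 10, rng)
        assert mu == math.inf
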