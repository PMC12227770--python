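"""Deterministic toy fixtures with machine-readable ground truth.

Each factory builds a toy system whose grand-canonical behaviour is known in
closed form or by low-dimensional quadrature, standing in for the force-field
systems (occluded pockets, host cavities, bulk solution boxes) that the
method targets in production.  The attached ``truth`` dictionary is consumed
directly by the test suite and the acceptance checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .adams import AdamsSpec, dg_from_kd, kd_from_b50
from .constants import beta as beta_fn
from .engine import GCMCRegion
from .titration import TABLE_COLUMNS
from .toy_systems import (
    BindingWell,
    MutualExclusion,
    SimulationBox,
    SpeciesSpec,
    SystemState,
    ToySystem,
)

__all__ = [
    "make_ideal_gas",
    "make_lj_fluid",
    "make_single_well",
    "make_double_well",
    "make_synthetic_occupancy",
    "well_partition_ratio",
]


def _seed_state(system: ToySystem, species: str, n: int,
                rng: np.random.Generator) -> SystemState:
    state = SystemState(system)
    for _ in range(n):
        p = rng.uniform(size=3) * system.box.edge_lengths
        state.add_molecule(species, p, ghost=False, rng=rng)
    return state


def make_ideal_gas(box_edge: float = 20.0, b: float = 0.0, seed: int = 0,
                   temperature: float = 298.0):
    """Zero-interaction gas: region count is exactly Poisson(e^B).

    Returns (system, state, region, truth).  The truth (mean = variance =
    e^B over the whole-box region) is a property of the ensemble and does
    not depend on the seed, which only sets the initial configuration.
    """
    species = SpeciesSpec("gas", lj_epsilon=0.0, lj_sigma=3.0)
    system = ToySystem(
        box=SimulationBox(np.full(3, box_edge)),
        species={"gas": species},
        temperature=temperature,
    )
    rng = np.random.default_rng(seed)
    n0 = max(0, round(math.exp(b))) if np.isfinite(b) else 0
    state = _seed_state(system, "gas", n0, rng)
    region = GCMCRegion("whole_box")
    truth = {"mean": math.exp(b), "variance": math.exp(b),
             "distribution": "poisson"}
    return system, state, region, truth


def make_lj_fluid(box_edge: float = 30.0, n_molecules: int = 30,
                  epsilon: float = 0.5, sigma: float = 3.0,
                  temperature: float = 298.0, cutoff: float = 12.0,
                  seed: int = 0):
    """Dilute soft-core LJ fluid for Widom / closed-loop concentration tests.

    Returns (system, state, region, truth) where truth carries the imposed
    concentration c* (mol/L) implied by n_molecules in the box.
    """
    from .constants import A3_TO_L, N_AVOGADRO

    species = SpeciesSpec("lj", lj_epsilon=epsilon, lj_sigma=sigma)
    system = ToySystem(
        box=SimulationBox(np.full(3, box_edge)),
        species={"lj": species},
        temperature=temperature,
        cutoff=cutoff,
    )
    rng = np.random.default_rng(seed)
    state = _seed_state(system, "lj", n_molecules, rng)
    region = GCMCRegion("whole_box")
    c_star = n_molecules / (N_AVOGADRO * system.box.volume * A3_TO_L)
    truth = {"concentration_M": c_star, "n_molecules": n_molecules}
    return system, state, region, truth


def well_partition_ratio(well: BindingWell, volume: float, beta: float) -> float:
    """Mean Boltzmann factor q = <e^{-beta U}> over a region of given volume.

    For a square well this is closed-form; for a gaussian well the compact
    radial integral is evaluated by quadrature (the well must be far from
    the region boundary for the tail to be negligible).
    """
    if well.form == "square":
        v_w = 4.0 / 3.0 * math.pi * well.width**3
        return 1.0 + (v_w / volume) * (math.e ** (beta * well.depth) - 1.0)
    integrand = lambda r: 4.0 * math.pi * r * r * (
        math.exp(beta * well.depth * math.exp(-r * r / (2 * well.width**2)))
        - 1.0
    )
    upper = max(10.0 * well.width, 1.0)
    val, _ = quad(integrand, 0.0, upper, limit=200)
    return 1.0 + val / volume


def make_single_well(depth: float = 3.0, width: float = 2.0,
                     box_edge: float = 16.0, temperature: float = 298.0,
                     form: str = "gaussian", exclusion_penalty: float = 1.0e4):
    """One attractive well with single-occupancy exclusion: exact Langmuir.

    The ligand species has no pair interactions other than the hard mutual
    exclusion, so the grand partition function over the whole box is exactly
    two-state, Xi = 1 + e^B q with q = <e^{-beta U}>, and the occupancy is
    the logistic 1/(1 + e^{-(B - B50)}) with slope exactly 1 and
    B50 = -ln q.  With mu' = 0 the analytic dissociation constant follows
    from the Adams machinery; deeper wells give smaller K_D.

    The default well is deliberately broad and shallow (a fragment-scale
    binder, K_D ~ 0.2 M): entry and exit then occur every few tens of
    cycles, so occupancy chains of a few hundred cycles are well mixed.

    Returns (system, state, region, truth) with truth keys b50, kd (mol/L),
    dg (kcal/mol), q.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    center = np.full(3, box_edge / 2.0)
    well = BindingWell(center, depth, width, form=form, species="ligand")
    species = SpeciesSpec("ligand", lj_epsilon=0.0, lj_sigma=3.0)
    system = ToySystem(
        box=SimulationBox(np.full(3, box_edge)),
        species={"ligand": species},
        wells=[well],
        temperature=temperature,
        exclusion=MutualExclusion("ligand", penalty=exclusion_penalty),
    )
    state = SystemState(system)
    region = GCMCRegion("whole_box")
    beta = beta_fn(temperature)
    q = well_partition_ratio(well, system.box.volume, beta)
    b50 = -math.log(q)
    spec = AdamsSpec(mu_ex=0.0, temperature=temperature,
                     v_gcmc=system.box.volume)
    kd = kd_from_b50(spec, b50)
    truth = {"b50": b50, "k": 1.0, "kd": kd,
             "dg": dg_from_kd(kd, temperature), "q": q}
    return system, state, region, truth


def make_double_well(delta_f_kt: float = 0.79, base_depth_kt: float = 3.0,
                     well_radius: float = 1.5, separation: float = 6.0,
                     box_edge: float = 12.0, sphere_radius: float = 5.0,
                     temperature: float = 298.0):
    """Two square wells whose bound-state populations differ by delta_f_kt.

    Equal-volume square wells at +/- separation/2 along y from the box
    center, with the favoured well deeper by delta_f_kt * kT, give an exact
    Boltzmann ratio e^{delta_f} between the two binding modes -- the toy
    analogue of a ligand with two competing poses.  Moves are confined to a
    GCMC sphere enclosing both wells; the sphere keeps the well volume
    fraction high enough that the chain switches modes frequently.  Square
    wells exert no force, so chains on this fixture use pure
    (instantaneous) Monte Carlo.

    Returns (system, state, region, truth, geometry); geometry carries the
    dihedral anchor points and bin edges that map well membership onto a
    signed dihedral angle for the binding-mode analyses.
    """
    kT = 1.0 / beta_fn(temperature)
    c = np.full(3, box_edge / 2.0)
    center_a = c + np.array([0.0, +separation / 2.0, 0.0])
    center_b = c + np.array([0.0, -separation / 2.0, 0.0])
    if separation / 2.0 + well_radius > sphere_radius:
        raise ValueError("wells must lie inside the GCMC sphere")
    depth_b = base_depth_kt * kT
    depth_a = depth_b + delta_f_kt * kT
    wells = [
        BindingWell(center_a, depth_a, well_radius, form="square",
                    species="ligand"),
        BindingWell(center_b, depth_b, well_radius, form="square",
                    species="ligand"),
    ]
    species = SpeciesSpec("ligand", lj_epsilon=0.0, lj_sigma=3.0)
    system = ToySystem(
        box=SimulationBox(np.full(3, box_edge)),
        species={"ligand": species},
        wells=wells,
        temperature=temperature,
        exclusion=MutualExclusion("ligand", penalty=1.0e4),
    )
    state = SystemState(system)
    region = GCMCRegion("sphere", center=c, radius=sphere_radius)
    p_major = 1.0 / (1.0 + math.exp(-delta_f_kt))
    # well A sits at +y: the anchor geometry below maps it to a negative
    # dihedral, well B to a positive one (see tests for the derivation)
    d = separation / 2.0
    geometry = {
        "anchors": [c + np.array([-2 * d, 0.0, 1.0]),
                    c + np.array([-d, 0.0, 0.0]),
                    c + np.array([+d, 0.0, 0.0])],
        "bin_edges": [-math.pi, 0.0, math.pi],
        "mode_of_bin": {0: "A", 1: "B"},
        "well_centers": {"A": center_a, "B": center_b},
        "well_radius": well_radius,
    }
    beta = beta_fn(temperature)
    v_w = 4.0 / 3.0 * math.pi * well_radius**3
    v_region = region.volume(system.box)
    q = 1.0 + (v_w / v_region) * (
        (math.exp(beta * depth_a) - 1.0) + (math.exp(beta * depth_b) - 1.0)
    )
    truth = {"delta_f_kt": delta_f_kt, "p_major": p_major,
             "ratio": math.exp(delta_f_kt), "q": q, "b50": -math.log(q)}
    return system, state, region, truth, geometry


def make_synthetic_occupancy(b50: float, k: float, b_values, n_cycles: int,
                             repeats: int, seed: int = 0,
                             noise: str = "binomial") -> pd.DataFrame:
    """Synthetic occupancy table from a known logistic, with optional noise.

    ``binomial`` noise emulates averaging a 0/1 occupancy over n_cycles
    uncorrelated cycles; ``none`` returns the exact logistic values.
    """
    if k <= 0:
        raise ValueError("logistic slope k must be positive")
    if noise not in ("binomial", "none"):
        raise ValueError("noise must be 'binomial' or 'none'")
    rng = np.random.default_rng(seed)
    rows = []
    for b in b_values:
        p = 1.0 / (1.0 + math.exp(max(min(k * (b50 - b), 500), -500)))
        for rep in range(repeats):
            if noise == "binomial":
                occ = rng.binomial(n_cycles, p) / n_cycles
            else:
                occ = p
            rows.append((b, rep, occ, n_cycles))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
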