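"""Occupancy-vs-B titrations and logistic fits yielding K_D and dG0.

A titration runs independent chains at a ladder of Adams values; the mean
post-equilibration occupancy of the GCMC region at each B traces a logistic

    N(B) = 1 / (1 + exp[k (B_50 - B)]),

whose midpoint B_50 maps to the dissociation constant K_D through the
Adams-value machinery.  Each repeat is fitted separately; K_D values derived
from the per-repeat B_50 are averaged, and their standard error carries
through to the reported binding free energy.  The same data re-expressed on
the log10-concentration scale fit an equivalent logistic whose midpoint is
log10 K_D directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import kendalltau

from . import adams as _adams
from .adams import AdamsSpec
from .engine import ChainSchedule, GCMCRegion, GCNCMCSampler

__all__ = [
    "OccupancyTable",
    "TitrationFit",
    "run_titration",
    "fit_b_scale",
    "fit_logc_scale",
    "aggregate",
]

#: columns of an occupancy table
TABLE_COLUMNS = ["b", "repeat", "occupancy", "n_cycles"]


def OccupancyTable(rows) -> pd.DataFrame:
    """Normalise rows/records into the canonical occupancy table."""
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if (df["occupancy"] < 0).any():
        raise ValueError("occupancies must be >= 0")
    return df


@dataclass
class TitrationFit:
    """Aggregated titration result."""

    b50: float
    b50_err: float
    k: float
    kd: float
    kd_err: float
    dg: float
    dg_err: float
    kendall_tau: float
    per_repeat_b50: list[float] = field(default_factory=list)
    per_repeat_k: list[float] = field(default_factory=list)
    n_repeats_used: int = 0
    flagged: bool = False


def _logistic(b, b50, k):
    return 1.0 / (1.0 + np.exp(np.clip(k * (b50 - b), -500, 500)))


def run_titration(
    make_sampler,
    b_values,
    repeats: int,
    schedule: ChainSchedule,
    base_seed: int,
    species: str | None = None,
    frozen_dynamics: bool = False,
) -> pd.DataFrame:
    """Run one chain per (B, repeat) and tabulate mean occupancies.

    ``make_sampler(b, rng)`` must return a fresh :class:`GCNCMCSampler`
    whose move pattern species is ``species`` (defaults to the first entry
    of the schedule's pattern).  Seeds are distinct per (B, repeat).  A chain
    that fails is flagged (occupancy NaN) and excluded from fits downstream.
    """
    b_values = list(b_values)
    if not b_values:
        raise ValueError("b_values must be non-empty")
    if species is None:
        species = schedule.species_move_pattern[0]
    rows = []
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(b_values) * repeats)
    k = 0
    for b in b_values:
        for rep in range(repeats):
            rng = np.random.default_rng(children[k])
            k += 1
            try:
                sampler = make_sampler(b, rng)
                result = sampler.run_chain(schedule, store_frames=False,
                                           frozen_dynamics=frozen_dynamics)
                occ = result.mean_occupancy(species)
            except Exception:
                occ = float("nan")
            rows.append((b, rep, occ, schedule.n_cycles))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _fit_one(b: np.ndarray, occ: np.ndarray) -> tuple[float, float]:
    """Logistic fit of one repeat; raises on degenerate data."""
    if len(np.unique(b)) < 4:
        raise ValueError("need >= 4 distinct B values")
    span = b.max() - b.min()
    if occ.max() < 0.05 or occ.min() > 0.95:
        raise ValueError("degenerate occupancy data (all empty or saturated)")
    # seed B50 where the curve first crosses 0.5 (linear interpolation)
    order = np.argsort(b)
    bs, os_ = b[order], occ[order]
    b50_0 = bs[len(bs) // 2]
    for i in range(len(bs) - 1):
        if (os_[i] - 0.5) * (os_[i + 1] - 0.5) <= 0 and os_[i] != os_[i + 1]:
            f = (0.5 - os_[i]) / (os_[i + 1] - os_[i])
            b50_0 = bs[i] + f * (bs[i + 1] - bs[i])
            break
    popt, _ = curve_fit(
        _logistic, b, occ, p0=[b50_0, 1.0],
        bounds=([bs.min() - span, 1e-6], [bs.max() + span, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def fit_b_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Per-repeat logistic fits on the Adams-value scale.

    Returns a frame with columns (repeat, b50, k); repeats whose data are
    degenerate or whose fit fails are excluded.
    """
    out = []
    for rep, grp in table.dropna(subset=["occupancy"]).groupby("repeat"):
        try:
            b50, k = _fit_one(grp["b"].to_numpy(float),
                              grp["occupancy"].to_numpy(float))
            out.append((rep, b50, k))
        except (ValueError, RuntimeError):
            continue
    return pd.DataFrame(out, columns=["repeat", "b50", "k"])


def fit_logc_scale(table: pd.DataFrame, spec: AdamsSpec) -> pd.DataFrame:
    """Per-repeat logistic fits on the log10-concentration scale.

    B maps to log10 c through the Adams relation, a linear reparameterization
    (B = ln(10) log10 c + const at fixed mu' and V_GCMC), so the fitted K_D
    agrees exactly with kd_from_b50 of the B-scale fit on the same data.
    """
    out = []
    for rep, grp in table.dropna(subset=["occupancy"]).groupby("repeat"):
        b = grp["b"].to_numpy(float)
        logc = np.array([
            np.log10(_adams.concentration_from_b(spec, bi)) for bi in b
        ])
        try:
            logkd, k = _fit_one(logc, grp["occupancy"].to_numpy(float))
            out.append((rep, 10.0**logkd, k))
        except (ValueError, RuntimeError):
            continue
    return pd.DataFrame(out, columns=["repeat", "kd", "k"])


def aggregate(fits: pd.DataFrame, spec: AdamsSpec,
              table: pd.DataFrame | None = None) -> TitrationFit:
    """Combine per-repeat B-scale fits into the final titration estimate.

    K_D is derived from each repeat's B_50 and averaged; the standard error
    of the mean K_D propagates into dG0 = kT ln(K_D/c0).  Kendall's tau is
    computed from all occupancy rows across repeats (occupancy-vs-B
    concordance, a data-quality indicator).
    """
    if len(fits) == 0:
        raise ValueError("no successful repeats to aggregate")
    kds = np.array([_adams.kd_from_b50(spec, b) for b in fits["b50"]])
    flagged = len(fits) < 2
    kd_mean = float(np.mean(kds))
    kd_err = (float(np.std(kds, ddof=1) / np.sqrt(len(kds)))
              if len(kds) > 1 else float("nan"))
    dg = _adams.dg_from_kd(kd_mean, spec.temperature, spec.c_std)
    dg_err = (spec.kT * kd_err / kd_mean) if kd_mean > 0 else float("nan")
    b50_mean = float(np.mean(fits["b50"]))
    b50_err = (float(np.std(fits["b50"], ddof=1) / np.sqrt(len(fits)))
               if len(fits) > 1 else float("nan"))
    tau = float("nan")
    if table is not None:
        sub = table.dropna(subset=["occupancy"])
        if len(sub) > 1:
            tau = float(kendalltau(sub["b"], sub["occupancy"]).statistic)
    return TitrationFit(
        b50=b50_mean, b50_err=b50_err, k=float(np.mean(fits["k"])),
        kd=kd_mean, kd_err=kd_err, dg=dg, dg_err=dg_err, kendall_tau=tau,
        per_repeat_b50=list(fits["b50"]), per_repeat_k=list(fits["k"]),
        n_repeats_used=len(fits), flagged=flagged,
    )
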