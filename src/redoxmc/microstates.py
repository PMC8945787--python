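"""Microstate energies, Boltzmann occupancies and redox titration.

A microstate picks one conformer per fragment; its free energy is

    dG_x = sum_i delta_xi [ 2.303 m_i kT (pH - pK_sol,i)
                            + n_i F (Eh - Em_sol,i)
                            + ddG_rxn,i + dG_pol,i ]
           + sum_(i<j) delta_xi delta_xj dG_ij

with kT = 0.5922 kcal/mol at 298 K and F = 23.061 kcal/(mol V).  The
pairwise sum counts each unordered pair once.  ``n`` counts electrons bound
in the *reduced* conformer of a redox couple, so raising Eh (a more
oxidizing bath) penalizes reduced conformers and drives oxidation.

Occupancies come either from exact enumeration of the microstate space
(small systems; the oracle) or from Metropolis Monte Carlo sampling with
batch-means error estimates.  Midpoints are extracted from occupancy
curves on an Eh grid; a multi-site cluster's midpoint uses the
second-oxidation convention (the Eh where the expected number of oxidized
sites crosses 1.5 on the way from the 1+ to the 2+ core).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import FARADAY, kt
from .fragments import Conformer
from .pb import EnergyTables

__all__ = [
    "TitrationCondition",
    "Microstate",
    "TitrationResult",
    "MCSchedule",
    "microstate_energy",
    "intrinsic_energies",
    "enumerate_occupancies",
    "mc_sample",
    "titrate",
    "site_midpoint",
    "extract_cluster_em",
    "oxidized_indicator",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class TitrationCondition:
    """Solution conditions: pH, redox potential Eh (mV) and temperature."""

    pH: float = 7.0
    Eh: float = 0.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Microstate:
    """One conformer choice per fragment (global conformer indices)."""

    selection: tuple[int, ...]
    total_energy: float = 0.0


@dataclass
class MCSchedule:
    """Metropolis sampling schedule (full sweeps)."""

    sweeps_burnin: int = 2000
    sweeps_sample: int = 10000
    n_batches: int = 25
    double_flip_prob: float = 0.1


@dataclass
class TitrationResult:
    """Occupancies on a condition grid plus extracted midpoints."""

    grid: list[TitrationCondition]
    occupancy: np.ndarray  # (n_conditions, M)
    mc_error: np.ndarray | None = None  # (n_conditions, M)
    midpoints: dict = field(default_factory=dict)
    fragment_ids: list[str] = field(default_factory=list)
    conformer_ids: list[str] = field(default_factory=list)

    def eh_values(self) -> np.ndarray:
        return np.array([c.Eh for c in self.grid])

    def to_frame(self):
        """Long-format TSV-ready table (Eh_mV, fragment, conformer, occupancy)."""
        import pandas as pd

        rows = []
        for ci, cond in enumerate(self.grid):
            for k in range(self.occupancy.shape[1]):
                rows.append(
                    {
                        "Eh_mV": cond.Eh,
                        "pH": cond.pH,
                        "fragment_id": self.fragment_ids[k] if self.fragment_ids else "",
                        "conformer_id": self.conformer_ids[k] if self.conformer_ids else k,
                        "occupancy": self.occupancy[ci, k],
                        "mc_error": 0.0 if self.mc_error is None else self.mc_error[ci, k],
                    }
                )
        return pd.DataFrame(rows)


def _group_by_fragment(conformers: list[Conformer]) -> tuple[list[str], list[np.ndarray]]:
    """Fragment ids (first-appearance order) and global conformer indices."""
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for k, c in enumerate(conformers):
        if c.fragment_id not in members:
            order.append(c.fragment_id)
            members[c.fragment_id] = []
        members[c.fragment_id].append(k)
    return order, [np.array(members[f]) for f in order]


def intrinsic_energies(conformers: list[Conformer], tables: EnergyTables,
                       cond: TitrationCondition) -> np.ndarray:
    """Per-conformer (self) part of the microstate energy, kcal/mol."""
    kT = kt(cond.temperature)
    out = np.zeros(len(conformers))
    for k, c in enumerate(conformers):
        e = LN10 * c.m * kT * (cond.pH - c.pk_sol)
        e += c.n * FARADAY * (cond.Eh - c.em_sol) / 1000.0
        e += tables.dG_rxn[k] + tables.dG_pol[k]
        out[k] = e
    return out


def microstate_energy(
    x: Microstate,
    tables: EnergyTables,
    conformers: list[Conformer],
    cond: TitrationCondition,
) -> float:
    """Exact microstate energy dG_x (kcal/mol); pairs counted once."""
    sel = list(x.selection)
    frag_of = [conformers[k].fragment_id for k in sel]
    if len(set(frag_of)) != len(frag_of):
        raise AssertionError("microstate selects two conformers of one fragment")
    intr = intrinsic_energies(conformers, tables, cond)
    e = float(np.sum(intr[sel]))
    for a in range(len(sel)):
        for b in range(a + 1, len(sel)):
            g = tables.dG_pair[sel[a], sel[b]]
            assert np.isfinite(g), "same-fragment sentinel selected"
            e += g
    return e


def _pair_matrix_for_mc(tables: EnergyTables) -> np.ndarray:
    """Pair matrix with same-fragment sentinels replaced by 0 (never co-selected)."""
    pair = tables.dG_pair.copy()
    pair[~np.isfinite(pair)] = 0.0
    return pair


def enumerate_occupancies(
    tables: EnergyTables,
    conformers: list[Conformer],
    cond: TitrationCondition,
    max_states: int = 1_000_000,
) -> np.ndarray:
    """Exact Boltzmann occupancies by full microstate enumeration."""
    frag_ids, members = _group_by_fragment(conformers)
    sizes = [len(m) for m in members]
    n_states = int(np.prod(sizes, dtype=np.int64))
    if n_states > max_states:
        raise ValueError(
            f"{n_states} microstates exceeds the enumeration limit {max_states}; "
            "use the Monte Carlo engine"
        )
    kT = kt(cond.temperature)
    intr = intrinsic_energies(conformers, tables, cond)
    pair = _pair_matrix_for_mc(tables)

    # accumulate energies on the (n1, n2, ..., nF) tensor
    energy = np.zeros(sizes)
    nf = len(members)
    for f, idx in enumerate(members):
        shape = [1] * nf
        shape[f] = sizes[f]
        energy += intr[idx].reshape(shape)
        for g in range(f):
            sub = pair[np.ix_(members[g], idx)]  # (ng, nf)
            shape2 = [1] * nf
            shape2[g] = sizes[g]
            shape2[f] = sizes[f]
            energy += sub.reshape(shape2)

    w = np.exp(-(energy - energy.min()) / kT)
    z = w.sum()
    occ = np.zeros(len(conformers))
    for f, idx in enumerate(members):
        axes = tuple(a for a in range(nf) if a != f)
        occ[idx] = w.sum(axis=axes) / z
    return occ


def mc_sample(
    tables: EnergyTables,
    conformers: list[Conformer],
    cond: TitrationCondition,
    schedule: MCSchedule | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis sampling of conformer occupancies.

    Single-conformer flips plus (with probability
    ``schedule.double_flip_prob``) correlated double flips of two random
    fragments, which decorrelate strongly coupled pairs.  Returns
    ``(occupancy, mc_error)``; the error is the batch-means standard
    error of each occupancy.  A fixed seed makes the run bit-reproducible.
    """
    schedule = schedule or MCSchedule()
    rng = np.random.default_rng(seed)
    kT = kt(cond.temperature)
    frag_ids, members = _group_by_fragment(conformers)
    nf = len(members)
    intr = intrinsic_energies(conformers, tables, cond)
    pair = _pair_matrix_for_mc(tables)

    state = np.array([m[0] for m in members])  # global conformer index per fragment

    n_sweeps = schedule.sweeps_burnin + schedule.sweeps_sample
    moves_per_sweep = nf
    total_moves = n_sweeps * moves_per_sweep
    u_frag = rng.integers(0, nf, size=total_moves)
    u_pick = rng.random(total_moves)
    u_acc = rng.random(total_moves)
    u_dbl = rng.random(total_moves)
    u_frag2 = rng.integers(0, nf, size=total_moves)
    u_pick2 = rng.random(total_moves)

    counts = np.zeros((schedule.n_batches, len(conformers)))
    sweeps_per_batch = max(1, schedule.sweeps_sample // schedule.n_batches)
    accepted = 0
    attempted = 0
    mv = 0
    for sweep in range(n_sweeps):
        for _ in range(moves_per_sweep):
            f = u_frag[mv]
            cand = members[f]
            new = cand[int(u_pick[mv] * len(cand))]
            old = state[f]
            do_double = nf > 1 and u_dbl[mv] < schedule.double_flip_prob
            if do_double:
                f2 = u_frag2[mv]
                if f2 == f:
                    f2 = (f + 1) % nf
                cand2 = members[f2]
                new2 = cand2[int(u_pick2[mv] * len(cand2))]
                old2 = state[f2]
                trial = state.copy()
                trial[f] = new
                trial[f2] = new2
                de = (
                    intr[new] - intr[old] + intr[new2] - intr[old2]
                    + pair[new, trial].sum() - pair[old, state].sum()
                    + pair[new2, trial].sum() - pair[old2, state].sum()
                    - pair[new, new2] + pair[old, old2]  # pair counted twice above
                )
            else:
                de = intr[new] - intr[old] + pair[new, state].sum() - pair[old, state].sum()
            changes = new != old or (do_double and new2 != old2)
            if changes:
                attempted += 1
            if de <= 0 or u_acc[mv] < math.exp(-de / kT):
                if changes:
                    accepted += 1
                state[f] = new
                if do_double:
                    state[f2] = new2
            mv += 1
        if sweep >= schedule.sweeps_burnin:
            b = min((sweep - schedule.sweeps_burnin) // sweeps_per_batch, schedule.n_batches - 1)
            np.add.at(counts[b], state, 1.0)

    if accepted == 0:
        warnings.warn("Metropolis acceptance ratio is zero: sampling is non-ergodic",
                      RuntimeWarning, stacklevel=2)

    # each recorded sweep contributes one count per fragment
    sweeps_rec = counts.sum(axis=1) / nf
    frac = counts / np.maximum(sweeps_rec[:, None], 1.0)
    occupancy = counts.sum(axis=0) / max(1.0, sweeps_rec.sum())
    nb = (sweeps_rec > 0).sum()
    if nb > 1:
        mc_error = frac[sweeps_rec > 0].std(axis=0, ddof=1) / math.sqrt(nb)
    else:
        mc_error = np.zeros(len(conformers))
    return occupancy, mc_error


def titrate(
    tables: EnergyTables,
    conformers: list[Conformer],
    pH: float,
    eh_grid: np.ndarray,
    engine: str = "enumerate",
    seed: int = 0,
    schedule: MCSchedule | None = None,
    temperature: float = 298.0,
) -> TitrationResult:
    """Occupancies across an Eh scan, plus per-site midpoints.

    ``engine`` is ``"enumerate"`` (exact) or ``"mc"``.  The Eh grid must
    be monotone increasing (mV).
    """
    eh_grid = np.asarray(eh_grid, float)
    if eh_grid.ndim != 1 or len(eh_grid) < 2 or np.any(np.diff(eh_grid) <= 0):
        raise ValueError("eh_grid must be monotone increasing with >= 2 points")
    if engine not in ("enumerate", "mc"):
        raise ValueError(f"unknown engine {engine!r}")

    conds = [TitrationCondition(pH=pH, Eh=float(eh), temperature=temperature) for eh in eh_grid]
    occ = np.zeros((len(conds), len(conformers)))
    err = np.zeros_like(occ) if engine == "mc" else None
    seeds = np.random.SeedSequence(seed).spawn(len(conds))
    for i, cond in enumerate(conds):
        if engine == "enumerate":
            occ[i] = enumerate_occupancies(tables, conformers, cond)
        else:
            occ[i], err[i] = mc_sample(tables, conformers, cond, schedule, seeds[i])

    frag_ids = [c.fragment_id for c in conformers]
    result = TitrationResult(
        grid=conds,
        occupancy=occ,
        mc_error=err,
        fragment_ids=frag_ids,
        conformer_ids=[f"{c.fragment_id}[{c.label or c.index}]" for c in conformers],
    )
    # per-redox-site midpoints where the curve crosses 0.5 inside the grid
    for fid in dict.fromkeys(frag_ids):
        try:
            result.midpoints[fid] = site_midpoint(result, conformers, fid)
        except ValueError:
            pass
    return result


def oxidized_indicator(conformers: list[Conformer], fragment_id: str) -> np.ndarray:
    """Boolean mask (over all conformers) of the fragment's oxidized conformers.

    In a redox couple the reduced conformer carries n >= 1; the oxidized
    conformers of the same fragment carry n = 0.  Raises if the fragment
    has no redox couple.
    """
    mask = np.zeros(len(conformers), dtype=bool)
    frag_confs = [(k, c) for k, c in enumerate(conformers) if c.fragment_id == fragment_id]
    if not frag_confs:
        raise KeyError(f"no conformers for fragment {fragment_id!r}")
    if not any(c.n > 0 for _, c in frag_confs):
        raise ValueError(f"fragment {fragment_id!r} is not redox-titratable (no n > 0 conformer)")
    for k, c in frag_confs:
        mask[k] = c.n == 0
    return mask


def _crossing(eh: np.ndarray, curve: np.ndarray, level: float) -> float:
    """First upward crossing of ``level`` by linear interpolation."""
    above = curve >= level
    if above[0] or not above.any():
        raise ValueError(
            f"curve does not cross {level} inside the Eh grid "
            f"[{eh[0]:.0f}, {eh[-1]:.0f}] mV (range {curve.min():.3f}..{curve.max():.3f})"
        )
    i = int(np.argmax(above))
    x0, x1 = eh[i - 1], eh[i]
    y0, y1 = curve[i - 1], curve[i]
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def site_midpoint(result: TitrationResult, conformers: list[Conformer], fragment_id: str) -> float:
    """Em (mV) of a single redox site: 0.5-crossing of its oxidized fraction."""
    mask = oxidized_indicator(conformers, fragment_id)
    curve = result.occupancy[:, mask].sum(axis=1)
    return _crossing(result.eh_values(), curve, 0.5)


def extract_cluster_em(
    result: TitrationResult,
    conformers: list[Conformer],
    cluster_fragment_ids: list[str],
    oxidation_number: int = 2,
) -> float:
    """Cluster midpoint (mV) by the second-oxidation convention.

    The cluster Em for the 2+/1+ couple is the Eh at which the expected
    number of oxidized Fe sites crosses ``oxidation_number - 0.5`` (1.5
    for the second oxidation), linearly interpolated between grid points.
    """
    if len(cluster_fragment_ids) < 2:
        raise ValueError("cluster must contain at least two redox sites")
    eh = result.eh_values()
    total = np.zeros(len(eh))
    for fid in cluster_fragment_ids:
        mask = oxidized_indicator(conformers, fid)
        total += result.occupancy[:, mask].sum(axis=1)
    return _crossing(eh, total, oxidation_number - 0.5)
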