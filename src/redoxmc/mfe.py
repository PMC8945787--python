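"""Mean-field energy (MFE) decomposition of in-protein midpoint shifts.

The in-protein midpoint of a redox site differs from its solution
reference because of desolvation, backbone interactions and interactions
with the Boltzmann-averaged occupancies of all other groups:

    F Em_MFE = n F Em_sol + dG_bkbn + ddG_rxn + dG_res^MFE

Each term is the *oxidized-minus-reduced* difference of the corresponding
energy for the site's conformers, with the residue term occupancy-weighted
at the condition of interest (normally the site's own Em).  The identity
above defines Em_MFE; it holds by construction.  The shift actually
realized by the sampled titration, F*(Em_calc - Em_sol), generally
differs from the mean-field sum — that difference is the content of the
mean-field approximation — so both are reported and labelled distinctly.

Per-residue interaction tables (a column per probe fragment, e.g. the
four bridging sulfurs of a cubane) use the same occupancy weighting and
are purely electrostatic by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import FARADAY
from .fragments import Conformer
from .microstates import TitrationCondition, enumerate_occupancies, oxidized_indicator
from .pb import EnergyTables

__all__ = [
    "MFEBreakdown",
    "InteractionTable",
    "mfe_decompose",
    "decompose_at_midpoint",
    "em_shift_energy",
    "residue_breakdown",
    "build_interaction_table",
    "aggregate_row_total",
    "aggregate_cluster_total",
    "strongest_interaction",
]


def em_shift_energy(em_calc: float, em_sol: float) -> float:
    """|Em_calc - Em_sol| converted from mV to kcal/mol via F."""
    return abs(em_calc - em_sol) * FARADAY / 1000.0


@dataclass
class MFEBreakdown:
    """Mean-field decomposition of one redox site's midpoint shift.

    Energies in kcal/mol; potentials in mV.  ``dEm`` is the shift of the
    *sampled* midpoint from the reference, F*(Em_calc - Em_sol), in
    energy units (signed); ``Em_mfe`` satisfies the mean-field identity
    exactly.
    """

    site_id: str
    Em_sol: float
    dG_bkbn: float
    dG_rxn: float
    dG_res_mfe: float
    Em_mfe: float
    Em_calc: float | None = None
    dEm: float | None = None
    n: int = 1
    residue_terms: pd.Series | None = None

    def identity_residual(self) -> float:
        lhs = self.n * FARADAY * self.Em_mfe / 1000.0
        rhs = (
            self.n * FARADAY * self.Em_sol / 1000.0
            + self.dG_bkbn + self.dG_rxn + self.dG_res_mfe
        )
        return lhs - rhs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [self.site_id],
                "Em_sol_mV": [self.Em_sol],
                "dG_bkbn": [self.dG_bkbn],
                "ddG_rxn": [self.dG_rxn],
                "dG_res_mfe": [self.dG_res_mfe],
                "Em_mfe_mV": [self.Em_mfe],
                "Em_calc_mV": [self.Em_calc],
                "dEm_kcal": [self.dEm],
            }
        )


def _site_state_vectors(conformers: list[Conformer], site_id: str, occupancy: np.ndarray):
    """Occupancy-weighted oxidized / reduced index weights for the site.

    With a single (ox, red) conformer pair the weights are one-hot; with
    geometric multiplicity they weight each variant by its conditional
    occupancy within its redox state.
    """
    ox_mask = oxidized_indicator(conformers, site_id)
    site_mask = np.array([c.fragment_id == site_id for c in conformers])
    red_mask = site_mask & ~ox_mask
    ox_mask = site_mask & ox_mask

    def weights(mask):
        w = np.where(mask, np.maximum(occupancy, 0.0), 0.0)
        tot = w.sum()
        if tot <= 0:  # state unpopulated at this condition: uniform over variants
            w = mask.astype(float)
            tot = w.sum()
        return w / tot

    return weights(ox_mask), weights(red_mask)


def mfe_decompose(
    site_id: str,
    occupancy: np.ndarray,
    tables: EnergyTables,
    conformers: list[Conformer],
    em_calc: float | None = None,
) -> MFEBreakdown:
    """Decompose a redox site's midpoint shift at given occupancies.

    ``occupancy`` is the per-conformer Boltzmann occupancy vector at the
    condition of interest (normally Eh = the site's Em).  The residue
    term sums occupancy-weighted pair energies over all conformers of
    *other* fragments (electrostatic part when available).
    """
    w_ox, w_red = _site_state_vectors(conformers, site_id, occupancy)
    red_idx = np.flatnonzero(w_red)
    em_sol = float(np.sum(w_red[red_idx] * np.array([conformers[k].em_sol for k in red_idx])))
    n = int(round(float(np.sum(w_red[red_idx] * np.array([conformers[k].n for k in red_idx])))))
    if n < 1:
        raise ValueError(f"site {site_id} has no electrons in its reduced state")

    diff = w_ox - w_red
    dG_rxn = float(np.dot(diff, tables.dG_rxn))
    dG_bkbn = float(np.dot(diff, tables.dG_pol))

    pair = tables.dG_pair_elec if tables.dG_pair_elec is not None else tables.dG_pair
    pair = np.where(np.isfinite(pair), pair, 0.0)
    other = np.array([c.fragment_id != site_id for c in conformers], dtype=float)
    partner_w = occupancy * other
    per_conf = (pair @ partner_w)  # interaction of each conformer with the mean field
    dG_res = float(np.dot(diff, per_conf))

    residue_terms: dict[str, float] = {}
    for k, c in enumerate(conformers):
        if c.fragment_id == site_id:
            continue
        contrib = float(np.dot(diff, pair[:, k]) * occupancy[k])
        residue_terms[c.fragment_id] = residue_terms.get(c.fragment_id, 0.0) + contrib

    em_mfe = em_sol + 1000.0 * (dG_bkbn + dG_rxn + dG_res) / (n * FARADAY)
    dem = None if em_calc is None else (em_calc - em_sol) * FARADAY / 1000.0
    return MFEBreakdown(
        site_id=site_id,
        Em_sol=em_sol,
        dG_bkbn=dG_bkbn,
        dG_rxn=dG_rxn,
        dG_res_mfe=dG_res,
        Em_mfe=em_mfe,
        Em_calc=em_calc,
        dEm=dem,
        n=n,
        residue_terms=pd.Series(residue_terms).sort_values(),
    )


def decompose_at_midpoint(
    site_id: str,
    tables: EnergyTables,
    conformers: list[Conformer],
    em_calc: float,
    pH: float = 7.0,
    temperature: float = 298.0,
) -> MFEBreakdown:
    """Convenience wrapper: exact occupancies at Eh = Em_calc, then decompose."""
    cond = TitrationCondition(pH=pH, Eh=em_calc, temperature=temperature)
    occ = enumerate_occupancies(tables, conformers, cond)
    return mfe_decompose(site_id, occ, tables, conformers, em_calc=em_calc)


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------


@dataclass
class InteractionTable:
    """Mean-field interaction energies, partner rows x probe columns.

    ``values`` holds full-precision energies (kcal/mol); display output
    may blank entries below ``display_threshold`` but stored totals
    always use the full values.
    """

    values: pd.DataFrame
    display_threshold: float = 0.5

    def row_totals(self) -> pd.Series:
        return self.values.sum(axis=1)

    def grand_total(self) -> float:
        return float(self.values.to_numpy().sum())

    def display(self) -> pd.DataFrame:
        """Report-style view: small entries blanked, totals appended."""
        shown = self.values.where(self.values.abs() >= self.display_threshold)
        out = shown.round(1)
        out["Tot."] = self.row_totals().round(1)
        return out


def residue_breakdown(
    probe_id: str,
    occupancy: np.ndarray,
    tables: EnergyTables,
    conformers: list[Conformer],
) -> pd.Series:
    """One probe fragment's mean-field interaction with every other fragment.

    entry(partner) = sum over partner conformers j of <occ_j> * dG(probe, j),
    with the probe's own conformers occupancy-weighted if it has several.
    Purely electrostatic when the tables carry the electrostatic split.
    """
    frag_ids = [c.fragment_id for c in conformers]
    if probe_id not in frag_ids:
        raise KeyError(f"unknown probe fragment {probe_id!r}")
    pair = tables.dG_pair_elec if tables.dG_pair_elec is not None else tables.dG_pair
    pair = np.where(np.isfinite(pair), pair, 0.0)

    probe_mask = np.array([f == probe_id for f in frag_ids], dtype=float)
    w_probe = probe_mask * np.maximum(occupancy, 0.0)
    if w_probe.sum() <= 0:
        w_probe = probe_mask
    w_probe = w_probe / w_probe.sum()

    field = w_probe @ pair  # probe's occupancy-averaged interaction with each conformer
    out: dict[str, float] = {}
    for k, c in enumerate(conformers):
        if c.fragment_id == probe_id:
            continue
        out[c.fragment_id] = out.get(c.fragment_id, 0.0) + field[k] * occupancy[k]
    return pd.Series(out, name=probe_id)


def build_interaction_table(
    probe_ids: list[str],
    occupancy: np.ndarray,
    tables: EnergyTables,
    conformers: list[Conformer],
    display_threshold: float = 0.5,
) -> InteractionTable:
    cols = [residue_breakdown(p, occupancy, tables, conformers) for p in probe_ids]
    return InteractionTable(pd.concat(cols, axis=1), display_threshold)


def aggregate_row_total(entries) -> float:
    """Row total across probes, blanks (NaN) treated as zero."""
    arr = np.asarray(pd.Series(entries).fillna(0.0), dtype=float)
    return float(arr.sum())


def aggregate_cluster_total(table: InteractionTable) -> float:
    """Grand total = sum of row totals."""
    return float(table.row_totals().sum())


def strongest_interaction(table: InteractionTable) -> tuple[str, str, float]:
    """Largest-magnitude single entry as (partner, probe, energy).

    Ties break lexicographically by (partner id, probe id).
    """
    vals = table.values
    if vals.size == 0:
        raise ValueError("empty interaction table")
    best = None
    for row in sorted(map(str, vals.index)):
        for col in sorted(map(str, vals.columns)):
            e = float(vals.loc[row, col])
            if np.isnan(e):
                continue
            if best is None or abs(e) > abs(best[2]) + 1e-12:
                best = (row, col, e)
    if best is None:
        raise ValueError("interaction table has no finite entries")
    return best
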