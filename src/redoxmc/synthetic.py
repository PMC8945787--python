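"""Synthetic structures, analytic titration systems and published fixtures.

Three generators back the test pyramid:

* :func:`make_toy_cluster` — a PDB-writable cubane-like Fe/S core with
  cysteine-thiolate-like ligands, Lys/Arg-like charged shell sites with
  charged/neutral conformer pairs, rigid backbone-like dipoles, and an
  optional neutral low-dielectric matrix sphere, emulating a buried
  multi-iron cluster in a protein.
* :func:`make_titration_system` — abstract energy tables whose titration
  behavior has a closed-form solution, for exercising the microstate
  engine and midpoint extraction without a PB solve.
* :func:`load_published_fixtures` — published per-sulfur interaction tables,
  ligand bond distances, energy decomposition terms and midpoint values
  for a cyanobacterial photosystem I benchmark (three 4Fe-4S clusters),
  transcribed once into versioned, checksummed data files.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .fragments import (
    ChargeConfig,
    Conformer,
    StructureModel,
    load_charge_config,
    parse_structure,
)
from .pb import SAME_FRAGMENT, EnergyTables

__all__ = [
    "ToySystemSpec",
    "PublishedFixtures",
    "FixtureError",
    "default_charge_config",
    "make_toy_cluster",
    "make_titration_system",
    "load_published_fixtures",
]

_CHECKSUMS = {
    "table5_interactions.tsv": "74715e87302d356382b887b158b801dfd43e6d50565a2fba386193878da12cf6",
    "cluster_tables.json": "ab0994a919d00bfd09fe2d0dc31943094c765877666703c6d7eb38c728ff4ed3",
}


class FixtureError(RuntimeError):
    """Fixture file missing or corrupted (checksum mismatch)."""


def _read_data(name: str, verify: bool = True) -> bytes:
    ref = resources.files("redoxmc.data") / name
    blob = ref.read_bytes()
    if verify and name in _CHECKSUMS:
        digest = hashlib.sha256(blob).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise FixtureError(f"checksum mismatch for fixture {name}: {digest}")
    return blob


def default_charge_config() -> ChargeConfig:
    """The bundled residue/hetero parameterization."""
    return load_charge_config(yaml.safe_load(_read_data("default_charges.yaml", verify=False)))


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


@dataclass
class ToySystemSpec:
    """Parameters of the synthetic buried-cluster structure.

    ``shell_charges`` entries are (charge e, distance from cluster center
    A, count); they become Lys/Arg-like (+1) or Asp/Glu-like (-1)
    single-atom fragments with a charged and a neutral conformer each.
    ``backbone_dipoles`` places rigid two-atom dipoles (+/-0.4 e, 1.2 A
    apart) just outside the cluster.  ``matrix_radius`` > 0 fills a
    sphere of neutral atoms to create a contiguous low-dielectric
    protein region around the cluster.
    """

    n_fe: int = 4
    cube_edge: float = 2.3  # A; also the Fe-S bond length of the ideal cubane
    ligands: bool = True
    ligand_distance: float = 2.3
    shell_charges: list = field(default_factory=list)  # (charge, distance, count)
    backbone_dipoles: int = 0
    dipole_distance: float = 6.0
    matrix_radius: float = 0.0
    site_em_sol: float = -170.0  # mV
    fe_radius: float = 1.3
    s_radius: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fe not in (1, 4):
            raise ValueError("n_fe must be 1 (single ion) or 4 (cubane)")


def _cubane_sites(edge: float) -> tuple[np.ndarray, np.ndarray]:
    """Fe and S positions on alternating vertices of a cube with side=edge."""
    a = edge
    fe = np.array([[0, 0, 0], [a, a, 0], [a, 0, a], [0, a, a]], float)
    s = np.array([[a, 0, 0], [0, a, 0], [0, 0, a], [a, a, a]], float)
    center = np.full(3, a / 2.0)
    return fe - center, s - center


def _pdb_atom(serial, name, resname, chain, resnum, pos, element, hetatm=False) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    nm = name if len(name) >= 4 else f" {name:<3}"
    return (
        f"{rec}{serial:>5} {nm:<4} {resname:<3} {chain}{resnum:>4}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          {element:>2}"
    )


def make_toy_cluster(spec: ToySystemSpec) -> tuple[StructureModel, str, ChargeConfig]:
    """Generate the toy structure; returns (model, pdb_text, charge_config).

    The PDB text regenerates the identical model through
    :func:`redoxmc.fragments.parse_structure` with the returned config
    (the bundled default), so the generator doubles as a round-trip
    fixture.  Deterministic for a fixed spec (seeded shell placement).
    """
    rng = np.random.default_rng(spec.seed)
    config = default_charge_config()
    lines: list[str] = []
    serial = 1

    if spec.n_fe == 4:
        fe, s = _cubane_sites(spec.cube_edge)
        for i in range(4):
            lines.append(_pdb_atom(serial, f"FE{i+1}", "SF4", "A", 500, fe[i], "FE", True))
            serial += 1
        for i in range(4):
            lines.append(_pdb_atom(serial, f"S{i+1}", "SF4", "A", 500, s[i], "S", True))
            serial += 1
        ligand_anchor = fe
    else:
        fe = np.zeros((1, 3))
        lines.append(_pdb_atom(serial, "FE1", "SF4", "A", 500, fe[0], "FE", True))
        serial += 1
        ligand_anchor = fe

    if spec.ligands:
        for i, p in enumerate(ligand_anchor):
            direction = p / np.linalg.norm(p) if np.linalg.norm(p) > 1e-9 else np.array([1.0, 0, 0])
            sg = p + direction * spec.ligand_distance
            lines.append(_pdb_atom(serial, "SG", "CYL", "L", i + 1, sg, "S"))
            serial += 1

    placed: list[np.ndarray] = []
    resnum = 1
    for charge, distance, count in spec.shell_charges:
        resname = "SHL" if charge > 0 else "SHM"
        aname = "NZ" if charge > 0 else "OD"
        elem = "N" if charge > 0 else "O"
        for _ in range(count):
            for _attempt in range(200):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos = v * distance
                if all(np.linalg.norm(pos - q) > 3.0 for q in placed):
                    break
            else:
                raise ValueError(f"cannot place shell charge at {distance} A without overlap")
            placed.append(pos)
            lines.append(_pdb_atom(serial, aname, resname, "S", resnum, pos, elem))
            serial += 1
            resnum += 1

    for i in range(spec.backbone_dipoles):
        for _attempt in range(200):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            base = v * spec.dipole_distance
            if all(np.linalg.norm(base - q) > 3.0 for q in placed):
                break
        else:
            raise ValueError("cannot place backbone dipole without overlap")
        placed.append(base)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        lines.append(_pdb_atom(serial, "NP", "BBD", "B", i + 1, base + 0.6 * axis, "N"))
        serial += 1
        lines.append(_pdb_atom(serial, "OM", "BBD", "B", i + 1, base - 0.6 * axis, "O"))
        serial += 1

    if spec.matrix_radius > 0:
        # fcc-ish lattice of neutral 1.8 A spheres filling the matrix ball
        step = 2.0
        r = spec.matrix_radius
        grid = np.arange(-r, r + step, step)
        mi = 1
        for x in grid:
            for y in grid:
                for z in grid:
                    p = np.array([x, y, z])
                    nr = np.linalg.norm(p)
                    if nr > r or nr < 2.2:  # keep the core clear of filler
                        continue
                    lines.append(_pdb_atom(serial, "C", "MTX", "M", mi, p, "C"))
                    serial += 1
                    mi += 1

    pdb_text = "\n".join(lines) + "\nEND\n"

    cfg_raw = json.loads(json.dumps(config.raw))  # deep copy
    cfg_raw["hetero"]["SF4"]["fe"]["radius"] = spec.fe_radius
    cfg_raw["hetero"]["SF4"]["s"]["radius"] = spec.s_radius
    for st in cfg_raw["hetero"]["SF4"]["fe"]["states"]:
        if st.get("n", 0) > 0:
            st["em_sol"] = spec.site_em_sol
    cfg = ChargeConfig(cfg_raw)
    model = parse_structure(pdb_text, cfg)
    return model, pdb_text, cfg


# ---------------------------------------------------------------------------
# analytic titration systems
# ---------------------------------------------------------------------------


def make_titration_system(
    site_ems: list[float],
    W: float | np.ndarray = 0.0,
    protein_shift: list[float] | None = None,
    interaction_overrides: np.ndarray | None = None,
) -> tuple[EnergyTables, list[Conformer]]:
    """Abstract redox sites with ferric-ferric couplings, for engine tests.

    Each site gets a reduced conformer (n=1, Em_sol = site value, charge
    +2) and an oxidized conformer (n=0, charge +3).  ``W`` (kcal/mol,
    scalar or per-pair matrix) couples oxidized-oxidized pairs —
    electrostatic repulsion between ferric ions.  ``protein_shift`` adds
    a desolvation-like self energy to each site's *oxidized* conformer,
    shifting its midpoint by 1000*shift/F mV.  ``interaction_overrides``
    (2M x 2M) replaces the whole pair matrix.
    """
    m = len(site_ems)
    conformers: list[Conformer] = []
    for i, em in enumerate(site_ems):
        fid = f"FE{i+1}"
        conformers.append(
            Conformer(fragment_id=fid, index=2 * i, charge_state=2, n=1, em_sol=float(em),
                      label="red")
        )
        conformers.append(Conformer(fragment_id=fid, index=2 * i + 1, charge_state=3, label="ox"))

    M = 2 * m
    dG_rxn = np.zeros(M)
    if protein_shift is not None:
        for i, s in enumerate(protein_shift):
            dG_rxn[2 * i + 1] = float(s)

    pair = np.zeros((M, M))
    if interaction_overrides is not None:
        pair = np.asarray(interaction_overrides, float).copy()
    else:
        Wm = np.asarray(W, float)
        if Wm.ndim == 0:
            Wm = np.full((m, m), float(W))
        for i in range(m):
            for j in range(m):
                if i != j:
                    pair[2 * i + 1, 2 * j + 1] = Wm[i, j] if Wm[i, j] else Wm[j, i]
    for i in range(m):
        pair[2 * i, 2 * i + 1] = pair[2 * i + 1, 2 * i] = SAME_FRAGMENT

    ids = [f"{c.fragment_id}[{c.label}]" for c in conformers]
    frag_ids = [c.fragment_id for c in conformers]
    tables = EnergyTables(ids, frag_ids, dG_rxn, np.zeros(M), pair)
    return tables, conformers


# ---------------------------------------------------------------------------
# published fixtures
# ---------------------------------------------------------------------------


@dataclass
class PublishedFixtures:
    """Published benchmark tables for the three 4Fe-4S clusters.

    ``table5`` maps cluster id -> DataFrame (rows: residue labels such
    as "K C51"; columns S1..S4; blanks stored as 0) with the printed row
    totals kept separately in ``table5_printed_totals``.
    """

    table5: dict[str, pd.DataFrame]
    table5_printed_totals: dict[str, pd.Series]
    table1_bold: dict[str, list[float]]
    table1_avg: dict[str, float]
    table3_terms: dict[str, dict[str, float]]
    em_values: dict


def load_published_fixtures() -> PublishedFixtures:
    """Load the transcribed benchmark tables (checksum-verified)."""
    import io

    tab5 = pd.read_csv(io.BytesIO(_read_data("table5_interactions.tsv")), sep="\t")
    labels = tab5["res"] + " " + tab5["id"]
    table5: dict[str, pd.DataFrame] = {}
    printed: dict[str, pd.Series] = {}
    for cl in ("FX", "FA", "FB"):
        cols = [f"{cl}_S{k}" for k in (1, 2, 3, 4)]
        df = tab5[cols].copy()
        df.columns = ["S1", "S2", "S3", "S4"]
        df.index = labels
        table5[cl] = df.fillna(0.0)
        printed[cl] = pd.Series(tab5[f"{cl}_tot"].fillna(0.0).to_numpy(), index=labels)

    meta = json.loads(_read_data("cluster_tables.json"))
    return PublishedFixtures(
        table5=table5,
        table5_printed_totals=printed,
        table1_bold=meta["table1_bold"],
        table1_avg=meta["table1_avg"],
        table3_terms=meta["table3_terms"],
        em_values=meta["em_values"],
    )
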