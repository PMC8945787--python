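"""Fragment model: atoms, fragments, conformers and structure parsing.

A protein/cofactor system is decomposed into *fragments* — the smallest
units that carry an integer charge and titrate independently.  For a
4Fe-4S cubane every Fe ion, every bridging sulfide and every cysteine
thiolate ligand is its own fragment; amino-acid side chains are fragments
with ionization-state conformers; backbone atoms have zero conformational
degrees of freedom and are kept as a fixed charge set.

Coordinates are angstroms in the PDB convention; charges are elementary
charges.  Parsing and writing go through gemmi.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "Fragment",
    "Conformer",
    "StructureModel",
    "ChargeConfig",
    "ParseError",
    "load_charge_config",
    "parse_structure",
    "assign_formal_charges",
    "clash_filter",
    "structure_to_pdb",
]

#: residue names dropped on parsing (replaced by the continuum medium)
SOLVENT_RESIDUES = {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA2", "ZN", "SO4", "PO4"}

#: atom names that belong to the peptide backbone
BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HA", "HN", "OXT", "H1", "H2", "H3"}

FRAGMENT_KINDS = ("fe_ion", "bridging_sulfur", "cysteine_ligand", "residue_sidechain", "backbone")


class ParseError(ValueError):
    """Raised for malformed or unparameterized structure input."""


@dataclass
class AtomRecord:
    """One atom with position, radius and partial charge."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray  # (3,) A
    radius: float  # A
    partial_charge: float = 0.0  # e
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0 for atom {self.name}, got {self.radius}")


@dataclass
class Fragment:
    """A titratable unit carrying an integer charge."""

    id: str
    kind: str
    atoms: list[AtomRecord] = field(default_factory=list)
    allowed_charge_states: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in FRAGMENT_KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        allowed = set(self.allowed_charge_states)
        if self.kind == "fe_ion" and not allowed <= {2, 3}:
            raise ValueError(f"fe_ion charges must be within {{+2,+3}}, got {sorted(allowed)}")
        if self.kind == "bridging_sulfur" and allowed != {-2}:
            raise ValueError(f"bridging_sulfur charge must be -2, got {sorted(allowed)}")


@dataclass
class Conformer:
    """One geometric/ionization variant of a fragment.

    ``m`` is the acid/base indicator of the pH term (0 neutral, +1 base,
    -1 acid); ``n`` is the number of electrons bound relative to the
    oxidized form (n >= 1 marks the reduced conformer of a redox couple,
    whose energy carries the n*F*(Eh - Em_sol) term).  A conformer is
    either an acid/base conformer (m != 0, n = 0) or a redox conformer
    (n > 0, m = 0) or fully neutral.
    """

    fragment_id: str
    index: int
    charge_state: int
    m: int = 0
    n: int = 0
    pk_sol: float = 7.0
    em_sol: float = 0.0  # mV
    positions: np.ndarray | None = None  # (n_atoms, 3)
    atom_charges: np.ndarray | None = None  # (n_atoms,) e
    atom_radii: np.ndarray | None = None  # (n_atoms,) A
    lj_rmin: np.ndarray | None = None  # (n_atoms,) A
    lj_eps: np.ndarray | None = None  # (n_atoms,) kcal/mol
    label: str = ""

    def __post_init__(self) -> None:
        if self.m not in (-1, 0, 1):
            raise ValueError(f"m must be -1, 0 or +1, got {self.m}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.m != 0 and self.n != 0:
            raise ValueError("a conformer is either acid/base (m != 0) or redox (n > 0), not both")
        for name in ("positions", "atom_charges", "atom_radii", "lj_rmin", "lj_eps"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def total_charge(self) -> float:
        if self.atom_charges is None:
            return float(self.charge_state)
        return float(np.sum(self.atom_charges))


@dataclass
class StructureModel:
    """Fragments plus their conformers plus the rigid backbone."""

    fragments: list[Fragment]
    conformers: list[Conformer]
    backbone: list[AtomRecord]

    def fragment(self, fragment_id: str) -> Fragment:
        for f in self.fragments:
            if f.id == fragment_id:
                return f
        raise KeyError(f"no fragment {fragment_id!r}")

    def conformers_of(self, fragment_id: str) -> list[Conformer]:
        return [c for c in self.conformers if c.fragment_id == fragment_id]

    def validate(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate fragment ids")
        for f in self.fragments:
            confs = self.conformers_of(f.id)
            if not confs:
                raise ValueError(f"fragment {f.id} has no conformer")
            for c in confs:
                if c.charge_state not in f.allowed_charge_states:
                    raise ValueError(
                        f"conformer charge {c.charge_state} outside allowed set "
                        f"{f.allowed_charge_states} of fragment {f.id}"
                    )

    def all_atoms(self) -> list[AtomRecord]:
        out = list(self.backbone)
        for f in self.fragments:
            out.extend(f.atoms)
        return out


# ---------------------------------------------------------------------------
# charge configuration
# ---------------------------------------------------------------------------

_DEFAULT_RADII = {"C": 1.70, "N": 1.50, "O": 1.40, "S": 1.85, "H": 1.00, "FE": 1.30, "P": 1.90}
_DEFAULT_LJ = {"rmin": 2.00, "eps": 0.10}


@dataclass
class ChargeConfig:
    """Residue/hetero-group parameterization.

    Built from a YAML mapping with keys ``radii``, ``lj``,
    ``backbone_charges``, ``residues`` and ``hetero`` (see
    ``redoxmc/data/default_charges.yaml`` for the schema by example).
    """

    raw: dict

    @property
    def radii(self) -> dict:
        d = dict(_DEFAULT_RADII)
        d.update(self.raw.get("radii", {}))
        return d

    @property
    def backbone_charges(self) -> dict:
        return self.raw.get("backbone_charges", {})

    def residue(self, name: str) -> dict | None:
        return self.raw.get("residues", {}).get(name)

    def hetero(self, name: str) -> dict | None:
        return self.raw.get("hetero", {}).get(name)

    def element_radius(self, element: str, atom_name: str = "") -> float:
        radii = self.radii
        if atom_name in radii:
            return radii[atom_name]
        if element.upper() in radii:
            return radii[element.upper()]
        return 1.7

    def lj_params(self, element: str) -> tuple[float, float]:
        lj = self.raw.get("lj", {}).get(element.upper())
        if lj is None:
            return _DEFAULT_LJ["rmin"], _DEFAULT_LJ["eps"]
        return float(lj.get("rmin", _DEFAULT_LJ["rmin"])), float(lj.get("eps", _DEFAULT_LJ["eps"]))


def load_charge_config(source: str | dict) -> ChargeConfig:
    """Load a charge configuration from YAML text, a file path, or a dict."""
    if isinstance(source, dict):
        return ChargeConfig(copy.deepcopy(source))
    text = source
    if "\n" not in source and source.endswith((".yaml", ".yml")):
        with open(source) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError("charge_config must be a mapping")
    return ChargeConfig(data)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _conformers_from_states(
    fragment: Fragment,
    states: list[dict],
    geometries: list[tuple[str, list[AtomRecord]]],
    config: ChargeConfig,
    start_index: int,
) -> list[Conformer]:
    """Cross geometric variants with ionization states into conformers."""
    confs: list[Conformer] = []
    idx = start_index
    for geo_label, atoms in geometries:
        pos = np.array([a.position for a in atoms])
        radii = np.array([a.radius for a in atoms])
        lj = np.array([config.lj_params(a.element or a.name[:1]) for a in atoms])
        for st in states:
            atom_charges = np.zeros(len(atoms))
            qmap = st.get("atom_charges")
            if qmap is None:
                # single-atom fragments: put the integer charge on the atom
                if len(atoms) == 1:
                    atom_charges[0] = float(st["charge"])
                elif st["charge"] != 0:
                    raise ParseError(
                        f"state {st.get('name')} of fragment {fragment.id} has net charge "
                        "but no atom_charges map"
                    )
            else:
                for i, a in enumerate(atoms):
                    atom_charges[i] = float(qmap.get(a.name, 0.0))
            confs.append(
                Conformer(
                    fragment_id=fragment.id,
                    index=idx,
                    charge_state=int(st["charge"]),
                    m=int(st.get("m", 0)),
                    n=int(st.get("n", 0)),
                    pk_sol=float(st.get("pk_sol", 7.0)),
                    em_sol=float(st.get("em_sol", 0.0)),
                    positions=pos,
                    atom_charges=atom_charges,
                    atom_radii=radii,
                    lj_rmin=lj[:, 0],
                    lj_eps=lj[:, 1],
                    label=f"{geo_label}:{st.get('name', st['charge'])}",
                )
            )
            idx += 1
    return confs


def _atom_records_from_residue(
    chain: gemmi.Chain, res: gemmi.Residue, config: ChargeConfig, altloc: str
) -> list[AtomRecord]:
    out = []
    for at in res:
        if at.altloc not in ("\0", "", " ", altloc):
            continue
        elem = at.element.name.upper()
        out.append(
            AtomRecord(
                serial=at.serial,
                name=at.name,
                residue_name=res.name,
                chain=chain.name,
                residue_number=res.seqid.num,
                position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                radius=config.element_radius(elem, at.name),
                element=elem,
            )
        )
    return out


def parse_structure(pdb_text: str, charge_config: ChargeConfig | str | dict) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel` under a charge config.

    Crystallographic waters and dissolved ions are dropped (they are
    represented by the continuum).  Amino acids are split into a rigid
    backbone part and a side-chain fragment with one conformer per
    (altloc geometry x ionization state).  Hetero groups listed under
    ``hetero`` in the config are split per atom into fe_ion /
    bridging_sulfur fragments (SF4 cubanes) or kept as single fragments.
    """
    config = charge_config if isinstance(charge_config, ChargeConfig) else load_charge_config(charge_config)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ParseError("no model in PDB input")
    model = st[0]

    serials = [at.serial for ch in model for res in ch for at in res]
    if len(serials) != len(set(serials)):
        dupes = sorted({s for s in serials if serials.count(s) > 1})
        raise ParseError(f"duplicate atom serial(s): {dupes}")

    fragments: list[Fragment] = []
    conformers: list[Conformer] = []
    backbone: list[AtomRecord] = []
    fe_positions: list[tuple[str, np.ndarray]] = []

    def next_index() -> int:
        return len(conformers)

    # first pass to locate Fe ions (for cysteine-ligand detection)
    for ch in model:
        for res in ch:
            if res.name in SOLVENT_RESIDUES:
                continue
            het = config.hetero(res.name)
            if het and "fe" in het:
                for at in res:
                    if at.element.name.upper() == "FE":
                        fid = f"{res.name}_{ch.name}{res.seqid.num}:{at.name}"
                        fe_positions.append((fid, np.array([at.pos.x, at.pos.y, at.pos.z])))

    for ch in model:
        for res in ch:
            if res.name in SOLVENT_RESIDUES:
                continue
            het = config.hetero(res.name)
            if het is not None:
                if het == "drop":
                    continue
                _parse_hetero(ch, res, het, config, fragments, conformers, next_index)
                continue
            rescfg = config.residue(res.name)
            if rescfg is None:
                raise ParseError(
                    f"no charge_config entry for residue {res.name} "
                    f"{ch.name}{res.seqid.num}"
                )
            _parse_residue(ch, res, rescfg, config, fragments, conformers, backbone, fe_positions, next_index)

    m = StructureModel(fragments=fragments, conformers=conformers, backbone=backbone)
    m.validate()
    return m


def _parse_hetero(chain, res, het, config, fragments, conformers, next_index) -> None:
    """Split an Fe-S hetero group into per-atom fragments."""
    resid = f"{res.name}_{chain.name}{res.seqid.num}"
    for at in res:
        elem = at.element.name.upper()
        pos = np.array([at.pos.x, at.pos.y, at.pos.z])
        if elem == "FE" and "fe" in het:
            sub = het["fe"]
            radius = float(sub.get("radius", 1.3))
            rec = AtomRecord(at.serial, at.name, res.name, chain.name, res.seqid.num, pos, radius, element="FE")
            frag = Fragment(
                id=f"{resid}:{at.name}",
                kind="fe_ion",
                atoms=[rec],
                allowed_charge_states=[int(s["charge"]) for s in sub["states"]],
            )
            fragments.append(frag)
            conformers.extend(
                _conformers_from_states(frag, sub["states"], [("", [rec])], config, next_index())
            )
        elif elem == "S" and "s" in het:
            sub = het["s"]
            radius = float(sub.get("radius", 1.8))
            rec = AtomRecord(at.serial, at.name, res.name, chain.name, res.seqid.num, pos, radius, element="S")
            frag = Fragment(
                id=f"{resid}:{at.name}",
                kind="bridging_sulfur",
                atoms=[rec],
                allowed_charge_states=[int(sub.get("charge", -2))],
            )
            fragments.append(frag)
            state = {"name": "s2-", "charge": int(sub.get("charge", -2))}
            conformers.extend(_conformers_from_states(frag, [state], [("", [rec])], config, next_index()))
        else:
            raise ParseError(f"unparameterized hetero atom {at.name} in {resid}")


def _parse_residue(chain, res, rescfg, config, fragments, conformers, backbone, fe_positions, next_index) -> None:
    resid = f"{res.name}_{chain.name}{res.seqid.num}"
    kind = rescfg.get("kind", "residue_sidechain")

    if kind == "backbone":
        # rigid dipole groups: all atoms are backbone-like fixed charges
        qmap = rescfg.get("atom_charges", {})
        for at in res:
            elem = at.element.name.upper()
            rec = AtomRecord(
                at.serial, at.name, res.name, chain.name, res.seqid.num,
                np.array([at.pos.x, at.pos.y, at.pos.z]),
                config.element_radius(elem, at.name), float(qmap.get(at.name, 0.0)), elem,
            )
            backbone.append(rec)
        return

    bb_extra = set(rescfg.get("backbone_atoms", ()))
    sidechain_atoms = rescfg.get("sidechain_atoms")
    altlocs = sorted({at.altloc for at in res if at.altloc not in ("\0", "", " ")}) or [""]

    # backbone part (altloc-independent; first altloc wins for duplicated atoms)
    seen = set()
    for at in res:
        is_bb = at.name in BACKBONE_ATOMS or at.name in bb_extra
        if sidechain_atoms is not None:
            is_bb = at.name not in sidechain_atoms
        if not is_bb or at.name in seen:
            continue
        seen.add(at.name)
        elem = at.element.name.upper()
        backbone.append(
            AtomRecord(
                at.serial, at.name, res.name, chain.name, res.seqid.num,
                np.array([at.pos.x, at.pos.y, at.pos.z]),
                config.element_radius(elem, at.name),
                float(config.backbone_charges.get(at.name, 0.0)), elem,
            )
        )

    geometries = []
    for alt in altlocs:
        atoms = [
            a for a in _atom_records_from_residue(chain, res, config, alt)
            if not (a.name in BACKBONE_ATOMS or a.name in bb_extra)
            or (sidechain_atoms is not None and a.name in sidechain_atoms)
        ]
        if sidechain_atoms is not None:
            atoms = [a for a in atoms if a.name in sidechain_atoms]
        if atoms:
            geometries.append((alt or "_", atoms))
    if not geometries:
        return  # e.g. glycine: backbone only

    frag_kind = kind
    if res.name == "CYS" and fe_positions:
        sg = [a for a in geometries[0][1] if a.name == "SG"]
        if sg and min(np.linalg.norm(sg[0].position - p) for _, p in fe_positions) < 2.8:
            frag_kind = "cysteine_ligand"

    frag = Fragment(
        id=resid,
        kind=frag_kind,
        atoms=list(geometries[0][1]),
        allowed_charge_states=sorted({int(s["charge"]) for s in rescfg["states"]}),
    )
    fragments.append(frag)
    conformers.extend(
        _conformers_from_states(frag, rescfg["states"], geometries, config, next_index())
    )


# ---------------------------------------------------------------------------
# formal charges
# ---------------------------------------------------------------------------


def assign_formal_charges(fragment: Fragment, redox_state: str) -> np.ndarray:
    """Per-atom charges for a named redox/ionization state of a fragment.

    ``redox_state`` is ``"oxidized"``/``"reduced"`` for fe_ion fragments
    (+3 / +2), ignored for bridging sulfurs (always -2).  For side-chain
    fragments it selects by state name.  The returned charges sum exactly
    to the integer formal charge of the state.
    """
    n = len(fragment.atoms)
    if fragment.kind == "fe_ion":
        if redox_state == "oxidized":
            q = 3
        elif redox_state == "reduced":
            q = 2
        else:
            raise ValueError(f"unknown fe_ion state {redox_state!r}")
        if q not in fragment.allowed_charge_states:
            raise ValueError(f"state {redox_state} (+{q}) not allowed for {fragment.id}")
        out = np.zeros(n)
        out[0] = q
        return out
    if fragment.kind == "bridging_sulfur":
        out = np.zeros(n)
        out[0] = -2
        return out
    raise ValueError(
        f"assign_formal_charges handles cluster fragments; {fragment.id} is {fragment.kind} "
        "(side-chain charges come from the charge_config states)"
    )


# ---------------------------------------------------------------------------
# clash preselection
# ---------------------------------------------------------------------------


def _min_gap(pos_a, rad_a, pos_b, rad_b) -> float:
    """Smallest (distance - r_i - r_j) over atom pairs of two atom sets."""
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    return float(np.min(d - rad_a[:, None] - rad_b[None, :]))


def clash_filter(
    conformers: list[Conformer],
    structure: StructureModel | None = None,
    overlap_tol: float = 0.1,
) -> list[Conformer]:
    """Discard conformers with hard van der Waals clashes.

    A conformer clashes if some atom pair against the rigid backbone, or
    against *every* conformer of another fragment, overlaps by more than
    ``overlap_tol`` (center distance < r_i + r_j - overlap_tol).  The
    rule is iterated to a fixed point so the filter is idempotent; the
    last surviving conformer of a fragment is never removed.  Input
    order is preserved.
    """
    if overlap_tol < 0:
        raise ValueError("overlap_tol must be >= 0")
    if not conformers:
        return []
    bb_pos = bb_rad = None
    if structure is not None and structure.backbone:
        bb_pos = np.array([a.position for a in structure.backbone])
        bb_rad = np.array([a.radius for a in structure.backbone])

    alive = list(conformers)
    while True:
        by_frag: dict[str, list[Conformer]] = {}
        for c in alive:
            by_frag.setdefault(c.fragment_id, []).append(c)

        marked: list[Conformer] = []
        for c in alive:
            if c.positions is None:
                continue
            clash = _clashes_backbone_only(c, bb_pos, bb_rad, overlap_tol)
            if not clash:
                for fid, others in by_frag.items():
                    if fid == c.fragment_id:
                        continue
                    if others and all(
                        o.positions is not None
                        and _min_gap(c.positions, c.atom_radii, o.positions, o.atom_radii)
                        < -overlap_tol
                        for o in others
                    ):
                        clash = True
                        break
            if clash:
                marked.append(c)

        # never empty a fragment: if every conformer of a fragment is marked,
        # spare the first one (stable order)
        marked_by_frag: dict[str, list[Conformer]] = {}
        for c in marked:
            marked_by_frag.setdefault(c.fragment_id, []).append(c)
        drop = set()
        for fid, ms in marked_by_frag.items():
            spare = 1 if len(ms) == len(by_frag[fid]) else 0
            drop.update(id(c) for c in ms[spare:])

        if not drop:
            return alive
        alive = [c for c in alive if id(c) not in drop]


def _clashes_backbone_only(c: Conformer, bb_pos, bb_rad, tol: float) -> bool:
    if bb_pos is None or c.positions is None:
        return False
    return _min_gap(c.positions, c.atom_radii, bb_pos, bb_rad) < -tol


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def structure_to_pdb(model: StructureModel) -> str:
    """Write a StructureModel back to PDB text (via gemmi).

    Geometric conformer variants are emitted as altloc A, B, ...;
    ionization variants share geometry and are regenerated by the charge
    config on re-parsing, so parse -> write -> parse round-trips.
    """
    # collect (chain, resnum, resname) -> [(AtomRecord, pos, altloc)]
    atoms_by_res: dict[tuple, list] = {}
    chain_order: list[str] = []

    def add_atom(a: AtomRecord, pos: np.ndarray, altloc: str = "\0") -> None:
        key = (a.chain, a.residue_number, a.residue_name)
        if a.chain not in chain_order:
            chain_order.append(a.chain)
        atoms_by_res.setdefault(key, []).append((a, pos, altloc))

    for a in sorted(model.backbone, key=lambda x: x.serial):
        add_atom(a, a.position)
    for frag in model.fragments:
        geo_labels: list[str] = []
        for c in model.conformers_of(frag.id):
            lbl = c.label.split(":")[0]
            if lbl not in geo_labels:
                geo_labels.append(lbl)
        multi = len(geo_labels) > 1
        for gi, lbl in enumerate(geo_labels):
            conf = next(c for c in model.conformers_of(frag.id) if c.label.split(":")[0] == lbl)
            for ai, a in enumerate(frag.atoms):
                add_atom(a, conf.positions[ai], chr(ord("A") + gi) if multi else "\0")

    st = gemmi.Structure()
    gm = gemmi.Model("1")
    for chain_name in chain_order:
        ch = gemmi.Chain(chain_name)
        keys = sorted((k for k in atoms_by_res if k[0] == chain_name), key=lambda k: k[1])
        for key in keys:
            r = gemmi.Residue()
            r.name = key[2]
            r.seqid = gemmi.SeqId(key[1], " ")
            r.het_flag = "A"
            for a, pos, altloc in atoms_by_res[key]:
                at = gemmi.Atom()
                at.name = a.name
                at.pos = gemmi.Position(*map(float, pos))
                at.element = gemmi.Element(a.element or a.name[:1])
                at.serial = a.serial
                at.occ = 1.0
                at.altloc = altloc
                r.add_atom(at)
            ch.add_residue(r)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    buf = st.make_pdb_string()
    # strip gemmi header records; keep coordinates + END
    lines = [l for l in buf.splitlines() if l.startswith(("ATOM", "HETATM", "TER", "END"))]
    return "\n".join(lines) + "\n"
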