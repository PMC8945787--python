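"""Structural descriptors of 4Fe-4S cubanes.

Fe-S (bridging sulfide), Fe-SG (cysteine thiolate) and Fe-Fe distances,
and the four ligand distances of a chosen Fe site (its three bridging
sulfurs plus its cysteine sulfur) with their average — the descriptors
used to rationalize differences in cluster midpoint potentials.  Which Fe
is "the second oxidized" site is an input here (it comes from the
titration ordering or from the user); geometry does not guess it.

Internal values keep full precision; 2-decimal rounding (half away from
zero) is applied only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fragments import StructureModel

__all__ = ["ClusterGeometry", "cluster_distances", "ligand_distance_summary", "round2"]


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (report style).

    A 1e-9 guard absorbs binary representation error so that decimal
    halves (e.g. the mean of 2-decimal bond lengths) round up as a
    hand calculation would.
    """
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5 + 1e-9) / 100.0, x)


@dataclass
class ClusterGeometry:
    """Distance sets of one cubane; pair entries are (id_a, id_b, distance A)."""

    cluster_id: str
    fe_s: list[tuple[str, str, float]]
    fe_sg: list[tuple[str, str, float]]
    fe_fe: list[tuple[str, str, float]]

    def validate(self) -> None:
        if len(self.fe_s) != 12 or len(self.fe_sg) != 4 or len(self.fe_fe) != 6:
            raise ValueError(
                f"not a 4Fe-4S cubane: |Fe-S|={len(self.fe_s)}, "
                f"|Fe-SG|={len(self.fe_sg)}, |Fe-Fe|={len(self.fe_fe)}"
            )

    def to_frame(self):
        import pandas as pd

        rows = [
            {"kind": kind, "a": a, "b": b, "distance_A": round2(d)}
            for kind, pairs in (("Fe-S", self.fe_s), ("Fe-SG", self.fe_sg), ("Fe-Fe", self.fe_fe))
            for a, b, d in pairs
        ]
        return pd.DataFrame(rows)


def _cluster_atoms(structure: StructureModel, cluster_id: str):
    fe, s = [], []
    for f in structure.fragments:
        if not f.id.startswith(cluster_id):
            continue
        if f.kind == "fe_ion":
            fe.append((f.id, f.atoms[0].position))
        elif f.kind == "bridging_sulfur":
            s.append((f.id, f.atoms[0].position))
    return fe, s


def cluster_distances(structure: StructureModel, cluster_id: str) -> ClusterGeometry:
    """All Fe-S / Fe-SG / Fe-Fe distances of one cubane.

    Each Fe is paired with its three nearest bridging sulfurs (12 Fe-S
    bonds in total) and with the nearest cysteine-type SG atom; Fe-Fe
    lists all six pairs.  Raises if the cluster does not contain 4 Fe,
    4 S and 4 ligand SG atoms, listing what was found.
    """
    fe, s = _cluster_atoms(structure, cluster_id)
    sg = []
    for f in structure.fragments:
        if f.kind in ("cysteine_ligand", "residue_sidechain"):
            for a in f.atoms:
                if a.name == "SG":
                    # ligating = within bonding range of some cluster Fe
                    if fe and min(np.linalg.norm(a.position - p) for _, p in fe) < 2.8:
                        sg.append((f.id, a.position))
    if len(fe) != 4 or len(s) != 4 or len(sg) != 4:
        raise ValueError(
            f"cluster {cluster_id!r} must have 4 Fe, 4 bridging S and 4 ligating SG; "
            f"found Fe={[i for i, _ in fe]}, S={[i for i, _ in s]}, SG={[i for i, _ in sg]}"
        )

    fe_s = []
    for fid, fp in fe:
        ds = sorted(((sid, float(np.linalg.norm(fp - sp))) for sid, sp in s), key=lambda t: t[1])
        for sid, d in ds[:3]:
            fe_s.append((fid, sid, d))
    fe_sg = []
    for fid, fp in fe:
        sid, d = min(((sid, float(np.linalg.norm(fp - sp))) for sid, sp in sg), key=lambda t: t[1])
        fe_sg.append((fid, sid, d))
    fe_fe = []
    for i in range(4):
        for j in range(i + 1, 4):
            fe_fe.append((fe[i][0], fe[j][0], float(np.linalg.norm(fe[i][1] - fe[j][1]))))

    geom = ClusterGeometry(cluster_id, fe_s, fe_sg, fe_fe)
    geom.validate()
    return geom


def ligand_distance_summary(
    geometry: ClusterGeometry, oxidized_fe: str
) -> tuple[list[float], float]:
    """The oxidized Fe's four ligand distances (3 bridging S + 1 SG) and mean.

    The returned values are full precision; apply :func:`round2` for
    report-style output.  Raises if ``oxidized_fe`` is not one of the
    cluster's Fe sites.
    """
    fe_ids = {a for a, _, _ in geometry.fe_sg}
    if oxidized_fe not in fe_ids:
        raise ValueError(f"{oxidized_fe!r} is not an Fe site of cluster "
                         f"{geometry.cluster_id!r} ({sorted(fe_ids)})")
    d_bridge = [d for a, _, d in geometry.fe_s if a == oxidized_fe]
    d_sg = [d for a, _, d in geometry.fe_sg if a == oxidized_fe]
    dists = d_bridge + d_sg
    if len(dists) != 4:
        raise ValueError(f"expected 4 ligand distances for {oxidized_fe}, got {len(dists)}")
    return dists, float(np.mean(dists))
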