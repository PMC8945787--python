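"""Parse a 4Fe-4S cubane from PDB text and report its bond geometry.

Builds an ideal cubane (Fe-S bond 2.3 A) with cysteine-thiolate-like
ligands, splits it into per-atom fragments with integer formal charges
(Fe +2/+3, bridging S -2), and prints the Fe-S / Fe-SG / Fe-Fe distance
table plus the ligand summary of a chosen "second oxidized" Fe site.
"""

import redoxmc as rx

model, pdb_text, config = rx.make_toy_cluster(rx.ToySystemSpec(n_fe=4, cube_edge=2.3))
print("fragments:")
for f in model.fragments:
    print(f"  {f.id:16s} {f.kind:16s} charges {f.allowed_charge_states}")

geom = rx.cluster_distances(model, "SF4_A500")
print("\ndistance table (A):")
print(geom.to_frame().to_string(index=False))

fe = geom.fe_sg[0][0]  # pretend this site is oxidized second
dists, avg = rx.ligand_distance_summary(geom, fe)
print(f"\nligand distances of {fe}: {[rx.round2(d) for d in dists]}, "
      f"avg {rx.round2(avg)} A")
# Shorter Fe-ligand distances mean stronger sulfur stabilization of the
# oxidized iron, which is how cluster geometry feeds into midpoint shifts.
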