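#!/usr/bin/env python
"""Demonstrate the structural criteria on a synthetic toy complex.

The deposited cathepsin K complexes (PDB 7QBL/7QBM/7QBN/7QBO) require a
database download; this driver exercises the same machinery — H-bond
candidates at 3.3 Å, hydrophobic-carbon contacts at 4.2 Å, covalent-adduct
exclusion, Kabsch backbone superposition and in-frame ligand r.m.s.d. — on a
small synthetic complex with hand-placed geometry, and can be pointed at
downloaded PDB files via the `covkin contacts` / `covkin superpose` CLI.
Writes results/toy_contacts.csv and results/toy_superposition.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from covkin.structure import (
    bfactor_profile,
    contacts_to_frame,
    find_hbond_candidates,
    find_nonpolar_contacts,
    ligand_rmsd,
    structure_from_pdb_string,
    superpose_backbone,
)

# synthetic toy complex: a short backbone trace with a 4-atom ligand, plus a
# copy whose ligand is displaced 1 Å within the (rigidly moved) protein frame


def _line(serial, name, resname, chain, resnum, xyz, b, element, het):
    record = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    return (f"{record}{serial:5d} {name:<4s} {resname:<3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def toy_complex(ligand_shift=(0, 0, 0), rotation=np.eye(3), translation=(0, 0, 0)):
    """Hand-placed geometry: the ligand sits above residue 2 so that
    O1...N(res2) = 3.2 Å (H-bond candidate), C1...CB(res2) = 3.9 Å
    (hydrophobic contact) and C2...CB(res2) = 4.3 Å (just outside 4.2 Å)."""
    atoms = []
    for i in range(1, 7):
        x = 3.8 * i
        for name, off in [("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.5, 0.0)),
                          ("C", (2.2, 1.6, 0.3))]:
            res = "ALA" if i == 2 else "GLY"
            atoms.append((name, res, "A", i,
                          np.array([x, 0.0, 0.0]) + off, 18.0, name[0], False))
        if i == 2:  # ALA-like side chain: CB bonded only to CA -> hydrophobic
            atoms.append(("CB", "ALA", "A", i, np.array([x + 1.46, 0.5, 1.54]),
                          20.0, "C", False))
    for name, xyz, b, el in [("C1", (9.06, 0.5, 5.44), 22.0, "C"),
                             ("C2", (10.4, 0.9, 5.6), 30.0, "C"),
                             ("N1", (11.6, 1.5, 5.6), 26.0, "N"),
                             ("O1", (7.6, 0.0, 3.2), 48.0, "O")]:
        atoms.append((name, "LIG", "L", 200,
                      np.asarray(xyz) + ligand_shift, b, el, True))
    lines = []
    for i, (name, res, chain, num, xyz, b, el, het) in enumerate(atoms):
        moved = np.asarray(rotation) @ np.asarray(xyz) + np.asarray(translation)
        lines.append(_line(i + 1, name, res, chain, num, moved, b, el, het))
    return "\n".join(lines + ["END"]) + "\n"


out_dir = pathlib.Path("results")
out_dir.mkdir(exist_ok=True)

model_a = structure_from_pdb_string(toy_complex(), name="toy-a")
theta = 0.4
rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
model_b = structure_from_pdb_string(
    toy_complex(ligand_shift=(0.6, 0.0, 0.8), rotation=rot,
                translation=(5.0, -3.0, 1.0)), name="toy-b")

records = find_hbond_candidates(model_a, "LIG") + find_nonpolar_contacts(model_a, "LIG")
contacts = contacts_to_frame(records)
contacts.to_csv(out_dir / "toy_contacts.csv", index=False)
print(f"toy complex: {sum(r.kind == 'hbond_candidate' for r in records)} H-bond "
      f"candidates (<= 3.3 Å), "
      f"{sum(r.kind == 'nonpolar_contact' for r in records)} nonpolar contacts "
      f"(<= 4.2 Å)")

sup = superpose_backbone(model_b, model_a)
lig = ligand_rmsd(model_b, model_a, "LIG", superposition=sup)
expected = float(np.linalg.norm([0.6, 0.0, 0.8]))
print(f"backbone r.m.s.d. after superposition: {sup.rmsd:.3f} Å "
      f"({sup.n_atoms_matched} atoms)")
print(f"ligand r.m.s.d. in the protein frame: {lig:.3f} Å "
      f"(constructed displacement {expected:.3f} Å)")

table, max_atom = bfactor_profile(model_a, "LIG")
print(f"highest ligand B-factor: {max_atom} "
      f"({table.loc[table['is_max'], 'bfactor'].iloc[0]:.0f} Å^2)")

pd.DataFrame([{"backbone_rmsd_A": sup.rmsd, "n_backbone_atoms": sup.n_atoms_matched,
               "ligand_rmsd_A": lig, "constructed_displacement_A": expected,
               "max_b_atom": max_atom}]).to_csv(
    out_dir / "toy_superposition.csv", index=False)
print("wrote results/toy_contacts.csv, results/toy_superposition.csv")
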