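"""Synthetic toy PDB fixtures built programmatically for structure tests.

These are small hand-placed atom sets, not real deposited models; geometry
is chosen to exercise specific distance criteria exactly.
"""

import numpy as np


def pdb_line(serial, name, resname, chain, resnum, xyz, occ=1.0, b=20.0,
             element="C", het=False, altloc=" "):
    record = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    return (f"{record}{serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def build_pdb(atoms):
    lines = [pdb_line(i + 1, *a) for i, a in enumerate(atoms)]
    return "\n".join(lines + ["END"]) + "\n"


def backbone_atoms(n_residues=5, chain="A", b=20.0, rng=None):
    """Non-collinear synthetic backbone trace: (name, res, chain, num, xyz...)."""
    rng = rng or np.random.default_rng(42)
    atoms = []
    for i in range(n_residues):
        base = np.array([3.8 * i, 0.4 * (-1) ** i, 0.15 * i])
        jitter = rng.normal(0, 0.2, (3, 3))
        for j, (name, offset) in enumerate([("N", [0, 0, 0]),
                                            ("CA", [1.46, 0.3, 0.1]),
                                            ("C", [2.2, 1.4, -0.2])]):
            xyz = base + np.array(offset) + jitter[j]
            el = name[0]
            atoms.append((name, "GLY", chain, i + 1, xyz, 1.0, b, el, False))
    return atoms


def protein_only_pdb(n_residues=5, seed=42):
    rng = np.random.default_rng(seed)
    return build_pdb(backbone_atoms(n_residues, rng=rng))


def rigid_transform(atoms, rotation, translation):
    moved = []
    for a in atoms:
        name, res, chain, num, xyz, occ, b, el, het = a
        moved.append((name, res, chain, num,
                      rotation @ np.asarray(xyz) + translation, occ, b, el, het))
    return moved


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def contact_complex_pdb():
    """Protein fragment + LIG ligand with exactly placed interaction partners.

    Layout (distances in Å, all along axes so they are exact):
      - protein backbone N of residue 1 at origin; ligand O1 at x=3.2
        -> one H-bond candidate (3.2 <= 3.3)
      - ligand O2 at x=3.4 from that N and farther from every other polar
        atom -> no candidate
      - Cys-like SG at (0, 6, 0); ligand S1 at (0, 8.05, 0), d=2.05
        -> covalently bonded (S-S), excluded despite being polar and close
      - Ala-like CB (only neighbour CA, a carbon) at (10, 0, 0); ligand CM1
        at (14.0, 0, 0), d=4.0 -> nonpolar contact
      - protein carbonyl C at (10, 5, 0) with O neighbour; ligand CM2 at
        (13.5, 5, 0), d=3.5 -> excluded (carbon with O neighbour)
      - ligand CM3 at (14.3, 0, 3) vs CB: d=sqrt(4.3^2+3^2)... placed at
        (10, -4.3, 0), d=4.3 -> outside the 4.2 cutoff
    """
    atoms = [
        # residue 1: N anchors the H-bond test; CA/C complete the backbone
        ("N", "GLY", "A", 1, (0.0, 0.0, 0.0), 1.0, 15.0, "N", False),
        ("CA", "GLY", "A", 1, (-1.46, 0.0, 0.0), 1.0, 15.0, "C", False),
        ("C", "GLY", "A", 1, (-2.2, -1.3, 0.0), 1.0, 15.0, "C", False),
        # Cys-like residue: SG covalently linked to ligand S1
        ("CA", "CYS", "A", 2, (0.0, 4.5, 0.0), 1.0, 18.0, "C", False),
        ("CB", "CYS", "A", 2, (0.0, 5.0, 1.4), 1.0, 18.0, "C", False),
        ("SG", "CYS", "A", 2, (0.0, 6.0, 0.0), 1.0, 18.0, "S", False),
        # Ala-like residue: CB is a hydrophobic carbon (only C neighbour)
        ("CA", "ALA", "A", 3, (10.0, 0.0, -1.5), 1.0, 22.0, "C", False),
        ("CB", "ALA", "A", 3, (10.0, 0.0, 0.0), 1.0, 22.0, "C", False),
        # carbonyl-like carbon with an O neighbour: not hydrophobic
        ("C", "SER", "A", 4, (10.0, 5.0, 0.0), 1.0, 25.0, "C", False),
        ("O", "SER", "A", 4, (10.0, 5.0, 1.23), 1.0, 25.0, "O", False),
        # ligand
        ("O1", "LIG", "L", 100, (3.2, 0.0, 0.0), 1.0, 30.0, "O", True),
        ("O2", "LIG", "L", 100, (3.4, 0.0, 0.0), 1.0, 31.0, "O", True),
        ("S1", "LIG", "L", 100, (0.0, 8.05, 0.0), 1.0, 32.0, "S", True),
        ("CM1", "LIG", "L", 100, (14.0, 0.0, 0.0), 1.0, 45.0, "C", True),
        ("CM2", "LIG", "L", 100, (13.5, 5.0, 0.0), 1.0, 60.0, "C", True),
        ("CM3", "LIG", "L", 100, (10.0, -4.3, 0.0), 1.0, 80.0, "C", True),
    ]
    return build_pdb(atoms)


def ligand_complex_pdb(ligand_shift=(0.0, 0.0, 0.0), seed=42, ligand_b=None):
    """Backbone protein plus a 4-atom LIG ligand, optionally shifted."""
    rng = np.random.default_rng(seed)
    atoms = backbone_atoms(5, rng=rng)
    shift = np.asarray(ligand_shift, dtype=float)
    lig = [
        ("C1", (2.0, 5.0, 2.0), "C"),
        ("C2", (3.5, 5.2, 2.1), "C"),
        ("N1", (4.3, 6.3, 2.0), "N"),
        ("O1", (2.2, 6.9, 3.1), "O"),
    ]
    bs = ligand_b or [20.0] * len(lig)
    for (name, xyz, el), b in zip(lig, bs):
        atoms.append((name, "LIG", "L", 200, np.asarray(xyz) + shift,
                      1.0, b, el, True))
    return build_pdb(atoms)
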