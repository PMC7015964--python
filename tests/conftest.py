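import numpy as np
import pytest

from kinetic_ensemble.structures import Atom, Conformer, Ensemble


def _dipeptide_atoms_coords(rng):
    """ALA-PHE dipeptide hydrogens (plus a few heavies) with plausible
    geometry: an ALA methyl and a PHE ring with its four ring hydrogens."""
    entries = [
        # resnum, resname, atomname, xyz
        (1, "ALA", "CA", (0.0, 0.0, 0.0)),
        (1, "ALA", "HA", (0.5, 0.9, 0.0)),
        (1, "ALA", "CB", (1.0, -1.0, 0.5)),
        (1, "ALA", "HB1", (1.9, -0.6, 0.9)),
        (1, "ALA", "HB2", (1.3, -1.7, -0.3)),
        (1, "ALA", "HB3", (0.5, -1.6, 1.3)),
        (2, "PHE", "CA", (3.5, 1.0, 0.0)),
        (2, "PHE", "HA", (3.0, 1.9, 0.3)),
        (2, "PHE", "HB2", (4.4, 0.3, 1.8)),
        (2, "PHE", "HB3", (5.0, 1.5, 0.9)),
        (2, "PHE", "HD1", (5.6, -1.0, -0.5)),
        (2, "PHE", "HD2", (4.6, 2.0, -2.2)),
        (2, "PHE", "HE1", (7.2, -1.3, -2.2)),
        (2, "PHE", "HE2", (6.2, 1.7, -3.9)),
    ]
    atoms = [Atom("A", num, res, name) for num, res, name, _ in entries]
    coords = np.array([xyz for *_, xyz in entries], dtype=float)
    return atoms, coords


@pytest.fixture
def dipeptide_ensemble():
    """Three-member ALA-PHE ensemble with small random displacements."""
    rng = np.random.default_rng(42)
    atoms, base = _dipeptide_atoms_coords(rng)
    conformers = [
        Conformer(f"m{i}", atoms, base + rng.normal(0, 0.15, base.shape))
        for i in range(3)
    ]
    from kinetic_ensemble.structures import detect_rotation_groups
    ens = Ensemble(conformers)
    ens.rotation_groups = detect_rotation_groups(ens)
    return ens


ALTLOC_PDB = """\
MODEL        1
ATOM      1  H1  SYN A   1       0.000   0.000   0.000  1.00  0.00           H
ATOM      2  H2 ASYN A   2       1.700   0.000   0.000  0.60  0.00           H
ATOM      3  H2 BSYN A   2       2.500   0.000   0.000  0.40  0.00           H
ATOM      4  H3  SYN A   3       0.000   2.000   0.000  1.00  0.00           H
ENDMDL
END
"""

MISMATCH_PDB = """\
MODEL        1
ATOM      1  H1  SYN A   1       0.000   0.000   0.000  1.00  0.00           H
ATOM      2  H2  SYN A   2       1.700   0.000   0.000  1.00  0.00           H
ENDMDL
MODEL        2
ATOM      1  H1  SYN A   1       0.000   0.000   0.000  1.00  0.00           H
ENDMDL
END
"""
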