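"""Structural ensembles: PDB I/O, rotation groups, toy systems, fixtures.

An :class:`Ensemble` is an ordered set of conformers sharing one atom roster,
with equilibrium populations and optional annotations: methyl/aromatic
rotation groups (magnetically equivalent hydrogens exchanged by fast
rotation) and a member partition into named kinetic groups (e.g. pincer
open/closed) used by the hierarchical exchange scheme.

Atom identifiers are strings ``"<chain>.<resnum><resname>.<atomname>"``
(e.g. ``"A.13ILE.HG21"``), unique within a conformer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import gemmi

from . import dipolar

logger = logging.getLogger(__name__)

# Hydrogens of auto-detected rotation groups, by residue name.
# Methyls rotate with 3-fold symmetry; PHE/TYR rings flip with 2-fold
# symmetry exchanging HD1<->HD2 and HE1<->HE2 jointly.
_METHYLS = {
    "ALA": [("HB1", "HB2", "HB3")],
    "VAL": [("HG11", "HG12", "HG13"), ("HG21", "HG22", "HG23")],
    "LEU": [("HD11", "HD12", "HD13"), ("HD21", "HD22", "HD23")],
    "ILE": [("HG21", "HG22", "HG23"), ("HD11", "HD12", "HD13")],
    "THR": [("HG21", "HG22", "HG23")],
    "MET": [("HE1", "HE2", "HE3")],
}
_AROMATICS = {
    "PHE": (("HD1", "HD2"), ("HE1", "HE2")),
    "TYR": (("HD1", "HD2"), ("HE1", "HE2")),
}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    name: str

    @property
    def atom_id(self) -> str:
        return f"{self.chain}.{self.res_number}{self.res_name}.{self.name}"

    @property
    def is_hydrogen(self) -> bool:
        return self.name.startswith("H") or (
            len(self.name) > 1 and self.name[0].isdigit() and self.name[1] == "H")


@dataclass
class Conformer:
    """One ensemble member: an id, the shared roster, and its coordinates (Å)."""

    id: str
    atoms: list[Atom]
    coords: np.ndarray
    occupancy_weight: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom ids within conformer")


@dataclass
class RotationGroup:
    """A set of hydrogens exchanged by methyl rotation or an aromatic flip."""

    kind: str  # "methyl" | "aromatic"
    symmetry_order: int
    member_atom_ids: list[str]
    permutation: dict[str, str]  # one rotation step

    def __post_init__(self) -> None:
        # the cyclic relabeling must have exactly the stated order
        perm = self.permutation
        for a in self.member_atom_ids:
            x = a
            for _ in range(self.symmetry_order):
                x = perm[x]
            if x != a:
                raise ValueError("permutation order does not match symmetry order")


@dataclass
class Ensemble:
    """Ordered conformers with populations and rotation-group annotations."""

    conformers: list[Conformer]
    populations: np.ndarray = None
    rotation_groups: list[RotationGroup] = field(default_factory=list)
    group_labels: np.ndarray = None  # member -> kinetic group index, optional

    def __post_init__(self) -> None:
        n = len(self.conformers)
        if n == 0:
            raise ValueError("ensemble must have at least one conformer")
        roster = [a.atom_id for a in self.conformers[0].atoms]
        for c in self.conformers[1:]:
            other = [a.atom_id for a in c.atoms]
            if other != roster:
                missing = set(roster) ^ set(other)
                raise ValueError(
                    f"inconsistent atom rosters across conformers "
                    f"({self.conformers[0].id} vs {c.id}); differing atoms: "
                    f"{sorted(missing)}")
        if self.populations is None:
            w = np.array([c.occupancy_weight for c in self.conformers], dtype=float)
            self.populations = w / w.sum()
        else:
            self.populations = np.asarray(self.populations, dtype=float)
            if self.populations.shape != (n,):
                raise ValueError("populations must have one entry per conformer")
            if np.any(self.populations < 0) or not math.isclose(
                    self.populations.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("populations must be nonnegative and sum to 1")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if self.group_labels.shape != (n,):
                raise ValueError("group labels must have one entry per conformer")

    @property
    def n_members(self) -> int:
        return len(self.conformers)

    @property
    def atoms(self) -> list[Atom]:
        return self.conformers[0].atoms

    @property
    def atom_ids(self) -> list[str]:
        return [a.atom_id for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """All coordinates, shape (n_members, n_atoms, 3)."""
        return np.stack([c.coords for c in self.conformers])

    def atom_index(self, atom_id: str) -> int:
        try:
            return self.atom_ids.index(atom_id)
        except ValueError:
            raise KeyError(f"atom {atom_id!r} not found in ensemble roster") from None

    def rotation_group_of(self, atom_id: str) -> RotationGroup | None:
        for g in self.rotation_groups:
            if atom_id in g.member_atom_ids:
                return g
        return None

    def subset(self, mask: np.ndarray) -> "Ensemble":
        """Subensemble of the members where ``mask`` is True, re-normalized."""
        mask = np.asarray(mask, dtype=bool)
        members = [c for c, m in zip(self.conformers, mask) if m]
        pi = self.populations[mask]
        labels = self.group_labels[mask] if self.group_labels is not None else None
        return Ensemble(members, pi / pi.sum(), self.rotation_groups, labels)


@dataclass
class SpinPairGeometry:
    """Per-state internuclear vectors (Å) for one proton pair."""

    vectors: np.ndarray
    populations: np.ndarray = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.populations is None:
            n = self.vectors.shape[0]
            self.populations = np.full(n, 1.0 / n)
        else:
            self.populations = np.asarray(self.populations, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("internuclear distances must be positive")

    @property
    def n_states(self) -> int:
        return self.vectors.shape[0]

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def dipole_vectors(self) -> np.ndarray:
        return dipolar.dipole_vector(self.vectors)


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def read_pdb_ensemble(path, model_selection="all") -> Ensemble:
    """Read a multi-model PDB file into an Ensemble.

    Each MODEL becomes a conformer; where alternate locations are present,
    each altloc label is expanded into a full conformer carrying all
    non-altloc atoms plus that altloc set, weighted by its occupancy.
    Structures must already carry hydrogens; no protonation is attempted.
    """
    st = gemmi.read_structure(str(path))
    models = list(st)
    if model_selection != "all":
        wanted = {str(m) for m in model_selection}
        models = [m for m in models if str(m.num) in wanted or m.name in wanted]
        if not models:
            raise ValueError(f"no models matched selection {model_selection!r}")

    conformers: list[Conformer] = []
    for model in models:
        base: list[tuple[Atom, np.ndarray]] = []
        alt: dict[str, list[tuple[Atom, np.ndarray, float]]] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    a = Atom(chain.name, res.seqid.num, res.name, atom.name)
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if atom.altloc in ("", "\x00"):
                        base.append((a, pos))
                    else:
                        alt.setdefault(atom.altloc, []).append((a, pos, atom.occ))
        if not alt:
            atoms = [a for a, _ in base]
            coords = np.array([p for _, p in base])
            conformers.append(Conformer(f"model{model.num}", atoms, coords))
        else:
            for label in sorted(alt):
                entries = base + [(a, p) for a, p, _ in alt[label]]
                # keep original file order: altloc atoms interleave by id
                atoms = [a for a, _ in entries]
                coords = np.array([p for _, p in entries])
                occ = float(np.mean([o for _, _, o in alt[label]]))
                conformers.append(
                    Conformer(f"model{model.num}.{label}", atoms, coords,
                              occupancy_weight=occ))
    ens = Ensemble(conformers)
    ens.rotation_groups = detect_rotation_groups(ens)
    return ens


def write_pdb_ensemble(ensemble: Ensemble, path) -> None:
    """Write the ensemble as a multi-model PDB file (one MODEL per member)."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for i, conf in enumerate(ensemble.conformers, start=1):
        model = gemmi.Model(i)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple, gemmi.Residue] = {}
        for atom, xyz in zip(conf.atoms, conf.coords):
            if atom.chain not in chains:
                chains[atom.chain] = gemmi.Chain(atom.chain)
            key = (atom.chain, atom.res_number, atom.res_name)
            if key not in residues:
                res = gemmi.Residue()
                res.name = atom.res_name
                res.seqid = gemmi.SeqId(atom.res_number, " ")
                chains[atom.chain].add_residue(res)
                residues[key] = chains[atom.chain][-1]
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.pos = gemmi.Position(*xyz)
            ga.occ = conf.occupancy_weight
            ga.element = gemmi.Element("H" if atom.is_hydrogen else atom.name[0])
            residues[key].add_atom(ga)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def require_hydrogens(ensemble: Ensemble, atom_ids) -> None:
    """Raise if any requested atom is absent or is not a hydrogen."""
    bad = []
    known = set(ensemble.atom_ids)
    for aid in atom_ids:
        if aid not in known:
            bad.append(f"{aid} (missing)")
        else:
            atom = ensemble.atoms[ensemble.atom_index(aid)]
            if not atom.is_hydrogen:
                bad.append(f"{aid} (not a hydrogen)")
    if bad:
        raise ValueError("requested atoms unavailable for NOE calculation: "
                         + ", ".join(bad))


# --------------------------------------------------------------------------
# Rotation-group detection
# --------------------------------------------------------------------------

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def detect_rotation_groups(ensemble: Ensemble) -> list[RotationGroup]:
    """Find methyl (3-fold) and PHE/TYR ring (2-fold) hydrogen groups.

    Only CH3 methyls and aromatic ring flips are detected; solvent
    exchangeable groups such as LYS NH3+ are deliberately excluded.
    Nonstandard residues are skipped with a warning.
    """
    by_residue: dict[tuple, dict[str, str]] = {}
    for atom in ensemble.atoms:
        key = (atom.chain, atom.res_number, atom.res_name)
        by_residue.setdefault(key, {})[atom.name] = atom.atom_id

    groups: list[RotationGroup] = []
    for (chain, num, resname), names in by_residue.items():
        if resname not in _STANDARD_RESIDUES:
            logger.warning("skipping nonstandard residue %s %s%d in rotation-group "
                           "detection", resname, chain, num)
            continue
        for triple in _METHYLS.get(resname, []):
            if all(n in names for n in triple):
                ids = [names[n] for n in triple]
                perm = {ids[0]: ids[1], ids[1]: ids[2], ids[2]: ids[0]}
                groups.append(RotationGroup("methyl", 3, ids, perm))
        if resname in _AROMATICS:
            (d1, d2), (e1, e2) = _AROMATICS[resname]
            if all(n in names for n in (d1, d2, e1, e2)):
                ids = [names[n] for n in (d1, d2, e1, e2)]
                perm = {ids[0]: ids[1], ids[1]: ids[0],
                        ids[2]: ids[3], ids[3]: ids[2]}
                groups.append(RotationGroup("aromatic", 2, ids, perm))
    return groups


# --------------------------------------------------------------------------
# Toy systems and synthetic fixtures
# --------------------------------------------------------------------------

def _two_site_angle(s2: float) -> float:
    """Jump angle giving order parameter s2 for a symmetric two-site jump,
    from S^2 = (1 + 3 cos^2 theta)/4."""
    if not 0.25 <= s2 <= 1.0:
        raise ValueError("two-site order parameter must lie in [0.25, 1]")
    return math.acos(math.sqrt((4.0 * s2 - 1.0) / 3.0))


def build_emf_toy(s_f2: float, s_s2: float) -> SpinPairGeometry:
    """Four-state planar toy reproducing extended model free dynamics.

    Two macrostates, each of two microstates separated by the fast jump
    angle theta_f (set so each macrostate's order parameter is ``s_f2``);
    the macrostate mean orientations are separated by theta_s, solved
    numerically so the overall order parameter equals ``s_f2 * s_s2``.
    States are ordered [macro1a, macro1b, macro2a, macro2b] to match the
    hierarchical generator with group sizes [2, 2].  All vectors are unit
    length (fixed bond distance), in the xy-plane.
    """
    if not 0.25 <= s_f2 <= 1.0:
        raise ValueError("s_f2 must lie in [0.25, 1] for a planar two-site jump")
    target = s_f2 * s_s2
    if target < 0.25 - 1e-12:
        raise ValueError("overall order parameter below the planar two-site limit")
    theta_f = _two_site_angle(s_f2)

    def vectors(theta_s: float) -> np.ndarray:
        angles = np.array([
            -theta_s / 2 - theta_f / 2, -theta_s / 2 + theta_f / 2,
            +theta_s / 2 - theta_f / 2, +theta_s / 2 + theta_f / 2,
        ])
        return np.stack([np.cos(angles), np.sin(angles), np.zeros(4)], axis=1)

    def overall(theta_s: float) -> float:
        return dipolar.order_parameter(vectors(theta_s))

    if abs(overall(0.0) - target) < 1e-13:
        return SpinPairGeometry(vectors(0.0))
    # bisection to 1e-12 on the overall order parameter; S^2 decreases
    # from s_f2 as theta_s opens
    lo, hi = 0.0, math.pi / 2
    if overall(hi) > target + 1e-12:
        raise ValueError("target order parameter not reachable within the "
                         "planar construction")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if overall(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    return SpinPairGeometry(vectors(0.5 * (lo + hi)))


def build_two_distance_toy(r_a: float, r_b: float, p_a: float) -> SpinPairGeometry:
    """Two collinear states differing only in distance (r_a, r_b; Å) with
    populations (p_a, 1 - p_a)."""
    if r_a <= 0 or r_b <= 0:
        raise ValueError("distances must be positive")
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("p_a must lie in [0, 1]")
    vectors = np.array([[0.0, 0.0, r_a], [0.0, 0.0, r_b]])
    return SpinPairGeometry(vectors, np.array([p_a, 1.0 - p_a]))


def generate_synthetic_ensemble(n_members: int, n_protons: int,
                                displacement_scale: float, seed: int) -> Ensemble:
    """Deterministic synthetic proton ensemble for testing.

    A base arrangement of ``n_protons`` is drawn with minimum separation
    2.2 Å inside a cube sized for ~30 Å^3 per proton; each member applies
    independent Gaussian displacements of the given scale (Å), resampled
    until all pairwise distances stay >= 1.5 Å.  Atom ids are
    ``"A.<i>SYN.H"``; no rotation groups are present.
    """
    if n_members < 1 or n_protons < 2:
        raise ValueError("need at least 1 member and 2 protons")
    rng = np.random.default_rng(seed)
    side = (30.0 * n_protons) ** (1.0 / 3.0)
    base = np.empty((n_protons, 3))
    placed = 0
    while placed < n_protons:
        cand = rng.uniform(0.0, side, 3)
        if placed == 0 or np.min(np.linalg.norm(base[:placed] - cand, axis=1)) >= 2.2:
            base[placed] = cand
            placed += 1

    atoms = [Atom("A", i + 1, "SYN", "H") for i in range(n_protons)]
    conformers = []
    for m in range(n_members):
        for _ in range(1000):
            coords = base + rng.normal(0.0, displacement_scale, (n_protons, 3)) \
                if displacement_scale > 0 else base.copy()
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            if dist.min() >= 1.5:
                break
        else:
            raise RuntimeError("could not place member with all distances >= 1.5 Å")
        conformers.append(Conformer(f"member{m}", atoms, coords))
    return Ensemble(conformers)
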