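"""Solomon relaxation matrix and NOESY buildup curves.

Pair spectral densities feed the homonuclear Solomon rates

    rho_i    = K * sum_j [ J_ij(0) + 3 J_ij(w0) + 6 J_ij(2 w0) ]
    sigma_ij = K * [ 6 J_ij(2 w0) - J_ij(0) ],    K = (1/10)(mu0/4pi)^2 hbar^2 gamma_H^4

with J in SI units (m^-6 s; the Å^-6 normalization of the kinetic-ensemble
J already carries the r^-6 distance dependence).  Magnetization transfer
over a mixing time is ``T(tau_m) = exp(-tau_m R)`` in the deviation-from-
equilibrium picture; theoretical NOE intensities between pseudoatoms
(groups of magnetically indistinguishable protons, Q notation) are block
sums of T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dipolar, kinetics
from .spectral import PairSpectral, pair_spectral, spectral_density
from .structures import Ensemble, RotationGroup

MU0_4PI = 1e-7                   # T m / A
GAMMA_H = 2.6752218744e8         # rad s^-1 T^-1
HBAR = 1.054571817e-34           # J s
# (1/10) (mu0/4pi)^2 hbar^2 gamma^4, in m^6 s^-2
SOLOMON_K = 0.1 * (MU0_4PI * HBAR * GAMMA_H ** 2) ** 2
ANG6_TO_M6 = 1e-60               # Å^6 -> m^6  (J scales by its inverse)

DEFAULT_CUTOFF = 5.5             # Å, on the ensemble-minimum pair distance
DEFAULT_MIXING_TIMES = np.arange(5e-3, 500.1e-3, 15e-3)  # 5-500 ms, 15 ms steps


@dataclass
class SpinSystem:
    """Protons, their pseudoatom grouping, and the spectrometer frequency."""

    spins: list[str]                      # atom ids
    groups: dict[str, list[str]]          # pseudoatom label -> spin ids
    omega0: float                         # proton Larmor frequency, rad/s

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            for m in members:
                if m in seen:
                    raise ValueError(f"spin {m} appears in more than one pseudoatom")
                if m not in self.spins:
                    raise ValueError(f"pseudoatom {label} references unknown spin {m}")
                seen.add(m)
        if seen != set(self.spins):
            raise ValueError("every spin must belong to exactly one pseudoatom group")

    @property
    def n_spins(self) -> int:
        return len(self.spins)

    def spin_index(self, atom_id: str) -> int:
        return self.spins.index(atom_id)


def pseudoatom_label(atom_id: str, group: RotationGroup | None) -> str:
    """Q-notation label: methyl HG21/HG22/HG23 -> QG2; ring HD1/HD2 -> QD."""
    prefix, name = atom_id.rsplit(".", 1)
    if group is None:
        return atom_id
    if group.kind == "methyl":
        return f"{prefix}.Q{name[1:-1]}"
    # aromatic: the indistinguishable pair is HD1/HD2 (or HE1/HE2)
    return f"{prefix}.Q{name[1:-1]}"


def build_spin_system(ensemble: Ensemble, spectrometer_mhz: float = 900.0,
                      spins: list[str] | None = None) -> SpinSystem:
    """All hydrogens of the ensemble, grouped into pseudoatoms by rotation
    group membership (methyls as one Q group; each aromatic HD/HE pair its
    own Q group; everything else a singleton)."""
    if spins is None:
        spins = [a.atom_id for a in ensemble.atoms if a.is_hydrogen]
    groups: dict[str, list[str]] = {}
    for aid in spins:
        label = pseudoatom_label(aid, ensemble.rotation_group_of(aid))
        groups.setdefault(label, []).append(aid)
    omega0 = 2.0 * np.pi * spectrometer_mhz * 1e6
    return SpinSystem(spins, groups, omega0)


# --------------------------------------------------------------------------
# Pair spectra with rotation expansion
# --------------------------------------------------------------------------

def _perm_power(group: RotationGroup, atom_id: str, r: int) -> str:
    out = atom_id
    for _ in range(r):
        out = group.permutation.get(out, out)
    return out


def _rotation_structure(group: RotationGroup) -> kinetics.SpectralStructure:
    name = "tau_methyl" if group.kind == "methyl" else "tau_aromatic"
    return kinetics.rotation_structure(group.symmetry_order, name)


def expanded_pair_states(ensemble: Ensemble, scheme: kinetics.KineticScheme,
                         aid1: str, aid2: str
                         ) -> tuple[np.ndarray, kinetics.SpectralStructure]:
    """Internuclear vectors over the (rotation-expanded) state space of a pair.

    Methyl/aromatic rotation is an independent exchange process, so the state
    space is the Kronecker product of ensemble members with each involved
    rotation group's states (the relabeled-atom enumeration).  A pair inside
    one group shares a single rotation process; a pair spanning two groups is
    expanded over the product of both (9 states per member for methyl-methyl).
    Returns the per-state vectors (Å) and the matching symbolic spectral
    structure.
    """
    g1 = ensemble.rotation_group_of(aid1)
    g2 = ensemble.rotation_group_of(aid2)
    coords = ensemble.coords
    idx = {a: i for i, a in enumerate(ensemble.atom_ids)}
    base = scheme.member_structure(ensemble.n_members, ensemble.group_labels)
    base.populations = ensemble.populations

    if g1 is None and g2 is None:
        vecs = coords[:, idx[aid1], :] - coords[:, idx[aid2], :]
        return vecs, base

    if g1 is g2 and g1 is not None:
        # both protons relabel jointly under the one rotation
        order = g1.symmetry_order
        structure = kinetics.kron_structure(base, _rotation_structure(g1))
        vecs = []
        for m in range(ensemble.n_members):
            for r in range(order):
                p1 = coords[m, idx[_perm_power(g1, aid1, r)], :]
                p2 = coords[m, idx[_perm_power(g1, aid2, r)], :]
                vecs.append(p1 - p2)
        return np.array(vecs), structure

    structure = base
    rotations: list[tuple[RotationGroup | None, str]] = []
    for g, aid in ((g1, aid1), (g2, aid2)):
        if g is not None:
            structure = kinetics.kron_structure(structure, _rotation_structure(g))
        rotations.append((g, aid))
    o1 = g1.symmetry_order if g1 is not None else 1
    o2 = g2.symmetry_order if g2 is not None else 1
    vecs = []
    for m in range(ensemble.n_members):
        for r1 in range(o1):
            a1 = _perm_power(g1, aid1, r1) if g1 is not None else aid1
            for r2 in range(o2):
                a2 = _perm_power(g2, aid2, r2) if g2 is not None else aid2
                vecs.append(coords[m, idx[a1], :] - coords[m, idx[a2], :])
    return np.array(vecs), structure


def pair_spectra(ensemble: Ensemble, scheme: kinetics.KineticScheme, tau_c: float,
                 system: SpinSystem, cutoff: float = DEFAULT_CUTOFF
                 ) -> dict[tuple[str, str], PairSpectral]:
    """Pair spectral descriptions for every proton pair within the distance
    cutoff (applied to the ensemble-minimum distance)."""
    spectra: dict[tuple[str, str], PairSpectral] = {}
    timescales = scheme.timescales()
    coords = ensemble.coords
    idx = {a: i for i, a in enumerate(ensemble.atom_ids)}
    for i, a1 in enumerate(system.spins):
        for a2 in system.spins[i + 1:]:
            dmin = np.min(np.linalg.norm(coords[:, idx[a1], :] - coords[:, idx[a2], :],
                                         axis=1))
            if dmin > cutoff:
                continue
            vecs, structure = expanded_pair_states(ensemble, scheme, a1, a2)
            d = dipolar.dipole_vector(vecs)
            a = dipolar.averaged_prefactors(d, structure)
            rates = structure.decay_rates(timescales)
            coeffs = tuple(m.rate_coeffs for m in structure.modes)
            spectra[(a1, a2)] = PairSpectral(a, rates, tau_c, coeffs)
    return spectra


# --------------------------------------------------------------------------
# Relaxation matrix and buildups
# --------------------------------------------------------------------------

def solomon_rates(ps: PairSpectral, omega0: float) -> tuple[float, float]:
    """(auto, cross) relaxation contributions of one pair, in s^-1."""
    j = np.asarray(spectral_density(ps, np.array([0.0, omega0, 2.0 * omega0])))
    j = j / ANG6_TO_M6  # Å^-6 s -> m^-6 s
    rho = SOLOMON_K * (j[0] + 3.0 * j[1] + 6.0 * j[2])
    sigma = SOLOMON_K * (6.0 * j[2] - j[0])
    return float(rho), float(sigma)


def relaxation_matrix(spectra: dict[tuple[str, str], PairSpectral],
                      system: SpinSystem) -> np.ndarray:
    """Symmetric Solomon matrix R (s^-1): auto rates on the diagonal, cross
    rates off-diagonal.  Pairs absent from ``spectra`` contribute nothing
    (they are beyond the distance cutoff)."""
    n = system.n_spins
    index = {aid: i for i, aid in enumerate(system.spins)}
    R = np.zeros((n, n))
    for (a1, a2), ps in spectra.items():
        i, j = index[a1], index[a2]
        rho, sigma = solomon_rates(ps, system.omega0)
        R[i, j] += sigma
        R[j, i] += sigma
        R[i, i] += rho
        R[j, j] += rho
    return R


def transfer_matrices(R: np.ndarray, mixing_times: np.ndarray) -> np.ndarray:
    """T(tau_m) = exp(-tau_m R) for every mixing time, via eigendecomposition
    of the symmetric R.  Shape (n_times, n, n); T(0) is the identity."""
    w, U = np.linalg.eigh(R)
    mts = np.asarray(mixing_times, dtype=float)
    return np.einsum("ik,tk,jk->tij", U, np.exp(-np.outer(mts, w)), U)


def buildup_curves(R: np.ndarray, system: SpinSystem,
                   mixing_times: np.ndarray) -> pd.DataFrame:
    """Theoretical buildups: summed fractional magnetization transfer for every
    ordered pseudoatom pair at every mixing time."""
    mts = np.asarray(mixing_times, dtype=float)
    if np.any(mts < 0):
        raise ValueError("mixing times must be nonnegative")
    T = transfer_matrices(R, mts)
    index = {aid: i for i, aid in enumerate(system.spins)}
    labels = list(system.groups)
    rows = []
    for gi in labels:
        ii = [index[a] for a in system.groups[gi]]
        for gj in labels:
            jj = [index[a] for a in system.groups[gj]]
            block = T[:, ii][:, :, jj].sum(axis=(1, 2))
            for mt, val in zip(mts, block):
                rows.append((gi, gj, mt * 1e3, val))
    return pd.DataFrame(rows, columns=["group1", "group2", "mixing_time_ms",
                                       "intensity"])


def simulate_buildup_table(ensemble: Ensemble, scheme: kinetics.KineticScheme,
                           tau_c: float,
                           mixing_times: np.ndarray = DEFAULT_MIXING_TIMES,
                           noise_sd: float = 0.0, seed: int = 0,
                           spectrometer_mhz: float = 900.0,
                           cutoff: float = DEFAULT_CUTOFF,
                           replicates: int = 1) -> pd.DataFrame:
    """Forward-simulated NOE table (cross peaks only) with multiplicative
    Gaussian noise of fractional width ``noise_sd``; deterministic per seed."""
    system = build_spin_system(ensemble, spectrometer_mhz)
    spectra = pair_spectra(ensemble, scheme, tau_c, system, cutoff)
    R = relaxation_matrix(spectra, system)
    curves = buildup_curves(R, system, mixing_times)
    cross = curves[curves.group1 < curves.group2].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    tables = []
    for rep in range(replicates):
        t = cross.copy()
        t["replicate"] = rep
        if noise_sd > 0:
            t["intensity"] = t["intensity"] * (
                1.0 + rng.normal(0.0, noise_sd, len(t)))
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


# --------------------------------------------------------------------------
# Buildup-table TSV dialect
# --------------------------------------------------------------------------

def read_buildup_table(path) -> pd.DataFrame:
    """Read a buildup TSV (group1, group2, mixing_time_ms, intensity
    [, replicate]); a missing replicate column is filled with 0."""
    df = pd.read_csv(path, sep="\t")
    required = {"group1", "group2", "mixing_time_ms", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"buildup table missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def write_buildup_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
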