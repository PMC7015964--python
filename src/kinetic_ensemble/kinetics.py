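"""Transition-rate matrices over ensemble states and their spectral structure.

Internal motion is modelled as a continuous-time Markov jump process on the
members of a structural ensemble.  The generator ``Q`` (rates in s^-1, rows
summing to zero) determines the internal correlation function of every
dipole-dipole interaction through its eigendecomposition: each unique
eigenvalue ``lambda_k <= 0`` contributes one exponential decay, and its
spectral projector ``A_lambda`` determines the exponential prefactor.

Two routes to the projectors are provided:

* a general numeric route via eigendecomposition (``spectral_structure``),
  valid for any irreducible generator but O(s^3);
* a fast symbolic route for the structured generators used here (uniform
  jump, two-level hierarchy, methyl/aromatic rotation, and Kronecker sums
  thereof), where each projector is an integer combination of
  block-partition matrices and prefactors cost O(s) per eigenvalue.

Both routes are kept and cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


# --------------------------------------------------------------------------
# Rate matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMatrix:
    """Markov generator ``Q`` (s^-1) with its stationary distribution."""

    Q: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        pi = np.asarray(self.populations, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "populations", pi)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if pi.shape != (Q.shape[0],):
            raise ValueError("populations must match Q")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12 * max(1.0, np.abs(Q).max())):
            raise ValueError("off-diagonal rates must be nonnegative")
        scale = max(1.0, np.abs(Q).max())
        if np.any(np.abs(Q.sum(axis=1)) > 1e-12 * scale):
            raise ValueError("rows of Q must sum to zero")

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def propagator(self, tau: float) -> np.ndarray:
        """Transition probabilities ``P(tau) = exp(tau Q)``."""
        return scipy.linalg.expm(tau * self.Q)


def uniform_jump_matrix(n: int, tau_ensemble: float) -> RateMatrix:
    """N-site jump model: every individual rate equals ``1/(N tau_ensemble)``.

    The eigenvalues are one 0 and ``n - 1`` degenerate copies of
    ``-1/tau_ensemble``, so a single parameter sets the exchange timescale
    regardless of ensemble size.
    """
    if n < 2:
        raise ValueError("uniform jump model needs at least 2 states")
    if tau_ensemble <= 0:
        raise ValueError("tau_ensemble must be positive")
    k = 1.0 / (tau_ensemble * n)
    Q = np.full((n, n), k)
    np.fill_diagonal(Q, -k * (n - 1))
    return RateMatrix(Q, np.full(n, 1.0 / n))


def hierarchical_matrix(group_sizes, tau_slow: float, tau_fast: float) -> RateMatrix:
    """Two-level jump model: slow exchange between groups, fast within.

    Inter-group rates are ``tau_slow^-1 / N``; intra-group rates within
    group i of size ``N_i`` are ``(tau_fast^-1 - (1 - N_i/N) tau_slow^-1)/N_i``.
    The spectrum is exactly {0, -1/tau_slow, -1/tau_fast} with multiplicities
    1, (#groups - 1), (N - #groups).
    """
    sizes = [int(s) for s in group_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be positive")
    if tau_slow <= 0 or tau_fast <= 0:
        raise ValueError("timescales must be positive")
    n = sum(sizes)
    if len(sizes) == 1:
        return uniform_jump_matrix(n, tau_fast)
    k_inter = 1.0 / (tau_slow * n)
    Q = np.full((n, n), k_inter)
    start = 0
    for gi, size in enumerate(sizes):
        numer = 1.0 / tau_fast - (1.0 - size / n) / tau_slow
        if numer < 0:
            raise ValueError(
                f"group {gi} (size {size}): intra-group rate would be negative; "
                "requires tau_slow >= tau_fast"
            )
        k_intra = numer / size
        block = slice(start, start + size)
        Q[block, block] = k_intra
        start += size
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, np.full(n, 1.0 / n))


def rotation_rate_matrix(symmetry_order: int, tau_rot: float) -> RateMatrix:
    """Jump model for methyl (order 3) or aromatic ring (order 2) rotation.

    Individual rates are ``1/(order * tau_rot)`` so the nonzero eigenvalues
    all equal ``-1/tau_rot``.
    """
    if symmetry_order not in (2, 3):
        raise ValueError("symmetry order must be 2 or 3")
    if tau_rot <= 0:
        raise ValueError("tau_rot must be positive")
    return uniform_jump_matrix(symmetry_order, tau_rot)


def two_state_matrix(p_a: float, tau_ex: float) -> RateMatrix:
    """Asymmetric two-state exchange with populations ``(p_a, 1 - p_a)``.

    Rates ``k_AB = (1-p_a)/tau_ex`` and ``k_BA = p_a/tau_ex`` give the single
    nonzero eigenvalue ``-1/tau_ex`` at arbitrary populations.
    """
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("p_a must lie in [0, 1]")
    if tau_ex <= 0:
        raise ValueError("tau_ex must be positive")
    k_ab = (1.0 - p_a) / tau_ex
    k_ba = p_a / tau_ex
    Q = np.array([[-k_ab, k_ab], [k_ba, -k_ba]])
    return RateMatrix(Q, np.array([p_a, 1.0 - p_a]))


def kronecker_sum(a: RateMatrix, b: RateMatrix) -> RateMatrix:
    """Generator of two kinetically independent processes on the product space.

    ``Q_o = Q_a (+) Q_b = Q_a kron I + I kron Q_b``; eigenvalues are all
    pairwise sums and the stationary distribution is the outer product.
    """
    na, nb = a.n_states, b.n_states
    Q = np.kron(a.Q, np.eye(nb)) + np.kron(np.eye(na), b.Q)
    pi = np.kron(a.populations, b.populations)
    return RateMatrix(Q, pi)


# --------------------------------------------------------------------------
# Spectral structure: unique eigenvalues + prefactor recipes
# --------------------------------------------------------------------------

def partition_matrix(labels: np.ndarray) -> np.ndarray:
    """Group matrix G for a state partition: entry 1/N_block within blocks.

    Every row sums to 1; reordering states makes G block diagonal.
    """
    labels = np.asarray(labels)
    n = labels.size
    G = np.zeros((n, n))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        G[np.ix_(idx, idx)] = 1.0 / idx.size
    return G


@dataclass
class Mode:
    """One unique eigenvalue of a generator together with its projector recipe.

    ``rate_coeffs`` expresses the eigenvalue symbolically as
    ``lambda = -sum_t c_t / tau_t`` over named timescales; the zero eigenvalue
    has an empty dict.  ``recipe`` is a list of (partition labels, coefficient)
    pairs reproducing the projector as ``A = sum_i k_i G(labels_i)``; it is
    None for modes built on the general numeric path, in which case
    ``projector`` holds the explicit matrix.
    """

    rate_coeffs: dict[str, float]
    recipe: list[tuple[np.ndarray, float]] | None = None
    projector: np.ndarray | None = None
    eigenvalue: float | None = None  # numeric, for the general path

    def materialize(self) -> np.ndarray:
        if self.projector is not None:
            return self.projector
        return sum(k * partition_matrix(lab) for lab, k in self.recipe)

    def rate(self, timescales: dict[str, float]) -> float:
        if self.eigenvalue is not None:
            return self.eigenvalue
        return -sum(c / timescales[name] for name, c in self.rate_coeffs.items())


@dataclass
class SpectralStructure:
    """Unique eigenvalues of a generator and their prefactor machinery."""

    n_states: int
    modes: list[Mode]
    populations: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.populations is None:
            self.populations = np.full(self.n_states, 1.0 / self.n_states)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def decay_rates(self, timescales: dict[str, float]) -> np.ndarray:
        return np.array([m.rate(timescales) for m in self.modes])

    def projectors(self) -> list[np.ndarray]:
        return [m.materialize() for m in self.modes]


def spectral_structure(rm: RateMatrix, degeneracy_tol: float = 1e-8) -> SpectralStructure:
    """Numeric spectral structure by eigendecomposition (the general path).

    Eigenvalues are clustered at relative tolerance ``degeneracy_tol`` and the
    projector of each cluster is formed from the corresponding columns of V
    and rows of V^-1.  Raises if the generator is reducible (more than one
    vanishing eigenvalue).
    """
    Q = rm.Q
    n = Q.shape[0]
    if n == 1:
        return SpectralStructure(1, [Mode({}, projector=np.ones((1, 1)), eigenvalue=0.0)],
                                 rm.populations)
    w, V = scipy.linalg.eig(Q)
    Vinv = scipy.linalg.inv(V)
    w = w.real  # generators satisfying detailed balance have a real spectrum
    scale = max(np.abs(w).max(), 1e-300)
    order = np.argsort(-w)  # zero first, then increasingly fast decays
    w, V, Vinv = w[order], V[:, order], Vinv[order, :]

    clusters: list[list[int]] = [[0]]
    for i in range(1, n):
        if abs(w[i] - w[clusters[-1][0]]) <= degeneracy_tol * scale:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    if abs(w[0]) > degeneracy_tol * scale:
        raise ValueError("generator has no zero eigenvalue (not a rate matrix?)")
    if len(clusters[0]) > 1:
        raise ValueError("reducible rate matrix: multiple zero eigenvalues")

    modes = []
    for ci, idx in enumerate(clusters):
        lam = 0.0 if ci == 0 else float(np.mean(w[idx]))
        A = (V[:, idx] @ Vinv[idx, :]).real
        modes.append(Mode({}, projector=A, eigenvalue=lam))
    return SpectralStructure(n, modes, rm.populations)


# Fast symbolic structures for the schemes used in this package. ----------

def uniform_structure(n: int, name: str = "tau_ensemble") -> SpectralStructure:
    """Symbolic structure of the uniform N-site jump model."""
    all_one = np.zeros(n, dtype=int)
    singletons = np.arange(n)
    modes = [
        Mode({}, recipe=[(all_one, 1.0)]),
        Mode({name: 1.0}, recipe=[(singletons, 1.0), (all_one, -1.0)]),
    ]
    return SpectralStructure(n, modes)


def hierarchical_structure(group_labels: np.ndarray,
                           slow: str = "tau_pincer",
                           fast: str = "tau_ensemble") -> SpectralStructure:
    """Symbolic structure of the two-level hierarchical jump model.

    Uses the three nested partitions (all states, by group, singletons) with
    integer coefficients {+1, -1}; the projectors are
    A_0 = G_all, A_slow = G_group - G_all, A_fast = I - G_group.
    """
    labels = np.asarray(group_labels)
    n = labels.size
    if np.unique(labels).size < 2:
        return uniform_structure(n, fast)
    all_one = np.zeros(n, dtype=int)
    singletons = np.arange(n)
    modes = [
        Mode({}, recipe=[(all_one, 1.0)]),
        Mode({slow: 1.0}, recipe=[(labels, 1.0), (all_one, -1.0)]),
        Mode({fast: 1.0}, recipe=[(singletons, 1.0), (labels, -1.0)]),
    ]
    return SpectralStructure(n, modes)


def rotation_structure(order: int, name: str) -> SpectralStructure:
    """Symbolic structure of a methyl/aromatic rotation jump model."""
    return uniform_structure(order, name)


@dataclass
class KineticScheme:
    """Named exchange timescales and the rate-matrix construction they imply.

    With only ``tau_ensemble`` set, members exchange by the uniform N-site
    jump model.  With ``tau_pincer`` set (and a member partition on the
    ensemble), the two-level hierarchical model is used; it requires
    ``tau_pincer >= tau_ensemble`` so intra-group rates stay nonnegative.
    ``tau_methyl``/``tau_aromatic`` govern the independent rotation processes
    (defaults 1 ps and 100 µs).
    """

    tau_ensemble: float
    tau_pincer: float | None = None
    tau_methyl: float = 1e-12
    tau_aromatic: float = 1e-4

    def __post_init__(self) -> None:
        for name, val in self.timescales().items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_pincer is not None and self.tau_pincer < self.tau_ensemble:
            raise ValueError("hierarchical scheme requires tau_pincer >= tau_ensemble")

    def timescales(self) -> dict[str, float]:
        out = {"tau_ensemble": self.tau_ensemble,
               "tau_methyl": self.tau_methyl,
               "tau_aromatic": self.tau_aromatic}
        if self.tau_pincer is not None:
            out["tau_pincer"] = self.tau_pincer
        return out

    @property
    def free_names(self) -> list[str]:
        """Timescales the fitting module optimizes (rotations stay fixed)."""
        names = ["tau_ensemble"]
        if self.tau_pincer is not None:
            names.append("tau_pincer")
        return names

    def replace(self, **kwargs) -> "KineticScheme":
        params = {"tau_ensemble": self.tau_ensemble, "tau_pincer": self.tau_pincer,
                  "tau_methyl": self.tau_methyl, "tau_aromatic": self.tau_aromatic}
        params.update(kwargs)
        return KineticScheme(**params)

    def member_structure(self, n: int,
                         group_labels: np.ndarray | None = None) -> SpectralStructure:
        if self.tau_pincer is not None and group_labels is not None:
            return hierarchical_structure(group_labels)
        return uniform_structure(n)

    def member_rate_matrix(self, n: int,
                           group_labels: np.ndarray | None = None) -> RateMatrix:
        """Numeric generator over ensemble members (oracle path)."""
        if self.tau_pincer is not None and group_labels is not None:
            labels = np.asarray(group_labels)
            order = np.argsort(labels, kind="stable")
            if not np.array_equal(order, np.arange(n)):
                raise ValueError("group labels must be contiguous for the numeric "
                                 "hierarchical generator")
            sizes = [int(np.sum(labels == lab)) for lab in np.unique(labels)]
            return hierarchical_matrix(sizes, self.tau_pincer, self.tau_ensemble)
        return uniform_jump_matrix(n, self.tau_ensemble)


def kron_structure(a: SpectralStructure, b: SpectralStructure) -> SpectralStructure:
    """Spectral structure of a Kronecker sum from those of its operands.

    Eigenvalues add; projectors multiply (A kron B), which at the recipe level
    is the product partition with multiplied coefficients.  State ordering
    follows ``np.kron``: index = i * n_b + j.
    """
    nb = b.n_states
    n = a.n_states * nb
    merged: dict[tuple, Mode] = {}
    for ma in a.modes:
        for mb in b.modes:
            coeffs: dict[str, float] = dict(ma.rate_coeffs)
            for k, v in mb.rate_coeffs.items():
                coeffs[k] = coeffs.get(k, 0.0) + v
            key = tuple(sorted(coeffs.items()))
            if ma.recipe is not None and mb.recipe is not None:
                recipe = []
                for lab_a, ka in ma.recipe:
                    for lab_b, kb in mb.recipe:
                        lab = (np.repeat(lab_a, nb) * (np.max(lab_b) + 1)
                               + np.tile(lab_b, a.n_states))
                        recipe.append((lab, ka * kb))
                if key in merged:
                    merged[key].recipe.extend(recipe)
                else:
                    merged[key] = Mode(coeffs, recipe=recipe)
            else:
                A = np.kron(ma.materialize(), mb.materialize())
                lam = None
                if ma.eigenvalue is not None and mb.eigenvalue is not None:
                    lam = ma.eigenvalue + mb.eigenvalue
                if key in merged:
                    merged[key].projector = merged[key].materialize() + A
                else:
                    merged[key] = Mode(coeffs, projector=A, eigenvalue=lam)
    pi = np.kron(a.populations, b.populations)
    # zero mode (empty coeffs) first, then by total rate coefficient weight
    modes = [merged[k] for k in sorted(merged, key=lambda k: (len(k), k))]
    return SpectralStructure(n, modes, pi)
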