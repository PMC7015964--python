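"""Dipole-dipole interaction tensors and averaged exponential prefactors.

For a proton pair whose internuclear vector in state i is ``r_i`` (Å), the
traceless symmetric interaction tensor is

    D_i = (3 r_i r_i^T - r_i^2 I) / r_i^5        [Å^-3]

and the correlation strength between two states is
``c(s_i, s_j) = tr(D_i D_j)/6 = P2(cos theta_ij) / (r_i^3 r_j^3)``.  The
tensor is recast as a 5-vector ``d_i`` in the rank-2 spherical basis so that
``c(s_i, s_j) = d_i . d_j`` exactly; averaging the vectors over states then
commutes with taking the dot product, which is what makes the grouped
prefactor computation linear in the number of states.
"""

from __future__ import annotations

import numpy as np

from .kinetics import SpectralStructure

_SQRT3 = np.sqrt(3.0)


def dipole_matrix(vec: np.ndarray) -> np.ndarray:
    """3x3 Cartesian interaction tensor for one internuclear vector (Å)."""
    v = np.asarray(vec, dtype=float)
    r2 = v @ v
    if r2 <= 0:
        raise ValueError("zero-length internuclear vector")
    r5 = r2 ** 2.5
    return (3.0 * np.outer(v, v) - r2 * np.eye(3)) / r5


def dipole_vector(vec: np.ndarray) -> np.ndarray:
    """5-vector form of the interaction tensor; ``d_i . d_j = tr(D_i D_j)/6``.

    Components (before the common 1/r^5): [(3z^2 - r^2)/2, (sqrt3/2)(x^2 - y^2),
    sqrt3 xz, sqrt3 yz, sqrt3 xy].  For a single state ``d . d = r^-6``.
    """
    v = np.atleast_2d(np.asarray(vec, dtype=float))
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    r2 = x * x + y * y + z * z
    if np.any(r2 <= 0):
        raise ValueError("zero-length internuclear vector")
    d = np.stack([
        0.5 * (3.0 * z * z - r2),
        0.5 * _SQRT3 * (x * x - y * y),
        _SQRT3 * x * z,
        _SQRT3 * y * z,
        _SQRT3 * x * y,
    ], axis=-1) / r2[:, None] ** 2.5
    return d[0] if np.asarray(vec).ndim == 1 else d


def correlation_strength(d_i: np.ndarray, d_j: np.ndarray) -> float:
    """Dipolar correlation strength between two states, in Å^-6."""
    return float(np.dot(d_i, d_j))


def averaged_prefactors(dvecs: np.ndarray, structure: SpectralStructure,
                        populations: np.ndarray | None = None) -> np.ndarray:
    """Exponential prefactor a_k for every unique eigenvalue of the generator.

    ``a_lambda = (Pi A_lambda) . C`` with C the matrix of correlation
    strengths.  When a mode carries a partition recipe the sum collapses to
    the grouped form  ``sum_i k_i sum_blocks pi_block |<d>_block|^2`` and is
    evaluated in O(s) per mode; otherwise the explicit projector is used.
    The prefactors satisfy ``sum_k a_k = <c_ii> = sum_i pi_i r_i^-6`` and the
    zero-mode prefactor equals ``|<d>_pi|^2 >= 0``.
    """
    d = np.asarray(dvecs, dtype=float)
    if d.shape[0] != structure.n_states:
        raise ValueError(
            f"geometry has {d.shape[0]} states but generator has {structure.n_states}")
    pi = structure.populations if populations is None else np.asarray(populations)
    out = np.empty(structure.n_modes)
    for k, mode in enumerate(structure.modes):
        if mode.recipe is not None:
            acc = 0.0
            for labels, coeff in mode.recipe:
                acc += coeff * _grouped_g(d, pi, labels)
            out[k] = acc
        else:
            A = mode.materialize()
            # a = sum_ij pi_i A_ij (d_i . d_j), evaluated per 5-vector component
            out[k] = float(np.einsum("im,ij,jm->", (pi[:, None] * d), A, d))
    return out


def _grouped_g(d: np.ndarray, pi: np.ndarray, labels: np.ndarray) -> float:
    """(Pi G) . C for a partition matrix G: sum over blocks of
    (sum_in pi d) . (mean_in d)."""
    acc = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        acc += float((pi[idx] @ d[idx]) @ d[idx].sum(axis=0)) / idx.size
    return acc


def order_parameter(vectors: np.ndarray, populations: np.ndarray | None = None) -> float:
    """Generalized angular order parameter S^2 = |<d_unit>_pi|^2 in [0, 1].

    Vectors are normalized to unit length before tensor construction, so only
    orientational disorder is measured (1 = rigid, 0 = isotropic).
    """
    v = np.asarray(vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    d = dipole_vector(v)
    n = v.shape[0]
    pi = np.full(n, 1.0 / n) if populations is None else np.asarray(populations)
    mean_d = pi @ d
    return float(mean_d @ mean_d)
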