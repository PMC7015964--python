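"""Goodness of fit and timescale optimization against NOE buildup tables.

Calculated intensities are fractional magnetization transfers on an
arbitrary scale relative to experiment, so agreement is measured with the
uncentered correlation ``R_u = sum(xy)/sqrt(sum(x^2) sum(y^2))``, which is
scale free in each argument but penalizes a nonzero intercept.

Timescales (tau_c and the scheme's exchange timescales) are optimized by a
coarse grid search followed by L-BFGS-B in log-timescale space with an
analytic gradient.  The exponential prefactors a_k of every pair are
independent of the timescales, so each objective evaluation only re-forms
the spectral densities, the Solomon matrix R, and its exponential; the
gradient propagates through the matrix exponential with the eigenbasis
divided-difference formula  dexp(A)[E] = U (W o (U^T E U)) U^T,
W_ij = (exp(mu_i) - exp(mu_j))/(mu_i - mu_j),  W_ii = exp(mu_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import relaxation
from .kinetics import KineticScheme
from .structures import Ensemble


def uncentered_correlation(calc, obs, weights=None) -> float:
    """R_u = sum(w x y)/sqrt(sum(w x^2) sum(w y^2)); 1 iff positive scalar
    multiples."""
    x = np.asarray(calc, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("calc and obs must be equal-length vectors of size >= 2")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    xx = np.sum(w * x * x)
    yy = np.sum(w * y * y)
    if xx == 0.0 or yy == 0.0:
        raise ValueError("zero-norm vector in uncentered correlation")
    return float(np.sum(w * x * y) / np.sqrt(xx * yy))


@dataclass
class FitResult:
    timescales: dict[str, float]   # optimized values, including tau_c (s)
    r_u: float
    converged: bool
    n_iterations: int
    grid: pd.DataFrame | None = None


class BuildupModel:
    """Forward model mapping timescales to calculated NOE intensities
    aligned with an observed buildup table.

    The expensive geometry-dependent part (prefactors of every pair within
    the distance cutoff) is computed once at construction; evaluations at
    new timescales are cheap.
    """

    def __init__(self, ensemble: Ensemble, scheme: KineticScheme,
                 table: pd.DataFrame, spectrometer_mhz: float = 900.0,
                 cutoff: float = relaxation.DEFAULT_CUTOFF,
                 weights: np.ndarray | None = None):
        self.ensemble = ensemble
        self.scheme = scheme
        self.system = relaxation.build_spin_system(ensemble, spectrometer_mhz)
        spectra = relaxation.pair_spectra(ensemble, scheme, 1e-9, self.system, cutoff)
        self._pairs = []  # (i, j, prefactors, coeff-matrix over param names)
        self.param_names = ["tau_c"] + scheme.free_names + \
            [n for n in ("tau_methyl", "tau_aromatic")
             if any(n in rc for ps in spectra.values() for rc in ps.rate_coeffs)]
        self._free = ["tau_c"] + scheme.free_names
        index = {aid: k for k, aid in enumerate(self.system.spins)}
        for (a1, a2), ps in spectra.items():
            C = np.zeros((len(ps.rate_coeffs), len(self.param_names)))
            for k, rc in enumerate(ps.rate_coeffs):
                for name, c in rc.items():
                    C[k, self.param_names.index(name)] = c
            self._pairs.append((index[a1], index[a2], ps.prefactors, C))

        self.obs = table["intensity"].to_numpy(dtype=float)
        self.weights = weights
        self.mixing_times = np.sort(table["mixing_time_ms"].unique()) * 1e-3
        mt_index = {mt: i for i, mt in enumerate(np.round(self.mixing_times * 1e3, 9))}
        known = set(self.system.groups)
        blocks: dict[tuple[str, str], int] = {}
        self._block_slices = []
        self._row_block = np.empty(len(table), dtype=int)
        self._row_mt = np.empty(len(table), dtype=int)
        for r, row in enumerate(table.itertuples(index=False)):
            g1, g2 = row.group1, row.group2
            if g1 not in known or g2 not in known:
                raise ValueError(f"table references unknown pseudoatom {g1!r}/{g2!r}")
            key = (g1, g2)
            if key not in blocks:
                blocks[key] = len(self._block_slices)
                self._block_slices.append((
                    [index[a] for a in self.system.groups[g1]],
                    [index[a] for a in self.system.groups[g2]]))
            self._row_block[r] = blocks[key]
            self._row_mt[r] = mt_index[round(row.mixing_time_ms, 9)]

    # -- forward evaluation -------------------------------------------------

    def _timescale_values(self, params: dict[str, float]) -> np.ndarray:
        ts = dict(self.scheme.timescales())
        ts["tau_c"] = params["tau_c"]
        for name in self.scheme.free_names:
            if name in params:
                ts[name] = params[name]
        return np.array([ts[n] for n in self.param_names])

    def _relaxation_and_grad(self, tau: np.ndarray, with_grad: bool):
        """Solomon matrix R and (optionally) dR/d log tau_p for every
        optimized parameter."""
        n = self.system.n_spins
        omega = np.array([0.0, self.system.omega0, 2.0 * self.system.omega0])
        n_free = len(self._free)
        R = np.zeros((n, n))
        dR = np.zeros((n_free, n, n)) if with_grad else None
        tau_c = tau[0]
        K = relaxation.SOLOMON_K / relaxation.ANG6_TO_M6
        for i, j, a, C in self._pairs:
            lam = -(C @ (1.0 / tau))        # internal eigenvalues, <= 0
            lam[np.abs(C).sum(axis=1) == 0] = 0.0
            tp = 1.0 / (1.0 / tau_c - lam)  # effective times tau'
            denom = 1.0 + np.outer(omega ** 2, tp ** 2)
            J = 2.0 * np.sum(a * tp / denom, axis=1)
            rho = K * (J[0] + 3.0 * J[1] + 6.0 * J[2])
            sigma = K * (6.0 * J[2] - J[0])
            R[i, j] += sigma
            R[j, i] += sigma
            R[i, i] += rho
            R[j, j] += rho
            if with_grad:
                fprime = (1.0 - np.outer(omega ** 2, tp ** 2)) / denom ** 2
                for p in range(n_free):
                    if p == 0:
                        dtp = tp ** 2 / tau_c          # d tau'/d log tau_c
                    else:
                        cp = C[:, p]
                        if not np.any(cp):
                            continue
                        dtp = cp * tp ** 2 / tau[p]    # d tau'/d log tau_p
                    dJ = 2.0 * np.sum(a * fprime * dtp, axis=1)
                    drho = K * (dJ[0] + 3.0 * dJ[1] + 6.0 * dJ[2])
                    dsig = K * (6.0 * dJ[2] - dJ[0])
                    dR[p, i, j] += dsig
                    dR[p, j, i] += dsig
                    dR[p, i, i] += drho
                    dR[p, j, j] += drho
        return R, dR

    def calc(self, params: dict[str, float]) -> np.ndarray:
        """Calculated intensity for every table row."""
        tau = self._timescale_values(params)
        R, _ = self._relaxation_and_grad(tau, with_grad=False)
        T = relaxation.transfer_matrices(R, self.mixing_times)
        return self._gather(T)

    def _gather(self, T: np.ndarray) -> np.ndarray:
        block_vals = np.empty((len(self._block_slices), T.shape[0]))
        for b, (ii, jj) in enumerate(self._block_slices):
            block_vals[b] = T[:, ii][:, :, jj].sum(axis=(1, 2))
        return block_vals[self._row_block, self._row_mt]

    def r_u(self, params: dict[str, float]) -> float:
        return uncentered_correlation(self.calc(params), self.obs, self.weights)

    def r_u_and_grad(self, params: dict[str, float]) -> tuple[float, np.ndarray]:
        """R_u and its gradient with respect to log timescales
        (order: tau_c, then the scheme's free timescales)."""
        tau = self._timescale_values(params)
        R, dR = self._relaxation_and_grad(tau, with_grad=True)
        w, U = np.linalg.eigh(R)
        n_free = len(self._free)
        mts = self.mixing_times
        n_t = len(mts)
        T = np.einsum("ik,tk,jk->tij", U, np.exp(-np.outer(mts, w)), U)
        x = self._gather(T)
        dx = np.empty((n_free, x.size))
        dRu = np.empty((n_free, n_t) + R.shape)
        for p in range(n_free):
            E = U.T @ (-dR[p]) @ U
            for t, mt in enumerate(mts):
                mu = -mt * w
                emu = np.exp(mu)
                diff = mu[:, None] - mu[None, :]
                W = np.where(np.abs(diff) < 1e-12 * max(1.0, np.abs(mu).max()),
                             emu[:, None],
                             (emu[:, None] - emu[None, :]) / np.where(diff == 0, 1, diff))
                dRu[p, t] = U @ (W * (mt * E)) @ U.T
            dx[p] = self._gather(dRu[p])

        y = self.obs
        wts = np.ones_like(x) if self.weights is None else self.weights
        sxy = np.sum(wts * x * y)
        sxx = np.sum(wts * x * x)
        syy = np.sum(wts * y * y)
        norm = np.sqrt(sxx * syy)
        r = sxy / norm
        dr_dx = wts * (y - (sxy / sxx) * x) / norm
        return float(r), dx @ dr_dx


def grid_search(model: BuildupModel, tau_c_grid, tau_ensemble_grid
                ) -> tuple[pd.DataFrame, dict[str, float]]:
    """R_u over a (tau_c, tau_ensemble) grid; returns the surface and argmax."""
    rows = []
    best = None
    for tc in np.atleast_1d(tau_c_grid):
        for te in np.atleast_1d(tau_ensemble_grid):
            ru = model.r_u({"tau_c": tc, "tau_ensemble": te})
            rows.append((tc, te, ru))
            if best is None or ru > best[2]:
                best = (tc, te, ru)
    surface = pd.DataFrame(rows, columns=["tau_c", "tau_ensemble", "r_u"])
    return surface, {"tau_c": best[0], "tau_ensemble": best[1], "r_u": best[2]}


def default_grids(tau_c_min: float = 1e-9, tau_c_max: float = 50e-9,
                  n: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Default log-spaced grids: tau_c over 1-50 ns; tau_ensemble over
    geometric-center tau_c times 10^(+/-3)."""
    tau_c = np.logspace(np.log10(tau_c_min), np.log10(tau_c_max), n)
    center = np.sqrt(tau_c_min * tau_c_max)
    tau_e = center * np.logspace(-3, 3, n)
    return tau_c, tau_e


def optimize_timescales(model: BuildupModel, start: dict[str, float],
                        max_iterations: int = 500) -> FitResult:
    """Maximize R_u over log timescales with L-BFGS-B and the analytic
    gradient.  Bounds are [-30, 0] in log seconds; convergence when the
    projected gradient norm falls below 1e-8 or R_u stops changing."""
    names = ["tau_c"] + model.scheme.free_names
    for nm in names:
        if start.get(nm, 0) <= 0:
            raise ValueError(f"start value for {nm} must be positive")
    x0 = np.log([start[nm] for nm in names])

    def objective(x: np.ndarray):
        params = dict(zip(names, np.exp(x)))
        r, g = model.r_u_and_grad(params)
        return -r, -g

    res = scipy.optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=[(-30.0, 0.0)] * len(names),
        options={"maxiter": max_iterations, "gtol": 1e-8, "ftol": 1e-12})
    values = dict(zip(names, np.exp(res.x)))
    return FitResult(values, -float(res.fun), bool(res.success), int(res.nit))


def randomization_test(ensemble: Ensemble, table: pd.DataFrame,
                       scheme: KineticScheme, tau_c_start: float,
                       n_random: int, seed: int,
                       spectrometer_mhz: float = 900.0,
                       cutoff: float = relaxation.DEFAULT_CUTOFF) -> dict:
    """Permutation test of a hierarchical member grouping.

    The reference grouping (``ensemble.group_labels``) is optimized, then the
    same optimization is repeated for ``n_random`` random groupings with the
    same sizes; the p-value bound is (#random >= reference + 1)/(n_random + 1).
    """
    if ensemble.group_labels is None:
        raise ValueError("ensemble carries no reference grouping")
    rng = np.random.default_rng(seed)
    start = {"tau_c": tau_c_start, **{nm: scheme.timescales()[nm]
                                      for nm in scheme.free_names}}

    def optimized_ru(labels: np.ndarray) -> float:
        ens = Ensemble(ensemble.conformers, ensemble.populations,
                       ensemble.rotation_groups, labels)
        model = BuildupModel(ens, scheme, table, spectrometer_mhz, cutoff)
        return optimize_timescales(model, start).r_u

    reference = optimized_ru(ensemble.group_labels)
    exceed = 0
    draws, drawn_labels = [], []
    for _ in range(n_random):
        labels = rng.permutation(ensemble.group_labels)
        ru = optimized_ru(labels)
        draws.append(ru)
        drawn_labels.append(labels)
        if ru >= reference:
            exceed += 1
    return {"reference_r_u": reference, "random_r_u": np.array(draws),
            "random_labels": drawn_labels,
            "p_value": (exceed + 1) / (n_random + 1)}
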