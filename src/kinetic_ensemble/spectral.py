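"""Correlation functions, spectral densities, and distance-averaging analyses.

The internal correlation function of a proton pair is a multi-exponential
decay ``C_I(tau) = sum_k a_k exp(lambda_k tau)`` whose prefactors come from
the dipolar module and whose decay rates are the unique eigenvalues of the
exchange generator.  Isotropic overall tumbling multiplies in analytically:
``C(tau) = exp(-tau/tau_c) C_I(tau)``, absorbed into modified eigenvalues
``lambda'_k = lambda_k - 1/tau_c`` with effective times
``tau'_k = -1/lambda'_k in (0, tau_c]``.  Fourier transformation gives

    J(omega) = 2 sum_k a_k tau'_k / (1 + omega^2 tau'_k^2)

which generalizes the extended-model-free (EMF) spectral density to an
arbitrary number of exchange modes and to distance fluctuations (the a_k
carry r^-6 units, Å^-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from . import dipolar, kinetics
from .structures import SpinPairGeometry, build_two_distance_toy


@dataclass
class PairSpectral:
    """Multi-exponential spectral description of one proton pair.

    ``prefactors`` are in Å^-6, ``decay_rates`` are the internal eigenvalues
    (s^-1, <= 0, first one 0), ``tau_c`` the tumbling time in seconds.
    ``rate_coeffs``, when present, expresses each decay rate as
    ``-sum_t c_t/tau_t`` over named scheme timescales; the fitting module
    uses it to differentiate J with respect to the timescales.
    """

    prefactors: np.ndarray
    decay_rates: np.ndarray
    tau_c: float
    rate_coeffs: tuple | None = None

    def __post_init__(self) -> None:
        self.prefactors = np.asarray(self.prefactors, dtype=float)
        self.decay_rates = np.asarray(self.decay_rates, dtype=float)
        if self.prefactors.shape != self.decay_rates.shape:
            raise ValueError("prefactors and decay rates must align")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if np.any(self.decay_rates > 1e-9 * max(1.0, np.abs(self.decay_rates).max())):
            raise ValueError("internal decay rates must be nonpositive")

    @property
    def modified_rates(self) -> np.ndarray:
        """lambda'_k = lambda_k - 1/tau_c (tumbling folded in)."""
        return self.decay_rates - 1.0 / self.tau_c

    @property
    def effective_times(self) -> np.ndarray:
        """tau'_k = -1/lambda'_k, each in (0, tau_c]."""
        return -1.0 / self.modified_rates

    def with_timescales(self, timescales: dict[str, float],
                        tau_c: float) -> "PairSpectral":
        """Re-evaluate the decay rates at new scheme timescales (prefactors
        are independent of the kinetics' timescales)."""
        if self.rate_coeffs is None:
            raise ValueError("pair spectral carries no symbolic rate composition")
        rates = np.array([-sum(c / timescales[name] for name, c in rc.items())
                          for rc in self.rate_coeffs])
        return PairSpectral(self.prefactors, rates, tau_c, self.rate_coeffs)


def pair_spectral(geometry: SpinPairGeometry,
                  structure: kinetics.SpectralStructure,
                  tau_c: float,
                  timescales: dict[str, float] | None = None) -> PairSpectral:
    """Assemble the pair spectral description from geometry and kinetics."""
    d = geometry.dipole_vectors()
    a = dipolar.averaged_prefactors(d, structure, geometry.populations)
    rates = structure.decay_rates(timescales or {})
    coeffs = tuple(m.rate_coeffs for m in structure.modes) \
        if all(m.eigenvalue is None for m in structure.modes) else None
    return PairSpectral(a, rates, tau_c, coeffs)


def internal_correlation(ps: PairSpectral, tau) -> np.ndarray | float:
    """C_I(tau) = sum_k a_k exp(lambda_k tau), in Å^-6."""
    tau = np.asarray(tau, dtype=float)
    out = np.sum(ps.prefactors * np.exp(np.multiply.outer(tau, ps.decay_rates)),
                 axis=-1)
    return float(out) if out.ndim == 0 else out


def correlation(ps: PairSpectral, tau) -> np.ndarray | float:
    """Full correlation function C(tau) = exp(-tau/tau_c) C_I(tau)."""
    tau = np.asarray(tau, dtype=float)
    out = np.sum(ps.prefactors * np.exp(np.multiply.outer(tau, ps.modified_rates)),
                 axis=-1)
    return float(out) if out.ndim == 0 else out


def spectral_density(ps: PairSpectral, omega) -> np.ndarray | float:
    """J(omega) = 2 sum_k a_k tau'_k/(1 + omega^2 tau'_k^2), in Å^-6 s."""
    omega = np.asarray(omega, dtype=float)
    tp = ps.effective_times
    out = 2.0 * np.sum(ps.prefactors * tp / (1.0 + np.multiply.outer(omega ** 2, tp ** 2)),
                       axis=-1)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Extended model free closed forms (reference implementation)
# --------------------------------------------------------------------------

@dataclass
class EMFParams:
    """Extended-model-free parameters: fast/slow order parameters and times."""

    s_f2: float
    s_s2: float
    tau_f: float
    tau_s: float
    tau_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_f2 <= 1.0 and 0.0 <= self.s_s2 <= 1.0):
            raise ValueError("order parameters must lie in [0, 1]")
        if min(self.tau_f, self.tau_s, self.tau_c) <= 0:
            raise ValueError("timescales must be positive")

    @property
    def tau_f_eff(self) -> float:
        return self.tau_f * self.tau_c / (self.tau_f + self.tau_c)

    @property
    def tau_s_eff(self) -> float:
        return self.tau_s * self.tau_c / (self.tau_s + self.tau_c)


def emf_internal_correlation(p: EMFParams, t) -> np.ndarray | float:
    """C_I(t) = S_f^2 S_s^2 + (1-S_f^2) e^{-t/tau_f} + S_f^2 (1-S_s^2) e^{-t/tau_s}."""
    t = np.asarray(t, dtype=float)
    out = (p.s_f2 * p.s_s2
           + (1.0 - p.s_f2) * np.exp(-t / p.tau_f)
           + p.s_f2 * (1.0 - p.s_s2) * np.exp(-t / p.tau_s))
    return float(out) if out.ndim == 0 else out


def emf_spectral_density(p: EMFParams, omega) -> np.ndarray | float:
    """Closed-form EMF spectral density (third-term coefficient S_f^2 (1-S_s^2),
    the Fourier transform of the EMF correlation function)."""
    omega = np.asarray(omega, dtype=float)
    tf, ts = p.tau_f_eff, p.tau_s_eff
    out = 2.0 * (p.s_f2 * p.s_s2 * p.tau_c / (1.0 + omega ** 2 * p.tau_c ** 2)
                 + (1.0 - p.s_f2) * tf / (1.0 + omega ** 2 * tf ** 2)
                 + p.s_f2 * (1.0 - p.s_s2) * ts / (1.0 + omega ** 2 * ts ** 2))
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Distance-averaging power analyses (two-distance toy)
# --------------------------------------------------------------------------

_P_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def two_state_j0(r_a: float, r_b: float, p_a: float,
                 tau_ex: float, tau_c: float) -> float:
    """J(0) for the two-distance toy at exchange time tau_ex (s, per the
    nonzero-eigenvalue convention k_AB + k_BA = 1/tau_ex)."""
    geom = build_two_distance_toy(r_a, r_b, p_a)
    rm = kinetics.two_state_matrix(p_a, tau_ex)
    structure = kinetics.spectral_structure(rm)
    ps = pair_spectral(geom, structure, tau_c)
    return float(spectral_density(ps, 0.0))


def fit_averaging_power(r_a: float, r_b: float, tau_ex: float, tau_c: float) -> float:
    """Effective distance-averaging power n of the NOE for two-site exchange.

    J(0) is computed exactly at populations p_A in {0, 0.2, ..., 1.0} and the
    model ``J(0) = 2 tau_c (p_A r_A^-n + (1-p_A) r_B^-n)^{6/n}`` is fitted for
    n by bounded 1-D least squares directly on J(0).  n -> 3 for exchange much
    faster than tumbling (<r^-3>^2 averaging) and n -> 6 for much slower
    (<r^-6>).
    """
    if tau_ex <= 0 or tau_c <= 0:
        raise ValueError("timescales must be positive")
    if abs(np.log(r_b / r_a)) < 1e-3:
        raise ValueError("distance ratio too close to 1 to identify n")
    j0 = np.array([two_state_j0(r_a, r_b, p, tau_ex, tau_c) for p in _P_GRID])

    def loss(n: float) -> float:
        model = 2.0 * tau_c * (_P_GRID * r_a ** -n
                               + (1.0 - _P_GRID) * r_b ** -n) ** (6.0 / n)
        return float(np.sum((model - j0) ** 2))

    res = scipy.optimize.minimize_scalar(loss, bounds=(2.5, 6.5), method="bounded",
                                         options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError("averaging-power fit did not converge")
    return float(res.x)


def default_tau_ex_grid(tau_c: float, n_points: int = 61) -> np.ndarray:
    """Log-spaced exchange-timescale grid over tau_c * 10^[-3, +3]."""
    return tau_c * np.logspace(-3.0, 3.0, n_points)


def averaging_power_curve(r_a: float, r_b: float, tau_c: float,
                          tau_ex_grid: np.ndarray) -> np.ndarray:
    """Fitted n at every exchange timescale of the grid."""
    return np.array([fit_averaging_power(r_a, r_b, t, tau_c) for t in tau_ex_grid])


def fit_halfpoint(r_a: float, r_b: float, tau_c: float,
                  tau_ex_grid: np.ndarray | None = None) -> float:
    """Midpoint tau_1/2 (in units of tau_c) of the hyperbola
    ``n = 3 + 3/(tau_1/2/tau_ex + 1)`` fitted to the n(tau_ex) curve.

    tau_1/2 is the exchange timescale at which the effective averaging power
    is 4.5, halfway between the fast (3) and slow (6) limits.
    """
    if tau_ex_grid is None:
        tau_ex_grid = default_tau_ex_grid(tau_c)
    span = np.log10(tau_ex_grid.max() / tau_c) - np.log10(tau_ex_grid.min() / tau_c)
    if span < 5.999:
        raise ValueError("tau_ex grid must span at least +/- 3 decades around tau_c")
    n_vals = averaging_power_curve(r_a, r_b, tau_c, tau_ex_grid)

    def residuals(log_t12: np.ndarray) -> np.ndarray:
        t12 = np.exp(log_t12[0])
        return 3.0 + 3.0 / (t12 / tau_ex_grid + 1.0) - n_vals

    res = scipy.optimize.least_squares(residuals, x0=[np.log(tau_c)], xtol=1e-14)
    if not res.success:
        raise RuntimeError("hyperbola fit did not converge")
    return float(np.exp(res.x[0]) / tau_c)
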