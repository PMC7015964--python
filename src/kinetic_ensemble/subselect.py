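"""Greedy subensemble selection against NOE buildup data.

Starting from a random ~50% inclusion of ensemble members, each round
evaluates every single-member swap (include <-> exclude), re-optimizing the
timescales from their current best values for each candidate, and accepts
the swap giving the greatest improvement in R_u.  The search terminates at
a local optimum under single swaps.  Matched random subensembles provide
the baseline distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import relaxation
from .fitting import BuildupModel, optimize_timescales
from .kinetics import KineticScheme
from .structures import Ensemble

# guards infinite loops from floating-point noise in R_u
IMPROVEMENT_TOLERANCE = 1e-9


@dataclass
class Selection:
    """Inclusion mask over ensemble members with the greedy trajectory."""

    mask: np.ndarray
    r_u: float
    timescales: dict[str, float]
    history: list[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def score_subensemble(ensemble: Ensemble, table: pd.DataFrame,
                      mask: np.ndarray, scheme: KineticScheme,
                      start: dict[str, float],
                      spectrometer_mhz: float = 900.0,
                      cutoff: float = relaxation.DEFAULT_CUTOFF):
    """Optimized (R_u, timescales) of the masked subensemble."""
    sub = ensemble.subset(mask)
    model = BuildupModel(sub, scheme, table, spectrometer_mhz, cutoff)
    fit = optimize_timescales(model, start)
    return fit.r_u, fit.timescales


def greedy_subselect(ensemble: Ensemble, table: pd.DataFrame, seed: int,
                     scheme: KineticScheme | None = None,
                     tau_c_start: float = 5e-9,
                     spectrometer_mhz: float = 900.0,
                     cutoff: float = relaxation.DEFAULT_CUTOFF,
                     max_rounds: int = 100) -> Selection:
    """Greedy single-swap subensemble optimization of R_u.

    Timescales are warm-started from their previously optimal values for
    every candidate; ties among equally improving swaps break to the lowest
    member index; swaps that would leave fewer than two members are
    rejected.  The accepted-swap R_u sequence is strictly increasing.
    """
    n = ensemble.n_members
    if n < 3:
        raise ValueError("subselection needs at least 3 members")
    scheme = scheme or KineticScheme(tau_ensemble=2e-9)
    rng = np.random.default_rng(seed)
    mask = rng.random(n) < 0.5
    while mask.sum() < 2:  # even-probability start, but never (near-)empty
        mask = rng.random(n) < 0.5

    start = {"tau_c": tau_c_start,
             **{nm: scheme.timescales()[nm] for nm in scheme.free_names}}
    r_u, timescales = score_subensemble(ensemble, table, mask, scheme, start,
                                        spectrometer_mhz, cutoff)
    sel = Selection(mask.copy(), r_u, timescales)
    sel.history.append({"round": 0, "swap": None, "r_u": r_u, **timescales})

    for rnd in range(1, max_rounds + 1):
        best = None
        for m in range(n):
            cand = sel.mask.copy()
            cand[m] = ~cand[m]
            if cand.sum() < 2:
                continue
            ru, ts = score_subensemble(ensemble, table, cand, scheme,
                                       sel.timescales, spectrometer_mhz, cutoff)
            if ru > sel.r_u + IMPROVEMENT_TOLERANCE and (best is None or ru > best[1]):
                best = (m, ru, ts)
        if best is None:
            break
        m, ru, ts = best
        sel.mask[m] = ~sel.mask[m]
        sel.r_u, sel.timescales = ru, ts
        sel.history.append({"round": rnd, "swap": m, "r_u": ru, **ts})
    return sel


def random_subensembles(n_members: int, size_distribution, n: int,
                        seed: int) -> list[np.ndarray]:
    """Uniform random inclusion masks drawn without replacement at sizes
    cycled from ``size_distribution``; deterministic per seed."""
    sizes = [int(s) for s in size_distribution]
    if any(s < 1 or s > n_members for s in sizes):
        raise ValueError("subensemble sizes must lie in [1, n_members]")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        size = sizes[k % len(sizes)]
        idx = rng.choice(n_members, size=size, replace=False)
        mask = np.zeros(n_members, dtype=bool)
        mask[idx] = True
        out.append(mask)
    return out
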