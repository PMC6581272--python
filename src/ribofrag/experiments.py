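"""Scripted population-level computational experiments.

Three studies built on the protocell simulator:

* ``stability_trial`` / ``phase_diagram`` — classify (V_div, N_cell)
  parameter sets as stable or unstable with and without transfer: a run
  is stable when it keeps producing divisions with both fragment types
  present up to a division budget.
* ``minor_fraction_sweep`` — minor-fragment concentrations of Y-dominant
  dividing cells across D, paired with the analytic fixed point of the
  reduced two-subsystem model.

Reproducibility: child seeds derive from (master seed, grid index, run
index) through a counter-based SeedSequence scheme, so grids are
order-independent and bit-for-bit repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams
from .reduced import c_of_totals
from .ssa import RunResult, run_population

__all__ = [
    "PhaseDiagramEntry",
    "child_seed",
    "stability_trial",
    "phase_diagram",
    "dividing_type_fractions",
    "minor_fraction_sweep",
]


@dataclass(frozen=True)
class PhaseDiagramEntry:
    V_div: int
    N_cell: int
    D: float
    n_runs: int
    n_stable: int

    @property
    def classification(self) -> str:
        if self.n_stable == self.n_runs:
            return "stable"
        if self.n_stable == 0:
            return "unstable"
        return "boundary"


def child_seed(master_seed: int, *indices: int) -> int:
    """Deterministic sub-stream seed from a master seed and counters."""
    ss = np.random.SeedSequence([int(master_seed) % 2**31,
                                 *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % 2**31)


def stability_trial(params: ModelParams, max_divisions: int, seed: int,
                    max_events: int = 0,
                    stall_events: int = 5_000_000) -> str:
    """Run one population from the standard initial condition and label
    it ``stable`` or ``unstable``.

    Unstable means the run ended before ``max_divisions`` by global loss
    of a fragment type, a frozen zero-propensity state, or a stall
    (no division within the event budget); stable means the division
    budget was reached.
    """
    res = run_population(params, max_divisions=max_divisions,
                         max_events=max_events, seed=seed,
                         stall_events=stall_events)
    return "stable" if res.status == "max_divisions" else "unstable"


def phase_diagram(V_div_grid: Sequence[int], N_cell_grid: Sequence[int],
                  D: float, n_runs: int, max_divisions: int,
                  seed: int) -> pd.DataFrame:
    """Stability classification over a (V_div, N_cell) grid.

    Returns a tidy table with one row per grid point: V_div, N_cell, D,
    n_runs, n_stable, classification.
    """
    if len(V_div_grid) == 0 or len(N_cell_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for gi, v_div in enumerate(V_div_grid):
        for gj, n_cell in enumerate(N_cell_grid):
            p = ModelParams(V_div=int(v_div), N_cell=int(n_cell), D=float(D))
            n_stable = sum(
                stability_trial(p, max_divisions,
                                child_seed(seed, gi, gj, r)) == "stable"
                for r in range(n_runs))
            e = PhaseDiagramEntry(int(v_div), int(n_cell), float(D),
                                  n_runs, n_stable)
            rows.append({"V_div": e.V_div, "N_cell": e.N_cell, "D": e.D,
                         "n_runs": e.n_runs, "n_stable": e.n_stable,
                         "classification": e.classification})
    return pd.DataFrame(rows)


def dividing_type_fractions(result: RunResult,
                            window_frac: float = 0.25) -> dict[str, float]:
    """Fractions of X- and Y-dominant dividing cells in the final
    ``window_frac`` of a run's division records (ties excluded)."""
    div = result.divisions
    n = len(div)
    if n == 0:
        return {"X-dominant": 0.0, "Y-dominant": 0.0, "n_typed": 0}
    tail = div.iloc[int(np.floor(n * (1.0 - window_frac))):]
    x_dom = int((tail["X_tot"] > tail["Y_tot"]).sum())
    y_dom = int((tail["Y_tot"] > tail["X_tot"]).sum())
    typed = x_dom + y_dom
    if typed == 0:
        return {"X-dominant": 0.0, "Y-dominant": 0.0, "n_typed": 0}
    return {"X-dominant": x_dom / typed, "Y-dominant": y_dom / typed,
            "n_typed": typed}


def minor_fraction_sweep(D_list: Iterable[float], params: ModelParams,
                         n_divisions_sampled: int, seed: int,
                         burn_in_frac: float = 0.5) -> pd.DataFrame:
    """Minor-fragment concentrations of Y-dominant dividing cells vs D.

    For each D, runs the population simulator, keeps division records of
    Y-dominant cells after a burn-in, and reports the mean free-X and
    total-X concentrations (n_x/V and X_tot/V at division) next to the
    analytic reduced-model values x2(D) = (1 - sqrt(1 - 4 sqrt(2D)))/2
    and x2 - c(x2), plus the 1/V_div catalyst-floor reference.  Rows
    with no Y-dominant divisions after burn-in are flagged.
    """
    rows = []
    for di, D in enumerate(D_list):
        if not 0.0 < D < 0.02:
            raise ValueError(f"D values must lie in (0, 0.02), got {D}")
        p = params.with_(D=float(D))
        res = run_population(p, max_divisions=n_divisions_sampled,
                             seed=child_seed(seed, di))
        div = res.divisions
        div = div.iloc[int(len(div) * burn_in_frac):]
        ydom = div[div["Y_tot"] > div["X_tot"]]
        x2 = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(2.0 * D)))
        free_x2 = x2 - c_of_totals(x2, 1.0 - x2, "approx")
        V = ydom["X_tot"] + ydom["Y_tot"]
        row = {"D": float(D),
               "mean_free_x": float(((ydom["X_tot"] - ydom["n_c"]) / V).mean())
               if len(ydom) else np.nan,
               "mean_x_tot": float((ydom["X_tot"] / V).mean())
               if len(ydom) else np.nan,
               "analytic_x2": float(x2),
               "analytic_free_x": float(free_x2),
               "floor_ref": 1.0 / p.V_div,
               "n_samples": int(len(ydom)),
               "flag": "" if len(ydom) else "no-Y-dominant-divisions",
               "status": res.status}
        rows.append(row)
    return pd.DataFrame(rows)
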