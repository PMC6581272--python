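"""Deterministic well-mixed (batch) dynamics of fragments and catalyst.

Concentrations x, y, c of free fragments X, Y and assembled catalyst C
evolve under mass action with a dilution term that keeps the total
molecular mass x + y + 2c constant:

    dx/dt = -k_f x y + k_b c + k_x x c - x mu
    dy/dt = -k_f x y + k_b c + k_y y c - y mu
    dc/dt =  k_f x y - k_b c           - c mu

with mu = k_x x c + k_y y c.  In terms of the totals x_tot = x + c and
y_tot = y + c (for k_x = k_y = k) the ratio obeys

    d/dt (x_tot / y_tot) = k c^2 / y_tot^2 * (x_tot - y_tot),

so the balanced state x_tot = y_tot is a steady state but an unstable
one: any excess of one fragment is amplified, the minor fragment is
diluted out, and replication eventually stops.  This positive feedback
is the failure mode the compartment model rescues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParams

__all__ = [
    "BatchState",
    "batch_rhs",
    "integrate_batch",
    "ratio_drift",
    "nfrag_batch_rhs",
    "nfrag_integrate",
]


@dataclass(frozen=True)
class BatchState:
    """Concentrations of free X, free Y and catalyst C (mass units)."""

    x: float
    y: float
    c: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.c < 0:
            raise ValueError(f"negative concentration in {self}")

    @property
    def x_tot(self) -> float:
        return self.x + self.c

    @property
    def y_tot(self) -> float:
        return self.y + self.c

    @property
    def mass(self) -> float:
        return self.x + self.y + 2.0 * self.c

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.c], dtype=float)


def _rhs_array(v: np.ndarray, p: ModelParams, conserve: str) -> np.ndarray:
    x, y, c = v
    react_x = -p.k_f * x * y + p.k_b * c + p.k_x * x * c
    react_y = -p.k_f * x * y + p.k_b * c + p.k_y * y * c
    react_c = p.k_f * x * y - p.k_b * c
    if conserve == "mass":
        mu = p.k_x * x * c + p.k_y * y * c
    elif conserve == "total":
        # alternative convention holding x + y + c (not mass) constant
        mu = -p.k_f * x * y + p.k_b * c + p.k_x * x * c + p.k_y * y * c
    else:
        raise ValueError(f"conserve must be 'mass' or 'total', got {conserve!r}")
    return np.array([react_x - x * mu, react_y - y * mu, react_c - c * mu])


def batch_rhs(state: BatchState, params: ModelParams,
              conserve: str = "mass") -> tuple[float, float, float]:
    """Time derivatives (dx/dt, dy/dt, dc/dt) of the batch system.

    With ``conserve='mass'`` (default) the dilution rate is
    mu = k_x x c + k_y y c, which holds the total mass x + y + 2c fixed
    whenever it equals 1.  ``conserve='total'`` holds x + y + c instead.
    """
    d = _rhs_array(state.as_array(), params, conserve)
    return float(d[0]), float(d[1]), float(d[2])


def ratio_drift(state: BatchState, params: ModelParams) -> float:
    """d/dt of the ratio x_tot/y_tot, equal to k c^2/y_tot^2 (x_tot - y_tot).

    Valid for k_x = k_y = k (the symmetric-rate case); uses k = k_x.
    Positive whenever x_tot > y_tot and c > 0: balance is unstable.
    """
    y_tot = state.y_tot
    if y_tot <= 0.0:
        raise ZeroDivisionError("ratio_drift undefined for y_tot = 0")
    k = params.k_x
    return k * state.c**2 / y_tot**2 * (state.x_tot - y_tot)


def integrate_batch(state0: BatchState, params: ModelParams, t_end: float,
                    n_out: int = 201, conserve: str = "mass",
                    rtol: float = 1e-10, atol: float = 1e-12) -> pd.DataFrame:
    """Integrate the batch ODEs; return a tidy trajectory table.

    Columns: t, x, y, c, x_tot, y_tot, mass.  The integration uses an
    adaptive stiff-capable method (LSODA) at tolerance well below the
    1e-8 relative mass-conservation guarantee, which is asserted on
    every output point.
    """
    v0 = state0.as_array()
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(lambda t, v: _rhs_array(v, params, conserve),
                    (0.0, t_end), v0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"batch integration failed: {sol.message}")
    x, y, c = sol.y
    # clip integrator round-off below zero
    x, y, c = (np.clip(a, 0.0, None) for a in (x, y, c))
    if conserve == "mass":
        mass = x + y + 2.0 * c
        m0 = state0.mass
    else:
        mass = x + y + c
        m0 = state0.x + state0.y + state0.c
    err = np.max(np.abs(mass - m0)) / m0
    if err > 1e-8:
        raise RuntimeError(f"conservation violated: relative error {err:.2e}")
    return pd.DataFrame({"t": sol.t, "x": x, "y": y, "c": c,
                         "x_tot": x + c, "y_tot": y + c, "mass": mass})


# ---------------------------------------------------------------------------
# N-fragment generalization: catalyst assembled from N distinct fragments
# in a single N-body step, k_f * prod(x_i) -> C; each fragment replicated
# at rate k_i x_i c.  Dilution mu = sum_i k_i x_i c holds sum(x) + N c = 1.
# ---------------------------------------------------------------------------

def nfrag_batch_rhs(state: Sequence[float], params: ModelParams,
                    k_repl: Sequence[float] | None = None) -> np.ndarray:
    """Derivative of the N-fragment batch system.

    ``state`` is (x_1, ..., x_N, c) with N = params.n_frag.  ``k_repl``
    optionally gives per-fragment replication rates (default: k_x for
    every fragment).  Reduces exactly to the two-fragment system for
    N = 2 with k_repl = (k_x, k_y).
    """
    v = np.asarray(state, dtype=float)
    n = params.n_frag
    if v.shape != (n + 1,):
        raise ValueError(f"state must have length n_frag+1 = {n + 1}, "
                         f"got shape {v.shape}")
    if np.any(v < 0):
        raise ValueError("negative concentrations rejected")
    xs, c = v[:n], v[n]
    if k_repl is None:
        ks = np.full(n, params.k_x)
        if n == 2:
            ks[1] = params.k_y
    else:
        ks = np.asarray(k_repl, dtype=float)
        if ks.shape != (n,):
            raise ValueError("k_repl length must equal n_frag")
    assembly = params.k_f * np.prod(xs)
    disassembly = params.k_b * c
    repl = ks * xs * c
    mu = float(np.sum(repl))
    dxs = -assembly + disassembly + repl - xs * mu
    dc = assembly - disassembly - c * mu
    return np.append(dxs, dc)


def nfrag_integrate(state0: Sequence[float], params: ModelParams,
                    t_end: float, n_out: int = 201,
                    k_repl: Sequence[float] | None = None) -> pd.DataFrame:
    """Integrate the N-fragment system; columns x1..xN, c, mass."""
    v0 = np.asarray(state0, dtype=float)
    n = params.n_frag
    sol = solve_ivp(lambda t, v: nfrag_batch_rhs(v, params, k_repl),
                    (0.0, t_end), v0, method="LSODA",
                    t_eval=np.linspace(0.0, t_end, n_out),
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    cols = {f"x{i + 1}": np.clip(sol.y[i], 0.0, None) for i in range(n)}
    cols["c"] = np.clip(sol.y[n], 0.0, None)
    df = pd.DataFrame({"t": sol.t, **cols})
    df["mass"] = sum(cols[f"x{i + 1}"] for i in range(n)) + n * cols["c"]
    return df
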