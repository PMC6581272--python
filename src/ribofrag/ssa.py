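"""Exact stochastic simulation of a population of dividing protocells.

Each of N_cell cells holds integer copy numbers (n_x, n_y, n_c) and runs
the assembly/disassembly/replication reactions by a single global
Gillespie algorithm over the union of all cells' reaction channels.
Cell volume is the fragment count V = n_x + n_y + 2 n_c.  When V reaches
the threshold V_div the cell divides immediately, every molecule being
assigned to a daughter with probability 1/2 (catalysts as intact units);
one cell chosen uniformly among the N+1 cells present just after the
division (the N-1 bystanders and both daughters) is removed to keep the
population size fixed (``daughters_eligible=False`` restricts removal
to the bystanders).  Horizontal transfer removes single molecules at
per-molecule rate D and delivers them (with probability 1 - p_loss) to a
uniformly chosen other cell.

The hot loop is compiled with numba; ``cell_propensities`` and
``divide_cell`` are the plain-Python single-event reference surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .params import ModelParams

__all__ = [
    "CellState",
    "PopulationState",
    "RunResult",
    "cell_propensities",
    "divide_cell",
    "classify_dominance",
    "is_globally_extinct",
    "init_population",
    "run_population",
    "dominance_counts",
]

#: reaction channel order used throughout:
#: 0 assembly, 1 disassembly, 2 replicate X, 3 replicate Y,
#: 4 transfer X, 5 transfer Y, 6 transfer C
N_CHANNELS = 7

_NO_DIVISION = 2**62

STATUS_NAMES = {0: "max_divisions", 1: "max_events", 2: "extinct",
                3: "frozen", 4: "stalled", 5: "t_end"}


@dataclass(frozen=True)
class CellState:
    """Copy numbers of one protocell."""

    n_x: int
    n_y: int
    n_c: int

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_c) < 0:
            raise ValueError(f"negative copy number in {self}")

    @property
    def V(self) -> int:
        """Cell volume = total fragment count (a catalyst holds two)."""
        return self.n_x + self.n_y + 2 * self.n_c

    @property
    def X_tot(self) -> int:
        return self.n_x + self.n_c

    @property
    def Y_tot(self) -> int:
        return self.n_y + self.n_c


@dataclass
class PopulationState:
    """Arrays of per-cell copy numbers plus the simulation clock."""

    n_x: np.ndarray
    n_y: np.ndarray
    n_c: np.ndarray
    t: float = 0.0
    n_divisions: int = 0

    def cell(self, i: int) -> CellState:
        return CellState(int(self.n_x[i]), int(self.n_y[i]), int(self.n_c[i]))

    @property
    def n_cells(self) -> int:
        return len(self.n_x)

    def copy(self) -> "PopulationState":
        return PopulationState(self.n_x.copy(), self.n_y.copy(),
                               self.n_c.copy(), self.t, self.n_divisions)


@dataclass
class RunResult:
    population: PopulationState
    divisions: pd.DataFrame  # columns t, cell, X_tot, Y_tot, n_c
    status: str
    n_events: int

    @property
    def stalled(self) -> bool:
        return self.status in ("stalled", "frozen")


def cell_propensities(cell: CellState, params: ModelParams,
                      omega_fixed: float | None = None) -> np.ndarray:
    """Per-channel propensities of a single cell (reference version).

    Bimolecular channels are scaled by the cell volume Omega, by default
    the current fragment count V (so counts/V behave like the normalized
    batch concentrations); ``omega_fixed`` selects a constant volume.
    Degenerate cells (V = 0) yield all-zero propensities.
    """
    x, y, c = cell.n_x, cell.n_y, cell.n_c
    om = float(cell.V) if omega_fixed is None else float(omega_fixed)
    a = np.zeros(N_CHANNELS)
    if om > 0:
        a[0] = params.k_f * x * y / om
        a[2] = params.k_x * x * c / om
        a[3] = params.k_y * y * c / om
    a[1] = params.k_b * c
    a[4] = params.D * x
    a[5] = params.D * y
    a[6] = params.D * c
    return a


def divide_cell(cell: CellState, rng: np.random.Generator,
                v_div: int | None = None) -> tuple[CellState, CellState]:
    """Binomially partition a cell into two daughters.

    Each X, Y and C molecule goes to daughter 1 independently with
    probability 1/2; catalysts are partitioned as intact units.  If
    ``v_div`` is given, calling below the threshold is rejected.
    """
    if v_div is not None and cell.V < v_div:
        raise ValueError(f"cell volume {cell.V} below threshold {v_div}")
    ax = rng.binomial(cell.n_x, 0.5)
    ay = rng.binomial(cell.n_y, 0.5)
    ac = rng.binomial(cell.n_c, 0.5)
    d1 = CellState(int(ax), int(ay), int(ac))
    d2 = CellState(cell.n_x - d1.n_x, cell.n_y - d1.n_y, cell.n_c - d1.n_c)
    return d1, d2


def classify_dominance(cell: CellState) -> str:
    """Label a cell X-dominant, Y-dominant, balanced or empty."""
    if cell.V == 0:
        return "empty"
    if cell.X_tot > cell.Y_tot:
        return "X-dominant"
    if cell.Y_tot > cell.X_tot:
        return "Y-dominant"
    return "balanced"


def dominance_counts(pop: PopulationState) -> dict[str, int]:
    counts = {"X-dominant": 0, "Y-dominant": 0, "balanced": 0, "empty": 0}
    for i in range(pop.n_cells):
        counts[classify_dominance(pop.cell(i))] += 1
    return counts


def is_globally_extinct(pop: PopulationState) -> bool:
    """True iff one fragment type is absent from the entire population.

    This state is absorbing: replication of the lost type can never
    resume, even with transfer, since no catalyst containing it exists.
    """
    sx = int(np.sum(pop.n_x) + np.sum(pop.n_c))
    sy = int(np.sum(pop.n_y) + np.sum(pop.n_c))
    return sx == 0 or sy == 0


def init_population(params: ModelParams) -> PopulationState:
    """Standard initial condition: V_div/4 copies of each free fragment
    and no catalysts in every cell."""
    n0 = params.V_div // 4
    n = params.N_cell
    return PopulationState(np.full(n, n0, dtype=np.int64),
                           np.full(n, n0, dtype=np.int64),
                           np.zeros(n, dtype=np.int64))


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _refresh(i, nx, ny, nc, a, asum, kf, kb, kx, ky, D, omega_fixed):
    x = float(nx[i])
    y = float(ny[i])
    c = float(nc[i])
    V = x + y + 2.0 * c
    om = omega_fixed if omega_fixed > 0.0 else V
    if om > 0.0:
        a[i, 0] = kf * x * y / om
        a[i, 2] = kx * x * c / om
        a[i, 3] = ky * y * c / om
    else:
        a[i, 0] = 0.0
        a[i, 2] = 0.0
        a[i, 3] = 0.0
    a[i, 1] = kb * c
    a[i, 4] = D * x
    a[i, 5] = D * y
    a[i, 6] = D * c
    old = asum[i]
    s = a[i, 0] + a[i, 1] + a[i, 2] + a[i, 3] + a[i, 4] + a[i, 5] + a[i, 6]
    asum[i] = s
    return s - old


@njit(cache=True)
def _ssa_kernel(nx, ny, nc, kf, kb, kx, ky, D, p_loss, v_div, omega_fixed,
                daughters_eligible, max_divisions, max_events, stall_events,
                seed, t0, t_end):
    np.random.seed(seed)
    N = nx.shape[0]
    a = np.zeros((N, 7))
    asum = np.zeros(N)
    total = 0.0
    for i in range(N):
        total += _refresh(i, nx, ny, nc, a, asum, kf, kb, kx, ky, D,
                          omega_fixed)
    SX = np.int64(0)
    SY = np.int64(0)
    for i in range(N):
        SX += nx[i] + nc[i]
        SY += ny[i] + nc[i]

    cap = max_divisions if max_divisions > 0 else 1
    div_rec = np.zeros((cap, 5))
    stack = np.zeros(128, dtype=np.int64)

    t = t0
    n_div = 0
    n_ev = np.int64(0)
    since_div = np.int64(0)
    status = 1  # default: max_events reached

    while True:
        if SX == 0 or SY == 0:
            status = 2
            break
        if total <= 0.0:
            status = 3
            break
        if n_ev >= max_events:
            status = 1
            break
        if stall_events > 0 and since_div >= stall_events:
            status = 4
            break
        if (n_ev & 0xFFFFF) == 0xFFFFF:  # drift guard
            total = 0.0
            for i in range(N):
                total += asum[i]
            continue_outer = total <= 0.0
            if continue_outer:
                status = 3
                break

        tau = np.random.exponential(1.0 / total)
        if t_end > 0.0 and t + tau > t_end:
            t = t_end
            status = 5
            break
        t += tau
        r = np.random.random() * total
        i = 0
        acc = 0.0
        while i < N - 1:
            if acc + asum[i] >= r:
                break
            acc += asum[i]
            i += 1
        rr = r - acc
        ch = 0
        acc2 = 0.0
        while ch < 6:
            if acc2 + a[i, ch] >= rr:
                break
            acc2 += a[i, ch]
            ch += 1

        grew = -1  # cell index whose volume increased this event
        # feasibility guards: a stale float pick at a channel boundary
        # must never drive a count negative
        if ch == 0:
            if nx[i] < 1 or ny[i] < 1:
                n_ev += 1
                continue
            nx[i] -= 1
            ny[i] -= 1
            nc[i] += 1
        elif ch == 1:
            if nc[i] < 1:
                n_ev += 1
                continue
            nx[i] += 1
            ny[i] += 1
            nc[i] -= 1
        elif ch == 2:
            if nx[i] < 1 or nc[i] < 1:
                n_ev += 1
                continue
            nx[i] += 1
            SX += 1
            grew = i
        elif ch == 3:
            if ny[i] < 1 or nc[i] < 1:
                n_ev += 1
                continue
            ny[i] += 1
            SY += 1
            grew = i
        else:
            sp = ch - 4  # species 0=X, 1=Y, 2=C
            if sp == 0:
                if nx[i] < 1:
                    n_ev += 1
                    continue
                nx[i] -= 1
            elif sp == 1:
                if ny[i] < 1:
                    n_ev += 1
                    continue
                ny[i] -= 1
            else:
                if nc[i] < 1:
                    n_ev += 1
                    continue
                nc[i] -= 1
            lost = p_loss > 0.0 and np.random.random() < p_loss
            if lost or N == 1:
                if sp == 0:
                    SX -= 1
                elif sp == 1:
                    SY -= 1
                else:
                    SX -= 1
                    SY -= 1
                if N == 1 and not lost:
                    # no other cell exists: molecule returns to source
                    if sp == 0:
                        nx[i] += 1
                        SX += 1
                    elif sp == 1:
                        ny[i] += 1
                        SY += 1
                    else:
                        nc[i] += 1
                        SX += 1
                        SY += 1
            else:
                j = np.random.randint(0, N - 1)
                if j >= i:
                    j += 1
                if sp == 0:
                    nx[j] += 1
                elif sp == 1:
                    ny[j] += 1
                else:
                    nc[j] += 1
                total += _refresh(j, nx, ny, nc, a, asum, kf, kb, kx, ky,
                                  D, omega_fixed)
                grew = j
        total += _refresh(i, nx, ny, nc, a, asum, kf, kb, kx, ky, D,
                          omega_fixed)
        n_ev += 1
        since_div += 1

        # division cascade: any cell whose volume reached the threshold
        # divides immediately
        done = False
        if grew >= 0 and v_div > 0:
            sp_top = 0
            stack[sp_top] = grew
            sp_top = 1
            while sp_top > 0:
                sp_top -= 1
                ci = stack[sp_top]
                V = nx[ci] + ny[ci] + 2 * nc[ci]
                if V < v_div:
                    continue
                if n_div < cap:
                    div_rec[n_div, 0] = t
                    div_rec[n_div, 1] = ci
                    div_rec[n_div, 2] = nx[ci] + nc[ci]
                    div_rec[n_div, 3] = ny[ci] + nc[ci]
                    div_rec[n_div, 4] = nc[ci]
                n_div += 1
                since_div = 0
                ax = np.random.binomial(nx[ci], 0.5)
                ay = np.random.binomial(ny[ci], 0.5)
                ac = np.random.binomial(nc[ci], 0.5)
                bx = nx[ci] - ax
                by = ny[ci] - ay
                bc = nc[ci] - ac
                if N == 1:
                    # no cell to replace: keep daughter 1 only
                    nx[ci] = ax
                    ny[ci] = ay
                    nc[ci] = ac
                    SX -= bx + bc
                    SY -= by + bc
                    total += _refresh(ci, nx, ny, nc, a, asum, kf, kb, kx,
                                      ky, D, omega_fixed)
                    if sp_top < 127:
                        stack[sp_top] = ci
                        sp_top += 1
                else:
                    if daughters_eligible:
                        # uniform over the N+1 post-division cells:
                        # N-1 others, daughter 1 (slot ci), daughter 2
                        j = np.random.randint(0, N + 1)
                    else:
                        j = np.random.randint(0, N - 1)
                        if j >= ci:
                            j += 1
                    if j == N:
                        # removed cell is daughter 2: discard it
                        nx[ci] = ax
                        ny[ci] = ay
                        nc[ci] = ac
                        SX -= bx + bc
                        SY -= by + bc
                        total += _refresh(ci, nx, ny, nc, a, asum, kf, kb,
                                          kx, ky, D, omega_fixed)
                        if sp_top < 127:
                            stack[sp_top] = ci
                            sp_top += 1
                    elif j == ci:
                        # removed cell is daughter 1 itself
                        nx[ci] = bx
                        ny[ci] = by
                        nc[ci] = bc
                        SX -= ax + ac
                        SY -= ay + ac
                        total += _refresh(ci, nx, ny, nc, a, asum, kf, kb,
                                          kx, ky, D, omega_fixed)
                        if sp_top < 127:
                            stack[sp_top] = ci
                            sp_top += 1
                    else:
                        SX -= nx[j] + nc[j]
                        SY -= ny[j] + nc[j]
                        nx[ci] = ax
                        ny[ci] = ay
                        nc[ci] = ac
                        nx[j] = bx
                        ny[j] = by
                        nc[j] = bc
                        total += _refresh(ci, nx, ny, nc, a, asum, kf, kb,
                                          kx, ky, D, omega_fixed)
                        total += _refresh(j, nx, ny, nc, a, asum, kf, kb,
                                          kx, ky, D, omega_fixed)
                        if sp_top < 126:
                            stack[sp_top] = ci
                            sp_top += 1
                            stack[sp_top] = j
                            sp_top += 1
                if max_divisions > 0 and n_div >= max_divisions:
                    done = True
                    break
        if done:
            status = 0
            break

    n_rec = n_div if n_div < cap else cap
    return t, status, n_ev, n_div, div_rec[:n_rec]


def run_population(params: ModelParams,
                   init: PopulationState | None = None,
                   max_divisions: int = 10_000,
                   max_events: int = 0,
                   seed: int = 0,
                   stall_events: int = 5_000_000,
                   omega_fixed: float | None = None,
                   daughters_eligible: bool = True,
                   division: bool = True,
                   t_end: float | None = None) -> RunResult:
    """Run the exact population SSA.

    Terminates at ``max_divisions`` division events, ``max_events``
    reaction events (0 means an automatic generous budget), global loss
    of a fragment type, a frozen state (zero total propensity), or a
    stall (``stall_events`` reaction events without a single division;
    0 disables).  Fully reproducible given ``seed``.

    ``division=False`` disables the division threshold entirely (single
    growing cells / pure chemistry runs).  ``omega_fixed`` switches the
    bimolecular volume convention from the growing fragment count V to a
    constant value.
    """
    if params.n_frag != 2:
        raise ValueError("the protocell simulator supports n_frag = 2")
    pop = init.copy() if init is not None else init_population(params)
    if pop.n_cells != params.N_cell:
        raise ValueError(f"init has {pop.n_cells} cells, "
                         f"params.N_cell = {params.N_cell}")
    if max_events <= 0:
        max_events = int(5000 * max(max_divisions, 1) *
                         max(params.V_div / 1000.0, 1.0) + 2_000_000)
    v_div = params.V_div if division else _NO_DIVISION
    if not division:
        stall_events = 0
    t, status, n_ev, n_div, rec = _ssa_kernel(
        pop.n_x, pop.n_y, pop.n_c,
        float(params.k_f), float(params.k_b), float(params.k_x),
        float(params.k_y), float(params.D), float(params.p_loss),
        np.int64(v_div), 0.0 if omega_fixed is None else float(omega_fixed),
        daughters_eligible, np.int64(max_divisions if division else 0),
        np.int64(max_events), np.int64(stall_events),
        np.int64(seed % 2**31), float(pop.t),
        -1.0 if t_end is None else float(t_end))
    pop.t = float(t)
    pop.n_divisions += int(n_div)
    df = pd.DataFrame(rec, columns=["t", "cell", "X_tot", "Y_tot", "n_c"])
    for col in ("cell", "X_tot", "Y_tot", "n_c"):
        df[col] = df[col].astype(np.int64)
    return RunResult(population=pop, divisions=df,
                     status=STATUS_NAMES[int(status)], n_events=int(n_ev))
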