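"""Reduced two-subsystem model of the protocell population.

The population of X-dominant and Y-dominant cells is approximated by two
well-mixed subsystems of equal volume exchanging molecules at rate D.
Each subsystem carries a single variable, the total-X concentration
x_i = x_tot^i (with y_tot^i = 1 - x_i since the total concentration of
each subsystem is normalized to 1).  With the fast-equilibrium catalyst
concentration c = x_tot y_tot / 2 and replication rate k = 1, the
single-subsystem drift is

    F(x) = -x^2 (1-x)^2 (1-2x) / 4,

and the coupled system reads

    dx_i/dt = F(x_i) - (D/2) x_i + (D/2) x_j.

For 0 < D < 1/32 an asymmetric fixed-point pair

    x1 = (1 + sqrt(1 - 4 sqrt(2 D))) / 2,   x2 = 1 - x1

exists; its Jacobian eigenvalues along v1 = (1, 1) and v2 = (1, -1) are
lambda1 = 5D - sqrt(2D)/2 and lambda2 = lambda1 - D.  The pair is stable
for D below the bifurcation at D* = 0.02 (lambda1 = 0) and merges with
the symmetric point x1 = x2 = 1/2 at D+ = 1/32 = 0.03125 (lambda2 = 0).
The window 0 < D < D* is where transfer stabilizes balanced replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

__all__ = [
    "ReducedState",
    "FixedPoint",
    "FixedPointSet",
    "PerturbationResult",
    "c_of_totals",
    "reduced_F",
    "reduced_rhs",
    "reduced_jacobian",
    "asymmetric_fixed_points",
    "interior_fixed_points_numeric",
    "eigen_at",
    "count_section_crossings",
    "find_bifurcations",
    "nullclines_and_flow",
    "volume_perturbation",
    "D_STAR_EXACT",
    "D_PLUS_EXACT",
]

#: analytic bifurcation values (loss of X<->Y symmetry; pair merger)
D_STAR_EXACT = 0.02
D_PLUS_EXACT = 1.0 / 32.0

_MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class ReducedState:
    """Total-X concentrations of the two subsystems."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 <= 1.0 and 0.0 <= self.x2 <= 1.0):
            raise ValueError(f"reduced state out of [0,1]^2: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)


@dataclass(frozen=True)
class FixedPoint:
    x1: float
    x2: float
    eigenvalues: tuple[float, float]
    eigenvectors: tuple[tuple[float, float], tuple[float, float]]
    stability: str  # stable | unstable | marginal
    kind: str       # symmetric-interior | asymmetric-pair | corner


@dataclass(frozen=True)
class FixedPointSet:
    D: float
    points: tuple[FixedPoint, ...]

    @property
    def asymmetric(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.kind == "asymmetric-pair")

    @property
    def interior(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.kind != "corner")


@dataclass(frozen=True)
class PerturbationResult:
    """Steady-state response to a volume-fraction perturbation epsilon."""

    D: float
    eps: float
    delta1: float
    delta2: float
    mu1: float
    mu2: float
    mu_star: float
    gamma: float


def c_of_totals(x_tot: float, y_tot: float, mode: str = "approx") -> float:
    """Fast-equilibrium catalyst concentration for k_f = k_b.

    ``exact`` returns 1 - sqrt(1 - x_tot*y_tot); ``approx`` returns
    x_tot*y_tot/2, the small-product expansion used throughout the
    reduced model (relative error < 5% for x_tot*y_tot < 0.18).
    """
    u = x_tot * y_tot
    if u < 0.0 or u > 1.0:
        raise ValueError(f"x_tot*y_tot must lie in [0,1], got {u}")
    if mode == "exact":
        return 1.0 - np.sqrt(1.0 - u)
    if mode == "approx":
        return u / 2.0
    raise ValueError(f"mode must be 'exact' or 'approx', got {mode!r}")


def reduced_F(x):
    """Single-subsystem drift F(x) = -x^2 (1-x)^2 (1-2x)/4 (k = 1)."""
    x = np.asarray(x, dtype=float)
    out = -(x**2) * (1.0 - x) ** 2 * (1.0 - 2.0 * x) / 4.0
    return float(out) if out.ndim == 0 else out


def reduced_rhs(state, D: float) -> np.ndarray:
    """(dx1/dt, dx2/dt) of the coupled two-subsystem system."""
    v = state.as_array() if isinstance(state, ReducedState) else \
        np.asarray(state, dtype=float)
    x1, x2 = v
    return np.array([reduced_F(x1) - 0.5 * D * x1 + 0.5 * D * x2,
                     reduced_F(x2) - 0.5 * D * x2 + 0.5 * D * x1])


def reduced_jacobian(state, D: float, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of reduced_rhs."""
    v = state.as_array() if isinstance(state, ReducedState) else \
        np.asarray(state, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        J[:, j] = (reduced_rhs(v + e, D) - reduced_rhs(v - e, D)) / (2.0 * h)
    return J


def _classify(eigvals: np.ndarray) -> str:
    mx = float(np.max(np.real(eigvals)))
    if abs(mx) < _MARGINAL_TOL:
        return "marginal"
    return "unstable" if mx > 0 else "stable"


def _make_fixed_point(x1: float, x2: float, D: float, kind: str) -> FixedPoint:
    J = reduced_jacobian((x1, x2), D)
    w, v = np.linalg.eig(J)
    w = np.real(w)
    v = np.real(v)
    # order eigenpairs so the first aligns with (1, 1)
    align = np.abs(v[0] + v[1])
    order = np.argsort(-align)
    w, v = w[order], v[:, order]
    vecs = tuple(tuple(v[:, i] / np.max(np.abs(v[:, i]))) for i in range(2))
    return FixedPoint(x1=x1, x2=x2, eigenvalues=(float(w[0]), float(w[1])),
                      eigenvectors=vecs, stability=_classify(w), kind=kind)


def asymmetric_fixed_points(D: float) -> FixedPointSet:
    """All fixed points of the reduced system at transfer constant D.

    The asymmetric pair (present for 0 < D < 1/32) is given by the
    closed form x1 = (1 + sqrt(1 - 4 sqrt(2D)))/2, x2 = 1 - x1, together
    with its swap image; the symmetric interior point (1/2, 1/2) and the
    no-growth corner states (0, 0) and (1, 1) are always included.
    """
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    pts = [_make_fixed_point(0.5, 0.5, D, "symmetric-interior"),
           _make_fixed_point(0.0, 0.0, D, "corner"),
           _make_fixed_point(1.0, 1.0, D, "corner")]
    disc = 1.0 - 4.0 * np.sqrt(2.0 * D)
    if D > 0 and disc > 0:
        x1 = 0.5 * (1.0 + np.sqrt(disc))
        pts.append(_make_fixed_point(x1, 1.0 - x1, D, "asymmetric-pair"))
        pts.append(_make_fixed_point(1.0 - x1, x1, D, "asymmetric-pair"))
    return FixedPointSet(D=D, points=tuple(pts))


def _branch_fixed_point_numeric(D: float) -> float | None:
    """x1 > 1/2 of the asymmetric fixed point on x2 = 1 - x1, by root
    bracketing of reduced_rhs restricted to the antisymmetric manifold;
    None if the branch does not exist at this D."""
    def g(x):
        return reduced_rhs((x, 1.0 - x), D)[0]
    # dense-near-0.5 scan: the root approaches 1/2 as D -> 1/32
    xs = 0.5 + np.concatenate([np.geomspace(1e-7, 0.4999, 600)])
    gs = np.array([g(x) for x in xs])
    sign = np.sign(gs)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    return brentq(g, xs[i], xs[i + 1], xtol=1e-15, rtol=8.9e-16)


def interior_fixed_points_numeric(D: float, n_seed: int = 25,
                                  tol: float = 1e-11) -> list[tuple[float, float]]:
    """Brute-force enumeration of interior fixed points by multi-start
    2-D root finding on reduced_rhs over (0, 1)^2, deduplicated.

    Independent of the closed-form branch; used as the oracle for
    asymmetric_fixed_points.
    """
    seeds = np.linspace(0.02, 0.98, n_seed)
    found: list[tuple[float, float]] = []
    for a in seeds:
        for b in seeds:
            sol = root(lambda v: reduced_rhs(v, D), [a, b], method="hybr",
                       options={"xtol": 1e-13})
            if not sol.success:
                continue
            x1, x2 = sol.x
            if not (1e-6 < x1 < 1 - 1e-6 and 1e-6 < x2 < 1 - 1e-6):
                continue
            if np.max(np.abs(reduced_rhs((x1, x2), D))) > tol:
                continue
            if not any(abs(x1 - p) < 1e-7 and abs(x2 - q) < 1e-7
                       for p, q in found):
                found.append((float(x1), float(x2)))
    return sorted(found)


def eigen_at(state, D: float) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Numeric Jacobian eigen-decomposition at a fixed point.

    Returns (lambda1, lambda2, v1, v2) with the first eigenpair the one
    aligned with (1, 1).  Rejects inputs that are not fixed points.
    """
    v = state.as_array() if isinstance(state, ReducedState) else \
        np.asarray(state, dtype=float)
    if np.max(np.abs(reduced_rhs(v, D))) > 1e-10:
        raise ValueError("eigen_at requires a fixed point "
                         f"(residual {np.max(np.abs(reduced_rhs(v, D))):.2e})")
    J = reduced_jacobian(v, D)
    w, vec = np.linalg.eig(J)
    w, vec = np.real(w), np.real(vec)
    align = np.abs(vec[0] + vec[1])
    order = np.argsort(-align)
    w, vec = w[order], vec[:, order]
    return float(w[0]), float(w[1]), vec[:, 0], vec[:, 1]


def _lambda1_on_branch(D: float) -> float:
    x1 = _branch_fixed_point_numeric(D)
    if x1 is None:
        raise ValueError(f"asymmetric branch absent at D = {D}")
    lam1, _, _, _ = eigen_at((x1, 1.0 - x1), D)
    return lam1


def find_bifurcations(D_max: float = 0.05, tol: float = 1e-8
                      ) -> tuple[float, float]:
    """Locate the two bifurcations of the asymmetric branch numerically.

    D_star: zero crossing of the (1,1)-eigenvalue lambda1 along the
    branch (loss of X<->Y symmetry stability), found by bisection.
    D_plus: termination of the branch, where the asymmetric pair merges
    with the symmetric point (equivalently the (1,-1)-eigenvalue reaches
    zero), found by bisecting the branch-existence predicate.

    Both are computed from numerically tracked fixed points and
    finite-difference Jacobians — no closed forms enter.
    """
    if not D_max > 0.04:
        raise ValueError("D_max must exceed 0.04 to bracket both bifurcations")
    if not tol > 0:
        raise ValueError("tol must be positive")

    # --- D_star: bisect sign change of lambda1 ---
    lo, hi = 1e-4, None
    Ds = np.linspace(1e-4, 0.03, 60)
    prev_D, prev_l = None, None
    for Dv in Ds:
        try:
            lam = _lambda1_on_branch(Dv)
        except ValueError:
            break
        if prev_l is not None and prev_l * lam < 0:
            lo, hi = prev_D, Dv
            break
        prev_D, prev_l = Dv, lam
    if hi is None:
        raise RuntimeError("no sign change of lambda1 found in scan range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _lambda1_on_branch(lo) * _lambda1_on_branch(mid) <= 0:
            hi = mid
        else:
            lo = mid
    D_star = 0.5 * (lo + hi)

    # --- D_plus: bisect branch existence ---
    lo, hi = D_star, D_max
    if _branch_fixed_point_numeric(hi) is not None:
        raise RuntimeError(f"asymmetric branch still present at D_max={D_max}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _branch_fixed_point_numeric(mid) is not None:
            lo = mid
        else:
            hi = mid
    D_plus = 0.5 * (lo + hi)
    return float(D_star), float(D_plus)


def nullclines_and_flow(D: float, grid_n: int = 401) -> dict:
    """Flow field and nullclines of the reduced system on [0,1]^2.

    Returns a dict with the grid, the two derivative components, and the
    nullcline point sets of dx1/dt = 0 and dx2/dt = 0 obtained by
    per-line sign-scan + bisection root refinement.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    g = np.linspace(0.0, 1.0, grid_n)
    X1, X2 = np.meshgrid(g, g, indexing="ij")
    dX1 = reduced_F(X1) - 0.5 * D * X1 + 0.5 * D * X2
    dX2 = reduced_F(X2) - 0.5 * D * X2 + 0.5 * D * X1

    def _contour(which: int) -> np.ndarray:
        pts = []
        for x2 in g:
            def f(x1):
                return reduced_rhs((x1, x2), D)[which]
            vals = np.array([f(x1) for x1 in g])
            s = np.sign(vals)
            for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
                r = brentq(f, g[i], g[i + 1], xtol=1e-12)
                pts.append((r, x2))
            for i in np.nonzero(vals == 0.0)[0]:
                pts.append((g[i], x2))
        return np.array(pts) if pts else np.empty((0, 2))

    return {"grid": g, "dx1": dX1, "dx2": dX2,
            "nullcline_x1": _contour(0), "nullcline_x2": _contour(1)}


def count_section_crossings(D: float) -> int:
    """Number of distinct interior fixed points on the two swap-symmetric
    sections x2 = x1 and x2 = 1 - x1.

    This is the fixed-point structure behind the 'three fixed points to
    one' transition: for 0 < D < 1/32 the antidiagonal carries the
    symmetric point and the asymmetric pair (3 points); above the merger
    only the symmetric point remains (1).  The full plane additionally
    contains off-section saddle crossings (see
    ``interior_fixed_points_numeric``), which do not take part in the
    transition.
    """
    pts: list[tuple[float, float]] = [(0.5, 0.5)]  # only interior root of F
    def g(x):
        return reduced_rhs((x, 1.0 - x), D)[0]
    xs = np.concatenate([0.5 + np.geomspace(1e-7, 0.4999, 400),
                         0.5 - np.geomspace(1e-7, 0.4999, 400)])
    xs = np.sort(xs)
    gs = np.array([g(x) for x in xs])
    s = np.sign(gs)
    for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
        r = brentq(g, xs[i], xs[i + 1], xtol=1e-14)
        if 1e-9 < r < 1 - 1e-9 and not any(
                abs(r - p) < 1e-7 and abs((1 - r) - q) < 1e-7
                for p, q in pts):
            pts.append((r, 1.0 - r))
    return len(pts)


def _mu_of_x(x: float) -> float:
    """Subsystem growth rate mu(x) = {1 - x(1-x)} x(1-x)/2 under the
    approximate catalyst concentration c = x(1-x)/2."""
    c = c_of_totals(x, 1.0 - x, "approx")
    return (1.0 - 2.0 * c) * c


def volume_perturbation(D: float, eps: float) -> PerturbationResult:
    """Frequency-dependent selection from a volume-fraction perturbation.

    The subsystems occupy volume fractions 1/2 + eps and 1/2 - eps.  A
    molecule leaving subsystem i returns to it with probability equal to
    its own cell-number share, and incoming amounts are converted to
    concentrations by the receiving volume, giving

        dx1/dt = F(x1) + D (1/2 - eps) (x2 - x1)
        dx2/dt = F(x2) + D (1/2 + eps) (x1 - x2).

    Returns the first-order concentration shifts delta1 = delta2 (linear
    solve at the unperturbed fixed point), the growth rates mu1, mu2 at
    the nonlinear perturbed steady state, the unperturbed rate mu*, and
    the selection coefficient gamma = (mu2 - mu*)/eps.  For 0 < D < D*
    and eps > 0 the minority subsystem grows faster (mu2 > mu* > mu1,
    gamma > 0), restoring the balanced 1:1 population.
    """
    if not 0.0 < D < D_STAR_EXACT:
        raise ValueError(f"volume_perturbation requires 0 < D < {D_STAR_EXACT}")
    if abs(eps) >= 0.1:
        raise ValueError("|eps| must be < 0.1")

    x_star = 0.5 * (1.0 + np.sqrt(1.0 - 4.0 * np.sqrt(2.0 * D)))
    base = np.array([x_star, 1.0 - x_star])
    mu_star = _mu_of_x(x_star)

    if eps == 0.0:
        return PerturbationResult(D=D, eps=0.0, delta1=0.0, delta2=0.0,
                                  mu1=mu_star, mu2=mu_star, mu_star=mu_star,
                                  gamma=float("nan"))

    def rhs_eps(v: np.ndarray, e: float) -> np.ndarray:
        x1, x2 = v
        return np.array([
            reduced_F(x1) + D * (0.5 - e) * (x2 - x1),
            reduced_F(x2) + D * (0.5 + e) * (x1 - x2),
        ])

    # first-order shifts: J delta = -d(rhs)/d(eps) * eps at the base point
    J = reduced_jacobian(base, D)
    h = 1e-7
    b = (rhs_eps(base, h) - rhs_eps(base, -h)) / (2.0 * h)
    delta = np.linalg.solve(J, -b * eps)

    # nonlinear perturbed steady state for the growth rates
    sol = root(lambda v: rhs_eps(v, eps), base + delta, method="hybr")
    if np.max(np.abs(rhs_eps(sol.x, eps))) > 1e-12:
        raise RuntimeError("no perturbed steady state found "
                           f"(D={D}, eps={eps})")
    x1s, x2s = sol.x
    mu1, mu2 = _mu_of_x(x1s), _mu_of_x(x2s)
    gamma = (mu2 - mu_star) / eps
    return PerturbationResult(D=D, eps=eps, delta1=float(delta[0]),
                              delta2=float(delta[1]), mu1=mu1, mu2=mu2,
                              mu_star=mu_star, gamma=float(gamma))
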