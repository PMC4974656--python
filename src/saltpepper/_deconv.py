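"""Core solver for non-negative AR(1) calcium deconvolution.

Solves, for a drift-corrected trace z and per-frame decay gamma,

    min_c  0.5 * ||z - c||^2 + lam * sum(s)      (penalized form)
    s.t.   s_0 = c_0 >= 0,  s_t = c_t - gamma * c_{t-1} >= 0

by pool-adjacent-violators on the equivalent weighted isotonic problem
(substituting u_t = c_t / gamma^t turns the AR(1) chain into a monotone
chain; clipping negative pools at zero is exact for isotonic regression
with a lower bound).  The noise-constrained form ``||z - c|| <= R`` is
obtained by bisecting the penalty lam, which is its Lagrange dual.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _oasis_ar1(yhat: np.ndarray, gamma: float) -> np.ndarray:
    """Project yhat onto {c : c_0 >= 0, c_t >= gamma * c_{t-1}}."""
    T = yhat.shape[0]
    # pool arrays: value numerator, weight, start index, length
    pv = np.empty(T)
    pw = np.empty(T)
    pt = np.empty(T, dtype=np.int64)
    pl = np.empty(T, dtype=np.int64)
    m = 0
    for t in range(T):
        pv[m] = yhat[t]
        pw[m] = 1.0
        pt[m] = t
        pl[m] = 1
        m += 1
        while m > 1 and pv[m - 1] / pw[m - 1] < gamma ** pl[m - 2] * pv[m - 2] / pw[m - 2]:
            g = gamma ** pl[m - 2]
            pv[m - 2] += g * pv[m - 1]
            pw[m - 2] += g * g * pw[m - 1]
            pl[m - 2] += pl[m - 1]
            m -= 1
    c = np.empty(T)
    for i in range(m):
        val = pv[i] / pw[i]
        if val < 0.0:
            val = 0.0
        for k in range(pl[i]):
            c[pt[i] + k] = val
            val *= gamma
    return c


def oasis_penalized(z: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    """Minimizer of 0.5*||z - c||^2 + lam*sum(s) over the AR(1) cone."""
    T = len(z)
    yhat = z - lam * (1.0 - gamma)
    yhat[-1] = z[-1] - lam  # last frame has no successor term
    return _oasis_ar1(np.ascontiguousarray(yhat, dtype=np.float64), gamma)


def spikes_from_calcium(c: np.ndarray, gamma: float) -> np.ndarray:
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return np.maximum(s, 0.0)


def natural_cubic_basis(T: int, n_knots: int) -> np.ndarray:
    """Natural cubic spline basis on frames 0..T-1 with equally spaced knots.

    Returns a (T, n_knots) design matrix (constant and linear terms
    included), linear beyond the boundary knots.
    """
    if n_knots < 4:
        raise ValueError("need at least 4 knots for a natural cubic spline")
    x = np.arange(T, dtype=float) / max(T - 1, 1)  # unit scale for conditioning
    knots = np.linspace(0.0, 1.0, n_knots)
    K = n_knots

    def d(k):
        return ((np.maximum(x - knots[k], 0.0) ** 3 -
                 np.maximum(x - knots[K - 1], 0.0) ** 3) / (knots[K - 1] - knots[k]))

    cols = [np.ones(T), x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)[:, :K]


def _sum_s_weights(T: int, gamma: float) -> np.ndarray:
    """Vector mu with mu @ c == sum(s) on the AR(1) cone."""
    mu = np.full(T, 1.0 - gamma)
    mu[-1] = 1.0
    return mu


def _solve_penalized_with_drift(
    y: np.ndarray, gamma: float, lam: float, basis: np.ndarray,
    c0: np.ndarray, basis_pinv: np.ndarray | None = None,
    max_iter: int = 20000, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint minimization over (c, drift) at fixed penalty lam.

    The drift coefficients are eliminated analytically: with P the
    projector orthogonal to the spline column space, the problem becomes
    ``min 0.5*||P(y - c)||^2 + lam * mu @ c`` over the AR(1) cone, solved
    by accelerated projected gradient (FISTA with function restart; the
    cone projection is the pool-adjacent-violators routine).  Plain
    block-coordinate alternation is avoided here because the spline and
    the slowly decaying cone directions are nearly collinear and make it
    stall far from the optimum.
    """
    Bp = np.linalg.pinv(basis) if basis_pinv is None else basis_pinv
    T = len(y)
    mu = _sum_s_weights(T, gamma)

    def project_out(v):
        return v - basis @ (Bp @ v)

    Py = project_out(y)

    def grad(c):
        return project_out(c) - Py + lam * mu

    def objective(c):
        r = Py - project_out(c)
        return 0.5 * float(r @ r) + lam * float(mu @ c)

    c = _oasis_ar1(np.ascontiguousarray(c0, dtype=np.float64), gamma)
    z = c.copy()
    tk = 1.0
    f_prev = objective(c)
    stall = 0
    for _ in range(max_iter):
        g = grad(z)
        c_new = _oasis_ar1(z - g, gamma)  # L = 1: P has unit spectral norm
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = c_new + ((tk - 1.0) / t_new) * (c_new - c)
        f_new = objective(c_new)
        if f_new > f_prev:  # function restart
            z = c_new.copy()
            t_new = 1.0
        if abs(f_prev - f_new) <= tol * max(1.0, abs(f_prev)):
            stall += 1
            if stall >= 5:
                c = c_new
                break
        else:
            stall = 0
        c, tk, f_prev = c_new, t_new, min(f_prev, f_new)
    d = Bp @ (y - c)
    return c, d


def deconvolve_constrained(
    y: np.ndarray,
    gamma: float,
    sigma: float,
    n_knots: int = 10,
    max_outer: int = 50,
    rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Noise-constrained deconvolution with spline drift.

    Solves  min sum(s)  s.t.  s >= 0, c_t = gamma*c_{t-1} + s_t,
    ||y - c - drift||_2 <= sigma*sqrt(T), drift spanned by a natural cubic
    spline basis with ``n_knots`` knots.

    Returns (spikes, drift, fitted_calcium, info); ``info['feasible']`` is
    False when even the unpenalized projection exceeds the noise ball, in
    which case that projection (the closest feasible-dynamics fit) is
    returned and flagged.
    """
    y = np.asarray(y, dtype=np.float64)
    T = len(y)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if T < 2 * n_knots:
        raise ValueError(f"trace too short ({T}) for {n_knots}-knot drift spline")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must be in (0, 1)")
    basis, _ = np.linalg.qr(natural_cubic_basis(T, n_knots))
    basis_pinv = basis.T
    R2 = sigma * sigma * T

    def rss_at(lam, c_warm):
        c, d = _solve_penalized_with_drift(y, gamma, lam, basis, c_warm, basis_pinv)
        r = y - c - basis @ d
        return float(r @ r), c, d

    rss0, c0, dd0 = rss_at(0.0, np.maximum(y, 0.0))
    info = {"feasible": True, "lam": 0.0}
    if rss0 > R2 * (1.0 + 1e-7):
        # noise ball unreachable even at zero penalty: flagged fallback
        info["feasible"] = False
        c, d = c0, dd0
    elif rss0 >= R2 * (1.0 - rtol):
        c, d = c0, dd0
    else:
        # bracket the dual penalty, then bisect RSS(lam) to the noise ball
        lo, hi = 0.0, max(1.0, sigma)
        c_warm = c0
        c_lo, d_lo = c0, dd0
        for _ in range(60):
            rss_hi, c_hi, d_hi = rss_at(hi, c_warm)
            c_warm = c_hi
            if rss_hi >= R2:
                break
            lo, c_lo, d_lo = hi, c_hi, d_hi
            if np.max(np.abs(c_hi)) == 0.0:
                break  # trace explained by drift alone: s = 0 is optimal
            hi *= 4.0
        c, d = c_lo, d_lo
        info["lam"] = lo
        if rss_hi >= R2:
            for _ in range(max_outer):
                mid = 0.5 * (lo + hi)
                rss_m, c_m, d_m = rss_at(mid, c_warm)
                c_warm = c_m
                if rss_m > R2:
                    hi = mid
                else:
                    lo, c, d = mid, c_m, d_m
                    info["lam"] = mid
                if abs(rss_m - R2) <= rtol * R2:
                    c, d = c_m, d_m
                    info["lam"] = mid
                    break
    spikes = spikes_from_calcium(c, gamma)
    drift = basis @ d
    return spikes, drift, c, info
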