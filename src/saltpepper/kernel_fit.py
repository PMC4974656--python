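"""Separable linear response model fit by alternating least squares.

Each cell's inferred spike train y(t) is modelled as

    y(t) = sum_tau v(tau) * w(cond(t - tau)) + b + a * r(t) + noise

where ``w`` is the spatial kernel on the folded Fourier (orientation x
spatial-frequency) grid, ``v`` a unit-norm temporal kernel over ``n_lags``
imaging frames, ``b`` a resting offset and ``a`` an additive locomotion
offset driven by the running indicator ``r(t)``.  ``w`` carries a
smoothness penalty (squared discrete Laplacian on the grid) whose strength
is selected by cross-validation over contiguous time blocks; model quality
is summarized by the r_L statistic, the correlation-like comparison of the
cross-validated model SSE against a stimulus-free baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse

from .stimulus import DesignTensor, FourierGrid

__all__ = [
    "FitConfig",
    "KernelFit",
    "fit_baseline",
    "als_fit",
    "als_fit_multistart",
    "cross_validate_penalty",
    "r_L_statistic",
    "kernel_peak",
    "select_cells",
    "fit_cell",
    "grid_laplacian",
]

R_L_THRESHOLD = 0.15
MIN_CELLS_PER_FIELD = 20


@dataclass(frozen=True)
class FitConfig:
    """Hyper-parameters of the ALS kernel fit."""

    n_lags: int = 8
    penalty_grid: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5)
    n_folds: int = 5
    max_als_iters: int = 30
    tol: float = 1e-6
    r_L_threshold: float = R_L_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if len(self.penalty_grid) == 0 or any(p <= 0 for p in self.penalty_grid):
            raise ValueError("penalty_grid must be non-empty and positive")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")


@dataclass
class KernelFit:
    """Result of fitting one cell."""

    w: np.ndarray
    v: np.ndarray
    b: float
    a: float
    penalty: float
    sse_model: float
    sse_baseline: float
    r_L: float
    significant: bool
    pref_orientation_deg: float
    pref_sf_cpd: float
    converged: bool = True
    objective_path: np.ndarray | None = field(default=None, repr=False)


def fit_baseline(y: np.ndarray, running: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of the stimulus-free model y = b + a * r.

    If the running indicator never changes, ``a`` is undefined: it is set
    to zero and the offset absorbs the mean.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(running, dtype=float)
    if y.shape != r.shape:
        raise ValueError("y and running must have equal length")
    if np.ptp(r) == 0.0:
        b = float(np.mean(y))
        sse = float(np.sum((y - b) ** 2))
        return b, 0.0, sse
    on = r > 0
    m1, m0 = float(np.mean(y[on])), float(np.mean(y[~on]))
    b, a = m0, m1 - m0
    sse = float(np.sum((y - b - a * r) ** 2))
    return b, a, sse


def grid_laplacian(grid: FourierGrid) -> np.ndarray:
    """Discrete Laplacian on the folded Fourier lattice.

    Four-connected neighbours; missing neighbours (grid edge or the
    excluded DC cell) are treated as reflecting, i.e. simply omitted, and
    neighbours across the fold seam map onto their representatives.  The
    smoothness penalty uses ``L.T @ L`` (squared Laplacian).
    """
    G = grid.n_cells
    L = np.zeros((G, G))
    for i in range(G):
        kx, ky = int(grid.kx[i]), int(grid.ky[i])
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            try:
                j = grid.index_of(kx + dx, ky + dy)
            except KeyError:
                continue
            L[i, i] += 1.0
            L[i, j] -= 1.0
    return L


class _CellDesign:
    """Pre-indexed design shared by all ALS steps for one recording.

    ``lag_idx[tau, t]`` is the folded grid cell of the condition shown
    ``tau`` frames before frame ``t`` (-1 when none).
    """

    def __init__(self, design: DesignTensor, running: np.ndarray, n_lags: int | None = None):
        self.grid = design.grid
        self.n_lags = int(n_lags or design.n_lags)
        T = design.n_frames
        self.n_frames = T
        self.running = np.asarray(running, dtype=float)
        if len(self.running) != T:
            raise ValueError("running indicator length must match design frames")
        self.lag_idx = np.stack([design.lagged_condition(k) for k in range(self.n_lags)])
        self.penalty_matrix = None  # set lazily

    def laplacian_sq(self) -> np.ndarray:
        if self.penalty_matrix is None:
            L = grid_laplacian(self.grid)
            self.penalty_matrix = L.T @ L
        return self.penalty_matrix

    def subset(self, frames: np.ndarray) -> "_CellDesign":
        out = object.__new__(_CellDesign)
        out.grid = self.grid
        out.n_lags = self.n_lags
        out.n_frames = len(frames)
        out.running = self.running[frames]
        out.lag_idx = self.lag_idx[:, frames]
        out.penalty_matrix = self.penalty_matrix
        return out

    # -- model algebra -----------------------------------------------------
    def temporal_profiles(self, w: np.ndarray) -> np.ndarray:
        """(n_lags, T) array u[tau, t] = w[lag_idx[tau, t]] (0 where none)."""
        wpad = np.concatenate([w, [0.0]])  # -1 indexes the zero pad
        return wpad[self.lag_idx]

    def predict(self, w: np.ndarray, v: np.ndarray, b: float, a: float) -> np.ndarray:
        return v @ self.temporal_profiles(w) + b + a * self.running

    def spatial_design(self, v: np.ndarray) -> scipy.sparse.csr_matrix:
        """Sparse (T, G + 2) design for the w-step; last cols are 1 and r."""
        T, G, L = self.n_frames, self.grid.n_cells, self.n_lags
        rows, cols, data = [], [], []
        for tau in range(L):
            idx = self.lag_idx[tau]
            ok = idx >= 0
            rows.append(np.nonzero(ok)[0])
            cols.append(idx[ok])
            data.append(np.full(ok.sum(), v[tau]))
        t_all = np.arange(T)
        rows = np.concatenate(rows + [t_all, t_all])
        cols = np.concatenate(cols + [np.full(T, G), np.full(T, G + 1)])
        data = np.concatenate(data + [np.ones(T), self.running])
        return scipy.sparse.csr_matrix(
            scipy.sparse.coo_matrix((data, (rows, cols)), shape=(T, G + 2))
        )


def _unit_norm_ls(U: np.ndarray, Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """min over (v, beta) of ||y - U v - Z beta||^2 subject to ||v|| = 1.

    Z columns (offsets) are profiled out; the sphere-constrained quadratic
    in v is solved exactly through its secular equation.
    """
    Q, _ = np.linalg.qr(Z)
    Ut = U - Q @ (Q.T @ U)
    yt = y - Q @ (Q.T @ y)
    H = Ut.T @ Ut
    g = Ut.T @ yt
    lam, V = np.linalg.eigh(H)
    beta = V.T @ g

    def norm2(nu):
        return float(np.sum((beta / (lam + nu)) ** 2))

    lo = -lam[0] + 1e-12 * max(1.0, lam[-1])
    # ensure ||v(lo)|| >= 1 (else the hard case: nudge along first eigvec)
    if norm2(lo) < 1.0:
        v = V @ (beta / (lam + lo))
        deficit = np.sqrt(max(0.0, 1.0 - float(v @ v)))
        v = v + deficit * V[:, 0]
    else:
        hi = lo + max(1.0, lam[-1])
        while norm2(hi) > 1.0:
            hi = lo + 2 * (hi - lo)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if norm2(mid) > 1.0:
                lo = mid
            else:
                hi = mid
        v = V @ (beta / (lam + 0.5 * (lo + hi)))
    nv = np.linalg.norm(v)
    if nv > 0:
        v = v / nv
    offs = np.linalg.lstsq(Z, y - U @ v, rcond=None)[0]
    return v, offs


V_INIT_DECAY_FRAMES = (1.0, 1.5, 2.0, 3.0)


def _default_v_init(n_lags: int, decay_frames: float = 2.0) -> np.ndarray:
    """Generic causal rise-and-decay temporal profile, unit norm.

    The lagged stimulus regressors are nearly collinear (one condition
    persists ~4 imaging frames), which leaves the bilinear ALS problem
    with sticky local basins; a causal bump is a far better-behaved start
    than a delta.
    """
    tau = np.arange(n_lags, dtype=float)
    v = tau * np.exp(-tau / decay_frames) if n_lags > 1 else np.ones(1)
    if not np.any(v):
        v = np.ones(n_lags)
    return v / np.linalg.norm(v)


def als_fit_multistart(
    y: np.ndarray,
    design,
    running: np.ndarray | None = None,
    config: FitConfig | None = None,
    penalty: float | None = None,
    decay_grid: tuple[float, ...] = V_INIT_DECAY_FRAMES,
) -> KernelFit:
    """ALS from several generic temporal-profile starts; best objective wins."""
    best = None
    for s in decay_grid:
        cfg = config or FitConfig()
        v0 = _default_v_init(cfg.n_lags, s)
        fit = als_fit(y, design, running, config, penalty,
                      init=(np.zeros(0), v0))
        obj = fit.objective_path[-1] if len(fit.objective_path) else np.inf
        if best is None or obj < best[0]:
            best = (obj, fit)
    return best[1]


def als_fit(
    y: np.ndarray,
    design: DesignTensor | _CellDesign,
    running: np.ndarray | None = None,
    config: FitConfig | None = None,
    penalty: float | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> KernelFit:
    """Alternating least squares for (w, v, b, a) at a fixed penalty.

    Alternates an exact penalized least-squares update of (w, b, a) given v
    with an exact unit-sphere-constrained update of (v, b, a) given w, so
    the penalized objective ``SSE + penalty * ||Lap w||^2`` is non-increasing
    at every half-step.  The temporal kernel's sign is fixed so that its
    largest-magnitude element is positive.
    """
    config = config or FitConfig()
    if isinstance(design, _CellDesign):
        cd = design
    else:
        if running is None:
            running = np.zeros(design.n_frames)
        cd = _CellDesign(design, running, config.n_lags)
    y = np.asarray(y, dtype=float)
    if len(y) != cd.n_frames:
        raise ValueError("y length must match design frames")
    if penalty is None:
        penalty = float(config.penalty_grid[0]) if len(config.penalty_grid) == 1 else None
    if penalty is None:
        raise ValueError("penalty must be given (or a single-element penalty_grid)")

    G, L = cd.grid.n_cells, cd.n_lags
    P = cd.laplacian_sq()
    Z = np.column_stack([np.ones(cd.n_frames), cd.running])
    if np.ptp(cd.running) == 0.0:
        Z = Z[:, :1]

    if init is None:
        v = _default_v_init(L)
        w = None
    else:
        w0, v0 = init
        v = np.asarray(v0, dtype=float).copy()
        w = None if w0 is None or np.size(w0) == 0 else np.asarray(w0, float).copy()

    def w_step(v, pen):
        M = cd.spatial_design(v)
        if Z.shape[1] == 1:
            M = M[:, : G + 1]
        A = (M.T @ M).toarray()
        A[:G, :G] += pen * P
        A[np.diag_indices_from(A)] += 1e-8 * max(1.0, A.diagonal().max())
        rhs = M.T @ y
        theta = scipy.linalg.solve(A, rhs, assume_a="pos")
        w = theta[:G]
        b = float(theta[G])
        a = float(theta[G + 1]) if Z.shape[1] == 2 else 0.0
        return w, b, a

    if w is None:
        w, b, a = w_step(v, 0.0)  # unpenalized spatial init

    obj_path = []
    prev = np.inf
    converged = False
    for _ in range(config.max_als_iters):
        w, b, a = w_step(v, penalty)
        resid = y - cd.predict(w, v, b, a)
        obj_w = float(resid @ resid) + penalty * float(w @ (P @ w))
        obj_path.append(obj_w)

        U = cd.temporal_profiles(w).T  # (T, L)
        v, offs = _unit_norm_ls(U, Z, y)
        b = float(offs[0])
        a = float(offs[1]) if Z.shape[1] == 2 else 0.0
        resid = y - cd.predict(w, v, b, a)
        obj_v = float(resid @ resid) + penalty * float(w @ (P @ w))
        obj_path.append(obj_v)
        if np.isfinite(prev) and prev - obj_v <= config.tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = obj_v

    imax = int(np.argmax(np.abs(v)))
    if v[imax] < 0:
        v = -v
        w = -w

    ori, sf = kernel_peak(w, cd.grid)
    return KernelFit(
        w=w, v=v, b=b, a=a, penalty=float(penalty),
        sse_model=float("nan"), sse_baseline=float("nan"), r_L=float("nan"),
        significant=False, pref_orientation_deg=ori, pref_sf_cpd=sf,
        converged=converged, objective_path=np.asarray(obj_path),
    )


def _fold_blocks(T: int, n_folds: int) -> list[np.ndarray]:
    """Contiguous time blocks, respecting temporal autocorrelation."""
    return [np.asarray(b) for b in np.array_split(np.arange(T), n_folds)]


def cross_validate_penalty(
    y: np.ndarray,
    design: DesignTensor | _CellDesign,
    running: np.ndarray | None = None,
    config: FitConfig | None = None,
    return_details: bool = False,
):
    """Choose the smoothness penalty by contiguous-block cross-validation.

    For each grid value, the model is fit on the training blocks and scored
    by summed held-out SSE; ties prefer the larger (smoother) penalty.
    With ``return_details`` also returns the pooled held-out model SSE at
    the selected penalty and the pooled held-out baseline SSE, the inputs
    of the r_L statistic.
    """
    config = config or FitConfig()
    if isinstance(design, _CellDesign):
        cd = design
    else:
        if running is None:
            running = np.zeros(design.n_frames)
        cd = _CellDesign(design, running, config.n_lags)
    y = np.asarray(y, dtype=float)
    cd.laplacian_sq()  # share across subsets
    blocks = _fold_blocks(cd.n_frames, config.n_folds)
    penalties = sorted(config.penalty_grid)

    cv_sse = np.zeros(len(penalties))
    sse_base = 0.0
    for k, test in enumerate(blocks):
        train = np.concatenate([b for j, b in enumerate(blocks) if j != k])
        cd_train = cd.subset(train)
        cd_test = cd.subset(test)
        y_tr, y_te = y[train], y[test]
        b0, a0, _ = fit_baseline(y_tr, cd_train.running)
        sse_base += float(np.sum((y_te - b0 - a0 * cd_test.running) ** 2))
        init = None
        for i, pen in enumerate(penalties):
            fit = als_fit(y_tr, cd_train, config=config, penalty=pen, init=init)
            init = (fit.w, fit.v)  # warm start the next penalty
            pred = cd_test.predict(fit.w, fit.v, fit.b, fit.a)
            cv_sse[i] += float(np.sum((y_te - pred) ** 2))
    mins = np.nonzero(cv_sse == cv_sse.min())[0]
    best = int(mins[-1])  # ties -> larger penalty
    penalty = float(penalties[best])
    if return_details:
        return penalty, float(cv_sse[best]), float(sse_base)
    return penalty


def r_L_statistic(sse_model: float, sse_baseline: float) -> float:
    """Goodness of fit r_L = sqrt(max(0, 1 - SSE_model / SSE_baseline)).

    Comparing the cross-validated model SSE against the stimulus-free
    baseline SSE, r_L plays the role of a correlation coefficient between
    model prediction and response.
    """
    if sse_baseline <= 0:
        raise ValueError("sse_baseline must be positive")
    return float(np.sqrt(max(0.0, 1.0 - sse_model / sse_baseline)))


def kernel_peak(w: np.ndarray, grid: FourierGrid) -> tuple[float, float]:
    """(preferred orientation deg, peak spatial frequency cpd) at argmax w.

    An all-equal kernel has no defined peak and returns (nan, nan); by the
    fold symmetry the peak is identical on the folded and full planes.
    """
    w = np.asarray(w, dtype=float)
    if np.ptp(w) == 0.0:
        return float("nan"), float("nan")
    i = int(np.argmax(w))
    return float(grid.orientation_deg[i]), float(grid.sf_cpd[i])


def select_cells(
    fits: list[KernelFit],
    r_L_threshold: float = R_L_THRESHOLD,
    min_cells: int = MIN_CELLS_PER_FIELD,
) -> tuple[bool, np.ndarray]:
    """Keep significantly tuned cells; accept the field if enough survive.

    Cells pass with ``r_L >= r_L_threshold`` (boundary inclusive); the
    field is accepted when the passing count strictly exceeds ``min_cells``.
    Returns (field_accepted, indices of kept cells).
    """
    if len(fits) == 0:
        raise ValueError("no fits given")
    kept = np.array([i for i, f in enumerate(fits)
                     if np.isfinite(f.r_L) and f.r_L >= r_L_threshold], dtype=int)
    return len(kept) > min_cells, kept


def fit_cell(
    y: np.ndarray,
    design: DesignTensor | _CellDesign,
    running: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> KernelFit:
    """Full per-cell pipeline: CV penalty selection, r_L, final ALS fit."""
    config = config or FitConfig()
    if isinstance(design, _CellDesign):
        cd = design
    else:
        if running is None:
            running = np.zeros(design.n_frames)
        cd = _CellDesign(design, running, config.n_lags)
    penalty, sse_model, sse_baseline = cross_validate_penalty(
        y, cd, config=config, return_details=True
    )
    rl = r_L_statistic(sse_model, sse_baseline)
    fit = als_fit_multistart(y, cd, config=config, penalty=penalty)
    return replace(
        fit,
        sse_model=sse_model,
        sse_baseline=sse_baseline,
        r_L=rl,
        significant=rl >= config.r_L_threshold,
    )
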