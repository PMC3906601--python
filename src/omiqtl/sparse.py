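"""L1-penalized least squares, cross-validated penalty selection, and the
Screen-and-Clean selection/p-value procedure.

The lasso objective is kept on the raw residual-sum-of-squares scale,

    f(beta) = sum_i (y_i - x_i . beta)^2 + lambda * sum_j |beta_j|,

with no intercept: designs are standardized and traits centered upstream, so
beta_0 drops out.  On this scale the solution is identically zero for
lambda >= lambda_max = 2 * max_j |x_j' y|, and for an orthonormal design with
x_j' x_j = N the coordinate solution is soft-threshold(x_j' y, lambda/2) / N.

The solver is cyclic coordinate descent over a warm-started descending
lambda path, with active-set sweeps between full sweeps (the glmnet
strategy).  Convergence: max coefficient change < tol * max(1, ||beta||_inf),
tol = 1e-9 by default, capped at 10,000 sweeps.

Screen-and-Clean splits the samples in two: the lasso (penalty chosen by
K-fold cross-validation) run on the screen half proposes a candidate set;
ordinary least squares on the clean half yields honest two-sided t-test
p-values for the candidates, thresholded at alpha (0.05).  Because the two
halves are disjoint, null p-values are uniform and the per-feature
false-selection rate is controlled at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import linalg, stats

#: the lambda grid is geometric from lambda_max down to
#: lambda_max * DEFAULT_LAMBDA_MIN_RATIO.  The screen half of a
#: Screen-and-Clean split often has J comparable to N, where lambdas below
#: ~0.01 * lambda_max approach the interpolation regime: the solution turns
#: dense, the Gram matrix near-singular, and coordinate descent slows by two
#: orders of magnitude while cross-validation never favors that regime.  The
#: grid floor therefore follows the n < p convention of reference lasso
#: implementations.
DEFAULT_N_LAMBDA = 60
DEFAULT_LAMBDA_MIN_RATIO = 1e-2
DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 10_000
#: looser tolerance used inside cross-validation folds, where the held-out
#: error is insensitive to the last digits of the coefficients
CV_TOL = 1e-4


@njit(cache=True)
def _cd_solve(XT, r, beta, lam, colsq, tol, max_iter):
    """Cyclic coordinate descent on one lambda; r and beta update in place.

    Alternates one full sweep with active-set sweeps restricted to the
    current nonzero coordinates.  Returns (sweeps, converged): converged is
    judged on a full sweep so the KKT conditions hold for every coordinate.
    """
    J, N = XT.shape
    lam_half = 0.5 * lam
    sweeps = 0
    while sweeps < max_iter:
        # full sweep
        maxd = 0.0
        maxb = 0.0
        for j in range(J):
            cj = colsq[j]
            if cj <= 0.0:
                continue
            bj = beta[j]
            xj = XT[j]
            xr = 0.0
            for i in range(N):
                xr += xj[i] * r[i]
            rho = xr + cj * bj
            if rho > lam_half:
                bn = (rho - lam_half) / cj
            elif rho < -lam_half:
                bn = (rho + lam_half) / cj
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                for i in range(N):
                    r[i] -= d * xj[i]
                beta[j] = bn
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
            ab = abs(bn)
            if ab > maxb:
                maxb = ab
        sweeps += 1
        if maxd <= tol * max(1.0, maxb):
            return sweeps, True
        # active-set sweeps until stable
        while sweeps < max_iter:
            maxd = 0.0
            maxb = 0.0
            for j in range(J):
                if beta[j] == 0.0:
                    continue
                cj = colsq[j]
                bj = beta[j]
                xj = XT[j]
                xr = 0.0
                for i in range(N):
                    xr += xj[i] * r[i]
                rho = xr + cj * bj
                if rho > lam_half:
                    bn = (rho - lam_half) / cj
                elif rho < -lam_half:
                    bn = (rho + lam_half) / cj
                else:
                    bn = 0.0
                d = bn - bj
                if d != 0.0:
                    for i in range(N):
                        r[i] -= d * xj[i]
                    beta[j] = bn
                    ad = abs(d)
                    if ad > maxd:
                        maxd = ad
                ab = abs(bn)
                if ab > maxb:
                    maxb = ab
            sweeps += 1
            if maxd <= tol * max(1.0, maxb):
                break
    return sweeps, False


@njit(cache=True)
def _cd_path(XT, y, lambdas, colsq, tol, max_iter):
    """Warm-started descending-lambda path; returns an L x J coefficient array."""
    J = XT.shape[0]
    L = lambdas.shape[0]
    betas = np.zeros((L, J))
    beta = np.zeros(J)
    r = y.copy()
    for l in range(L):
        _cd_solve(XT, r, beta, lambdas[l], colsq, tol, max_iter)
        betas[l] = beta
    return betas


def _as_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(np.asarray(X, dtype=float).T)  # J x N, row-contiguous
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    colsq = np.einsum("jn,jn->j", X, X)
    return X, y, colsq


@dataclass
class LassoSolution:
    coefficients: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool


def lasso_objective(X, y, beta, lam) -> float:
    r = y - X @ beta
    return float(r @ r + lam * np.abs(beta).sum())


@njit(cache=True)
def _abs_xty_max(XT, y):
    # same sequential summation as the descent kernel, so that at
    # lambda == lambda_max the subgradient tie is exact in floating point
    best = 0.0
    for j in range(XT.shape[0]):
        s = 0.0
        xj = XT[j]
        for i in range(y.shape[0]):
            s += xj[i] * y[i]
        a = abs(s)
        if a > best:
            best = a
    return best


def lambda_max(X, y) -> float:
    """Smallest penalty with an all-zero solution: 2 * max_j |x_j' y|."""
    XT = np.ascontiguousarray(np.asarray(X, dtype=float).T)
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    return float(2.0 * _abs_xty_max(XT, y))


def lambda_grid(
    lmax: float,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Geometric grid from lambda_max down to lambda_max * min_ratio."""
    if n_lambda < 1:
        raise ValueError("n_lambda must be positive")
    if lmax <= 0:
        raise ValueError("lambda_max must be positive to build a grid")
    return lmax * np.geomspace(1.0, min_ratio, n_lambda)


def lasso_fit(
    X,
    y,
    lam: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> LassoSolution:
    """Solve min ||y - X beta||^2 + lam * ||beta||_1 (no intercept).

    Deterministic for fixed inputs (fixed cyclic coordinate order).  On
    non-convergence the best iterate is returned with ``converged=False``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    XT, y, colsq = _as_design(X, y)
    beta = np.zeros(XT.shape[0])
    r = y.copy()
    n_iter, converged = _cd_solve(XT, r, beta, lam, colsq, tol, max_iter)
    return LassoSolution(
        coefficients=beta,
        lam=float(lam),
        objective=float(r @ r + lam * np.abs(beta).sum()),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def lasso_path(X, y, lambdas, tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Coefficients along a descending lambda grid (L x J), warm-started."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be non-increasing")
    XT, y, colsq = _as_design(X, y)
    return _cd_path(XT, y, lambdas, colsq, tol, max_iter)


@dataclass
class CVResult:
    lam: float
    lambdas: np.ndarray
    mean_mse: np.ndarray
    fold_mse: np.ndarray
    seed: int
    #: largest lambda whose mean CV error is within one standard error of
    #: the minimum -- the parsimony rule used for screening
    lam_1se: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "lambdas": self.lambdas.tolist(),
            "mean_mse": self.mean_mse.tolist(),
            "seed": self.seed,
        }


def select_lambda_cv(
    X,
    y,
    n_folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = CV_TOL,
) -> CVResult:
    """Choose lambda minimizing mean held-out squared error over K folds.

    Fold assignment is a seeded permutation split; ties on the error curve
    resolve to the largest (sparsest) lambda.  Within each fold the training
    design and response are re-centered on training means before fitting and
    the centering is applied to the held-out samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N = y.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if N < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {N}")
    if np.var(y) == 0.0:
        raise ValueError("response has zero variance; nothing to cross-validate")
    if grid is None:
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        grid = lambda_grid(lambda_max(Xc, yc), n_lambda, min_ratio)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    folds = np.array_split(perm, n_folds)
    fold_mse = np.empty((n_folds, grid.size))
    for f, val in enumerate(folds):
        mask = np.ones(N, dtype=bool)
        mask[val] = False
        Xtr = X[mask]
        ytr = y[mask]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        betas = lasso_path(Xtr - xm, ytr - ym, grid, tol=tol)
        pred = (X[val] - xm) @ betas.T + ym
        fold_mse[f] = ((pred - y[val][:, None]) ** 2).mean(axis=0)
    mean_mse = fold_mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # grid descends: first min = largest lambda
    se_best = float(fold_mse[:, best].std(ddof=1) / np.sqrt(n_folds))
    within = np.flatnonzero(mean_mse <= mean_mse[best] + se_best)
    lam_1se = float(grid[within[0]])  # largest qualifying lambda
    return CVResult(
        lam=float(grid[best]),
        lambdas=grid,
        mean_mse=mean_mse,
        fold_mse=fold_mse,
        seed=seed,
        lam_1se=lam_1se,
    )


# ---------------------------------------------------------------------------
# Screen and Clean


@dataclass
class CleanResult:
    """Outcome of the two-split Screen-and-Clean procedure.

    ``selected`` indexes the original design columns whose clean-stage
    p-value passed alpha; ``coefficients``/``p_values`` align with it.
    ``screen_set`` is the lasso support on the screen half (after the
    truncation that keeps the clean regression overdetermined, flagged by
    ``truncated``).
    """

    selected: np.ndarray
    coefficients: np.ndarray
    p_values: np.ndarray
    screen_set: np.ndarray
    screen_coefficients: np.ndarray
    lam: float
    split_seed: int
    n_screen: int
    n_clean: int
    alpha: float
    truncated: bool = False
    dropped_collinear: list[int] = field(default_factory=list)
    #: every feature actually tested in the clean OLS (screen set minus
    #: collinear drops) with its coefficient and p-value, regardless of alpha
    tested: np.ndarray = field(default_factory=lambda: np.array([], int))
    tested_coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    tested_p_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def coef_map(self) -> dict[int, float]:
        return {int(j): float(b) for j, b in zip(self.selected, self.coefficients)}

    @property
    def pval_map(self) -> dict[int, float]:
        return {int(j): float(p) for j, p in zip(self.selected, self.p_values)}


def _ols_t_tests(X: np.ndarray, y: np.ndarray):
    """OLS with rank detection: returns (kept columns, beta, p-values, dropped)."""
    n, p = X.shape
    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        return np.array([], int), np.array([]), np.array([]), list(range(p))
    rank = int(np.sum(diag > diag[0] * max(n, p) * np.finfo(float).eps))
    keep = np.sort(piv[:rank])
    dropped = sorted(int(j) for j in piv[rank:])
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    dof = n - rank
    if dof <= 0:
        raise ValueError("clean-stage regression is not overdetermined")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0.0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return keep, beta, pvals, dropped


def screen_and_clean(
    X,
    y,
    alpha: float = 0.05,
    split_fraction: float = 0.5,
    seed: int = 0,
    cv_folds: int = 10,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    lambda_rule: str = "1se",
) -> CleanResult:
    """Two-split Screen-and-Clean on a standardized design and centered trait.

    Screen: CV-tuned lasso on a seeded ``split_fraction`` half of the samples
    defines the candidate set.  The screening penalty follows the
    one-standard-error parsimony rule by default (``lambda_rule="min"``
    switches to the raw CV minimizer): the screen stage only has to carry
    the true features forward, and the sparser 1-SE candidate set sends
    fewer null features into the clean-stage tests, each of which is a
    false-selection opportunity at level alpha.  Clean: OLS t-tests on the
    other half; the features with p <= alpha are selected and their
    clean-stage coefficients reported as association strengths.  An empty
    screen set yields an empty (not erroneous) selection.  Candidate sets
    too large for the clean half are truncated to the largest-|beta|
    candidates keeping >= 2 residual degrees of freedom.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N = y.shape[0]
    if N < 20:
        raise ValueError("Screen-and-Clean needs N >= 20 (both halves must support fitting)")
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")

    ss = np.random.SeedSequence(seed)
    s_split, s_cv = ss.spawn(2)
    rng = np.random.default_rng(s_split)
    perm = rng.permutation(N)
    n_screen = int(round(split_fraction * N))
    n_screen = min(max(n_screen, 2), N - 2)
    screen_idx = perm[:n_screen]
    clean_idx = perm[n_screen:]
    n_clean = clean_idx.size

    Xs = X[screen_idx]
    ys = y[screen_idx]
    Xs = Xs - Xs.mean(axis=0)
    ys = ys - ys.mean()

    empty = CleanResult(
        selected=np.array([], int),
        coefficients=np.array([]),
        p_values=np.array([]),
        screen_set=np.array([], int),
        screen_coefficients=np.array([]),
        lam=float("nan"),
        split_seed=seed,
        n_screen=n_screen,
        n_clean=n_clean,
        alpha=alpha,
    )
    if np.var(ys) == 0.0:
        return empty

    cv_seed = int(s_cv.generate_state(1)[0] % (2**31))
    cv = select_lambda_cv(
        Xs, ys, n_folds=min(cv_folds, n_screen), seed=cv_seed,
        n_lambda=n_lambda, min_ratio=min_ratio,
    )
    lam = cv.lam_1se if lambda_rule == "1se" else cv.lam
    sol = lasso_fit(Xs, ys, lam)
    screen_set = np.flatnonzero(sol.coefficients)
    if screen_set.size == 0:
        empty.lam = lam
        return empty

    truncated = False
    max_candidates = n_clean - 2  # keep >= 2 residual dof in the clean OLS
    if screen_set.size > max_candidates:
        mag = np.abs(sol.coefficients[screen_set])
        order = np.lexsort((screen_set, -mag))  # by |beta| desc, ties by index
        screen_set = np.sort(screen_set[order[:max_candidates]])
        truncated = True

    Xc = X[clean_idx][:, screen_set]
    yc = y[clean_idx]
    Xc = Xc - Xc.mean(axis=0)
    yc = yc - yc.mean()
    keep, beta, pvals, dropped = _ols_t_tests(Xc, yc)
    kept_features = screen_set[keep]
    sel_mask = pvals <= alpha
    return CleanResult(
        selected=kept_features[sel_mask],
        coefficients=beta[sel_mask],
        p_values=pvals[sel_mask],
        screen_set=screen_set,
        screen_coefficients=sol.coefficients[screen_set],
        lam=lam,
        split_seed=seed,
        n_screen=n_screen,
        n_clean=n_clean,
        alpha=alpha,
        truncated=truncated,
        dropped_collinear=[int(screen_set[j]) for j in dropped],
        tested=kept_features,
        tested_coefficients=beta,
        tested_p_values=pvals,
    )


def kkt_violation(X, y, beta, lam) -> float:
    """Max KKT residual on the gradient scale: for active j,
    |2 x_j'(y - X beta) - lam * sign(beta_j)|; for inactive j,
    max(0, |2 x_j' r| - lam)."""
    g = 2.0 * X.T @ (y - X @ beta)
    active = beta != 0.0
    v_active = np.abs(g[active] - lam * np.sign(beta[active]))
    v_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0)
    parts = np.concatenate([v_active, v_inactive])
    return float(parts.max()) if parts.size else 0.0
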