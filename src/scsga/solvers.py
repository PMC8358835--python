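"""Coefficient estimators for the lagged regression system.

Four objectives are implemented:

* ``fit_l2`` — ordinary least squares, minimum-norm on singular systems;
* ``fit_lasso`` — squared loss with an L1 penalty, solved by cyclic
  coordinate descent with Gram-matrix updates;
* ``fit_lapps`` — L1 fitting loss with an L1/2 penalty, solved by an
  inexact (linearized) ADMM that alternates the half-thresholding and
  soft-thresholding proximal operators;
* ``fit_scsga`` — ``fit_lapps`` on a design whose predictor blocks are
  scaled by the Pearson correlation between each predictor channel and
  the target channel, with coefficients reported back on the original
  scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .mvar import DesignSystem, MVARFit

__all__ = [
    "SolverConfig",
    "ADMMState",
    "SolverDivergence",
    "soft_threshold",
    "half_threshold",
    "fit_l2",
    "fit_lasso",
    "fit_lapps",
    "weight_design",
    "fit_scsga",
    "select_lambda",
    "SOLVERS",
]

#: Coefficients smaller than this are reported as exact zeros.
ZERO_SNAP = 1e-10

#: Global minimizer of tau*|x|^(1/2) + (x-z)^2/2 is nonzero iff
#: |z| > HALF_THRESH_C * (2*tau)^(2/3).
HALF_THRESH_C = 54.0 ** (1.0 / 3.0) / 4.0


class SolverDivergence(RuntimeError):
    """ADMM residuals grew for too many consecutive iterations."""


@dataclass(frozen=True)
class SolverConfig:
    """Hyperparameters shared by the iterative solvers.

    ``lam`` scales the sparsity penalty, ``eta`` the L1 fitting loss
    (larger ``eta`` down-weights the data term), ``rho`` is the ADMM
    penalty parameter.  The penalty exponent is fixed at 1/2.
    """

    lam: float = 0.1
    eta: float = 1.0
    rho: float = 1.0
    max_iter: int = 500
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    seed: int = 0
    weight_mode: str = "abs"  # {"abs", "signed"}

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.weight_mode not in ("abs", "signed"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class ADMMState:
    """Per-iteration trace of the ADMM solver."""

    x: np.ndarray
    r: np.ndarray
    u: np.ndarray
    primal_res: list[float]
    dual_res: list[float]


def soft_threshold(z: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of ``tau * |x|_1``: sign(z) * max(|z| - tau, 0)."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - tau, 0.0)


def half_threshold(z: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of ``tau * |x|^(1/2)``: closed-form half-thresholding.

    Componentwise solution of ``min_x tau*|x|**0.5 + 0.5*(x - z)**2``.
    The classical trigonometric form is stated for the objective
    ``lam*|x|**0.5 + (x - z)**2``; with ``lam = 2*tau`` it solves ours:
    zero when ``|z| <= (54**(1/3)/4) * (2*tau)**(2/3)``, otherwise

        x = (2/3) * z * (1 + cos((2/3) * (pi - phi))),
        phi = arccos((2*tau/8) * (|z|/3)**(-3/2)).
    """
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    z = np.asarray(z, dtype=float)
    if tau == 0:
        return z.copy()
    lam = 2.0 * tau
    out = np.zeros_like(z)
    keep = np.abs(z) > HALF_THRESH_C * lam ** (2.0 / 3.0)
    if np.any(keep):
        zk = z[keep]
        arg = (lam / 8.0) * (np.abs(zk) / 3.0) ** (-1.5)
        phi = np.arccos(np.clip(arg, -1.0, 1.0))
        out[keep] = (2.0 / 3.0) * zk * (1.0 + np.cos((2.0 / 3.0) * (np.pi - phi)))
    return out


def _snap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    x[np.abs(x) < ZERO_SNAP] = 0.0
    return x


def _finalize(ds: DesignSystem, x_weighted: np.ndarray, **kw) -> MVARFit:
    """Back-scale weighted coefficients and fill residual diagnostics."""
    w = np.repeat(ds.weights, ds.s)
    coeffs = _snap(x_weighted * w)
    resid = ds.y - ds.A @ x_weighted
    return MVARFit(
        coeffs=coeffs,
        residuals=resid,
        resid_var=float(np.var(resid)),
        **kw,
    )


def fit_l2(ds: DesignSystem) -> MVARFit:
    """Least-squares fit; minimum-norm solution when the Gram matrix is singular."""
    x, _, rank, _ = linalg.lstsq(ds.A, ds.y, lapack_driver="gelsd")
    return _finalize(ds, x, rank=int(rank))


def fit_lasso(ds: DesignSystem, cfg: SolverConfig) -> MVARFit:
    """L1-penalized least squares by cyclic coordinate descent.

    Minimizes ``||y - A x||_2^2 + lam * ||x||_1`` with Gram-matrix
    ("covariance") updates; converges when the largest coefficient change
    in a sweep falls below 1e-8.
    """
    A, y = ds.A, ds.y
    p = A.shape[1]
    G = A.T @ A
    b = A.T @ y
    diag = np.diag(G).copy()
    x = np.zeros(p)
    yty = float(y @ y)

    def objective(x: np.ndarray) -> float:
        return float(x @ G @ x - 2.0 * b @ x + yty + cfg.lam * np.abs(x).sum())

    trace = [objective(x)]
    tol = 1e-8
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0:
                continue
            cj = b[j] - G[j] @ x + diag[j] * x[j]
            new = soft_threshold(np.array(cj), cfg.lam / 2.0).item() / diag[j]
            max_delta = max(max_delta, abs(new - x[j]))
            x[j] = new
        trace.append(objective(x))
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {cfg.max_iter} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return _finalize(
        ds, x, objective_trace=trace, converged=converged, n_iter=it
    )


def fit_lapps(ds: DesignSystem, cfg: SolverConfig) -> MVARFit:
    """Robust sparse fit: ``(1/eta)*||A x - y||_1 + lam*||x||_{1/2}^{1/2}``.

    Inexact ADMM on the split ``r = A x - y``:

    1. linearized proximal step on x with the half-thresholding operator,
       step ``1/L`` where ``L = rho * sigma_max(A)^2``;
    2. exact r update via soft-thresholding with threshold ``1/(eta*rho)``;
    3. dual ascent on the scaled multiplier u.

    Warm-started at the least-squares solution.  Raises
    :class:`SolverDivergence` if the primal residual grows for 50
    consecutive iterations.
    """
    A, y = ds.A, ds.y
    n_rows, p = A.shape
    rho = cfg.rho
    smax = linalg.svdvals(A)[0] if min(A.shape) else 0.0
    L = rho * max(smax**2, 1e-12)

    # warm start: minimum-norm least squares on the (possibly weighted) design
    x, _, _, _ = linalg.lstsq(A, y, lapack_driver="gelsd")
    Ax = A @ x
    r = soft_threshold(Ax - y, 1.0 / (cfg.eta * rho))
    u = np.zeros(n_rows)

    primal_hist: list[float] = []
    dual_hist: list[float] = []
    obj_trace: list[float] = []
    grow = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        grad = rho * (A.T @ (Ax - y - r + u))
        x = half_threshold(x - grad / L, cfg.lam / L)
        Ax = A @ x
        r_old = r
        r = soft_threshold(Ax - y + u, 1.0 / (cfg.eta * rho))
        u = u + Ax - y - r

        primal = float(np.linalg.norm(Ax - y - r))
        dual = float(rho * np.linalg.norm(A.T @ (r - r_old)))
        primal_hist.append(primal)
        dual_hist.append(dual)
        obj_trace.append(
            float(np.abs(Ax - y).sum() / cfg.eta + cfg.lam * np.sqrt(np.abs(x)).sum())
        )

        # genuine divergence grows past the data scale; ignore plateau jitter
        if (
            len(primal_hist) > 1
            and primal > primal_hist[-2]
            and primal > 10.0 * max(1.0, float(np.linalg.norm(y)))
        ):
            grow += 1
            if grow >= 50:
                raise SolverDivergence(
                    "ADMM residuals grew for 50 consecutive iterations; "
                    "try a smaller rho or step size"
                )
        else:
            grow = 0

        eps_pri = np.sqrt(n_rows) * cfg.tol_abs + cfg.tol_rel * max(
            np.linalg.norm(Ax), np.linalg.norm(r), np.linalg.norm(y)
        )
        eps_dual = np.sqrt(p) * cfg.tol_abs + cfg.tol_rel * rho * np.linalg.norm(A.T @ u)
        if primal <= eps_pri and dual <= eps_dual:
            converged = True
            break

    state = ADMMState(x=x, r=r, u=u, primal_res=primal_hist, dual_res=dual_hist)
    fit = _finalize(
        ds, x, objective_trace=obj_trace, converged=converged, n_iter=it
    )
    fit.admm_state = state  # type: ignore[attr-defined]
    return fit


def weight_design(ds: DesignSystem, E: np.ndarray) -> DesignSystem:
    """Scale predictor block ``i`` by the correlation weight ``|M[i, k]|``.

    ``E`` is the m x m Pearson matrix; ``k`` is the design's target channel.
    The weight vector is stored on the returned design so that fits can be
    reported on the original coefficient scale.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (ds.m, ds.m):
        raise ValueError(f"correlation matrix has shape {E.shape}, expected {(ds.m, ds.m)}")
    w = np.abs(E[:, ds.k]).astype(float)
    A_w = ds.A * np.repeat(w, ds.s)[np.newaxis, :]
    return replace(ds, A=A_w, weights=ds.weights * w)


def fit_scsga(ds: DesignSystem, E: np.ndarray, cfg: SolverConfig) -> MVARFit:
    """Sensor-correlation-weighted robust sparse fit.

    Runs :func:`fit_lapps` on the correlation-weighted design; the
    returned coefficients are multiplied back by the block weights so the
    original-model semantics (effect of channel i on the target) hold.
    With ``weight_mode="signed"`` the signed correlation is used instead
    of its absolute value.
    """
    E = np.asarray(E, dtype=float)
    if cfg.weight_mode == "signed":
        if E.shape != (ds.m, ds.m):
            raise ValueError(
                f"correlation matrix has shape {E.shape}, expected {(ds.m, ds.m)}"
            )
        w = E[:, ds.k].astype(float)
        A_w = ds.A * np.repeat(w, ds.s)[np.newaxis, :]
        wds = replace(ds, A=A_w, weights=ds.weights * w)
    else:
        wds = weight_design(ds, E)
    return fit_lapps(wds, cfg)


def select_lambda(
    ds: DesignSystem,
    cfg: SolverConfig,
    solver=fit_lapps,
    grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int | None = None,
) -> float:
    """Pick ``lam`` by k-fold CV on the design rows over a log grid.

    Rows are shuffled (seeded) before splitting; the lambda with lowest
    mean held-out absolute prediction error wins.
    """
    if grid is None:
        grid = np.logspace(-3, 1, 9)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_rows = ds.A.shape[0]
    perm = rng.permutation(n_rows)
    fold_ids = np.arange(n_rows) % folds
    errors = np.zeros(len(grid))
    for f in range(folds):
        test = perm[fold_ids == f]
        train = perm[fold_ids != f]
        sub = replace(ds, A=ds.A[train], y=ds.y[train], n=ds.s + len(train))
        for gi, lam in enumerate(grid):
            fit = solver(sub, replace(cfg, lam=float(lam)))
            w = np.repeat(sub.weights, sub.s)
            x_w = np.divide(fit.coeffs, w, out=np.zeros_like(fit.coeffs), where=w != 0)
            pred = ds.A[test] @ x_w
            errors[gi] += float(np.abs(ds.y[test] - pred).mean())
    return float(grid[int(np.argmin(errors))])


#: Registry used by the pipeline/CLI.
SOLVERS = {
    "l2": lambda ds, E, cfg: fit_l2(ds),
    "lasso": lambda ds, E, cfg: fit_lasso(ds, cfg),
    "lapps": lambda ds, E, cfg: fit_lapps(ds, cfg),
    "scsga": lambda ds, E, cfg: fit_scsga(ds, E, cfg),
}
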