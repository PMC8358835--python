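"""Lagged design-matrix construction for multivariate autoregression.

For ``m`` channels and lag order ``s``, the design matrix ``A`` has
``n - s`` rows (prediction times) and ``m * s`` columns arranged in ``m``
contiguous blocks; block ``i`` holds the ``s`` lagged copies of channel
``i`` (most recent lag first).  The response for target channel ``k`` is
its series at the prediction times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording

__all__ = [
    "DesignSystem",
    "MVARFit",
    "lag_block",
    "build_design",
    "coeffs_to_tensor",
    "select_order",
]


@dataclass(frozen=True)
class DesignSystem:
    """Design matrix ``A`` with the response ``y`` of one target channel.

    ``weights`` records per-block column scaling (all-ones when the design
    is unweighted); solvers use it to report coefficients on the original
    scale.
    """

    A: np.ndarray
    y: np.ndarray
    s: int
    k: int
    m: int
    n: int
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if A.shape != (self.n - self.s, self.m * self.s):
            raise ValueError(
                f"A has shape {A.shape}, expected {(self.n - self.s, self.m * self.s)}"
            )
        if y.shape != (self.n - self.s,):
            raise ValueError(f"y has shape {y.shape}, expected {(self.n - self.s,)}")
        w = self.weights
        if w is None:
            w = np.ones(self.m)
        w = np.asarray(w, dtype=float)
        if w.shape != (self.m,):
            raise ValueError(f"weights must have length m={self.m}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "weights", w)


@dataclass
class MVARFit:
    """Coefficients of one target equation plus residual diagnostics.

    ``coeffs`` is ordered like the design columns: entry ``i*s + l`` is the
    weight of channel ``i`` at lag ``l+1`` in the target's equation, on the
    original (unweighted) design scale.
    """

    coeffs: np.ndarray
    residuals: np.ndarray
    resid_var: float
    objective_trace: list[float] = field(default_factory=list)
    rank: int | None = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.resid_var < 0:
            raise ValueError("residual variance must be nonnegative")


def lag_block(series: np.ndarray, s: int) -> np.ndarray:
    """Lag matrix of one channel: row ``r`` holds samples ``r+s-1 .. r``.

    For a series ``W(1..n)`` (1-based) the first row is
    ``W(s), W(s-1), ..., W(1)`` and the last row ends at ``W(n-s)``.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if s < 1:
        raise ValueError(f"lag order must be >= 1, got {s}")
    if s >= n:
        raise ValueError(f"series too short for lag order (n={n}, s={s})")
    # windows[r] = series[r : r+s]; reverse so most recent lag comes first
    windows = np.lib.stride_tricks.sliding_window_view(series[: n - 1], s)
    return windows[:, ::-1].copy()


def build_design(rec: Recording, s: int, k: int) -> DesignSystem:
    """Assemble the full lagged design for target channel index ``k`` (0-based)."""
    m, n = rec.m, rec.n
    if not 0 <= k < m:
        raise IndexError(f"target index {k} out of range for {m} channels")
    blocks = [lag_block(rec.data[i], s) for i in range(m)]
    A = np.hstack(blocks)
    y = rec.data[k, s:].copy()
    return DesignSystem(A=A, y=y, s=s, k=k, m=m, n=n)


def coeffs_to_tensor(fits: list[MVARFit], m: int, s: int) -> np.ndarray:
    """Repack per-target coefficient vectors into a tensor ``a[i, k, l]``.

    ``a[i, k, l]`` is the effect of channel ``i`` at lag ``l+1`` on channel
    ``k`` (all indices 0-based).
    """
    if len(fits) != m:
        raise ValueError(f"expected {m} fits, got {len(fits)}")
    tensor = np.zeros((m, m, s))
    for k, fit in enumerate(fits):
        x = np.asarray(fit.coeffs, dtype=float)
        if x.shape != (m * s,):
            raise ValueError(
                f"fit {k}: coefficient vector has shape {x.shape}, expected {(m * s,)}"
            )
        tensor[:, k, :] = x.reshape(m, s)
    return tensor


def select_order(
    rec: Recording,
    candidates: range | list[int] = range(1, 9),
    penalty: float | None = None,
) -> int:
    """Pick a lag order by penalized mean residual variance (BIC-like).

    Optional helper; the pipeline default lag order is fixed in config.
    """
    from .solvers import fit_l2

    n_eff = rec.n
    if penalty is None:
        penalty = np.log(n_eff) / n_eff
    best_s, best_score = None, np.inf
    for s in candidates:
        if s >= rec.n:
            continue
        total = 0.0
        for k in range(rec.m):
            fit = fit_l2(build_design(rec, s, k))
            total += np.log(max(fit.resid_var, 1e-300))
        score = total / rec.m + penalty * s * rec.m
        if score < best_score:
            best_s, best_score = s, score
    if best_s is None:
        raise ValueError("no admissible lag order among candidates")
    return best_s
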