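"""Sensor correlation, directed causality networks, and classifier features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Recording

__all__ = [
    "CorrelationMatrix",
    "CausalityNetwork",
    "FeatureSet",
    "pearson",
    "correlation_matrix",
    "aggregate_network",
    "network_features",
    "write_edge_list",
    "write_dense_matrix",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric m x m Pearson matrix with unit diagonal."""

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {M.shape}")
        object.__setattr__(self, "M", M)

    @property
    def m(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class CausalityNetwork:
    """Nonnegative directed adjacency; entry (i, k) is the strength of i -> k."""

    G: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError(f"adjacency must be square, got {G.shape}")
        if len(self.channel_names) != G.shape[0]:
            raise ValueError("channel_names length must match adjacency size")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def m(self) -> int:
        return self.G.shape[0]


@dataclass(frozen=True)
class FeatureSet:
    """Samples x d feature matrix with labels and per-column names."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if labels.shape != (X.shape[0],):
            raise ValueError("one label per row required")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match feature count")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson coefficient Cov(u, v) / sqrt(Var[u] * Var[v]).

    Population vs sample normalization cancels in the ratio, so either
    convention gives the same value; population moments are used here.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    du = u - u.mean()
    dv = v - v.mean()
    vu = float(du @ du)
    vv = float(dv @ dv)
    if vu == 0 or vv == 0:
        raise ValueError("zero variance channel")
    return float((du @ dv) / np.sqrt(vu * vv))


def correlation_matrix(rec: Recording) -> CorrelationMatrix:
    """All-pairs Pearson matrix of a recording's channels."""
    data = rec.data
    sd = data.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"zero variance channel {rec.channel_names[i]!r}")
    M = np.corrcoef(data)
    np.fill_diagonal(M, 1.0)
    return CorrelationMatrix(M=M)


def aggregate_network(
    tensor: np.ndarray,
    channel_names: tuple[str, ...] | None = None,
    mode: str = "abs_sum",
) -> CausalityNetwork:
    """Collapse the lag axis of a coefficient tensor into one edge weight.

    ``tensor[i, k, l]`` is the lag-(l+1) effect of channel i on channel k.
    Modes: ``abs_sum`` (default, sum of |coeff| over lags), ``max``
    (max |coeff|), ``l2`` (Euclidean norm over lags).  The diagonal
    (self-loops) is forced to zero.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3 or tensor.shape[0] != tensor.shape[1]:
        raise ValueError(f"tensor must be m x m x s, got {tensor.shape}")
    m = tensor.shape[0]
    if mode == "abs_sum":
        G = np.abs(tensor).sum(axis=2)
    elif mode == "max":
        G = np.abs(tensor).max(axis=2)
    elif mode == "l2":
        G = np.sqrt((tensor**2).sum(axis=2))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    np.fill_diagonal(G, 0.0)
    if channel_names is None:
        channel_names = tuple(f"ch{i + 1:02d}" for i in range(m))
    return CausalityNetwork(G=G, channel_names=channel_names)


def _offdiag_raster(net: CausalityNetwork) -> tuple[np.ndarray, list[str]]:
    m = net.m
    vals, names = [], []
    for i in range(m):
        for k in range(m):
            if i == k:
                continue
            vals.append(net.G[i, k])
            names.append(f"{net.channel_names[i]}->{net.channel_names[k]}")
    return np.asarray(vals), names


def network_features(
    nets: list[CausalityNetwork],
    band_names: list[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Vectorize one trial's per-band networks into a feature row.

    Off-diagonal entries in row-major order, bands concatenated in the
    declared order; feature dimension is ``bands * m * (m - 1)``.
    """
    if not nets:
        raise ValueError("need at least one network")
    m = nets[0].m
    order = nets[0].channel_names
    if band_names is None:
        band_names = [f"band{b}" for b in range(len(nets))]
    if len(band_names) != len(nets):
        raise ValueError("one band name per network required")
    chunks, names = [], []
    for net, band in zip(nets, band_names):
        if net.m != m or net.channel_names != order:
            raise ValueError("networks must share channel count and order")
        vals, edge_names = _offdiag_raster(net)
        chunks.append(vals)
        names.extend(f"{band}:{e}" for e in edge_names)
    return np.concatenate(chunks), tuple(names)


def write_edge_list(net: CausalityNetwork, path) -> None:
    """Write a network as a TSV edge list (source, target, weight), nonzero edges only."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(net.m):
            for k in range(net.m):
                if i != k and net.G[i, k] != 0:
                    fh.write(
                        f"{net.channel_names[i]}\t{net.channel_names[k]}\t"
                        f"{float(net.G[i, k])!r}\n"
                    )


def write_dense_matrix(net: CausalityNetwork, path) -> None:
    """Write a network as a dense CSV with channel-name headers."""
    with open(path, "w") as fh:
        fh.write("," + ",".join(net.channel_names) + "\n")
        for i in range(net.m):
            row = ",".join(repr(float(v)) for v in net.G[i])
            fh.write(f"{net.channel_names[i]},{row}\n")
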