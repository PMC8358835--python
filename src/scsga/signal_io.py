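"""Reading, validation, channel selection and band decomposition of recordings.

A :class:`Recording` is an ``m x n`` real matrix (channels in rows) with a
sampling rate.  Band decomposition uses a 4th-order Butterworth band-pass
applied forward-backward, so the filtered output is zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "BandSpec",
    "DEFAULT_BANDS",
    "read_recording",
    "select_channels",
    "bandpass_filter",
    "write_container",
    "read_container",
]


class ValidationError(ValueError):
    """Raised when an input recording violates the data contract."""


@dataclass(frozen=True)
class Recording:
    """Multichannel time series: ``data`` is channels x samples."""

    data: np.ndarray
    srate: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError(f"data must be 2-D, got shape {data.shape}")
        m, n = data.shape
        if m < 2:
            raise ValidationError(f"need at least 2 channels, got {m}")
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        bad = np.argwhere(~np.isfinite(data))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-finite value at channel {r}, sample {c}"
            )
        if self.srate <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.srate}")
        names = self.channel_names
        if not names:
            names = tuple(f"ch{i + 1:02d}" for i in range(m))
        else:
            names = tuple(str(x) for x in names)
        if len(names) != m:
            raise ValidationError(
                f"{len(names)} channel names for {m} channels"
            )
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", names)

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[lo, hi]`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValidationError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )


#: Conventional EEG rhythm bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("gamma", 31.0, 50.0),
)


def _parse_delimited(path: Path) -> np.ndarray:
    """Parse a delimited numeric matrix, reporting bad cells by location."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if "," in line:
                cells = line.split(",")
            elif "\t" in line:
                cells = line.split("\t")
            else:
                cells = line.split()
            row = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric value {cell.strip()!r} "
                        f"at row {lineno}, column {colno}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged row {i} has {len(row)} cells, expected {width}"
            )
    return np.asarray(rows, dtype=float)


def read_recording(
    path: str | Path,
    srate: float,
    channel_names: Sequence[str] | None = None,
    orientation: str = "channels",
) -> Recording:
    """Read a delimited numeric matrix from ``path`` into a Recording.

    Parameters
    ----------
    path : file path of a CSV/TSV/whitespace-delimited matrix.
    srate : sampling rate in Hz.
    channel_names : optional channel identifiers; defaults to ``ch01..``.
    orientation : ``"channels"`` if rows are channels (default),
        ``"samples"`` if rows are samples (the matrix is transposed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if orientation not in ("channels", "samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    data = _parse_delimited(path)
    if orientation == "samples":
        data = data.T
    return Recording(data=data, srate=srate, channel_names=tuple(channel_names or ()))


def select_channels(rec: Recording, keep: Sequence[str]) -> Recording:
    """Return a Recording restricted (and re-ordered) to ``keep``."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    unknown = [name for name in keep if name not in index]
    if unknown:
        raise ValidationError(f"unknown channel {', '.join(unknown)}")
    order = [index[name] for name in keep]
    return Recording(
        data=rec.data[order].copy(),
        srate=rec.srate,
        channel_names=tuple(keep),
    )


def bandpass_filter(rec: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``) so the output
    has zero group delay; shape and sampling rate are preserved.
    """
    nyq = rec.srate / 2.0
    if band.hi >= nyq:
        raise ValidationError(
            f"band {band.name!r} upper edge {band.hi} Hz >= Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=rec.srate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data=filtered, srate=rec.srate, channel_names=rec.channel_names)


def write_container(
    path: str | Path,
    trials: Sequence[Recording],
    labels: Sequence[int] | None = None,
) -> None:
    """Write trials to an HDF5 container (one group per trial)."""
    with h5py.File(path, "w") as fh:
        for i, rec in enumerate(trials):
            grp = fh.create_group(f"trial_{i:04d}")
            grp.create_dataset("data", data=rec.data)
            grp.attrs["srate"] = rec.srate
            grp.attrs["channel_names"] = list(rec.channel_names)
            if labels is not None:
                grp.attrs["label"] = int(labels[i])


def read_container(path: str | Path) -> tuple[list[Recording], list[int | None]]:
    """Read trials (and labels when present) from an HDF5 container."""
    trials: list[Recording] = []
    labels: list[int | None] = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            grp = fh[key]
            names = tuple(
                n.decode() if isinstance(n, bytes) else str(n)
                for n in grp.attrs.get("channel_names", ())
            )
            trials.append(
                Recording(
                    data=np.asarray(grp["data"]),
                    srate=float(grp.attrs["srate"]),
                    channel_names=names,
                )
            )
            lab = grp.attrs.get("label")
            labels.append(int(lab) if lab is not None else None)
    return trials, labels
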