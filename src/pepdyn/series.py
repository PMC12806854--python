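"""The universal 1-D measurement container and its text-table I/O.

Every technique hands the pipeline the same object: an ordered grid ``x``
(Hz, K, nm^-1, ppm or rad s^-1 depending on the technique), one or two
response columns ``y`` (a second column is folded into a complex array),
and a metadata mapping with the measurement conditions.

On disk a series is a comment-annotated CSV::

    # technique=dielectric
    # temperature_K=300.0
    # pressure_MPa=0.1
    # sample=PBLG_6
    f_Hz,eps1,eps2
    1.0e-2,4.51,0.72
    ...

Round-tripping through :func:`write_series` / :func:`read_series` is
lossless to better than 12 significant digits.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["MeasurementSeries", "read_series", "write_series", "SeriesError"]

#: canonical x-axis column name per technique
_X_NAMES = {
    "dielectric": "f_Hz",
    "dsc": "T_K",
    "waxs": "q_nm^-1",
    "nmr": "ppm",
    "rheo": "omega_rad_s",
}

#: metadata keys that must be present for a technique
REQUIRED_META = {
    "dielectric": ("temperature_K",),
    "dsc": ("modulation_period_s",),
    "waxs": (),
    "nmr": (),
    "rheo": ("temperature_K",),
}


class SeriesError(ValueError):
    """Raised for malformed measurement tables."""


@dataclass
class MeasurementSeries:
    """One measured 1-D curve plus its condition metadata.

    Parameters
    ----------
    x : ndarray
        Strictly increasing grid in the technique's canonical unit.
    y : ndarray
        Response values; complex for two-column techniques (dielectric
        permittivity ``eps1 - i*eps2`` stored as ``eps1 + 1j*eps2``, rheology
        ``G' + 1j*G''``).
    technique : str
        One of ``dielectric | dsc | waxs | nmr | rheo``.
    meta : dict
        Condition metadata; technique-specific keys are validated.
    """

    x: np.ndarray
    y: np.ndarray
    technique: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if self.technique not in _X_NAMES:
            raise SeriesError(f"unknown technique {self.technique!r}")
        if self.x.ndim != 1 or self.y.shape[0] != self.x.shape[0]:
            raise SeriesError("x and y must be 1-D arrays of equal length")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            bad = self.x[1:][dx <= 0][0]
            raise SeriesError(f"x grid not strictly increasing at x={bad!r}")
        if not np.all(np.isfinite(self.x)):
            raise SeriesError("non-finite x value")
        if not np.all(np.isfinite(self.y)):
            raise SeriesError("non-finite y value")
        for key in REQUIRED_META[self.technique]:
            if key not in self.meta:
                raise SeriesError(
                    f"technique {self.technique!r} requires meta key {key!r}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.y)

    @property
    def temperature(self) -> float | None:
        t = self.meta.get("temperature_K")
        return None if t is None else float(t)

    @property
    def pressure(self) -> float:
        """Pressure in MPa; ambient (0.1 MPa) when not recorded."""
        return float(self.meta.get("pressure_MPa", 0.1))

    def __len__(self) -> int:
        return len(self.x)


_COLUMNS = {
    "dielectric": ("f_Hz", "eps1", "eps2"),
    "dsc": ("T_K", "cp_J_g_K"),
    "waxs": ("q_nm^-1", "intensity"),
    "nmr": ("ppm", "intensity"),
    "rheo": ("omega_rad_s", "G1_Pa", "G2_Pa"),
}


def write_series(series: MeasurementSeries, path: str | os.PathLike) -> None:
    """Write a series as comment-annotated CSV (see module docstring)."""
    cols = _COLUMNS[series.technique]
    buf = io.StringIO()
    buf.write(f"# technique={series.technique}\n")
    for k in sorted(series.meta):
        buf.write(f"# {k}={series.meta[k]}\n")
    buf.write(",".join(cols) + "\n")
    if series.is_complex:
        data = np.column_stack([series.x, series.y.real, series.y.imag])
    else:
        data = np.column_stack([series.x, series.y])
    if data.shape[1] != len(cols):
        raise SeriesError(
            f"technique {series.technique!r} expects {len(cols) - 1} response "
            f"column(s), got {data.shape[1] - 1}"
        )
    for row in data:
        buf.write(",".join(f"{v:.17g}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_meta_value(raw: str) -> Any:
    try:
        f = float(raw)
    except ValueError:
        return raw
    return f


def read_series(path: str | os.PathLike, technique: str | None = None) -> MeasurementSeries:
    """Read a comment-annotated CSV table into a validated series.

    ``technique`` overrides (and is checked against) the ``technique`` line
    in the file's metadata block.
    """
    meta: dict[str, Any] = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    continue
                k, _, v = body.partition("=")
                meta[k.strip()] = _parse_meta_value(v.strip())
            elif header is None:
                header = [c.strip() for c in line.split(",")]
            else:
                rows.append([float(c) for c in line.split(",")])
    file_tech = meta.pop("technique", None)
    tech = technique or file_tech
    if tech is None:
        raise SeriesError(f"{path}: no technique given in file or argument")
    if technique is not None and file_tech is not None and technique != file_tech:
        raise SeriesError(
            f"{path}: file declares technique {file_tech!r}, caller asked {technique!r}"
        )
    if header is None or not rows:
        raise SeriesError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    x = data[:, 0]
    # duplicate-x check before the monotonicity error for a clearer message
    uniq, counts = np.unique(x, return_counts=True)
    if np.any(counts > 1):
        raise SeriesError(f"{path}: duplicated x value {uniq[counts > 1][0]!r}")
    if data.shape[1] == 3:
        y: np.ndarray = data[:, 1] + 1j * data[:, 2]
    elif data.shape[1] == 2:
        y = data[:, 1]
    else:
        raise SeriesError(f"{path}: expected 2 or 3 columns, got {data.shape[1]}")
    return MeasurementSeries(x=x, y=y, technique=str(tech), meta=meta)
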