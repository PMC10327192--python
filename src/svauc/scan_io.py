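"""Reading, validating, filtering and assembling SV-AUC radial scan files.

Scan files follow the customary Beckman XL-A/XL-I text layout: a free-text
title line, a header line with the scan metadata, and two or three numeric
columns (radius, signal, optional standard deviation).  File names are
5-digit zero-padded scan numbers with a channel extension, e.g.
``00001.ip2`` for interference channel 2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_SPIKE_THRESHOLD = 0.4


@dataclass
class Scan:
    """A single radial scan.

    Attributes
    ----------
    radii : strictly increasing radial positions in cm from rotor center.
    values : signal (OD or fringes), one per radius.
    scan_time : seconds since run start.
    w2t : accumulated omega^2 t in 1/s (the sedimentation clock).
    rotor_speed : rpm.
    temperature : deg C.
    wavelength : nm.
    cell_id : centrifuge cell number.
    data_type : one-character code from the scan header.
    title : free-text first line of the file.
    """

    radii: np.ndarray
    values: np.ndarray
    scan_time: float
    w2t: float
    rotor_speed: float
    temperature: float
    wavelength: float = 280.0
    cell_id: int = 1
    data_type: str = "R"
    title: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.ndim != 1 or len(self.radii) != len(self.values):
            raise ValueError("radii and values must be 1-D arrays of equal length")
        if len(self.radii) > 1 and not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if self.rotor_speed <= 0:
            raise ValueError(f"rotor_speed must be > 0, got {self.rotor_speed}")
        if self.scan_time < 0:
            raise ValueError(f"scan_time must be >= 0, got {self.scan_time}")


@dataclass
class ScanSet:
    """Scans aligned on a common radial grid.

    ``signal`` is an [n_radii x n_scans] matrix; per-scan metadata vectors
    follow scan order.  All scans share one rotor speed and times are
    strictly increasing.
    """

    radii: np.ndarray
    signal: np.ndarray
    times: np.ndarray
    w2t: np.ndarray
    temperatures: np.ndarray
    rotor_speed: float
    wavelength: float = 280.0
    channel: str = ""
    source_paths: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.shape != (len(self.radii), len(self.times)):
            raise ValueError("signal must be [n_radii x n_scans]")
        if self.n_scans < 2:
            raise ValueError("a ScanSet needs at least 2 scans")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("scan times must be strictly increasing")
        if np.any(~np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values after assembly")

    @property
    def n_radii(self) -> int:
        return len(self.radii)

    @property
    def n_scans(self) -> int:
        return len(self.times)


def enumerate_scan_files(
    data_directory: str | os.PathLike,
    channel: str,
    first: int,
    last: int,
    interval: int,
) -> list[Path]:
    """Build the ordered list of scan paths ``first, first+interval, ... <= last``.

    Names are 5-digit zero-padded numbers with the (lower-cased) channel
    extension; matching on disk is case-insensitive on the extension.
    Every selected file must exist.
    """
    if not channel:
        raise ValueError("channel extension must be nonempty")
    if not (1 <= first <= last):
        raise ValueError(f"require 1 <= first <= last, got first={first}, last={last}")
    if interval < 1:
        raise ValueError(f"interval must be >= 1, got {interval}")
    directory = Path(data_directory)
    ext = channel.lower().lstrip(".")
    paths: list[Path] = []
    for number in range(first, last + 1, interval):
        stem = f"{number:05d}"
        candidate = directory / f"{stem}.{ext}"
        if not candidate.exists():
            # case-insensitive fallback on the extension
            hits = [
                p
                for p in (directory.glob(f"{stem}.*") if directory.is_dir() else [])
                if p.suffix.lower() == f".{ext}"
            ]
            if not hits:
                raise FileNotFoundError(f"scan file not found: {candidate}")
            candidate = hits[0]
        paths.append(candidate)
    if not paths:
        raise ValueError("scan selection is empty")
    return paths


def read_scan_file(path: str | os.PathLike) -> Scan:
    """Parse one scan file into a :class:`Scan`.

    Layout: line 1 title; line 2 ``data-type cell temperature rpm time w2t
    wavelength``; remaining lines ``radius value [stddev]`` (any stddev
    column is ignored).
    """
    path = Path(path)
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: scan file needs a title, a header and data rows")
    title = lines[0]
    header = lines[1].split()
    if len(header) < 7:
        raise ValueError(f"{path}:2: header needs 7 fields, got {len(header)}")
    try:
        data_type = header[0]
        cell_id = int(header[1])
        temperature = float(header[2])
        rotor_speed = float(header[3])
        scan_time = float(header[4])
        w2t = float(header[5])
        wavelength = float(header[6])
    except ValueError as exc:
        raise ValueError(f"{path}:2: unparseable header: {exc}") from exc
    radii, values = [], []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        try:
            radii.append(float(cols[0]))
            values.append(float(cols[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable data row: {exc}") from exc
    radii_arr = np.array(radii)
    if len(radii_arr) > 1 and not np.all(np.diff(radii_arr) > 0):
        raise ValueError(f"{path}: radii are not strictly increasing")
    return Scan(
        radii=radii_arr,
        values=np.array(values),
        scan_time=scan_time,
        w2t=w2t,
        rotor_speed=rotor_speed,
        temperature=temperature,
        wavelength=wavelength,
        cell_id=cell_id,
        data_type=data_type,
        title=title,
    )


def write_scan_file(scan: Scan, path: str | os.PathLike) -> Path:
    """Write a :class:`Scan` in the dialect read by :func:`read_scan_file`."""
    path = Path(path)
    header = (
        f"{scan.data_type} {scan.cell_id} {scan.temperature:.6g} "
        f"{scan.rotor_speed:.10g} {scan.scan_time:.10g} {scan.w2t:.10g} "
        f"{scan.wavelength:.6g}"
    )
    rows = "\n".join(
        f"{r:.7f} {v:.7E}" for r, v in zip(scan.radii, scan.values)
    )
    title = scan.title or "svauc scan"
    try:
        with open(path, "w") as fh:
            fh.write(f"{title}\n{header}\n{rows}\n")
    except OSError as exc:
        raise OSError(f"cannot write scan file {path}: {exc}") from exc
    return path


def filter_spikes(scan: Scan, threshold: float = DEFAULT_SPIKE_THRESHOLD) -> Scan:
    """Remove isolated data spikes.

    A spike is an interior point whose signal deviates from BOTH neighbors
    by more than ``threshold`` with the same sign of deviation; endpoints
    are never removed.  Passes repeat until no spike remains, so the
    filter is idempotent.  Removed points are dropped (not replaced).
    """
    if threshold <= 0:
        raise ValueError(f"spike threshold must be > 0, got {threshold}")
    radii, values = scan.radii, scan.values
    while len(values) >= 3:
        d_prev = values[1:-1] - values[:-2]
        d_next = values[1:-1] - values[2:]
        spike = (
            (np.abs(d_prev) > threshold)
            & (np.abs(d_next) > threshold)
            & (np.sign(d_prev) == np.sign(d_next))
        )
        if not spike.any():
            break
        keep = np.ones(len(values), dtype=bool)
        keep[1:-1] = ~spike
        radii, values = radii[keep], values[keep]
    if len(values) == len(scan.values):
        return scan
    return replace(scan, radii=radii, values=values)


def assemble_scan_set(scans: Sequence[Scan], channel: str = "", source_paths=None) -> ScanSet:
    """Align scans onto a common radial grid and stack them.

    The common grid is the first scan's radii restricted to the
    intersection of all radial ranges; other scans are linearly
    interpolated onto it (real instrument scans share grids, so the
    interpolation is usually the identity).
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    speeds = {s.rotor_speed for s in scans}
    if len(speeds) > 1:
        raise ValueError(f"scans have mismatched rotor speeds: {sorted(speeds)}")
    lo = max(s.radii[0] for s in scans)
    hi = min(s.radii[-1] for s in scans)
    if lo >= hi:
        raise ValueError("scans have non-overlapping radial ranges")
    base = scans[0].radii
    grid = base[(base >= lo) & (base <= hi)]
    if len(grid) < 2:
        raise ValueError("common radial grid has fewer than 2 points")
    signal = np.column_stack(
        [np.interp(grid, s.radii, s.values) for s in scans]
    )
    return ScanSet(
        radii=grid,
        signal=signal,
        times=np.array([s.scan_time for s in scans], dtype=float),
        w2t=np.array([s.w2t for s in scans], dtype=float),
        temperatures=np.array([s.temperature for s in scans], dtype=float),
        rotor_speed=scans[0].rotor_speed,
        wavelength=scans[0].wavelength,
        channel=channel,
        source_paths=list(source_paths) if source_paths else [],
    )


def check_time_stamps(
    paths: Sequence[str | os.PathLike], scans: Sequence[Scan]
) -> tuple[bool, np.ndarray]:
    """Check whether filesystem time stamps are usable for scan-time correction.

    Accessible is True iff every file has a modification time and the
    mtimes are strictly increasing in scan order; corrected times are then
    the first header time plus elapsed mtime differences.  Otherwise the
    header times are returned unchanged.
    """
    if len(paths) != len(scans):
        raise ValueError("paths and scans must correspond one-to-one")
    header_times = np.array([s.scan_time for s in scans], dtype=float)
    try:
        mtimes = np.array([os.path.getmtime(p) for p in paths], dtype=float)
    except OSError:
        return False, header_times
    if len(mtimes) > 1 and not np.all(np.diff(mtimes) > 0):
        return False, header_times
    corrected = header_times[0] + (mtimes - mtimes[0])
    return True, corrected
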