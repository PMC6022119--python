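"""Domain types and I/O for labelled multi-session reflectance spectra.

The pipeline's universal currency is the :class:`SpectraSet`: an ``n × p``
intensity matrix on a shared wavelength grid, with one :class:`SampleMeta`
record per row describing which specimen, acquisition session, sampling
position and scan the row came from.

Raw acquisitions consist of several scans per sampling position; these are
averaged into one sample per position with :func:`average_scans` before any
further processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AVERAGED",
    "WavelengthGrid",
    "SampleMeta",
    "Spectrum",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "average_scans",
]

#: Marker used for ``scan_index`` once the scans of a position were averaged.
AVERAGED = "averaged"

# Sanity bounds for wavelength values, nm.  Wide enough for any visible-range
# instrument; tight enough to catch column-index headers passed by mistake.
_WL_MIN, _WL_MAX = 300.0, 800.0

_META_COLUMNS = [
    "row_id",
    "specimen_id",
    "type_label",
    "organic",
    "session_id",
    "position_index",
    "scan_index",
    "country",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength grid contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN or wl[-1] > _WL_MAX:
            raise ValueError(
                f"wavelengths must lie within [{_WL_MIN:g}, {_WL_MAX:g}] nm, "
                f"got range [{wl[0]:g}, {wl[-1]:g}]"
            )
        object.__setattr__(self, "wavelengths", wl)
        self.wavelengths.setflags(write=False)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    @classmethod
    def linspace(cls, start: float = 380.0, stop: float = 700.0, num: int = 1024) -> "WavelengthGrid":
        """Evenly spaced grid; the default emulates a visible-range detector."""
        return cls(np.linspace(start, stop, num))


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one spectrum row.

    ``scan_index`` is 1-3 for raw scans or :data:`AVERAGED` once the scans of
    a position have been combined.  ``organic`` is the cultivation label the
    organic-status task predicts.
    """

    specimen_id: str
    type_label: str
    organic: bool
    session_id: str
    position_index: int
    scan_index: int | str
    country: str | None = None

    def __post_init__(self) -> None:
        if self.position_index not in (1, 2, 3, 4):
            raise ValueError(f"position_index must be 1-4, got {self.position_index!r}")
        if self.scan_index != AVERAGED and self.scan_index not in (1, 2, 3):
            raise ValueError(
                f"scan_index must be 1-3 or {AVERAGED!r}, got {self.scan_index!r}"
            )


@dataclass(frozen=True)
class Spectrum:
    """A single intensity vector with its grid and provenance."""

    grid: WavelengthGrid
    intensities: np.ndarray
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if x.size != len(self.grid):
            raise ValueError(
                f"intensity length {x.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities contain non-finite values")
        object.__setattr__(self, "intensities", x)


@dataclass
class SpectraSet:
    """``n`` spectra on one shared grid with per-row metadata."""

    grid: WavelengthGrid
    matrix: np.ndarray
    metas: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (rows × wavelengths)")
        if m.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {m.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if len(self.metas) != m.shape[0]:
            raise ValueError(
                f"{m.shape[0]} rows but {len(self.metas)} metadata records"
            )
        if m.size and not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite values")
        self.matrix = m

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.n_rows

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(self.n_rows):
            yield Spectrum(self.grid, self.matrix[i], self.metas[i])

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i], self.metas[i])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.grid, self.matrix[idx], [self.metas[i] for i in idx])

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a tidy DataFrame (one row per spectrum)."""
        return pd.DataFrame(
            {
                "specimen_id": [m.specimen_id for m in self.metas],
                "type_label": [m.type_label for m in self.metas],
                "organic": [m.organic for m in self.metas],
                "session_id": [m.session_id for m in self.metas],
                "position_index": [m.position_index for m in self.metas],
                "scan_index": [m.scan_index for m in self.metas],
                "country": [m.country for m in self.metas],
            }
        )

    def session_ids(self) -> set[str]:
        return {m.session_id for m in self.metas}


def read_spectra(path: str | Path, meta_path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV and its metadata CSV into a :class:`SpectraSet`.

    The spectra file has a ``row_id`` first column and numeric wavelength
    headers; the metadata file is keyed by the same ``row_id``.  Row order of
    the spectra file is preserved.
    """
    data = pd.read_csv(path)
    if data.columns[0] != "row_id":
        raise ValueError(f"first column of {path} must be 'row_id', got {data.columns[0]!r}")
    try:
        wavelengths = np.array([float(c) for c in data.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from None
    grid = WavelengthGrid(wavelengths)

    matrix = data.iloc[:, 1:].to_numpy(dtype=float)

    meta = pd.read_csv(meta_path, dtype={"row_id": str})
    missing = set(_META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {meta_path} is missing columns: {sorted(missing)}")
    if len(meta) != len(data):
        raise ValueError(
            f"row count mismatch: {len(data)} spectra rows vs {len(meta)} metadata rows"
        )
    meta = meta.set_index("row_id")
    row_ids = data["row_id"].astype(str)
    if not set(row_ids) <= set(meta.index):
        missing_ids = sorted(set(row_ids) - set(meta.index))[:5]
        raise ValueError(f"metadata missing row ids, e.g. {missing_ids}")

    metas = []
    for rid in row_ids:
        rec = meta.loc[rid]
        scan = rec["scan_index"]
        country = rec["country"]
        metas.append(
            SampleMeta(
                specimen_id=str(rec["specimen_id"]),
                type_label=str(rec["type_label"]),
                organic=_parse_bool(rec["organic"]),
                session_id=str(rec["session_id"]),
                position_index=int(rec["position_index"]),
                scan_index=AVERAGED if str(scan) == AVERAGED else int(scan),
                country=None if pd.isna(country) else str(country),
            )
        )
    return SpectraSet(grid, matrix, metas)


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean organic flag from {v!r}")


def write_spectra(s: SpectraSet, path: str | Path, meta_path: str | Path) -> None:
    """Write ``s`` as the spectra/metadata CSV pair read by :func:`read_spectra`.

    Round-tripping reproduces the matrix to floating-text precision and the
    metadata exactly.
    """
    row_ids = [f"r{i:06d}" for i in range(s.n_rows)]
    # shortest decimal that round-trips to the exact float, so read(write(s))
    # reproduces the grid bit-for-bit
    header = [repr(float(wl)) for wl in s.grid.wavelengths]
    data = pd.DataFrame(s.matrix, columns=header)
    data.insert(0, "row_id", row_ids)
    data.to_csv(path, index=False, float_format="%.12g")

    meta = s.meta_frame()
    meta.insert(0, "row_id", row_ids)
    meta.to_csv(meta_path, index=False)


def average_scans(s: SpectraSet) -> SpectraSet:
    """Average the scans of each (specimen, session, position) group.

    Each group of raw scans collapses to a single row whose intensities are
    the arithmetic mean of the group's rows and whose ``scan_index`` is
    :data:`AVERAGED`.  Group members must agree on class labels.  The
    operation is idempotent: already-averaged rows form singleton groups.
    """
    groups: dict[tuple[str, str, int], list[int]] = {}
    order: list[tuple[str, str, int]] = []
    for i, m in enumerate(s.metas):
        key = (m.specimen_id, m.session_id, m.position_index)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    rows = np.empty((len(order), len(s.grid)))
    metas = []
    for j, key in enumerate(order):
        idx = groups[key]
        members = [s.metas[i] for i in idx]
        if len({(m.type_label, m.organic) for m in members}) > 1:
            raise ValueError(
                f"scans of specimen {key[0]!r} session {key[1]!r} position {key[2]} "
                "disagree on type_label/organic"
            )
        rows[j] = s.matrix[idx].mean(axis=0)
        metas.append(replace(members[0], scan_index=AVERAGED))
    return SpectraSet(s.grid, rows, metas)
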