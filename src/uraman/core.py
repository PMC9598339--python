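"""Domain types and delimited-text I/O for urine Raman spectra.

A :class:`Spectrum` is one intensity vector on a :class:`WavenumberAxis`
(Raman shift in cm^-1), carrying acquisition metadata; a
:class:`SpectraSet` is a collection of spectra sharing one axis, the
in-memory form of a spectral matrix file.  :class:`BiomarkerPanel` holds
the five assayed urine analytes (urea, creatinine, glucose, phosphate in
mmol/L; total protein in mg/dL) for one sample, and
:class:`ReferenceRange` the clinical normal range for one analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "ANALYTES",
    "ANALYTE_UNITS",
    "WavenumberAxis",
    "SpectrumMeta",
    "Spectrum",
    "SpectraSet",
    "BiomarkerPanel",
    "ReferenceRange",
    "MalformedAxisError",
    "JoinError",
    "SpectraParseError",
    "AxisMismatchError",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "read_panels",
    "write_panels",
    "resample_to_grid",
]


class Group(str, Enum):
    """Clinical group: healthy controls vs diabetic & hypertensive."""

    CT = "CT"
    DMHBP = "DMHBP"


class Sex(str, Enum):
    M = "M"
    W = "W"
    UNKNOWN = "unknown"


#: The five assayed analytes, in canonical column order.
ANALYTES = ("urea", "creatinine", "glucose", "phosphate", "total_protein")

#: Fixed units per analyte.
ANALYTE_UNITS = {
    "urea": "mmol/L",
    "creatinine": "mmol/L",
    "glucose": "mmol/L",
    "phosphate": "mmol/L",
    "total_protein": "mg/dL",
}

WAVENUMBER_COLUMN = "wavenumber_cm-1"


class MalformedAxisError(ValueError):
    """Wavenumber axis violates its invariants (ordering, range, length)."""


class JoinError(KeyError):
    """Spectral matrix and metadata table do not share the same spectrum ids."""


class SpectraParseError(ValueError):
    """A cell of a spectral file could not be parsed as a number."""


class AxisMismatchError(ValueError):
    """Operation received spectra on different wavenumber grids."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift grid in cm^-1, within [100, 4000]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 16:
            raise MalformedAxisError(
                f"axis must be a 1-d grid of at least 16 points, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise MalformedAxisError("axis contains non-finite values")
        if np.any(np.diff(v) <= 0):
            raise MalformedAxisError("axis must be strictly increasing")
        if v[0] < 100.0 or v[-1] > 4000.0:
            raise MalformedAxisError(
                f"axis range [{v[0]}, {v[-1]}] outside the plausible Raman-shift"
                " window [100, 4000] cm^-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=1e-8, atol=1e-10))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with lo <= wavenumber <= hi."""
        return (self.values >= lo) & (self.values <= hi)


def default_grid() -> WavenumberAxis:
    """Default working grid: 400-1800 cm^-1 at 2 cm^-1 spacing (701 points)."""
    return WavenumberAxis(np.arange(400.0, 1800.0 + 1.0, 2.0))


@dataclass
class SpectrumMeta:
    spectrum_id: str
    sample_id: str = ""
    group: Group | None = None
    sex: Sex = Sex.UNKNOWN
    replicate_index: int = 1
    qc_pass: bool | None = None
    snr: float | None = None
    n_spikes_removed: int | None = None
    baseline_converged: bool | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class Spectrum:
    """One Raman spectrum: intensities (arbitrary units) on a shared axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ValueError(
                f"intensity length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains missing or non-finite values")
        self.intensity = y

    def with_intensity(self, y: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy with new intensities (same axis); meta fields may be updated."""
        meta = replace(self.meta, **meta_updates) if meta_updates else replace(self.meta)
        return Spectrum(self.axis, np.asarray(y, dtype=float).copy(), meta)


class SpectraSet:
    """Ordered collection of spectra on one shared wavenumber axis."""

    def __init__(self, axis: WavenumberAxis, spectra: Iterable[Spectrum] = ()):
        self.axis = axis
        self.spectra: list[Spectrum] = []
        for s in spectra:
            self.append(s)

    def append(self, s: Spectrum) -> None:
        if s.axis != self.axis:
            raise AxisMismatchError(
                f"spectrum {s.meta.spectrum_id!r} is on a different wavenumber grid"
            )
        if any(t.meta.spectrum_id == s.meta.spectrum_id for t in self.spectra):
            raise ValueError(f"duplicate spectrum_id {s.meta.spectrum_id!r}")
        self.spectra.append(s)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def ids(self) -> list[str]:
        return [s.meta.spectrum_id for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """Spectra stacked as rows: shape (n_spectra, n_channels)."""
        if not self.spectra:
            return np.empty((0, len(self.axis)))
        return np.vstack([s.intensity for s in self.spectra])

    def groups(self) -> np.ndarray:
        return np.array(
            [s.meta.group.value if s.meta.group else "" for s in self.spectra]
        )

    def subset(self, keep: Sequence[bool]) -> "SpectraSet":
        if len(keep) != len(self.spectra):
            raise ValueError("mask length mismatch")
        return SpectraSet(self.axis, [s for s, k in zip(self.spectra, keep) if k])

    def select_group(self, group: Group) -> "SpectraSet":
        return SpectraSet(
            self.axis, [s for s in self.spectra if s.meta.group == group]
        )


@dataclass
class BiomarkerPanel:
    """Assayed concentrations for one urine sample (fixed units per analyte)."""

    sample_id: str
    urea: float  # mmol/L
    creatinine: float  # mmol/L
    glucose: float  # mmol/L
    phosphate: float  # mmol/L
    total_protein: float  # mg/dL

    def __post_init__(self) -> None:
        for a in ANALYTES:
            v = getattr(self, a)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{a} concentration must be finite and >= 0, got {v}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, a) for a in ANALYTES], dtype=float)

    def __getitem__(self, analyte: str) -> float:
        if analyte not in ANALYTES:
            raise KeyError(analyte)
        return getattr(self, analyte)


@dataclass(frozen=True)
class ReferenceRange:
    """Clinical reference interval for one analyte, possibly sex-specific."""

    analyte: str
    sex: Sex = Sex.UNKNOWN  # UNKNOWN means "any"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError("reference range requires lower < upper")

    @property
    def units(self) -> str:
        return ANALYTE_UNITS[self.analyte]


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Spectral matrix: first column "wavenumber_cm-1", then one column per
# spectrum headed by its spectrum_id.  Metadata: one row per spectrum with
# columns spectrum_id, sample_id, group, sex, replicate_index (+ optional QC
# columns).  Concentration table: sample_id + the five analytes.
# ---------------------------------------------------------------------------

_META_COLUMNS = ["spectrum_id", "sample_id", "group", "sex", "replicate_index"]


def read_spectra(
    matrix_path: str | Path,
    metadata_path: str | Path,
    sep: str = ",",
) -> SpectraSet:
    """Read a spectral matrix plus its metadata table into a SpectraSet.

    Raises :class:`MalformedAxisError` for a bad wavenumber column,
    :class:`JoinError` when matrix columns and metadata rows do not match
    one-to-one, and :class:`SpectraParseError` for non-numeric cells.
    """
    raw = pd.read_csv(matrix_path, sep=sep, dtype=str)
    if raw.shape[1] < 1:
        raise SpectraParseError(f"{matrix_path}: empty spectral matrix")

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SpectraParseError(
                f"{matrix_path}: non-numeric value at row {row + 2}, column {col!r}"
            )
        return vals.to_numpy(dtype=float)

    axis_col = raw.columns[0]
    axis = WavenumberAxis(_numeric(axis_col))

    meta_df = pd.read_csv(metadata_path, sep=sep, dtype=str)
    missing_cols = [c for c in _META_COLUMNS if c not in meta_df.columns]
    if missing_cols:
        raise JoinError(f"{metadata_path}: missing metadata columns {missing_cols}")
    meta_by_id = {str(r.spectrum_id): r for r in meta_df.itertuples(index=False)}

    spectrum_ids = [str(c) for c in raw.columns[1:]]
    absent = [sid for sid in spectrum_ids if sid not in meta_by_id]
    if absent:
        raise JoinError(f"metadata has no rows for spectrum ids {absent}")

    spectra = []
    for sid in spectrum_ids:
        row = meta_by_id[sid]
        group = Group(row.group) if str(row.group) not in ("", "nan") else None
        sex = Sex(row.sex) if str(row.sex) in ("M", "W") else Sex.UNKNOWN
        qc = getattr(row, "qc_pass", None)
        meta = SpectrumMeta(
            spectrum_id=sid,
            sample_id=str(row.sample_id),
            group=group,
            sex=sex,
            replicate_index=int(float(row.replicate_index)),
            qc_pass=None if qc in (None, "", "nan") else str(qc).lower() == "true",
        )
        spectra.append(Spectrum(axis, _numeric(sid), meta))
    return SpectraSet(axis, spectra)


def write_spectra(
    spectra: SpectraSet,
    matrix_path: str | Path,
    metadata_path: str | Path,
    sep: str = ",",
) -> None:
    """Write a SpectraSet as a spectral matrix + metadata table.

    Round-trips through :func:`read_spectra` within 1e-9 relative on
    intensities and exactly on metadata.
    """
    cols = {WAVENUMBER_COLUMN: spectra.axis.values}
    for s in spectra:
        cols[s.meta.spectrum_id] = s.intensity
    pd.DataFrame(cols).to_csv(matrix_path, sep=sep, index=False, float_format="%.12g")

    rows = []
    for s in spectra:
        m = s.meta
        rows.append(
            {
                "spectrum_id": m.spectrum_id,
                "sample_id": m.sample_id,
                "group": m.group.value if m.group else "",
                "sex": m.sex.value if m.sex != Sex.UNKNOWN else "unknown",
                "replicate_index": m.replicate_index,
                "qc_pass": "" if m.qc_pass is None else str(m.qc_pass),
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS + ["qc_pass"]).to_csv(
        metadata_path, sep=sep, index=False
    )


def read_panels(path: str | Path, sep: str = ",") -> list[BiomarkerPanel]:
    """Read a concentration table (sample_id + five analytes, fixed units)."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("sample_id",) + ANALYTES if c not in df.columns]
    if missing:
        raise SpectraParseError(f"{path}: missing concentration columns {missing}")
    return [
        BiomarkerPanel(
            sample_id=str(r.sample_id),
            **{a: float(getattr(r, a)) for a in ANALYTES},
        )
        for r in df.itertuples(index=False)
    ]


def write_panels(panels: Sequence[BiomarkerPanel], path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        [{"sample_id": p.sample_id, **{a: getattr(p, a) for a in ANALYTES}} for p in panels],
        columns=["sample_id", *ANALYTES],
    ).to_csv(path, sep=sep, index=False, float_format="%.12g")


def resample_to_grid(s: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid inside its range.

    Exact for affine intensity profiles; raises ValueError when the target
    grid extends beyond the source range (no extrapolation).
    """
    src = s.axis.values
    if target.values[0] < src[0] or target.values[-1] > src[-1]:
        raise ValueError(
            f"target grid [{target.values[0]}, {target.values[-1]}] extends beyond"
            f" source range [{src[0]}, {src[-1]}]; extrapolation is not supported"
        )
    y = np.interp(target.values, src, s.intensity)
    return Spectrum(target, y, replace(s.meta))
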