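"""Spectrum data model, canonical wavenumber grid, resampling, normalization and text I/O.

An FTIR absorbance spectrum is a pair of equal-length sequences: a strictly
increasing wavenumber grid (cm⁻¹) and arbitrary-unit absorbance intensities.
All downstream comparisons in this package happen after min-max normalization,
so intensities carry no unit semantics beyond "absorbance, arbitrary".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "canonical_grid",
    "reduced_grid",
    "resample_to_grid",
    "minmax_normalize",
    "read_spectra",
    "write_spectra",
    "WAVENUMBER_COLUMN",
]

#: Header of the wavenumber column in the delimited-text layouts.
WAVENUMBER_COLUMN = "wavenumber_cm-1"

#: Tolerance used when asserting that a spectrum is min-max normalized.
NORMALIZED_ATOL = 1e-9


class SpectraError(ValueError):
    """Base class for spectrum-domain errors."""


class ParseError(SpectraError):
    """Raised when a delimited-text spectra file cannot be parsed."""


@dataclass(frozen=True)
class Spectrum:
    """One FTIR trace: wavenumber grid, intensities and an optional class label.

    Parameters
    ----------
    wavenumbers
        Strictly increasing wavenumbers in cm⁻¹, length > 1.
    intensities
        Absorbance values (arbitrary units), same length as ``wavenumbers``.
    label
        Optional class name (a polymer type, ``"membrane_filter"``, or None).
    meta
        Free-form provenance mapping.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1:
            raise SpectraError("wavenumbers and intensities must be 1-D")
        if wn.size != it.size:
            raise SpectraError(
                f"length mismatch: {wn.size} wavenumbers vs {it.size} intensities"
            )
        if wn.size < 2:
            raise SpectraError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wn) > 0):
            raise SpectraError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def is_normalized(self) -> bool:
        """True when intensities span exactly [0, 1] (within 1e-9)."""
        return (
            abs(float(self.intensities.min())) <= NORMALIZED_ATOL
            and abs(float(self.intensities.max()) - 1.0) <= NORMALIZED_ATOL
        )

    def with_intensities(self, intensities: np.ndarray, label: str | None = ...) -> "Spectrum":
        """Copy of this spectrum with new intensities (and optionally a new label)."""
        return Spectrum(
            self.wavenumbers,
            intensities,
            self.label if label is ... else label,
            dict(self.meta),
        )


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber grid."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for i, s in enumerate(self.spectra):
                if s.wavenumbers.size != grid.size or not np.array_equal(
                    s.wavenumbers, grid
                ):
                    raise SpectraError(
                        f"spectrum {i} is not on the shared wavenumber grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise SpectraError("empty SpectrumSet has no grid")
        return self.spectra[0].wavenumbers

    @property
    def class_names(self) -> list[str]:
        """Distinct labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            if s.label is not None:
                seen.setdefault(s.label, None)
        return list(seen)

    def by_label(self, label: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.label == label]


def canonical_grid() -> np.ndarray:
    """The canonical FTIR wavenumber grid: 650.0, 650.5, …, 3999.5 cm⁻¹.

    Arithmetic sequence with step 0.5 and exactly 6700 points, matching the
    acquisition range used for the reference datasets.
    """
    return np.linspace(650.0, 3999.5, 6700)


def reduced_grid() -> np.ndarray:
    """A reduced 650–1650 cm⁻¹ grid at step 2.0 (501 points).

    Covers the fingerprint region only; intended for fast simulations and
    tests. The canonical grid remains the default everywhere else.
    """
    return np.linspace(650.0, 1650.0, 501)


def resample_to_grid(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Piecewise-linear resampling of ``s`` onto ``grid``.

    ``grid`` must be strictly increasing and lie inside the spectrum's support;
    extrapolation is refused rather than silently zero-filled.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise SpectraError("target grid must be a non-empty 1-D sequence")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise SpectraError("target grid must be strictly increasing")
    lo, hi = float(s.wavenumbers[0]), float(s.wavenumbers[-1])
    if grid[0] < lo:
        raise SpectraError(
            f"grid point {grid[0]:g} cm⁻¹ below the spectrum's lower bound {lo:g}"
        )
    if grid[-1] > hi:
        raise SpectraError(
            f"grid point {grid[-1]:g} cm⁻¹ above the spectrum's upper bound {hi:g}"
        )
    values = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, values, s.label, dict(s.meta))


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Map intensities affinely onto [0, 1].

    Raises for a constant spectrum: the map is undefined and downstream
    gradient correlations would be undefined on constants anyway.
    """
    lo = float(s.intensities.min())
    hi = float(s.intensities.max())
    if hi == lo:
        raise SpectraError("cannot min-max normalize a constant spectrum")
    return s.with_intensities((s.intensities - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# wide layout: column 1 "wavenumber_cm-1", then one column per spectrum with
#   header "<label>#<replicate>".
# long layout: columns spectrum_id,label,wavenumber_cm-1,intensity.
# Delimiter by extension: .tsv/.tab → tab, otherwise comma.


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _split_header(name: str) -> str | None:
    label = name.split("#", 1)[0]
    return label if label else None


def read_spectra(path: str | Path, layout: str = "wide") -> SpectrumSet:
    """Read a SpectrumSet from delimited text.

    No resampling or normalization is performed; per-spectrum wavenumbers are
    sorted ascending. Duplicate wavenumbers within one spectrum are an error.
    """
    path = Path(path)
    if layout not in {"wide", "long"}:
        raise ValueError(f"unknown layout {layout!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty data section")

    if layout == "wide":
        if WAVENUMBER_COLUMN not in df.columns:
            raise ParseError(f"{path}: missing column {WAVENUMBER_COLUMN!r}")
        data_cols = [c for c in df.columns if c != WAVENUMBER_COLUMN]
        if not data_cols:
            raise ParseError(f"{path}: no spectrum columns")
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = num.isna() & df.notna()
        if bad.any().any():
            r, c = next(zip(*np.nonzero(bad.values)))
            raise ParseError(
                f"{path}: non-numeric cell at row {r + 2}, column {df.columns[c]!r}"
            )
        if num.isna().any().any():
            raise ParseError(f"{path}: missing values in data section")
        num = num.sort_values(WAVENUMBER_COLUMN)
        wn = num[WAVENUMBER_COLUMN].to_numpy()
        if np.any(np.diff(wn) == 0):
            raise ParseError(f"{path}: duplicate wavenumbers in wide table")
        spectra = [
            Spectrum(wn, num[c].to_numpy(), _split_header(c)) for c in data_cols
        ]
        return SpectrumSet(spectra)

    required = ["spectrum_id", "label", WAVENUMBER_COLUMN, "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    spectra = []
    for sid, group in df.groupby("spectrum_id", sort=False):
        group = group.sort_values(WAVENUMBER_COLUMN)
        wn = pd.to_numeric(group[WAVENUMBER_COLUMN], errors="raise").to_numpy(float)
        it = pd.to_numeric(group["intensity"], errors="raise").to_numpy(float)
        if np.any(np.diff(wn) == 0):
            raise ParseError(
                f"{path}: duplicate wavenumbers within spectrum {sid!r}"
            )
        labels = group["label"].unique()
        label = None if len(labels) != 1 or pd.isna(labels[0]) else str(labels[0])
        spectra.append(Spectrum(wn, it, label, {"spectrum_id": str(sid)}))
    # long layout permits heterogeneous grids; wrap without the shared-grid check
    out = SpectrumSet.__new__(SpectrumSet)
    out.spectra = spectra
    return out


def write_spectra(sset: SpectrumSet, path: str | Path, layout: str = "wide") -> Path:
    """Write a SpectrumSet as delimited text; inverse of :func:`read_spectra`."""
    path = Path(path)
    sep = _sep_for(path)
    if layout == "wide":
        grids = {s.wavenumbers.tobytes() for s in sset.spectra}
        if len(grids) > 1:
            raise SpectraError("wide layout requires all spectra on one grid")
        cols = {WAVENUMBER_COLUMN: sset.spectra[0].wavenumbers}
        for i, s in enumerate(sset.spectra, start=1):
            name = f"{s.label or 'spectrum'}#{i}"
            cols[name] = s.intensities
        pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.10g")
        return path
    if layout == "long":
        frames = []
        for i, s in enumerate(sset.spectra, start=1):
            frames.append(
                pd.DataFrame(
                    {
                        "spectrum_id": s.meta.get("spectrum_id", f"s{i}"),
                        "label": s.label,
                        WAVENUMBER_COLUMN: s.wavenumbers,
                        "intensity": s.intensities,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep=sep, index=False, float_format="%.10g"
        )
        return path
    raise ValueError(f"unknown layout {layout!r}")


def stack_intensities(spectra: Iterable[Spectrum]) -> np.ndarray:
    """Column-stack spectra intensities into an N×M matrix."""
    cols = [s.intensities for s in spectra]
    if not cols:
        raise SpectraError("no spectra to stack")
    return np.column_stack(cols)
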