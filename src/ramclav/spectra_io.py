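"""Reading, writing and validation of Raman spectra and cohort metadata.

A measurement is a two-column delimited text file (wavenumber in cm^-1,
intensity in counts).  A cohort is a directory of such files plus a CSV
metadata table with one row per file describing the specimen the spectrum
was taken from (individual, age group, side, anatomical region, and the
measurement position 1-15 along the anterior surface of the clavicle).

Internally the wavenumber axis is always strictly ascending, whatever the
file order, and all spectra of a :class:`SpectrumSet` share one axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "SIDES",
    "REGIONS",
    "ParseError",
    "SpectrumMeta",
    "RamanSpectrum",
    "SpectrumSet",
    "region_for_position",
    "read_spectrum",
    "write_spectrum",
    "read_cohort",
    "write_cohort",
    "write_table",
]

#: Age-group labels, youngest to oldest. Boundary ages (18, 30) belong to the
#: younger-labelled group by convention.
AGE_GROUPS: tuple[str, ...] = ("13-18", "18-30", "30-40")
SIDES: tuple[str, ...] = ("left", "right")
#: Anatomical regions along the clavicle, shoulder end (lateral) to sternum
#: end (medial); position 1 is the most lateral measurement.
REGIONS: tuple[str, ...] = ("lateral", "middle", "medial")

METADATA_COLUMNS = (
    "file",
    "specimen_id",
    "individual_id",
    "age_group",
    "side",
    "region",
    "position",
)

_SPECTRUM_SUFFIXES = (".csv", ".txt", ".tsv", ".dat")


class ParseError(ValueError):
    """Raised when a spectrum or metadata file violates the format contract."""


def region_for_position(position: int) -> str:
    """Map a measurement position (1-15) to its five-measurement region.

    Positions 1-5 are lateral, 6-10 middle, 11-15 medial.
    """
    if not 1 <= int(position) <= 15:
        raise ValueError(f"position must be in 1..15, got {position}")
    return REGIONS[(int(position) - 1) // 5]


@dataclass(frozen=True)
class SpectrumMeta:
    """Provenance of one measurement: which clavicle and where on it."""

    specimen_id: str
    individual_id: str
    age_group: str
    side: str
    region: str
    position: int

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group {self.age_group!r} not one of {AGE_GROUPS}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side {self.side!r} not one of {SIDES}")
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not one of {REGIONS}")
        expected = region_for_position(self.position)
        if self.region != expected:
            raise ValueError(
                f"position {self.position} lies in region {expected!r}, "
                f"metadata says {self.region!r}"
            )

    def as_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "individual_id": self.individual_id,
            "age_group": self.age_group,
            "side": self.side,
            "region": self.region,
            "position": self.position,
        }


@dataclass
class RamanSpectrum:
    """One Raman measurement: wavenumber axis, intensities, provenance.

    ``wavenumbers`` must be strictly ascending and finite; ``intensities``
    has the same length (>= 2).  Intensities are arbitrary counts; after
    preprocessing they are unit-norm normalized values.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(w) != len(y):
            raise ValueError(
                f"length mismatch: {len(w)} wavenumbers vs {len(y)} intensities"
            )
        if len(w) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError("wavenumbers and intensities must be finite")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.wavenumbers, intensities, self.meta)

    def label(self) -> str:
        """Short identity string for error messages."""
        if self.meta is None:
            return "<anonymous spectrum>"
        return f"{self.meta.specimen_id}:pos{self.meta.position:02d}"


class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis."""

    def __init__(self, spectra: Sequence[RamanSpectrum]):
        spectra = list(spectra)
        if spectra:
            axis = spectra[0].wavenumbers
            for s in spectra[1:]:
                if not np.array_equal(s.wavenumbers, axis):
                    raise ValueError(
                        f"spectrum {s.label()} is not on the shared axis"
                    )
        self.spectra: list[RamanSpectrum] = spectra

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no axis")
        return self.spectra[0].wavenumbers

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_wavenumbers) matrix of intensities."""
        if not self.spectra:
            return np.empty((0, 0))
        return np.vstack([s.intensities for s in self.spectra])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.spectra:
            if s.meta is None:
                raise ValueError(f"spectrum {s.label()} has no metadata")
            rows.append(s.meta.as_dict())
        return pd.DataFrame(rows, columns=METADATA_COLUMNS[1:])

    def with_matrix(self, axis: np.ndarray, matrix: np.ndarray) -> "SpectrumSet":
        """Rebuild the set with new axis/intensities, preserving metadata."""
        if matrix.shape[0] != len(self.spectra):
            raise ValueError("matrix row count does not match set size")
        return SpectrumSet(
            [
                RamanSpectrum(axis, matrix[i], s.meta)
                for i, s in enumerate(self.spectra)
            ]
        )


# ---------------------------------------------------------------------------
# file parsing


def _split_row(text: str) -> list[str]:
    parts = re.split(r"[,\t;]+|\s+", text.strip())
    return [p for p in parts if p]


def read_spectrum(path: str | Path, meta: SpectrumMeta | None = None) -> RamanSpectrum:
    """Read a two-column delimited spectrum file.

    Accepts comma, tab, semicolon or whitespace delimiters and an optional
    single header line.  The returned spectrum is sorted ascending in
    wavenumber regardless of file order.  Non-numeric data rows, duplicated
    wavenumbers or fewer than two points raise :class:`ParseError` naming
    the offending line.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    intensities: list[float] = []
    saw_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = _split_row(text)
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                w, y = float(parts[0]), float(parts[1])
            except ValueError:
                if not saw_data:
                    continue  # header line
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric row {text!r}"
                ) from None
            saw_data = True
            wavenumbers.append(w)
            intensities.append(y)
    if len(wavenumbers) < 2:
        raise ParseError(f"{path.name}: fewer than 2 data points")
    w = np.asarray(wavenumbers)
    y = np.asarray(intensities)
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    dup = np.flatnonzero(np.diff(w) == 0)
    if dup.size:
        raise ParseError(
            f"{path.name}: duplicated wavenumber {w[dup[0]]:g}"
        )
    return RamanSpectrum(w, y, meta)


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as ``wavenumber_cm1,intensity`` CSV (8 sig. digits)."""
    df = pd.DataFrame(
        {
            "wavenumber_cm1": spectrum.wavenumbers,
            "intensity": spectrum.intensities,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write tabular records as CSV with a header.

    Numbers are written with 8 significant digits, missing values as ``NA``;
    identical input yields byte-identical output.  An empty DataFrame yields
    a header-only file.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.8g", na_rep="NA")


# ---------------------------------------------------------------------------
# cohort reading / writing


def _meta_from_row(row: pd.Series) -> SpectrumMeta:
    try:
        position = int(row["position"])
    except (TypeError, ValueError):
        raise ParseError(
            f"metadata row for file {row['file']!r}: "
            f"position {row['position']!r} is not an integer"
        ) from None
    try:
        return SpectrumMeta(
            specimen_id=str(row["specimen_id"]),
            individual_id=str(row["individual_id"]),
            age_group=str(row["age_group"]),
            side=str(row["side"]),
            region=str(row["region"]),
            position=position,
        )
    except ValueError as exc:
        raise ParseError(
            f"metadata row for file {row['file']!r}: {exc}"
        ) from None


def read_cohort(spectra_dir: str | Path, metadata_path: str | Path) -> SpectrumSet:
    """Read a cohort directory against its metadata table.

    Every metadata row must match exactly one spectrum file (join key:
    filename stem == the ``file`` column, extension optional) and every
    spectrum file in the directory must be claimed by a row.  Spectra on
    identical axes are kept bit-equal; differing axes are resampled by
    linear interpolation onto the intersection grid (the first spectrum's
    axis clipped to the range shared by all).
    """
    spectra_dir = Path(spectra_dir)
    metadata_path = Path(metadata_path)
    table = pd.read_csv(metadata_path, dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ParseError(
            f"{metadata_path.name}: missing metadata columns {missing_cols}"
        )

    by_stem: dict[str, Path] = {}
    for p in sorted(spectra_dir.iterdir()):
        if p.resolve() == metadata_path.resolve():
            continue
        if p.suffix.lower() in _SPECTRUM_SUFFIXES and p.is_file():
            by_stem[p.stem] = p

    spectra: list[RamanSpectrum] = []
    claimed: set[str] = set()
    for _, row in table.iterrows():
        stem = Path(str(row["file"])).stem
        if stem not in by_stem:
            raise ParseError(
                f"metadata row {row['file']!r} matches no file in {spectra_dir}"
            )
        if stem in claimed:
            raise ParseError(f"metadata rows claim file {stem!r} twice")
        claimed.add(stem)
        spectra.append(read_spectrum(by_stem[stem], _meta_from_row(row)))
    unclaimed = sorted(set(by_stem) - claimed)
    if unclaimed:
        raise ParseError(
            f"spectrum files without metadata rows: {unclaimed[:5]}"
            + ("..." if len(unclaimed) > 5 else "")
        )

    if not spectra:
        return SpectrumSet([])
    axis0 = spectra[0].wavenumbers
    if all(np.array_equal(s.wavenumbers, axis0) for s in spectra):
        return SpectrumSet(spectra)

    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if lo > hi:
        raise ParseError("spectra have no common wavenumber range")
    common = axis0[(axis0 >= lo) & (axis0 <= hi)]
    if len(common) < 2:
        raise ParseError("common wavenumber range has fewer than 2 points")
    resampled = [
        RamanSpectrum(
            common, np.interp(common, s.wavenumbers, s.intensities), s.meta
        )
        for s in spectra
    ]
    return SpectrumSet(resampled)


def write_cohort(sset: SpectrumSet, out_dir: str | Path) -> Path:
    """Write one CSV per spectrum plus ``metadata.csv``; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sset:
        if s.meta is None:
            raise ValueError(f"spectrum {s.label()} has no metadata")
        name = f"{s.meta.specimen_id}_pos{s.meta.position:02d}"
        write_spectrum(s, out_dir / f"{name}.csv")
        rows.append({"file": name, **s.meta.as_dict()})
    meta_path = out_dir / "metadata.csv"
    write_table(pd.DataFrame(rows, columns=METADATA_COLUMNS), meta_path)
    return meta_path
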