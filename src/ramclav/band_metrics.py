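"""True peak heights, band ratios and phosphate-FWHM crystal maturity.

The bone bands used throughout are the field's standard assignments:
proline ~850, phosphate nu1 ~960, carbonate ~1070, amide III ~1270,
CH2 deformation ~1450 and amide I ~1670 cm^-1.  Each band is measured
inside a fixed window wide enough to absorb apex drift but narrow enough
to exclude neighbours; the apex is the in-window maximum refined by
parabolic interpolation through its grid triplet.

*True peak height* is the apex intensity minus the baseline reference at
the apex.  In ``global`` mode (the pipeline default) spectra are already
baseline-corrected, so the reference is zero; ``local_chord`` mode
subtracts the straight line joining the window endpoints instead, which
is more robust when neighbouring bands overlap.

Three diagnostic ratios are computed per spectrum:

* 960:1450 (phosphate : CH2) — mineral-to-matrix / collagen preservation,
* P:C = 960:1070 (phosphate : carbonate) — intra-mineral composition,
* P:A = 960:1270 (phosphate : amide III) — mineral-to-protein.

Crystal maturity uses the full width at half the height of the phosphate
peak: a narrower band means a more ordered, more mature apatite lattice,
so maturity rankings sort group-mean FWHM ascending (rank 1 = narrowest
= most mature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import RamanSpectrum, SpectrumSet

__all__ = [
    "BandWindow",
    "DEFAULT_BANDS",
    "band_by_name",
    "ApexResult",
    "FwhmResult",
    "PeakMeasurement",
    "SpectrumMetrics",
    "locate_apex",
    "true_peak_height",
    "fwhm",
    "spectrum_metrics",
    "cohort_metrics",
    "grouped_summary",
    "rank_crystal_maturity",
    "METRIC_COLUMNS",
]


@dataclass(frozen=True)
class BandWindow:
    """A named search window [lo, hi] around a nominal band center."""

    name: str
    lo: float
    hi: float
    nominal_center: float

    def __post_init__(self) -> None:
        if not self.lo < self.nominal_center < self.hi:
            raise ValueError(
                f"band {self.name!r}: need lo < nominal_center < hi, "
                f"got {self.lo}, {self.nominal_center}, {self.hi}"
            )


DEFAULT_BANDS: tuple[BandWindow, ...] = (
    BandWindow("proline", 830.0, 870.0, 850.0),
    BandWindow("phosphate", 930.0, 990.0, 960.0),
    BandWindow("carbonate", 1040.0, 1100.0, 1070.0),
    BandWindow("amide_iii", 1220.0, 1300.0, 1270.0),
    BandWindow("ch2", 1420.0, 1480.0, 1450.0),
    BandWindow("amide_i", 1620.0, 1700.0, 1670.0),
)


def band_by_name(name: str, bands: tuple[BandWindow, ...] = DEFAULT_BANDS) -> BandWindow:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"no band named {name!r}")


@dataclass(frozen=True)
class ApexResult:
    """Located band apex; ``at_edge`` flags a degenerate window-edge maximum."""

    position: float
    height: float
    at_edge: bool
    index: int  # grid index of the apex within the full spectrum


@dataclass(frozen=True)
class FwhmResult:
    value: float | None
    reason: str | None = None


def _window_slice(s: RamanSpectrum, w: BandWindow) -> np.ndarray:
    idx = np.flatnonzero((s.wavenumbers >= w.lo) & (s.wavenumbers <= w.hi))
    if idx.size == 0:
        raise ValueError(
            f"band window {w.name!r} [{w.lo}, {w.hi}] lies outside the axis"
        )
    if idx.size < 3:
        raise ValueError(
            f"band window {w.name!r} contains only {idx.size} points (< 3)"
        )
    return idx


def locate_apex(s: RamanSpectrum, w: BandWindow) -> ApexResult:
    """Find the band apex within the window.

    Interior local maxima are preferred over window-edge maxima; the
    highest interior maximum is refined by a parabola through its grid
    triplet (sub-grid position and height).  A monotone window (no
    interior maximum) returns the edge point with ``at_edge=True``.
    """
    idx = _window_slice(s, w)
    xi = s.wavenumbers[idx]
    yi = s.intensities[idx]
    interior = np.flatnonzero(
        (yi[1:-1] > yi[:-2]) & (yi[1:-1] >= yi[2:])
    ) + 1
    if interior.size == 0:
        j = int(np.argmax(yi))
        return ApexResult(float(xi[j]), float(yi[j]), True, int(idx[j]))
    j = int(interior[np.argmax(yi[interior])])
    x3 = xi[j - 1 : j + 2]
    y3 = yi[j - 1 : j + 2]
    a, b, c = np.polyfit(x3 - x3[1], y3, 2)
    if a >= 0:  # flat/degenerate triplet
        return ApexResult(float(xi[j]), float(yi[j]), False, int(idx[j]))
    dx = -b / (2.0 * a)
    dx = float(np.clip(dx, x3[0] - x3[1], x3[2] - x3[1]))
    pos = float(x3[1] + dx)
    height = float(a * dx * dx + b * dx + c)
    return ApexResult(pos, height, False, int(idx[j]))


def _chord(s: RamanSpectrum, w: BandWindow) -> tuple[float, float]:
    """Slope/intercept of the line joining the window-endpoint intensities."""
    idx = _window_slice(s, w)
    x0, x1 = s.wavenumbers[idx[0]], s.wavenumbers[idx[-1]]
    y0, y1 = s.intensities[idx[0]], s.intensities[idx[-1]]
    slope = (y1 - y0) / (x1 - x0)
    return float(slope), float(y0 - slope * x0)


def true_peak_height(
    s: RamanSpectrum, w: BandWindow, mode: str = "global"
) -> float:
    """Apex intensity minus the baseline reference at the apex position.

    ``global``: reference 0 (spectrum already baseline-corrected).
    ``local_chord``: reference is the straight line joining the window
    endpoints, evaluated at the apex position.
    """
    apex = locate_apex(s, w)
    if mode == "global":
        return apex.height
    if mode == "local_chord":
        slope, intercept = _chord(s, w)
        return apex.height - (slope * apex.position + intercept)
    raise ValueError(f"unknown height mode {mode!r}")


def fwhm(s: RamanSpectrum, w: BandWindow, mode: str = "global") -> FwhmResult:
    """Full width at half the (true) height of the band.

    The two half-height crossings nearest the apex are found by linear
    interpolation between bracketing grid points, referenced to the same
    baseline as :func:`true_peak_height`.  Missing (with a reason) when
    the height is non-positive or a crossing lies outside the window.
    """
    apex = locate_apex(s, w)
    idx = _window_slice(s, w)
    xi = s.wavenumbers[idx]
    if mode == "global":
        ref = np.zeros(idx.size)
        ref_apex = 0.0
    elif mode == "local_chord":
        slope, intercept = _chord(s, w)
        ref = slope * xi + intercept
        ref_apex = slope * apex.position + intercept
    else:
        raise ValueError(f"unknown height mode {mode!r}")
    height = apex.height - ref_apex
    if height <= 0:
        return FwhmResult(None, "non_positive_height")
    g = s.intensities[idx] - ref
    half = height / 2.0
    j = int(apex.index - idx[0])

    def cross(direction: int) -> float | None:
        k = j
        while 0 <= k + direction < g.size:
            k2 = k + direction
            if g[k2] < half <= g[k]:
                frac = (g[k] - half) / (g[k] - g[k2])
                return float(xi[k] + frac * (xi[k2] - xi[k]))
            k = k2
        return None

    left = cross(-1)
    right = cross(+1)
    if left is None or right is None:
        return FwhmResult(None, "no_crossing")
    return FwhmResult(right - left, None)


@dataclass(frozen=True)
class PeakMeasurement:
    band: str
    apex_position: float
    true_height: float
    fwhm: float | None
    fwhm_reason: str | None
    at_edge: bool


@dataclass
class SpectrumMetrics:
    """Per-spectrum band measurements and the three diagnostic ratios."""

    peaks: dict[str, PeakMeasurement]
    ratio_960_1450: float | None
    ratio_p_c: float | None
    ratio_p_a: float | None
    fwhm_960: float | None


def _ratio(num: float, den: float) -> float | None:
    if den is None or den <= 0 or num is None:
        return None
    return num / den


def spectrum_metrics(
    s: RamanSpectrum,
    bands: tuple[BandWindow, ...] = DEFAULT_BANDS,
    mode: str = "global",
) -> SpectrumMetrics:
    """Measure every band and form the 960:1450, P:C and P:A ratios.

    A non-positive denominator leaves that ratio missing; the others are
    still computed.  All ratios are invariant to global intensity scaling
    (and hence to vector normalization).
    """
    peaks: dict[str, PeakMeasurement] = {}
    for w in bands:
        apex = locate_apex(s, w)
        h = true_peak_height(s, w, mode)
        fw = fwhm(s, w, mode)
        peaks[w.name] = PeakMeasurement(
            w.name, apex.position, h, fw.value, fw.reason, apex.at_edge
        )

    def h(name: str) -> float | None:
        return peaks[name].true_height if name in peaks else None

    return SpectrumMetrics(
        peaks=peaks,
        ratio_960_1450=_ratio(h("phosphate"), h("ch2")),
        ratio_p_c=_ratio(h("phosphate"), h("carbonate")),
        ratio_p_a=_ratio(h("phosphate"), h("amide_iii")),
        fwhm_960=peaks["phosphate"].fwhm if "phosphate" in peaks else None,
    )


#: Numeric columns produced by :func:`cohort_metrics` (heights use the band name).
METRIC_COLUMNS = (
    "height_proline",
    "height_phosphate",
    "height_carbonate",
    "height_amide_iii",
    "height_ch2",
    "height_amide_i",
    "ratio_960_1450",
    "ratio_p_c",
    "ratio_p_a",
    "fwhm_960",
)


def cohort_metrics(
    sset: SpectrumSet,
    bands: tuple[BandWindow, ...] = DEFAULT_BANDS,
    mode: str = "global",
) -> pd.DataFrame:
    """One row per spectrum: metadata plus heights, ratios and FWHM.

    Per-spectrum failures are recorded as missing values rather than
    aborting the table.
    """
    meta_cols = [
        "specimen_id", "individual_id", "age_group", "side", "region", "position",
    ]
    rows = []
    for s in sset:
        row: dict = (
            s.meta.as_dict() if s.meta is not None else {c: None for c in meta_cols}
        )
        try:
            m = spectrum_metrics(s, bands, mode)
        except ValueError:
            m = None
        for w in bands:
            row[f"height_{w.name}"] = (
                m.peaks[w.name].true_height if m is not None else math.nan
            )
        row["ratio_960_1450"] = m.ratio_960_1450 if m else math.nan
        row["ratio_p_c"] = m.ratio_p_c if m else math.nan
        row["ratio_p_a"] = m.ratio_p_a if m else math.nan
        row["fwhm_960"] = m.fwhm_960 if m else math.nan
        rows.append(row)
    columns = meta_cols + [f"height_{w.name}" for w in bands] + [
        "ratio_960_1450", "ratio_p_c", "ratio_p_a", "fwhm_960",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table.astype({c: float for c in columns if c not in meta_cols})


def grouped_summary(
    table: pd.DataFrame,
    keys: list[str] | tuple[str, ...],
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format mean/sd/n summary for any metadata key combination."""
    keys = list(keys)
    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    if table.empty:
        return pd.DataFrame(columns=keys + ["metric", "mean", "sd", "n"])
    out = []
    for group_vals, sub in table.groupby(keys, sort=True):
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        for metric in metrics:
            vals = sub[metric].dropna()
            out.append(
                dict(zip(keys, group_vals))
                | {
                    "metric": metric,
                    "mean": vals.mean() if len(vals) else math.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else math.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(out, columns=keys + ["metric", "mean", "sd", "n"])


def rank_crystal_maturity(
    table: pd.DataFrame, grouping: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Rank groups by mean phosphate FWHM, narrowest (most mature) first.

    Rank 1 is the smallest group-mean FWHM; larger FWHM means less mature
    mineral.  Exact ties share the order of their lexicographic group
    labels and are flagged ``tied``.
    """
    grouping = list(grouping)
    if "fwhm_960" not in table.columns:
        raise ValueError("table has no fwhm_960 column")
    means = (
        table.dropna(subset=["fwhm_960"])
        .groupby(grouping, sort=True)["fwhm_960"]
        .mean()
    )
    if means.empty:
        raise ValueError("all phosphate FWHM values are missing")
    df = means.reset_index().rename(columns={"fwhm_960": "mean_fwhm_960"})
    df = df.sort_values(
        ["mean_fwhm_960"] + grouping, kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    vals = df["mean_fwhm_960"].to_numpy()
    tied = np.zeros(len(df), dtype=bool)
    tied[1:] |= vals[1:] == vals[:-1]
    tied[:-1] |= vals[1:] == vals[:-1]
    df["tied"] = tied
    return df
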