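"""Spectral preprocessing: crop, iterative polynomial baseline, vector norm.

The chain reproduces standard fluorescence removal for bone Raman spectra:

1. crop to the working range (default 594-1704 cm^-1),
2. baseline-correct with an iterative *modified polyfit*: an order-7
   polynomial is least-squares fitted on an axis affinely scaled to [-1, 1];
   points above the fit are replaced by the fit and the fit repeated until
   the baseline stops changing (relative tolerance 1e-6) or 100 iterations.
   Because Raman bands only add intensity above the fluorescence background,
   the clipping step makes the polynomial track the background rather than
   the band envelope.  A plain one-shot least-squares fit through a peaked
   spectrum would overestimate the baseline under every band.
3. vector-normalize: divide by the Euclidean norm over the cropped range.

Negative post-correction intensities are retained (not clipped) so the
normalization stays unbiased.  The whole chain commutes with global
intensity scaling of the raw input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .spectra_io import RamanSpectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "BaselineFit",
    "crop",
    "fit_baseline",
    "fit_baseline_matrix",
    "baseline_correct",
    "vector_normalize",
    "median_despike",
    "preprocess_spectrum",
    "preprocess_set",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``poly_order`` is the degree of the baseline polynomial (order 7 by
    default; configurable in case "polynomial of 7" is read as 7
    coefficients, i.e. degree 6).  ``despike`` enables an optional median
    filter before baseline correction; off by default since the acquisition
    chain modelled here applies none.
    """

    crop_lo: float = 594.0
    crop_hi: float = 1704.0
    poly_order: int = 7
    max_iter: int = 100
    rel_tol: float = 1e-6
    despike: bool = False
    despike_window: int = 5

    def __post_init__(self) -> None:
        if not self.crop_lo < self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")


@dataclass
class BaselineFit:
    """Fitted baseline: coefficients on the scaled axis, values on the grid."""

    coefficients: np.ndarray
    baseline_values: np.ndarray
    iterations_used: int


def crop(s: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Retain points with lo <= wavenumber <= hi (closed interval)."""
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"crop [{lo}, {hi}] does not overlap axis "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return RamanSpectrum(s.wavenumbers[mask], s.intensities[mask], s.meta)


def _scaled_axis(x: np.ndarray) -> np.ndarray:
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("degenerate wavenumber axis (zero span)")
    return 2.0 * (x - x[0]) / span - 1.0


def fit_baseline_matrix(
    x: np.ndarray,
    Y: np.ndarray,
    poly_order: int = 7,
    max_iter: int = 100,
    rel_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterative modified-polyfit baselines for many spectra at once.

    Parameters
    ----------
    x : (n_points,) shared wavenumber axis.
    Y : (n_points, n_spectra) intensities, one spectrum per column.

    Returns ``(baselines, coefficients, iterations)`` with shapes
    (n_points, n_spectra), (poly_order+1, n_spectra) and (n_spectra,).
    Convergence is per column: the fit stops for a spectrum once the
    maximum absolute change of its baseline falls below ``rel_tol`` times
    the baseline's maximum magnitude.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != x.shape[0]:
        raise ValueError("Y must be (n_points, n_spectra)")
    n, m = Y.shape
    if n <= poly_order + 1:
        raise ValueError(
            f"need more than poly_order+1={poly_order + 1} points, got {n}"
        )
    xs = _scaled_axis(x)
    V = np.polynomial.polynomial.polyvander(xs, poly_order)
    Q, R = np.linalg.qr(V)

    work = Y.copy()
    baselines = np.zeros_like(Y)
    coeffs = np.zeros((poly_order + 1, m))
    iterations = np.full(m, max_iter, dtype=int)
    prev = np.zeros_like(Y)
    active = np.arange(m)

    for it in range(1, max_iter + 1):
        C = scipy.linalg.solve_triangular(R, Q.T @ work[:, active])
        B = V @ C
        coeffs[:, active] = C
        baselines[:, active] = B
        if it == 1:
            done = np.zeros(active.size, dtype=bool)
        else:
            delta = np.abs(B - prev[:, active]).max(axis=0)
            scale = np.maximum(np.abs(B).max(axis=0), np.finfo(float).tiny)
            done = delta <= rel_tol * scale
        prev[:, active] = B
        newly = active[done]
        iterations[newly] = it
        active = active[~done]
        if active.size == 0:
            break
        # clip: original intensities above the current fit are replaced by
        # the fit (non-destructive - points recover wherever the fit rises
        # back above them, which avoids burning the first iteration's
        # least-squares lobes into the data)
        work[:, active] = np.minimum(Y[:, active], B[:, ~done])

    return baselines, coeffs, iterations


def fit_baseline(s: RamanSpectrum, cfg: PreprocessConfig) -> BaselineFit:
    """Fit the iterative modified-polyfit baseline of one spectrum."""
    B, C, its = fit_baseline_matrix(
        s.wavenumbers,
        s.intensities[:, None],
        poly_order=cfg.poly_order,
        max_iter=cfg.max_iter,
        rel_tol=cfg.rel_tol,
    )
    return BaselineFit(C[:, 0], B[:, 0], int(its[0]))


def baseline_correct(s: RamanSpectrum, cfg: PreprocessConfig) -> RamanSpectrum:
    """Subtract the fitted baseline; small negatives are retained."""
    fit = fit_baseline(s, cfg)
    return s.with_intensities(s.intensities - fit.baseline_values)


def vector_normalize(s: RamanSpectrum) -> RamanSpectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError(f"cannot normalize zero-norm spectrum {s.label()}")
    return s.with_intensities(s.intensities / norm)


def median_despike(s: RamanSpectrum, window: int = 5) -> RamanSpectrum:
    """Optional cosmic-ray suppression by a running median (odd window)."""
    from scipy.ndimage import median_filter

    if window < 3 or window % 2 == 0:
        raise ValueError("despike window must be odd and >= 3")
    return s.with_intensities(
        median_filter(s.intensities, size=window, mode="nearest")
    )


def preprocess_spectrum(s: RamanSpectrum, cfg: PreprocessConfig | None = None) -> RamanSpectrum:
    """crop -> (optional despike) -> baseline_correct -> vector_normalize."""
    cfg = cfg or PreprocessConfig()
    out = crop(s, cfg.crop_lo, cfg.crop_hi)
    if cfg.despike:
        out = median_despike(out, cfg.despike_window)
    out = baseline_correct(out, cfg)
    return vector_normalize(out)


def preprocess_set(
    sset: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    return_qc: bool = False,
):
    """Preprocess every spectrum of a set (shared axis, vectorized fit).

    With ``return_qc=True`` also returns a QC table (one row per spectrum:
    baseline iterations used and residual norm before normalization).
    """
    import pandas as pd

    cfg = cfg or PreprocessConfig()
    if len(sset) == 0:
        return (SpectrumSet([]), pd.DataFrame()) if return_qc else SpectrumSet([])

    axis = sset.axis
    mask = (axis >= cfg.crop_lo) & (axis <= cfg.crop_hi)
    if not mask.any():
        raise ValueError("crop range does not overlap the shared axis")
    axis_c = axis[mask]
    Y = sset.intensity_matrix()[:, mask].T  # (n_points, n_spectra)
    if cfg.despike:
        from scipy.ndimage import median_filter

        Y = median_filter(Y, size=(cfg.despike_window, 1), mode="nearest")
    B, _, its = fit_baseline_matrix(
        axis_c, Y, cfg.poly_order, cfg.max_iter, cfg.rel_tol
    )
    corrected = Y - B
    norms = np.linalg.norm(corrected, axis=0)
    bad = np.flatnonzero((norms == 0) | ~np.isfinite(norms))
    if bad.size:
        raise ValueError(
            f"cannot normalize zero-norm spectrum {sset[int(bad[0])].label()}"
        )
    normalized = (corrected / norms).T
    out = sset.with_matrix(axis_c, normalized)
    if not return_qc:
        return out
    qc_rows = []
    for i, s in enumerate(sset):
        row = s.meta.as_dict() if s.meta is not None else {"index": i}
        row["baseline_iterations"] = int(its[i])
        row["residual_norm"] = float(norms[i])
        qc_rows.append(row)
    return out, pd.DataFrame(qc_rows)
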