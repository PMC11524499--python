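"""PCA-LDA chemometrics: scores, wavenumber loadings, band attribution.

Spectra are first reduced by principal component analysis (mean-centered,
no variance scaling; default 10 retained components) and linear
discriminant analysis is then fitted in the retained PC space by solving
the generalized eigenproblem of between-class versus pooled within-class
scatter,

    S_b v = lambda (S_w + eps I) v,

with a small ridge eps = 1e-8 * trace(S_w)/p stabilizing near-singular
within-class scatter.  C classes yield C-1 discriminant directions
(LD1, LD2, ...), ordered by eigenvalue.  Each discriminant is mapped back
to wavenumber space through the PC loadings; the sign convention (the
maximum-|coefficient| of each wavenumber loading is positive) makes
results reproducible across eigen-solvers.  Band attribution scores each
band window by the maximum absolute loading inside it, ranking which
chemistry drives the class separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import PCA

from .band_metrics import BandWindow, DEFAULT_BANDS
from .spectra_io import SpectrumSet

__all__ = [
    "PcaModel",
    "LdaModel",
    "PcaLdaResult",
    "AttributionResult",
    "pca_fit",
    "lda_fit",
    "pca_lda",
    "attribute_loadings",
    "ld1_density",
]


@dataclass
class PcaModel:
    """Mean spectrum plus orthonormal component loadings in wavenumber space."""

    mean_: np.ndarray
    components_: np.ndarray  # (n_retained, n_features)
    explained_variance_: np.ndarray
    n_retained: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, T: np.ndarray) -> np.ndarray:
        return np.asarray(T, dtype=float) @ self.components_ + self.mean_


def pca_fit(
    X: np.ndarray,
    n_components: int | None = 10,
    variance_fraction: float | None = None,
) -> PcaModel:
    """Mean-centered PCA of a spectra matrix (rows = spectra).

    Retention policy: ``n_components`` fixed (default 10, capped at
    n_samples - 1) or, when ``variance_fraction`` is given, the smallest
    count whose cumulative explained-variance ratio reaches it.
    ``n_components=None`` retains everything up to the cap.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 spectra to fit a PCA")
    cap = min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=cap, svd_solver="full").fit(X)
    if variance_fraction is not None:
        if not 0 < variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        cum = np.cumsum(model.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
        k = min(k, cap)
    else:
        k = cap if n_components is None else min(int(n_components), cap)
    return PcaModel(
        mean_=model.mean_,
        components_=model.components_[:k],
        explained_variance_=model.explained_variance_[:k],
        n_retained=k,
    )


@dataclass
class LdaModel:
    """Discriminant directions in PC space, ordered by eigenvalue."""

    classes: np.ndarray
    directions: np.ndarray  # (n_dims, n_discriminants), unit columns
    eigenvalues: np.ndarray
    ridge: float


def lda_fit(
    scores: np.ndarray, labels, ridge_scale: float = 1e-8
) -> LdaModel:
    """LDA via the between/within generalized eigenproblem.

    Requires >= 2 classes, each with >= 2 members (a singleton class has
    no within-class spread and is reported by name).  The within-class
    scatter is stabilized with ``ridge_scale * trace(S_w)/p * I``.
    """
    T = np.asarray(scores, dtype=float)
    if T.ndim != 2:
        raise ValueError("scores must be a 2-D matrix")
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    counts = np.bincount(y)
    small = classes[counts < 2]
    if small.size:
        raise ValueError(
            f"class {small[0]!r} has fewer than 2 members ({counts[counts < 2][0]})"
        )
    p = T.shape[1]
    mu = T.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in range(classes.size):
        Tc = T[y == c]
        mc = Tc.mean(axis=0)
        D = Tc - mc
        Sw += D.T @ D
        d = mc - mu
        Sb += Tc.shape[0] * np.outer(d, d)
    eps = ridge_scale * np.trace(Sw) / p
    if eps <= 0:
        eps = ridge_scale
    w, V = scipy.linalg.eigh(Sb, Sw + eps * np.eye(p))
    order = np.argsort(w)[::-1]
    k = min(classes.size - 1, p)
    keep = order[:k]
    directions = V[:, keep]
    directions = directions / np.linalg.norm(directions, axis=0)
    return LdaModel(
        classes=classes,
        directions=directions,
        eigenvalues=w[keep],
        ridge=float(eps),
    )


@dataclass
class AttributionResult:
    """Per-LD band ranking; LDs with all-zero loadings are flagged degenerate."""

    table: pd.DataFrame
    degenerate: list[str]


@dataclass
class PcaLdaResult:
    pca: PcaModel
    lda: LdaModel
    scores: pd.DataFrame  # metadata + label + LD1..LDk
    loadings: pd.DataFrame  # wavenumber + LD1..LDk
    class_means: pd.DataFrame
    attribution: AttributionResult


def _resolve_labels(sset: SpectrumSet, label_key) -> np.ndarray:
    if callable(label_key):
        return np.asarray([str(label_key(s.meta)) for s in sset])
    if isinstance(label_key, str):
        meta = sset.metadata_frame()
        if label_key not in meta.columns:
            raise KeyError(f"metadata has no key {label_key!r}")
        return meta[label_key].astype(str).to_numpy()
    labels = np.asarray(label_key)
    if labels.shape[0] != len(sset):
        raise ValueError("label array length does not match set size")
    return labels.astype(str)


def pca_lda(
    sset: SpectrumSet,
    label_key,
    n_components: int | None = 10,
    variance_fraction: float | None = None,
    bands: tuple[BandWindow, ...] = DEFAULT_BANDS,
) -> PcaLdaResult:
    """Fit PCA then LDA on a preprocessed set and map loadings back.

    ``label_key`` is a metadata key, a callable ``meta -> str``, or an
    explicit label array.  Wavenumber-space loadings are the PC loadings
    composed with the discriminant directions, sign-fixed so the largest
    |coefficient| of each LD is positive; scores and class means follow
    the same sign convention.
    """
    labels = _resolve_labels(sset, label_key)
    X = sset.intensity_matrix()
    pca = pca_fit(X, n_components=n_components, variance_fraction=variance_fraction)
    T = pca.transform(X)
    lda = lda_fit(T, labels)

    W = pca.components_.T @ lda.directions  # (n_wavenumbers, k)
    flip = np.ones(W.shape[1])
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            flip[j] = -1.0
    W = W * flip
    directions = lda.directions * flip
    lda = LdaModel(lda.classes, directions, lda.eigenvalues, lda.ridge)

    S = T @ directions
    ld_cols = [f"LD{j + 1}" for j in range(S.shape[1])]
    try:
        scores = sset.metadata_frame()
    except ValueError:
        scores = pd.DataFrame(index=range(len(sset)))
    scores = scores.copy()
    scores["label"] = labels
    for j, col in enumerate(ld_cols):
        scores[col] = S[:, j]

    loadings = pd.DataFrame({"wavenumber_cm1": sset.axis})
    for j, col in enumerate(ld_cols):
        loadings[col] = W[:, j]

    means = scores.groupby("label", sort=True)[ld_cols].mean().reset_index()
    attribution = attribute_loadings(loadings, bands)
    return PcaLdaResult(pca, lda, scores, loadings, means, attribution)


def attribute_loadings(
    loadings: pd.DataFrame, bands: tuple[BandWindow, ...] = DEFAULT_BANDS
) -> AttributionResult:
    """Rank bands per LD by the maximum |loading| inside each band window.

    An LD whose loading is numerically zero everywhere yields no ranking
    rows and is listed in ``degenerate``.
    """
    x = loadings["wavenumber_cm1"].to_numpy()
    ld_cols = [c for c in loadings.columns if c.startswith("LD")]
    rows = []
    degenerate = []
    for col in ld_cols:
        v = loadings[col].to_numpy()
        if np.max(np.abs(v)) < 1e-12:
            degenerate.append(col)
            continue
        scored = []
        for b in bands:
            m = (x >= b.lo) & (x <= b.hi)
            score = float(np.max(np.abs(v[m]))) if m.any() else np.nan
            scored.append((b.name, score))
        scored.sort(key=lambda t: (-(t[1] if np.isfinite(t[1]) else -np.inf), t[0]))
        for rank, (name, score) in enumerate(scored, start=1):
            rows.append({"ld": col, "band": name, "score": score, "rank": rank})
    table = pd.DataFrame(rows, columns=["ld", "band", "score", "rank"])
    return AttributionResult(table, degenerate)


def ld1_density(
    scores: pd.DataFrame, n_points: int = 256
) -> pd.DataFrame:
    """Per-class Gaussian KDE of LD1 (Silverman bandwidth) for 1D scores plots."""
    from scipy.stats import gaussian_kde

    lo = scores["LD1"].min()
    hi = scores["LD1"].max()
    pad = 0.1 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_points)
    out = {"LD1": grid}
    for label, sub in scores.groupby("label", sort=True):
        vals = sub["LD1"].to_numpy()
        if len(vals) < 2 or np.ptp(vals) == 0:
            out[str(label)] = np.full(n_points, np.nan)
            continue
        kde = gaussian_kde(vals, bw_method="silverman")
        out[str(label)] = kde(grid)
    return pd.DataFrame(out)
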