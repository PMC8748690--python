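"""Boolean marker-combination features, the transform chain and PCA scoring.

Feature values are percentages of gated cells positive for every marker in an
AND-combination.  The transform chain is arcsine-square-root on percentages
(as fractions), log10 on tumor volumes, then per-column standardization to
zero mean / unit sample SD, so the subsequent PCA is on the correlation scale.
Variable cos2 is the squared variable coordinate (loading * sqrt(eigenvalue));
contributions are cos2 normalized to 100 per component.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("spherotil")

VOLUME_FEATURE = "tumor_volume"


@dataclass
class MarkerMatrix:
    """Per-cell boolean marker positivity for one sample (mouse)."""

    sample_id: str
    group: str
    positivity: np.ndarray         # (n_cells, n_markers) bool
    marker_names: list[str]
    lineage: str = "CD8"
    tumor_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        self.positivity = np.asarray(self.positivity, dtype=bool)
        if self.positivity.ndim != 2:
            raise ValueError("positivity must be (cells, markers)")
        if self.positivity.shape[1] != len(self.marker_names):
            raise ValueError("marker_names must match positivity columns")
        if self.positivity.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id}: empty lineage gate")


def all_and_subsets(marker_names: list[str]) -> list[tuple[str, ...]]:
    """All non-empty AND-subsets of the markers (2^m - 1 combinations)."""
    out = []
    for k in range(1, len(marker_names) + 1):
        out.extend(itertools.combinations(marker_names, k))
    return out


def combo_percentages(matrices: list[MarkerMatrix],
                      combo_spec: list[tuple[str, ...]] | None = None,
                      include_volume: bool = True) -> pd.DataFrame:
    """Percentage of gated cells positive for every marker of each combination.

    Rows = samples; columns = combination features (named ``A&B&...``), plus
    the tumor-volume column when available, plus a ``group`` label column.
    """
    if not matrices:
        raise ValueError("no samples")
    names = matrices[0].marker_names
    for m in matrices:
        if m.marker_names != names:
            raise ValueError("marker set must be consistent across samples")
    if combo_spec is None:
        combo_spec = all_and_subsets(names)
    logger.info("combination feature count: %d", len(combo_spec))
    col_idx = {nm: i for i, nm in enumerate(names)}
    rows = {}
    for m in matrices:
        vals = {}
        for combo in combo_spec:
            mask = np.ones(m.positivity.shape[0], dtype=bool)
            for nm in combo:
                mask &= m.positivity[:, col_idx[nm]]
            vals["&".join(combo)] = 100.0 * mask.mean()
        if include_volume and m.tumor_volume_mm3 is not None:
            vals[VOLUME_FEATURE] = m.tumor_volume_mm3
        vals["group"] = m.group
        rows[m.sample_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


def transform_features(table: pd.DataFrame) -> pd.DataFrame:
    """Arcsine-sqrt percentages (as fractions of 1) and log10 tumor volume."""
    out = table.copy()
    for col in out.columns:
        if col == "group":
            continue
        x = out[col].to_numpy(dtype=float)
        if col == VOLUME_FEATURE:
            if np.any(x <= 0):
                raise ValueError("tumor volumes must be positive for log10")
            out[col] = np.log10(x)
        else:
            if np.any((x < 0) | (x > 100)):
                raise ValueError(f"column {col!r} has percentages outside [0, 100]")
            out[col] = np.arcsin(np.sqrt(x / 100.0))
    return out


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores with sample SD (ddof=1); constant columns dropped."""
    out = {}
    for col in table.columns:
        if col == "group":
            out[col] = table[col]
            continue
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd == 0:
            logger.warning("dropping constant column %r", col)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


@dataclass
class PCAModel:
    eigenvalues: np.ndarray            # descending
    loadings: np.ndarray               # (n_vars, n_pcs), orthonormal columns
    scores: pd.DataFrame               # (n_samples, n_pcs), + group column
    variable_names: list[str]
    retained: list[int]                # 0-based PC indices with eigenvalue > 1
    coordinates: np.ndarray            # loading * sqrt(eigenvalue)
    cos2: np.ndarray                   # coordinates**2
    contributions: np.ndarray          # 100 * cos2 / column sum

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def fit_pca(table: pd.DataFrame, eigenvalue_cut: float = 1.0) -> PCAModel:
    """Correlation-scale PCA of a standardized feature table.

    Eigendecomposition of the sample covariance of the standardized columns
    (the correlation matrix of the originals).  Retained components have
    eigenvalue > ``eigenvalue_cut``.
    """
    groups = table["group"] if "group" in table.columns else None
    x = table.drop(columns=["group"], errors="ignore")
    names = list(x.columns)
    mat = x.to_numpy(dtype=float)
    n, p = mat.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 samples and >= 2 variables")
    cov = np.cov(mat, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    scores = mat @ evecs
    coords = evecs * np.sqrt(evals)[None, :]
    cos2 = coords**2
    colsum = cos2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(colsum > 0, 100.0 * cos2 / colsum, 0.0)
    score_df = pd.DataFrame(
        scores, index=table.index,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])])
    if groups is not None:
        score_df["group"] = groups
    return PCAModel(
        eigenvalues=evals, loadings=evecs, scores=score_df,
        variable_names=names,
        retained=[k for k, ev in enumerate(evals) if ev > eigenvalue_cut],
        coordinates=coords, cos2=cos2, contributions=contrib,
    )


@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray     # descending
    angle_rad: float          # orientation of the major axis

    def contains(self, pts: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(pts) - self.center
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        q = rel @ rot.T
        return (q[:, 0] / self.semi_axes[0])**2 + (q[:, 1] / self.semi_axes[1])**2 <= 1.0


def group_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> Ellipse:
    """Covariance confidence ellipse of 2D scores.

    Semi-axes = sqrt(chi2 quantile at ``level`` (2 df) * covariance
    eigenvalues), oriented along the covariance eigenvectors (population-
    covariance construction, as in common factor-map implementations).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) score array")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    return Ellipse(center=center,
                   semi_axes=np.sqrt(q * np.clip(evals, 0, None)),
                   angle_rad=float(np.arctan2(evecs[1, 0], evecs[0, 0])))


def run_pca_pipeline(matrices: list[MarkerMatrix],
                     combo_spec: list[tuple[str, ...]] | None = None,
                     eigenvalue_cut: float = 1.0) -> PCAModel:
    """combo -> transform -> standardize -> fit, deterministically."""
    table = combo_percentages(matrices, combo_spec)
    return fit_pca(standardize(transform_features(table)), eigenvalue_cut)
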