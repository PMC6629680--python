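"""Unsupervised structure and clinical-marker correlation screens."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .matrix import AdjustedMatrix, ValidationError

__all__ = [
    "PcaResult",
    "pca_project",
    "ward_cluster_order",
    "marker_correlations",
    "DEFAULT_MARKERS",
]

DEFAULT_MARKERS = ("ca19_9", "albumin", "bilirubin")


@dataclass
class PcaResult:
    """Principal component projection of the adjusted sample matrix."""

    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # molecules x components, orthonormal
    explained_variance_ratio: np.ndarray  # descending


def pca_project(adj: AdjustedMatrix, n_components: int = 2) -> PcaResult:
    """SVD-based PCA of the centered samples x molecules matrix.

    Sign convention: within each component the largest-magnitude
    loading is made positive, so projections are reproducible across
    runs and platforms.
    """
    X = adj.samples_by_molecules().to_numpy(dtype=float)
    n, m = X.shape
    if n_components > n:
        raise ValidationError("more components requested than samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = S**2 / (S**2).sum()
    for comp in range(min(n_components, Vt.shape[0])):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U[:, :n_components] * S[:n_components]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=adj.samples, columns=comp_names),
        loadings=pd.DataFrame(
            Vt[:n_components].T, index=adj.molecules, columns=comp_names
        ),
        explained_variance_ratio=evr[:n_components],
    )


def ward_cluster_order(adj: AdjustedMatrix) -> dict:
    """Ward/Euclidean agglomerative ordering in both dimensions.

    Returns leaf orders (for heatmap rendering) and the raw linkage
    matrices for dendrogram drawing.
    """
    arr = adj.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("matrix contains non-finite entries")
    link_molecules = linkage(arr, method="ward", metric="euclidean")
    link_samples = linkage(arr.T, method="ward", metric="euclidean")
    return {
        "molecule_order": adj.molecules[leaves_list(link_molecules)],
        "sample_order": adj.samples[leaves_list(link_samples)],
        "molecule_linkage": link_molecules,
        "sample_linkage": link_samples,
    }


def marker_correlations(
    adj: AdjustedMatrix,
    clinical: pd.DataFrame,
    markers=DEFAULT_MARKERS,
    r_threshold: float = 0.6,
    q_threshold: float = 0.05,
    min_observations: int = 5,
) -> pd.DataFrame:
    """Pearson screen of every molecule against clinical blood markers.

    P-values are Benjamini-Hochberg adjusted across the full molecule x
    marker grid.  A hit requires ``|r| > r_threshold`` and adjusted
    ``p <= q_threshold`` (the absolute value matters: negative
    correlations count as findings).  Constant markers are excluded
    with a warning; markers need at least ``min_observations``
    non-missing values.
    """
    rows = []
    data = adj.samples_by_molecules()
    for marker in markers:
        if marker not in clinical.columns:
            raise ValidationError(f"marker {marker!r} not in clinical table")
        mvals = clinical.loc[data.index, marker].astype(float)
        ok = mvals.notna()
        if ok.sum() < min_observations:
            raise ValidationError(
                f"marker {marker!r} has fewer than {min_observations} values"
            )
        if np.isclose(mvals[ok].std(ddof=1), 0.0):
            warnings.warn(
                f"marker {marker!r} is constant; correlation undefined, skipped",
                stacklevel=2,
            )
            continue
        x = mvals[ok].to_numpy()
        for mol in data.columns:
            yv = data.loc[ok, mol].to_numpy(dtype=float)
            r, p = stats.pearsonr(x, yv)
            rows.append(
                {
                    "molecule": mol,
                    "class": adj.classes.get(mol),
                    "marker": marker,
                    "r": float(r),
                    "p": float(p),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    _, q, _, _ = multipletests(result["p"], method="fdr_bh")
    result["q"] = np.maximum(q, result["p"])  # adjusted p never below raw p
    result["direction"] = np.where(result["r"] >= 0, "positive", "negative")
    result["hit"] = (result["r"].abs() > r_threshold) & (
        result["q"] <= q_threshold
    )
    return result
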