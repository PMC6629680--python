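"""Raw concentration tables -> analysis-ready complete log matrix.

Three stages, applied in order: natural-log transform, the modified 80%
missingness filter (a molecule is discarded only when more than 80% of
its values are missing in *every* clinical group), and QRILC-style
left-censored imputation, which estimates each molecule's complete-data
normal parameters from the observed upper order statistics and draws
the missing tail from the correspondingly truncated normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ConcentrationMatrix, ValidationError, validate_clinical

__all__ = [
    "PreprocessedMatrix",
    "log_transform",
    "modified_80_rule",
    "qrilc_impute",
    "preprocess_pipeline",
]


@dataclass
class PreprocessedMatrix:
    """Complete log-scale matrix with provenance of what was filled in."""

    values: pd.DataFrame            # molecules x samples, no NaN
    classes: pd.Series
    imputed_mask: pd.DataFrame      # True where a value was imputed
    dropped_molecules: pd.DataFrame  # molecule, per-group fractions, reason
    per_molecule_min_observed: pd.Series

    @property
    def molecules(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_by_molecules(self) -> pd.DataFrame:
        return self.values.T


def log_transform(raw: ConcentrationMatrix) -> ConcentrationMatrix:
    """Elementwise natural log of the observed entries.

    Missing entries stay missing.  Non-positive observed values are a
    data error and are reported with molecule and sample coordinates.
    """
    if raw.log_scale:
        raise ValidationError("matrix is already on the log scale")
    arr = raw.values.to_numpy(dtype=float)
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            "non-positive concentration for molecule "
            f"{raw.molecules[i]!r} in sample {raw.samples[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        logged = np.log(arr)
    return ConcentrationMatrix(
        values=pd.DataFrame(logged, index=raw.molecules, columns=raw.samples),
        classes=raw.classes,
        log_scale=True,
    )


def missing_fractions(
    mat: ConcentrationMatrix, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Per molecule x clinical group fraction of missing values."""
    clinical = validate_clinical(clinical, mat.samples)
    mask = mat.missing_mask
    out = {}
    for group, sub in clinical.groupby("group", sort=False):
        out[group] = mask[sub.index].mean(axis=1)
    return pd.DataFrame(out)


def modified_80_rule(
    mat: ConcentrationMatrix, clinical: pd.DataFrame
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Drop molecules missing in more than 80% of samples of every group.

    The comparison is strict: a molecule sitting exactly at 0.8 in each
    group is retained.  Returns the filtered matrix (row order
    preserved) and a report of the dropped molecules with their
    per-group missing fractions.
    """
    fracs = missing_fractions(mat, clinical)
    drop = (fracs > 0.8).all(axis=1)
    report = fracs[drop].copy()
    report["reason"] = "missing fraction > 0.8 in all groups"
    retained = mat.subset_molecules(mat.molecules[~drop.to_numpy()])
    return retained, report


def _qrilc_estimate(observed: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate complete-data normal (mean, sd) from observed order stats.

    The missing values are assumed to occupy the lowest ranks of the
    full sample of size ``n_total``; the sorted observed values are
    regressed on the standard-normal quantiles of their full-sample
    plotting positions (i - 0.5)/n_total.  Slope and intercept of that
    censored normal probability plot recover sd and mean.
    """
    srt = np.sort(observed)
    n_obs = srt.size
    n_mis = n_total - n_obs
    ranks = np.arange(n_mis + 1, n_total + 1)
    probs = (ranks - 0.5) / n_total
    z = stats.norm.ppf(probs)
    slope, intercept, *_ = stats.linregress(z, srt)
    if slope <= 0:  # degenerate (e.g. constant observed values)
        slope = max(np.std(srt, ddof=1), 1e-12)
    return float(intercept), float(slope)


def qrilc_impute(
    mat: ConcentrationMatrix, seed: int | None = None
) -> PreprocessedMatrix:
    """Impute left-censored missing values, molecule by molecule.

    Each missing entry is drawn from ``N(mean_j, sd_j)`` truncated above
    at the molecule's minimum observed value, with ``(mean_j, sd_j)``
    the censored probability-plot estimates of the complete-data
    distribution.  Deterministic given ``seed``.
    """
    if not mat.log_scale:
        raise ValidationError("qrilc_impute expects a log-scale matrix")
    arr = mat.values.to_numpy(dtype=float).copy()
    mask = np.isnan(arr)
    n_total = arr.shape[1]
    rng = np.random.default_rng(seed)
    min_obs = np.full(arr.shape[0], np.nan)
    for i in range(arr.shape[0]):
        row_mask = mask[i]
        observed = arr[i, ~row_mask]
        if observed.size < 3:
            raise ValidationError(
                f"molecule {mat.molecules[i]!r} has fewer than 3 observed "
                "values; apply a stricter missingness filter first"
            )
        min_obs[i] = observed.min()
        n_mis = int(row_mask.sum())
        if n_mis == 0:
            continue
        mean, sd = _qrilc_estimate(observed, n_total)
        upper = (min_obs[i] - mean) / sd
        draws = stats.truncnorm.rvs(
            -np.inf, upper, loc=mean, scale=sd, size=n_mis, random_state=rng
        )
        # Guard against numerically hitting the bound exactly.
        draws = np.minimum(draws, np.nextafter(min_obs[i], -np.inf))
        arr[i, row_mask] = draws
    values = pd.DataFrame(arr, index=mat.molecules, columns=mat.samples)
    return PreprocessedMatrix(
        values=values,
        classes=mat.classes,
        imputed_mask=pd.DataFrame(
            mask, index=mat.molecules, columns=mat.samples
        ),
        dropped_molecules=pd.DataFrame(),
        per_molecule_min_observed=pd.Series(
            min_obs, index=mat.molecules, name="min_observed"
        ),
    )


def preprocess_pipeline(
    raw: ConcentrationMatrix,
    clinical: pd.DataFrame,
    seed: int | None = None,
) -> PreprocessedMatrix:
    """log -> modified 80% rule -> QRILC, as one call."""
    logged = log_transform(raw)
    retained, report = modified_80_rule(logged, clinical)
    pre = qrilc_impute(retained, seed=seed)
    pre.dropped_molecules = report
    return pre
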