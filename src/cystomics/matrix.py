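"""Core in-memory containers for concentration and clinical data.

File convention is molecules-as-rows (the usual omics layout); the
modelling and classification code works samples-as-rows and converts
explicitly via :meth:`ConcentrationMatrix.samples_by_molecules`.
Missing measurements are encoded as ``NaN`` inside ``values``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationMatrix",
    "AdjustedMatrix",
    "ValidationError",
    "validate_clinical",
]

#: Clinical covariate columns that downstream stages may rely on.
GROUP_COLUMN = "group"
FLUID_COLUMN = "fluid"


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class ConcentrationMatrix:
    """Molecules x samples concentration table with class annotations.

    Parameters
    ----------
    values
        DataFrame indexed by molecule ID with sample IDs as columns.
        ``NaN`` entries denote missing (below detection) measurements.
    classes
        Series mapping molecule ID to its lipid/metabolite class label.
    log_scale
        Whether ``values`` are natural-log concentrations.
    """

    values: pd.DataFrame
    classes: pd.Series
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate molecule IDs: {dups}")
        self.classes = self.classes.reindex(self.values.index)

    @property
    def molecules(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a measurement is missing."""
        return self.values.isna()

    def samples_by_molecules(self) -> pd.DataFrame:
        """Analysis orientation: samples as rows, molecules as columns."""
        return self.values.T

    def subset_molecules(self, keep) -> "ConcentrationMatrix":
        return replace(
            self, values=self.values.loc[keep], classes=self.classes.loc[keep]
        )

    def subset_samples(self, keep) -> "ConcentrationMatrix":
        return replace(self, values=self.values[list(keep)])


@dataclass
class AdjustedMatrix:
    """Confounder-adjusted, per-molecule standardized log concentrations.

    ``values`` stays molecules x samples; every row has sample mean 0 and
    unit variance.  ``gamma_means`` records the posterior-mean covariate
    slopes that were subtracted, keyed by covariate name.
    """

    values: pd.DataFrame
    classes: pd.Series
    gamma_means: dict = field(default_factory=dict)

    @property
    def molecules(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_by_molecules(self) -> pd.DataFrame:
        return self.values.T


def validate_clinical(
    clinical: pd.DataFrame,
    samples=None,
    require: tuple[str, ...] = (GROUP_COLUMN,),
) -> pd.DataFrame:
    """Check a clinical covariate table against the sample set.

    Raises
    ------
    ValidationError
        If required columns are absent, a sample is missing from the
        table, or a sample lacks a group label.
    """
    for col in require:
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks required column {col!r}")
    if samples is not None:
        missing = [s for s in samples if s not in clinical.index]
        if missing:
            raise ValidationError(f"samples absent from clinical table: {missing}")
        clinical = clinical.loc[list(samples)]
    if GROUP_COLUMN in require:
        unlabeled = clinical.index[clinical[GROUP_COLUMN].isna()].tolist()
        if unlabeled:
            raise ValidationError(f"samples without group label: {unlabeled}")
    return clinical


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, unit (ddof=1) variance."""
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = values.index[np.ravel(sd == 0)].tolist()
        raise ValidationError(f"constant molecules cannot be standardized: {bad}")
    return pd.DataFrame(
        (arr - mu) / sd, index=values.index, columns=values.columns
    )
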