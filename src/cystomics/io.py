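"""Reading and writing of the pipeline's table formats.

Concentration matrices travel as CSV with molecules as rows: the first
two columns are ``molecule`` and ``class``, the remaining header cells
are sample IDs, and empty cells or ``NA`` denote missing values.
Everything else is plain CSV/TSV with documented headers.  Posterior
draws are persisted as an ``.npz`` archive (a runtime artifact, not a
deliverable format).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cppls import ClassificationReport, VipRanking
from .hierarchical import FoldChangeTable, ModelSpec, PosteriorDraws
from .matrix import ConcentrationMatrix, ValidationError

__all__ = [
    "read_concentration_csv",
    "write_concentration_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "write_fold_change_tsv",
    "read_fold_change_tsv",
    "write_classification_tsv",
    "write_vip_tsv",
    "write_filter_report_tsv",
    "save_draws",
    "load_draws",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}
FLOAT_FORMAT = "%.10g"


def read_concentration_csv(path) -> ConcentrationMatrix:
    """Parse a molecules x samples concentration CSV.

    Errors carry the 1-based line number of the offending row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "molecule" or header[1] != "class":
            raise ValidationError(
                f"{path}: header must start with 'molecule,class' followed "
                "by sample IDs"
            )
        samples = header[2:]
        ids, classes, rows = [], [], []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} cells, "
                    f"got {len(row)}"
                )
            mol = row[0]
            if mol in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate molecule ID {mol!r}"
                )
            seen.add(mol)
            vals = []
            for cell in row[2:]:
                cell = cell.strip()
                if cell in _MISSING_TOKENS:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric cell {cell!r}"
                    ) from None
            ids.append(mol)
            classes.append(row[1])
            rows.append(vals)
    values = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    values.index.name = "molecule"
    return ConcentrationMatrix(
        values=values,
        classes=pd.Series(classes, index=ids, name="class"),
    )


def write_concentration_csv(mat, path, classes: pd.Series | None = None) -> None:
    """Inverse of :func:`read_concentration_csv`; NaN becomes ``NA``."""
    values = mat.values if hasattr(mat, "values") else mat
    if classes is None:
        classes = getattr(mat, "classes", None)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule", "class"] + list(values.columns))
        for mol, row in values.iterrows():
            cls = "" if classes is None else str(classes.get(mol, ""))
            cells = [
                "NA" if pd.isna(v) else FLOAT_FORMAT % v for v in row.to_numpy()
            ]
            writer.writerow([mol, cls] + cells)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    return df


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format=FLOAT_FORMAT)


def write_fold_change_tsv(fct: FoldChangeTable, path) -> None:
    """TSV: molecule, [class,] fc, lo95, hi95, significant."""
    out = fct.table.copy()
    out.index.name = "molecule"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_fold_change_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="molecule")


def write_classification_tsv(report: ClassificationReport, path) -> None:
    report.per_task.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_vip_tsv(ranking: VipRanking, path) -> None:
    out = ranking.table.copy()
    out.index.name = "molecule"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_filter_report_tsv(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out.index.name = "molecule"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_truth_json(cohort, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(cohort.truth_dict(), fh, indent=1)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws to an npz archive (runtime artifact)."""
    np.savez_compressed(
        path,
        theta=draws.theta,
        phi=draws.phi,
        lam=draws.lam,
        eta=draws.eta,
        gamma=draws.gamma,
        sigma=draws.sigma,
        alpha=draws.alpha,
        beta=draws.beta,
        zeta=draws.zeta,
        omega=draws.omega,
        groups=np.array(draws.spec.groups),
        covariates=np.array(draws.spec.covariates),
        molecules=np.array(draws.molecules, dtype=str),
        samples=np.array(draws.samples, dtype=str),
        n_chains=draws.n_chains,
        cov_means=draws.cov_means,
        cov_sds=draws.cov_sds,
    )


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec(
            groups=tuple(z["groups"]), covariates=tuple(z["covariates"])
        )
        return PosteriorDraws(
            theta=z["theta"],
            phi=z["phi"],
            lam=z["lam"],
            eta=z["eta"],
            gamma=z["gamma"],
            sigma=z["sigma"],
            alpha=z["alpha"],
            beta=z["beta"],
            zeta=z["zeta"],
            omega=z["omega"],
            spec=spec,
            molecules=pd.Index(z["molecules"]),
            samples=pd.Index(z["samples"]),
            n_chains=int(z["n_chains"]),
            cov_means=z["cov_means"],
            cov_sds=z["cov_sds"],
        )
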