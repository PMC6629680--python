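"""Synthetic cyst-fluid/plasma cohort generation.

Runs the hierarchical lognormal model forward: log-concentrations are a
grand mean plus sample, molecule, group-by-molecule and covariate
effects with Gaussian noise, exponentiated to the natural muM/L scale,
and finally censored from the left (MNAR) so the imputation and
filtering stages have realistic work to do.  Clinical covariates are
drawn uniformly within per-group ranges typical of pancreatic-cyst
resection cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ConcentrationMatrix, ValidationError

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "apply_censoring",
    "default_class_composition",
    "contrast_effect_table",
]

DEFAULT_GROUPS = ("SCN", "LGD", "HGD", "Cancer")

# Per-group clinical ranges (min, max) for continuous covariates and
# prevalences for binary ones.  Unknown (e.g. merged) group labels fall
# back to the pooled envelope.
_AGE_RANGE = {
    "SCN": (34.0, 58.0),
    "LGD": (56.0, 81.0),
    "HGD": (66.0, 75.0),
    "Cancer": (46.0, 83.0),
}
_BMI_RANGE = {
    "SCN": (24.1, 32.0),
    "LGD": (21.8, 36.6),
    "HGD": (23.4, 28.3),
    "Cancer": (20.2, 29.7),
}
_CA19_9_RANGE = {
    "SCN": (6.8, 62.0),
    "LGD": (6.4, 182.0),
    "HGD": (0.5, 115.0),
    "Cancer": (0.5, 1040.0),
}
_ALBUMIN_RANGE = {
    "SCN": (33.0, 39.0),
    "LGD": (26.0, 38.0),
    "HGD": (22.0, 39.0),
    "Cancer": (19.0, 38.0),
}
_BILIRUBIN_RANGE = {
    "SCN": (3.0, 18.0),
    "LGD": (1.5, 13.0),
    "HGD": (1.5, 315.0),
    "Cancer": (5.0, 150.0),
}
_FEMALE_FRAC = {"SCN": 1.0, "LGD": 0.50, "HGD": 0.429, "Cancer": 0.273}
_STATIN_FRAC = {"SCN": 0.20, "LGD": 0.125, "HGD": 0.143, "Cancer": 0.091}
_DIABETES_FRAC = {"SCN": 0.0, "LGD": 0.125, "HGD": 0.429, "Cancer": 0.364}

_DEFAULT_CLASSES = (
    "TAG", "FFA", "CER", "PC", "PE", "SM", "LPC", "LPE", "CE", "DAG",
    "amino acid", "organic acid",
)


def _range_for(table: dict, group: str) -> tuple[float, float]:
    if group in table:
        return table[group]
    los, his = zip(*table.values())
    return min(los), max(his)


def default_class_composition(m_molecules: int) -> dict[str, int]:
    """Spread ``m_molecules`` across the default class panel.

    Classes are filled round-robin so every class present gets at least
    one molecule when ``m_molecules >= len(classes)``.
    """
    comp: dict[str, int] = {}
    n_classes = len(_DEFAULT_CLASSES)
    base, extra = divmod(m_molecules, n_classes)
    for idx, cls in enumerate(_DEFAULT_CLASSES):
        count = base + (1 if idx < extra else 0)
        if count:
            comp[cls] = count
    return comp


def contrast_effect_table(
    groups: tuple[str, ...],
    m_molecules: int,
    contrasts: dict[int, tuple[str, str, float]] | None = None,
) -> np.ndarray:
    """Build a (k, m) group-by-molecule effect table with given contrasts.

    ``contrasts[j] = (g, h, delta)`` requests ``eta[g, j] - eta[h, j] ==
    delta`` on the log scale; the pair is assigned ``+delta/2`` and
    ``-delta/2`` so every column sums to zero.
    """
    eta = np.zeros((len(groups), m_molecules))
    for j, (g, h, delta) in (contrasts or {}).items():
        gi, hi = groups.index(g), groups.index(h)
        eta[gi, j] = delta / 2.0
        eta[hi, j] = -delta / 2.0
    return eta


@dataclass
class CohortSpec:
    """Ground-truth parameters of a simulated cohort."""

    n_per_group: dict[str, int]
    m_molecules: int
    class_composition: dict[str, int] | None = None
    effect_table: np.ndarray | None = None        # (k, m) eta, log scale
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    sigma: float = 0.5
    hyper_sds: tuple[float, float] = (0.3, 1.0)   # (alpha, beta)
    theta: float = 1.0
    q_cens: float = 0.1
    steepness: float = np.inf
    fluid: str = "cyst"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValidationError("n_per_group must name at least one group")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValidationError("all group counts must be >= 1")
        if self.m_molecules < 1:
            raise ValidationError("m_molecules must be >= 1")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if not 0.0 <= self.q_cens <= 0.5:
            raise ValidationError("q_cens must lie in [0, 0.5]")
        if self.class_composition is None:
            self.class_composition = default_class_composition(self.m_molecules)
        if sum(self.class_composition.values()) != self.m_molecules:
            raise ValidationError("class_composition must sum to m_molecules")
        k = len(self.n_per_group)
        if self.effect_table is None:
            self.effect_table = np.zeros((k, self.m_molecules))
        self.effect_table = np.asarray(self.effect_table, dtype=float)
        if self.effect_table.shape != (k, self.m_molecules):
            raise ValidationError(
                f"effect_table shape {self.effect_table.shape} != "
                f"({k}, {self.m_molecules})"
            )
        colsums = self.effect_table.sum(axis=0)
        if not np.allclose(colsums, 0.0, atol=1e-8):
            raise ValidationError(
                "effect_table columns must sum to zero across groups"
            )
        for name, vec in self.covariate_effects.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.m_molecules,):
                raise ValidationError(
                    f"covariate effect {name!r} must have length m_molecules"
                )
            self.covariate_effects[name] = vec

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_per_group)

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group.values())


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth that generated it."""

    concentrations: ConcentrationMatrix
    clinical: pd.DataFrame
    spec: CohortSpec
    complete_log: pd.DataFrame      # pre-censoring log-concentrations
    sample_effects: np.ndarray      # phi, one per sample
    molecule_effects: np.ndarray    # lambda, one per molecule

    def truth_dict(self) -> dict:
        """JSON-serializable ground-truth record for recovery tests."""
        return {
            "theta": self.spec.theta,
            "sigma": self.spec.sigma,
            "groups": list(self.spec.groups),
            "effect_table": self.spec.effect_table.tolist(),
            "covariate_effects": {
                k: v.tolist() for k, v in self.spec.covariate_effects.items()
            },
            "sample_effects": self.sample_effects.tolist(),
            "molecule_effects": self.molecule_effects.tolist(),
            "seed": self.spec.seed,
        }


def _molecule_ids(class_composition: dict[str, int]) -> tuple[list, list]:
    ids, classes = [], []
    for cls, count in class_composition.items():
        prefix = cls.replace(" ", "_")
        for i in range(count):
            ids.append(f"{prefix}_{i + 1:04d}")
            classes.append(cls)
    return ids, classes


def _draw_clinical(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for group, count in spec.n_per_group.items():
        age_lo, age_hi = _range_for(_AGE_RANGE, group)
        bmi_lo, bmi_hi = _range_for(_BMI_RANGE, group)
        ca_lo, ca_hi = _range_for(_CA19_9_RANGE, group)
        alb_lo, alb_hi = _range_for(_ALBUMIN_RANGE, group)
        bil_lo, bil_hi = _range_for(_BILIRUBIN_RANGE, group)
        for _ in range(count):
            idx += 1
            rows.append(
                {
                    "sample_id": f"S{idx:04d}",
                    "group": group,
                    "fluid": spec.fluid,
                    "age": rng.uniform(age_lo, age_hi),
                    "bmi": rng.uniform(bmi_lo, bmi_hi),
                    "sex": "F"
                    if rng.random() < _FEMALE_FRAC.get(group, 0.5)
                    else "M",
                    "statin": bool(rng.random() < _STATIN_FRAC.get(group, 0.15)),
                    "diabetes": bool(
                        rng.random() < _DIABETES_FRAC.get(group, 0.2)
                    ),
                    # CA19-9 spans orders of magnitude: log-uniform.
                    "ca19_9": float(
                        np.exp(rng.uniform(np.log(ca_lo), np.log(ca_hi)))
                    ),
                    "albumin": rng.uniform(alb_lo, alb_hi),
                    "bilirubin": rng.uniform(bil_lo, bil_hi),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def apply_censoring(
    complete: pd.DataFrame,
    q_cens: float,
    steepness: float = np.inf,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Censor each molecule (row) from the left.

    The per-molecule censoring threshold is the ``q_cens`` empirical
    quantile; only values below it are eligible.  With infinite
    ``steepness`` exactly ``floor(q_cens * n)`` smallest values per row
    go missing; with finite steepness an eligible value at depth ``d``
    below the threshold survives with probability ``exp(-steepness * d /
    scale)`` (scale = row standard deviation), i.e. missingness
    probability decreases monotonically with the value.

    Returns
    -------
    censored, mask
        The matrix with ``NaN`` at censored cells and the boolean mask.
    """
    if not 0.0 <= q_cens <= 0.5:
        raise ValidationError("q_cens must lie in [0, 0.5]")
    arr = complete.to_numpy(dtype=float)
    n = arr.shape[1]
    k_miss = int(np.floor(q_cens * n))
    mask = np.zeros_like(arr, dtype=bool)
    if k_miss > 0:
        rng = np.random.default_rng(seed)
        order = np.argsort(arr, axis=1, kind="stable")
        rows = np.arange(arr.shape[0])[:, None]
        eligible = order[:, :k_miss]                    # k smallest per row
        if np.isinf(steepness):
            mask[rows, eligible] = True
        else:
            thr = arr[rows, order[:, k_miss : k_miss + 1]]   # first kept value
            scale = arr.std(axis=1, ddof=1, keepdims=True)
            scale[scale == 0] = 1.0
            depth = (thr - arr[rows, eligible]) / scale
            p_miss = 1.0 - np.exp(-steepness * np.maximum(depth, 0.0))
            mask[rows, eligible] = rng.random(eligible.shape) < p_miss
    censored = arr.copy()
    censored[mask] = np.nan
    out = pd.DataFrame(censored, index=complete.index, columns=complete.columns)
    return out, pd.DataFrame(mask, index=complete.index, columns=complete.columns)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the generative model in ``spec``.

    Deterministic given ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_clin, rng_eff, rng_noise, seed_cens = root.spawn(4)
    rng_clin = np.random.default_rng(rng_clin)
    rng_eff = np.random.default_rng(rng_eff)
    rng_noise = np.random.default_rng(rng_noise)

    clinical = _draw_clinical(spec, rng_clin)
    n, m = spec.n_samples, spec.m_molecules
    alpha, beta = spec.hyper_sds
    phi = rng_eff.normal(0.0, alpha, size=n)
    lam = rng_eff.normal(0.0, beta, size=m)

    group_idx = np.array(
        [list(spec.groups).index(g) for g in clinical["group"]]
    )
    y = (
        spec.theta
        + phi[:, None]
        + lam[None, :]
        + spec.effect_table[group_idx, :]
    )
    for name, gamma in spec.covariate_effects.items():
        if name not in clinical.columns:
            raise ValidationError(f"covariate {name!r} not in clinical table")
        y = y + np.outer(clinical[name].to_numpy(dtype=float), gamma)
    y = y + rng_noise.normal(0.0, spec.sigma, size=(n, m))

    mol_ids, mol_classes = _molecule_ids(spec.class_composition)
    complete_log = pd.DataFrame(y.T, index=mol_ids, columns=clinical.index)
    censored_log, mask = apply_censoring(
        complete_log, spec.q_cens, spec.steepness, seed=seed_cens
    )
    concentrations = ConcentrationMatrix(
        values=np.exp(censored_log),
        classes=pd.Series(mol_classes, index=mol_ids, name="class"),
        log_scale=False,
    )
    return SyntheticCohort(
        concentrations=concentrations,
        clinical=clinical,
        spec=spec,
        complete_log=complete_log,
        sample_effects=phi,
        molecule_effects=lam,
    )
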