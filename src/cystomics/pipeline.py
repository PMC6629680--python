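"""End-to-end orchestration: transform -> filter -> impute -> fit ->
fold changes -> adjust -> PCA / classification / correlation.

A run is fully described by a :class:`RunConfig`; re-running an
identical config reproduces byte-identical outputs.  All randomness is
derived from the single mandatory root seed, split per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .cppls import DEFAULT_POWER_GRID, recursive_elimination
from .explore import DEFAULT_MARKERS, marker_correlations, pca_project
from .hierarchical import ModelSpec, adjust_matrix, fit_model, fold_changes, merge_groups
from .matrix import ValidationError, validate_clinical
from .preprocess import log_transform, modified_80_rule, qrilc_impute

logger = logging.getLogger("cystomics")

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "preprocess",
    "fit",
    "foldchange",
    "adjust",
    "pca",
    "classify",
    "correlate",
)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    concentrations: str
    clinical: str
    out_dir: str
    seed: int
    fluid: str | None = None
    merge: list = field(default_factory=list)   # [{"labels": [...], "new_label": str}]
    covariates: tuple[str, ...] = ("age", "bmi")
    n_draws: int = 4000
    n_chains: int = 4
    warmup: int = 500
    drop_fraction: float = 0.05
    max_components: int = 8
    power_grid: tuple[float, ...] = DEFAULT_POWER_GRID
    markers: tuple[str, ...] = DEFAULT_MARKERS

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ValidationError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.power_grid = tuple(float(p) for p in cfg.power_grid)
        cfg.covariates = tuple(cfg.covariates)
        cfg.markers = tuple(cfg.markers)
        return cfg

    def canonical_json(self) -> str:
        payload = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in self.__dict__.items()
        }
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _stage_seeds(root_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure the partial manifest (stages completed so far
    plus the failing stage name) is still written before the exception
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "versions": {
            "cystomics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    seeds = dict(zip(STAGES, _stage_seeds(config.seed, len(STAGES))))
    manifest["stage_seeds"] = seeds

    def finish_stage(name: str, outputs: list[str]) -> None:
        manifest["stages"][name] = {"outputs": outputs, "seed": seeds[name]}
        logger.info("stage %s done: %s", name, ", ".join(outputs))

    def write_manifest() -> None:
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    current = "preprocess"
    try:
        raw = io.read_concentration_csv(config.concentrations)
        clinical = io.read_clinical_csv(config.clinical)
        if config.fluid is not None:
            if config.fluid not in set(clinical.get("fluid", ())):
                raise ValidationError(
                    f"fluid selector {config.fluid!r} matches no sample"
                )
            clinical = clinical[clinical["fluid"] == config.fluid]
            raw = raw.subset_samples(clinical.index)
        for rule in config.merge:
            clinical = merge_groups(clinical, rule["labels"], rule["new_label"])
        clinical = validate_clinical(clinical, raw.samples)

        # -- preprocess
        logged = log_transform(raw)
        retained, filter_report = modified_80_rule(logged, clinical)
        pre = qrilc_impute(retained, seed=seeds["preprocess"])
        pre.dropped_molecules = filter_report
        io.write_concentration_csv(
            pre, out / "preprocessed.csv", classes=pre.classes
        )
        io.write_filter_report_tsv(filter_report, out / "filter_report.tsv")
        finish_stage("preprocess", ["preprocessed.csv", "filter_report.tsv"])

        # -- fit
        current = "fit"
        groups = tuple(dict.fromkeys(clinical["group"]))
        spec = ModelSpec(groups=groups, covariates=config.covariates)
        draws = fit_model(
            pre,
            clinical,
            spec=spec,
            n_draws=config.n_draws,
            n_chains=config.n_chains,
            warmup=config.warmup,
            seed=seeds["fit"],
        )
        io.save_draws(draws, out / "posterior.npz")
        summary = pd.DataFrame(
            {
                "parameter": ["theta", "sigma", "alpha", "beta"],
                "mean": [
                    draws.theta.mean(),
                    draws.sigma.mean(),
                    draws.alpha.mean(),
                    draws.beta.mean(),
                ],
            }
        )
        summary.to_csv(out / "posterior_summary.csv", index=False,
                       float_format=io.FLOAT_FORMAT)
        if len(draws.convergence):
            draws.convergence.to_csv(out / "convergence.csv",
                                     float_format=io.FLOAT_FORMAT)
        finish_stage("fit", ["posterior.npz", "posterior_summary.csv"])

        # -- fold changes, every unordered group pair
        current = "foldchange"
        fc_files = []
        for g, h in combinations(groups, 2):
            fct = fold_changes(draws, g, h, classes=pre.classes)
            safe = f"foldchange_{g}_vs_{h}.tsv".replace("/", "-")
            io.write_fold_change_tsv(fct, out / safe)
            fc_files.append(safe)
        finish_stage("foldchange", fc_files)

        # -- adjust
        current = "adjust"
        adj = adjust_matrix(pre, clinical, draws)
        io.write_concentration_csv(adj, out / "adjusted.csv",
                                   classes=adj.classes)
        finish_stage("adjust", ["adjusted.csv"])

        # -- pca
        current = "pca"
        pca = pca_project(adj, n_components=2)
        pca.scores.to_csv(out / "pca_scores.csv",
                          float_format=io.FLOAT_FORMAT)
        finish_stage("pca", ["pca_scores.csv"])

        # -- classify
        current = "classify"
        X = adj.samples_by_molecules().to_numpy(dtype=float)
        y = clinical.loc[adj.samples, "group"].to_numpy()
        report, ranking = recursive_elimination(
            X,
            y,
            drop_fraction=config.drop_fraction,
            power_grid=config.power_grid,
            max_components=config.max_components,
            feature_names=adj.molecules,
        )
        io.write_classification_tsv(report, out / "classification.tsv")
        io.write_vip_tsv(ranking, out / "vip.tsv")
        report.trace.to_csv(out / "elimination_trace.tsv", sep="\t",
                            index=False, float_format=io.FLOAT_FORMAT)
        finish_stage(
            "classify",
            ["classification.tsv", "vip.tsv", "elimination_trace.tsv"],
        )

        # -- correlate
        current = "correlate"
        available = [m for m in config.markers if m in clinical.columns]
        corr = marker_correlations(adj, clinical, markers=available)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False,
                    float_format=io.FLOAT_FORMAT)
        finish_stage("correlate", ["correlations.tsv"])
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        write_manifest()
        logger.error("stage %s failed: %s", current, exc)
        logger.removeHandler(log_handler)
        log_handler.close()
        raise
    write_manifest()
    logger.removeHandler(log_handler)
    log_handler.close()
    return out
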