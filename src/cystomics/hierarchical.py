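"""Bayesian hierarchical lognormal mixed model for concentration panels.

The observation model for the log-concentration of molecule ``j`` in
sample ``i`` of group ``g`` is

    y_gij ~ N(mu_gij, sigma^2)
    mu_gij = theta + phi_i + lambda_j + eta_gj + sum_v gamma_vj x_vi

with weakly informative priors: ``theta ~ t(3, 0, 10)``; ``phi_i ~
N(0, alpha^2)``; ``lambda_j ~ N(0, beta^2)``; ``eta_gj ~ N(0,
zeta_g^2)``; ``gamma_vj ~ N(0, omega_v^2)``; and half-t(3, 0, 10) on
every scale (sigma, alpha, beta, zeta_g, omega_v).  Effects sharing a
discrete category are constrained to sum to zero (phi over samples,
lambda over molecules, eta over groups within each molecule), which
identifies the model.

Inference is a blocked Gibbs sampler.  Student-t and half-t priors are
made conjugate with the usual inverse-gamma auxiliary representation
(a half-t(nu, 0, A) scale is equivalent to ``s^2 | a ~ IG(nu/2, nu/a)``
with ``a ~ IG(1/2, 1/A^2)``), so every conditional is exact — no
tuning, no step sizes.  The sampler runs in the unconstrained
parametrization, where all full conditionals are Gaussian or
inverse-gamma, and the sum-to-zero constraints are applied by sweeping
means into the enclosing term when a draw is stored; the swept
parametrization is exactly the identified one and leaves every fitted
mean mu unchanged, so contrasts such as ``eta_gj - eta_hj`` are
unaffected.

Fold changes between groups g and h are ``exp(eta_gj - eta_hj)``,
summarized per molecule by the posterior median and the equal-tailed
95% credibility interval; a molecule is flagged significant when that
interval excludes 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    AdjustedMatrix,
    ValidationError,
    validate_clinical,
    zscore_rows,
)
from .preprocess import PreprocessedMatrix

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "FoldChangeTable",
    "ConvergenceWarning",
    "fit_model",
    "fold_changes",
    "merge_groups",
    "adjust_matrix",
    "select_covariates",
]


class ConvergenceWarning(UserWarning):
    """Emitted when R-hat of a monitored parameter exceeds the threshold."""


@dataclass
class ModelSpec:
    """Structural description of one model fit."""

    groups: tuple[str, ...]
    covariates: tuple[str, ...] = ("age", "bmi")
    prior_df: float = 3.0
    prior_scale: float = 10.0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.covariates = tuple(self.covariates)
        if len(self.groups) < 2:
            raise ValidationError("model needs at least 2 groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("duplicate group labels")


@dataclass
class PosteriorDraws:
    """Retained posterior draws, chains stacked along the first axis.

    All arrays satisfy the sum-to-zero constraints draw by draw:
    ``phi`` sums to zero over samples, ``lam`` over molecules, and
    ``eta[:, :, j]`` over groups for every molecule ``j``.
    """

    theta: np.ndarray          # (D,)
    phi: np.ndarray            # (D, n)
    lam: np.ndarray            # (D, m)
    eta: np.ndarray            # (D, k, m)
    gamma: np.ndarray          # (D, V, m) on per-unit covariate scale
    sigma: np.ndarray          # (D,)
    alpha: np.ndarray          # (D,)
    beta: np.ndarray           # (D,)
    zeta: np.ndarray           # (D, k)
    omega: np.ndarray          # (D, V)
    spec: ModelSpec
    molecules: pd.Index
    samples: pd.Index
    n_chains: int
    cov_means: np.ndarray      # (V,) covariate centering used in the fit
    cov_sds: np.ndarray        # (V,)
    convergence: pd.DataFrame = field(default_factory=pd.DataFrame)
    log_lik: np.ndarray | None = None   # (D, n*m) pointwise log-likelihood

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def group_index(self, label: str) -> int:
        try:
            return self.spec.groups.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown group label {label!r}; model groups are "
                f"{self.spec.groups}"
            ) from None


@dataclass
class FoldChangeTable:
    """Per-molecule fold changes between two groups with 95% CrI."""

    table: pd.DataFrame        # fc, lo95, hi95, significant (+ class)
    group_pair: tuple[str, str]
    n_draws: int


# ---------------------------------------------------------------------------
# Gibbs sampler internals
# ---------------------------------------------------------------------------


def _inv_gamma(rng: np.random.Generator, shape: float, rate, size=None):
    """Draw from InverseGamma(shape, rate)."""
    return rate / rng.gamma(shape, 1.0, size=size)


def _slice_sample(logp, x0: float, rng: np.random.Generator,
                  width: float = 2.0, max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping out and shrinkage."""
    y = logp(x0) + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logp(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _marginal_var_update(
    Q: float,
    L: int,
    v0: float,
    s2: float,
    a_aux: float,
    nu: float,
    rng: np.random.Generator,
) -> float:
    """Collapsed update of a variance component.

    The effect vector is integrated out: with a balanced design the L
    per-element sufficient statistics are iid ``N(0, s2 + v0)`` with
    ``Q`` their sum of squares, so the marginal posterior of the
    variance is univariate and is slice-sampled on the log scale.  This
    sidesteps the funnel that makes centered Gibbs updates of
    hierarchical scales mix slowly when effects are near zero.
    """

    def logp(xi: float) -> float:
        es = np.exp(xi)
        w = es + v0
        return (
            -0.5 * (L * np.log(w) + Q / w)
            - (nu / 2.0) * xi
            - nu / (a_aux * es)
        )

    return float(np.exp(_slice_sample(logp, np.log(s2), rng)))


def _gibbs_chain(
    Y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    k: int,
    nu: float,
    A: float,
    n_keep: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
    store_loglik: bool,
) -> dict[str, np.ndarray]:
    n, m = Y.shape
    V = X.shape[1]
    N = n * m
    group_rows = [np.flatnonzero(group_idx == g) for g in range(k)]
    n_g = np.array([r.size for r in group_rows], dtype=float)

    # state
    theta = float(Y.mean())
    phi = np.zeros(n)
    lam = Y.mean(axis=0) - theta
    eta = np.zeros((k, m))
    gam = np.zeros((V, m))
    sig2 = max(float(Y.var()) / 2.0, 1e-6)
    tau_theta = A**2
    alpha2 = beta2 = 0.25
    zeta2 = np.full(k, 0.25)
    omega2 = np.full(V, 0.25) if V else np.zeros(0)
    a_sig = a_alpha = a_beta = 1.0
    a_zeta = np.ones(k)
    a_omega = np.ones(V)

    out = {
        "theta": np.empty(n_keep),
        "phi": np.empty((n_keep, n)),
        "lam": np.empty((n_keep, m)),
        "eta": np.empty((n_keep, k, m)),
        "gamma": np.empty((n_keep, V, m)),
        "sigma": np.empty(n_keep),
        "alpha": np.empty(n_keep),
        "beta": np.empty(n_keep),
        "zeta": np.empty((n_keep, k)),
        "omega": np.empty((n_keep, V)),
    }
    if store_loglik:
        out["log_lik"] = np.empty((n_keep, N))

    kept = 0
    total = warmup + n_keep * thin
    for it in range(total):
        Xg = X @ gam if V else 0.0
        base = Y - phi[:, None] - lam[None, :] - eta[group_idx, :] - Xg

        # theta | rest
        prec = N / sig2 + 1.0 / tau_theta
        mean = base.sum() / sig2 / prec
        theta = rng.normal(mean, np.sqrt(1.0 / prec))
        tau_theta = _inv_gamma(rng, (nu + 1) / 2, (nu * A**2 + theta**2) / 2)

        # phi block: collapsed variance update, then conjugate redraw.
        # Row means of the partial residual are iid N(phi_i, sig2/m).
        r = base + phi[:, None] - theta
        rbar = r.mean(axis=1)
        alpha2 = _marginal_var_update(
            float((rbar**2).sum()), n, sig2 / m, alpha2, a_alpha, nu, rng
        )
        a_alpha = _inv_gamma(rng, (nu + 1) / 2, nu / alpha2 + 1.0 / A**2)
        v = 1.0 / (m / sig2 + 1.0 / alpha2)
        phi = rng.normal(v * rbar * m / sig2, np.sqrt(v))

        # lambda block
        r = Y - theta - phi[:, None] - eta[group_idx, :] - Xg
        cbar = r.mean(axis=0)
        beta2 = _marginal_var_update(
            float((cbar**2).sum()), m, sig2 / n, beta2, a_beta, nu, rng
        )
        a_beta = _inv_gamma(rng, (nu + 1) / 2, nu / beta2 + 1.0 / A**2)
        v = 1.0 / (n / sig2 + 1.0 / beta2)
        lam = rng.normal(v * cbar * n / sig2, np.sqrt(v))

        # eta blocks, one per group
        r = Y - theta - phi[:, None] - lam[None, :] - Xg
        for g in range(k):
            gbar = r[group_rows[g]].mean(axis=0)
            zeta2[g] = _marginal_var_update(
                float((gbar**2).sum()),
                m,
                sig2 / n_g[g],
                zeta2[g],
                a_zeta[g],
                nu,
                rng,
            )
            a_zeta[g] = _inv_gamma(
                rng, (nu + 1) / 2, nu / zeta2[g] + 1.0 / A**2
            )
            v_g = 1.0 / (n_g[g] / sig2 + 1.0 / zeta2[g])
            eta[g] = rng.normal(v_g * gbar * n_g[g] / sig2, np.sqrt(v_g))

        # gamma blocks: collapsed per-covariate scale updates, then a
        # joint redraw of all covariate slopes per molecule (the V x V
        # precision is shared across molecules, so one Cholesky serves
        # all of them; joint sampling matters when covariates correlate)
        if V:
            core = Y - theta - phi[:, None] - lam[None, :] - eta[group_idx, :]
            sxx = (X**2).sum(axis=0)
            for vv in range(V):
                others = X @ gam - np.outer(X[:, vv], gam[vv])
                r_v = core - others
                bhat = (X[:, vv] @ r_v) / sxx[vv]   # ~ N(gam_vj, sig2/sxx)
                omega2[vv] = _marginal_var_update(
                    float((bhat**2).sum()),
                    m,
                    sig2 / sxx[vv],
                    omega2[vv],
                    a_omega[vv],
                    nu,
                    rng,
                )
                a_omega[vv] = _inv_gamma(
                    rng, (nu + 1) / 2, nu / omega2[vv] + 1.0 / A**2
                )
            prec = X.T @ X / sig2 + np.diag(1.0 / omega2)
            B = X.T @ core / sig2                    # (V, m)
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, B)
            z = rng.standard_normal((V, m))
            gam = mean + np.linalg.solve(L.T, z)
            Xg = X @ gam

        # sigma | rest
        resid = Y - theta - phi[:, None] - lam[None, :] - eta[group_idx, :] - Xg
        ssr = float((resid**2).sum())
        sig2 = _inv_gamma(rng, (nu + N) / 2, nu / a_sig + ssr / 2)
        a_sig = _inv_gamma(rng, (nu + 1) / 2, nu / sig2 + 1.0 / A**2)

        if it >= warmup and (it - warmup) % thin == 0:
            # Sweep the likelihood-flat directions into their identified
            # owners before storing.  Each move leaves every mu_gij
            # unchanged: (1) the component of phi lying in the covariate
            # span is a molecule-common slope, so it belongs to gamma;
            # (2) per-group means of phi are molecule-common group
            # effects, so they belong to eta; (3) the per-molecule mean
            # of eta over groups belongs to lambda, and the overall
            # means belong to theta.  The stored draw then satisfies
            # the sum-to-zero constraints exactly.
            phi_s = phi
            gam_s = gam
            if V:
                b = np.linalg.solve(X.T @ X, X.T @ phi_s)
                phi_s = phi_s - X @ b
                gam_s = gam + b[:, None]
            pm = np.array([phi_s[group_rows[g]].mean() for g in range(k)])
            phi_s = phi_s - pm[group_idx]
            eta_s = eta + pm[:, None]
            eta_mean = eta_s.mean(axis=0)          # per molecule
            eta_s = eta_s - eta_mean
            lam_s = lam + eta_mean
            lam_off = lam_s.mean()
            lam_s = lam_s - lam_off
            phi_off = phi_s.mean()
            phi_s = phi_s - phi_off
            out["theta"][kept] = theta + lam_off + phi_off
            out["phi"][kept] = phi_s
            out["lam"][kept] = lam_s
            out["eta"][kept] = eta_s
            out["gamma"][kept] = gam_s
            out["sigma"][kept] = np.sqrt(sig2)
            out["alpha"][kept] = np.sqrt(alpha2)
            out["beta"][kept] = np.sqrt(beta2)
            out["zeta"][kept] = np.sqrt(zeta2)
            out["omega"][kept] = np.sqrt(omega2)
            if store_loglik:
                out["log_lik"][kept] = (
                    -0.5 * np.log(2 * np.pi * sig2) - resid.ravel() ** 2 / (2 * sig2)
                )
            kept += 1
    return out


def _compute_convergence(
    chains: list[dict[str, np.ndarray]], spec: ModelSpec
) -> pd.DataFrame:
    """Split-R-hat and bulk ESS for the monitored scalar blocks."""
    import arviz as az

    posterior = {}
    for name in ("theta", "sigma", "alpha", "beta", "zeta", "omega", "eta"):
        stacked = np.stack([c[name] for c in chains])  # (chain, draw, ...)
        if stacked.shape[-1] == 0 and stacked.ndim > 2:
            continue
        posterior[name] = stacked
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in posterior:
        rows.append(
            {
                "parameter": name,
                "rhat_max": float(rhat[name].max()),
                "ess_min": float(ess[name].min()),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def fit_model(
    pre: PreprocessedMatrix,
    clinical: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_draws: int = 20_000,
    n_chains: int = 4,
    warmup: int = 500,
    thin: int = 1,
    seed: int = 0,
    store_loglik: bool = False,
) -> PosteriorDraws:
    """Fit the hierarchical model by blocked Gibbs sampling.

    Parameters
    ----------
    pre
        Complete log-scale matrix (molecules x samples).
    clinical
        Covariate table indexed by sample ID; must contain ``group``
        and every covariate named in ``spec``.
    n_draws
        Total retained draws across all chains.
    spec
        Model structure; by default the groups are taken in order of
        first appearance in the clinical table and covariates are
        ``("age", "bmi")``.

    Notes
    -----
    Continuous covariates are centered and scaled internally for
    conditioning; the stored ``gamma`` draws are transformed back to the
    per-unit covariate scale.  A :class:`ConvergenceWarning` is emitted
    (never silenced) when any monitored R-hat exceeds the threshold.
    """
    Y = pre.samples_by_molecules().to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValidationError("matrix contains non-finite values")
    clinical = validate_clinical(clinical, pre.samples)
    if spec is None:
        seen = list(dict.fromkeys(clinical["group"]))
        covs = tuple(c for c in ("age", "bmi") if c in clinical.columns)
        spec = ModelSpec(groups=tuple(seen), covariates=covs)
    present = set(clinical["group"])
    extra = present - set(spec.groups)
    if extra:
        raise ValidationError(f"samples with unknown groups: {sorted(extra)}")
    for cov in spec.covariates:
        if cov not in clinical.columns:
            raise ValidationError(f"covariate {cov!r} not in clinical table")

    group_idx = np.array([spec.groups.index(g) for g in clinical["group"]])
    V = len(spec.covariates)
    if V:
        Xraw = clinical[list(spec.covariates)].to_numpy(dtype=float)
        if np.isnan(Xraw).any():
            raise ValidationError("missing covariate values")
        cov_means = Xraw.mean(axis=0)
        cov_sds = Xraw.std(axis=0, ddof=1)
        cov_sds[cov_sds == 0] = 1.0
        X = (Xraw - cov_means) / cov_sds
    else:
        X = np.zeros((Y.shape[0], 0))
        cov_means = np.zeros(0)
        cov_sds = np.zeros(0)

    if n_draws % n_chains:
        raise ValidationError("n_draws must be divisible by n_chains")
    per_chain = n_draws // n_chains
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _gibbs_chain(
            Y,
            X,
            group_idx,
            len(spec.groups),
            spec.prior_df,
            spec.prior_scale,
            per_chain,
            warmup,
            thin,
            np.random.default_rng(s),
            store_loglik,
        )
        for s in seeds
    ]

    convergence = pd.DataFrame()
    if per_chain >= 4:
        convergence = _compute_convergence(chains, spec)
        worst = convergence["rhat_max"].max()
        if worst >= spec.rhat_threshold:
            warnings.warn(
                f"max R-hat {worst:.3f} >= {spec.rhat_threshold}; "
                "increase warmup or draws",
                ConvergenceWarning,
                stacklevel=2,
            )

    def cat(name):
        return np.concatenate([c[name] for c in chains], axis=0)

    gamma = cat("gamma")
    if V:  # back to per-unit covariate scale
        gamma = gamma / cov_sds[None, :, None]
    return PosteriorDraws(
        theta=cat("theta"),
        phi=cat("phi"),
        lam=cat("lam"),
        eta=cat("eta"),
        gamma=gamma,
        sigma=cat("sigma"),
        alpha=cat("alpha"),
        beta=cat("beta"),
        zeta=cat("zeta"),
        omega=cat("omega"),
        spec=spec,
        molecules=pre.molecules,
        samples=pre.samples,
        n_chains=n_chains,
        cov_means=cov_means,
        cov_sds=cov_sds,
        convergence=convergence,
        log_lik=cat("log_lik") if store_loglik else None,
    )


# ---------------------------------------------------------------------------
# Posterior functionals
# ---------------------------------------------------------------------------


def fold_changes(
    draws: PosteriorDraws,
    g: str,
    h: str,
    classes: pd.Series | None = None,
) -> FoldChangeTable:
    """Fold-change table ``exp(eta_g - eta_h)`` with 95% CrI per molecule."""
    if g == h:
        raise ValidationError("fold change requires two distinct groups")
    gi, hi = draws.group_index(g), draws.group_index(h)
    log_fc = draws.eta[:, gi, :] - draws.eta[:, hi, :]  # (D, m)
    # percentiles on the log scale keep FC(g,h) and 1/FC(h,g) identical
    lo, med, hi95 = np.exp(
        np.percentile(log_fc, [2.5, 50.0, 97.5], axis=0)
    )
    table = pd.DataFrame(
        {
            "fc": med,
            "lo95": lo,
            "hi95": hi95,
            "significant": (lo > 1.0) | (hi95 < 1.0),
        },
        index=draws.molecules,
    )
    if classes is not None:
        table.insert(0, "class", classes.reindex(draws.molecules))
    return FoldChangeTable(
        table=table, group_pair=(g, h), n_draws=draws.n_draws
    )


def merge_groups(
    clinical: pd.DataFrame, labels_to_merge, new_label: str
) -> pd.DataFrame:
    """Relabel a set of diagnosis groups as one combined group."""
    labels_to_merge = list(labels_to_merge)
    existing = set(clinical["group"])
    unknown = [l for l in labels_to_merge if l not in existing]
    if unknown:
        raise ValidationError(f"labels not present: {unknown}")
    untouched = existing - set(labels_to_merge)
    if new_label in untouched:
        raise ValidationError(
            f"new label {new_label!r} collides with an existing group"
        )
    out = clinical.copy()
    out.loc[out["group"].isin(labels_to_merge), "group"] = new_label
    return out


def adjust_matrix(
    pre: PreprocessedMatrix,
    clinical: pd.DataFrame,
    draws: PosteriorDraws,
) -> AdjustedMatrix:
    """Remove posterior-mean covariate effects, then z-score per molecule.

    Each entry becomes ``y_ij - sum_v E[gamma_vj] (x_vi - mean(x_v))``,
    followed by per-molecule standardization to mean 0, unit variance.
    """
    covs = draws.spec.covariates
    if not covs:
        raise ValidationError("fitted draws contain no covariate effects")
    clinical = validate_clinical(clinical, pre.samples)
    Y = pre.values.to_numpy(dtype=float)  # molecules x samples
    gamma_mean = draws.gamma.mean(axis=0)  # (V, m) per-unit scale
    gamma_dict = {}
    for vi, cov in enumerate(covs):
        x = clinical[cov].to_numpy(dtype=float) - draws.cov_means[vi]
        Y = Y - np.outer(gamma_mean[vi], x)
        gamma_dict[cov] = pd.Series(gamma_mean[vi], index=pre.molecules)
    adjusted = pd.DataFrame(Y, index=pre.molecules, columns=pre.samples)
    return AdjustedMatrix(
        values=zscore_rows(adjusted),
        classes=pre.classes,
        gamma_means=gamma_dict,
    )


# ---------------------------------------------------------------------------
# Covariate selection by PSIS-LOO expected log predictive density
# ---------------------------------------------------------------------------


def _psis_loo_elpd(draws: PosteriorDraws) -> tuple[float, float]:
    """(elpd_loo, se) from stored pointwise log-likelihood draws."""
    import arviz as az

    if draws.log_lik is None:
        raise ValidationError("fit was run without store_loglik=True")
    D = draws.n_draws
    per_chain = D // draws.n_chains
    ll = draws.log_lik.reshape(draws.n_chains, per_chain, -1)
    idata = az.from_dict(
        posterior={"theta": draws.theta.reshape(draws.n_chains, per_chain)},
        log_likelihood={"y": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=False)
    return float(res.elpd_loo), float(res.se)


def select_covariates(
    pre: PreprocessedMatrix,
    clinical: pd.DataFrame,
    candidate_sets,
    groups: tuple[str, ...] | None = None,
    n_draws: int = 1000,
    n_chains: int = 2,
    warmup: int = 400,
    seed: int = 0,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Score candidate covariate sets by PSIS-LOO elpd; return the best.

    Each candidate set is fitted as its own model (same data, same
    seed-derived chains) and scored by the Pareto-smoothed importance
    sampling estimate of the expected log pointwise predictive density.
    Ties break toward the earlier candidate.
    """
    clinical = validate_clinical(clinical, pre.samples)
    if groups is None:
        groups = tuple(dict.fromkeys(clinical["group"]))
    rows = []
    best: tuple[float, int, tuple[str, ...]] | None = None
    for pos, cand in enumerate(candidate_sets):
        cand = tuple(cand)
        for cov in cand:
            if cov not in clinical.columns:
                raise ValidationError(f"unknown covariate {cov!r}")
        spec = ModelSpec(groups=groups, covariates=cand)
        draws = fit_model(
            pre,
            clinical,
            spec=spec,
            n_draws=n_draws,
            n_chains=n_chains,
            warmup=warmup,
            seed=seed,
            store_loglik=True,
        )
        elpd, se = _psis_loo_elpd(draws)
        rows.append({"covariates": cand, "elpd_loo": elpd, "se": se})
        if best is None or elpd > best[0]:
            best = (elpd, pos, cand)
    scores = pd.DataFrame(rows)
    return best[2], scores
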