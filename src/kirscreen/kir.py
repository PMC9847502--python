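"""Kinome regression (KIR): kinase-target deconvolution by elastic net.

The idea: a kinase inhibitor is a polypharmacological probe — it hits many
kinases at once, with a profiled fractional inhibition per kinase. Across a
panel of inhibitors at several doses, the proliferation deficit of each
(inhibitor, dose) condition is modelled as a linear combination of the
fractional inhibitions of the expressed kinases::

    delta_kp(i, d) ~ sum_k beta_k * inhibition_k(i, d)

An elastic-net penalty (mixing weight alpha = 0.15 by default, mostly
ridge-like with a sparsifying L1 component) is fit over a log-spaced lambda
path; lambda is chosen at the minimum cross-validated mean squared error and
the kinases with non-zero coefficients at that lambda, ranked by
|coefficient|, form the per-growth-factor output. Kinases selected for every
growth factor are intersected and ordered by the sum of their per-growth-
factor ranks.

The penalized objective follows the glmnet convention::

    (1/2n) * ||y - b0 - X beta||^2
        + lambda * (alpha * ||beta||_1 + (1-alpha)/2 * ||beta||_2^2)

Features are standardized to unit variance for fitting when requested;
coefficients are reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .errors import MissingDataError, ValidationError
from .simulate import (
    EXPRESSION_CUTOFF,
    GroundTruth,
    InhibitionMatrix,
    KinasePanel,
    inhibition_at_dose,
)

__all__ = [
    "KirConfig",
    "DesignMatrix",
    "KinaseRanking",
    "IntersectionResult",
    "filter_by_expression",
    "build_design",
    "elastic_net_fit",
    "fit_kir",
    "intersect_rank_sum",
    "recovery_metrics",
]


@dataclass(frozen=True)
class KirConfig:
    """Elastic-net settings: mixing weight alpha (0 = ridge, 1 = lasso),
    standardization flag, CV fold count, expression cutoff (arbitrary
    units), and the lambda grid (log-spaced, ``n_lambda`` points spanning
    ``lambda_min_ratio`` decades down from lambda_max)."""

    alpha: float = 0.15
    standardize: bool = True
    cv_folds: int = 10
    expression_cutoff: float = EXPRESSION_CUTOFF
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.expression_cutoff < 0:
            raise ValidationError("expression cutoff must be nonnegative")


@dataclass(frozen=True)
class DesignMatrix:
    """Rows: (inhibitor, dose) conditions; columns: expressed kinases;
    entries: fractional inhibition in [0, 1]; response: Delta k_p (per h)."""

    rows: tuple[tuple[str, float], ...]
    kinase_ids: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    growth_factor: str

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.rows), len(self.kinase_ids)):
            raise ValidationError("design matrix shape mismatch")
        if len(self.y) != len(self.rows):
            raise ValidationError("response length must equal row count")
        if np.any(self.X < 0) or np.any(self.X > 1):
            raise ValidationError("design entries must lie in [0, 1]")


@dataclass(frozen=True)
class KinaseRanking:
    """Non-zero-coefficient kinases of one growth factor, ordered by
    decreasing |coefficient|; ranks run 1..n. ``diagnostics`` carries the
    lambda grid, CV curve and selected lambda."""

    growth_factor: str
    entries: tuple[tuple[str, float, int], ...]  # (kinase_id, coef, rank)
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def kinase_ids(self) -> tuple[str, ...]:
        return tuple(k for k, _, _ in self.entries)

    def rank_of(self, kinase_id: str) -> int | None:
        for k, _, r in self.entries:
            if k == kinase_id:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["kinase_id", "coefficient", "rank"]
        ).assign(growth_factor=self.growth_factor)


@dataclass(frozen=True)
class IntersectionResult:
    """Kinases selected under every growth factor, ordered by ascending
    rank sum (ties broken lexicographically by kinase id)."""

    kinases: tuple[tuple[str, int, tuple[int, ...]], ...]
    growth_factors: tuple[str, ...]

    @property
    def kinase_ids(self) -> tuple[str, ...]:
        return tuple(k for k, _, _ in self.kinases)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, rs, ranks in self.kinases:
            row = {"kinase_id": k, "rank_sum": rs}
            row.update(
                {f"rank_{gf}": r for gf, r in zip(self.growth_factors, ranks)}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def filter_by_expression(
    inhibition: InhibitionMatrix,
    panel: KinasePanel,
    cutoff: float = EXPRESSION_CUTOFF,
) -> InhibitionMatrix:
    """Restrict an inhibition matrix to kinases expressed at/above cutoff.

    Column order is preserved; a kinase present in the matrix but absent
    from the expression panel is an error.
    """
    expr = dict(zip(panel.kinase_ids, panel.expression))
    missing = [k for k in inhibition.kinase_ids if k not in expr]
    if missing:
        raise ValidationError(f"kinases missing from expression panel: {missing[:5]}")
    keep = [k for k in inhibition.kinase_ids if expr[k] >= cutoff]
    return inhibition.subset_kinases(keep)


def build_design(
    inhibition: InhibitionMatrix,
    dose_ladder_uM: Sequence[float],
    phenotypes: pd.DataFrame,
    growth_factor: str,
) -> DesignMatrix:
    """Assemble the regression problem for one growth factor.

    Rows follow the phenotype table's (inhibitor, dose) conditions for that
    growth factor; entry (row, k) is the dose-mapped fractional inhibition
    of kinase k. The response is the replicate-averaged Delta k_p.
    """
    sub = phenotypes[phenotypes["growth_factor"] == growth_factor]
    if sub.empty:
        raise MissingDataError(f"no phenotype rows for {growth_factor!r}")
    known = set(inhibition.inhibitor_ids)
    ladder = {round(float(d), 12) for d in dose_ladder_uM}
    offenders = [
        (i, d)
        for i, d in zip(sub["inhibitor_id"], sub["dose_uM"])
        if i not in known or round(float(d), 12) not in ladder
    ]
    if offenders:
        raise MissingDataError(
            f"phenotype rows without a biochemical profile/ladder dose: "
            f"{offenders[:5]}"
        )
    rows = []
    X = np.empty((len(sub), len(inhibition.kinase_ids)))
    for r, (inh_id, dose) in enumerate(zip(sub["inhibitor_id"], sub["dose_uM"])):
        X[r] = inhibition_at_dose(
            inhibition.row(inh_id), inhibition.assay_conc_uM, float(dose)
        )
        rows.append((inh_id, float(dose)))
    return DesignMatrix(
        rows=tuple(rows),
        kinase_ids=inhibition.kinase_ids,
        X=X,
        y=sub["delta_kp"].to_numpy(dtype=float),
        growth_factor=growth_factor,
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def elastic_net_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Solve the glmnet-convention elastic net at one fixed lambda.

    Returns (coefficients on the original feature scale, intercept).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # harmless alpha=0 advisory
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=tol, max_iter=max_iter
        )
        model.fit(Xs, y)
    coef = model.coef_ / sd
    intercept = float(model.intercept_ - (model.coef_ / sd) @ mu)
    return coef, intercept


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, config: KirConfig) -> np.ndarray:
    yc = y - y.mean()
    # smallest lambda that zeroes every coefficient under the L1 part
    lam_max = np.max(np.abs(Xs.T @ yc)) / (len(y) * max(config.alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def fit_kir(
    design: DesignMatrix, config: KirConfig = KirConfig(), seed: int = 0
) -> KinaseRanking:
    """Cross-validated elastic-net fit and kinase ranking.

    The lambda path is fit within each of ``cv_folds`` shuffled folds
    (seeded); lambda is selected at the minimum mean CV squared error, the
    model refit on all rows at that lambda, and the kinases with non-zero
    coefficients returned ranked by |coefficient| (descending, ties broken
    by kinase id). A zero-variance response yields an empty ranking with a
    warning.
    """
    X, y = design.X, design.y
    if len(y) < 2 * config.cv_folds:
        raise ValidationError(
            f"need at least {2 * config.cv_folds} rows for {config.cv_folds}-fold CV"
        )
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValidationError("design contains missing values")
    if float(np.var(y)) == 0.0:
        warnings.warn(
            f"{design.growth_factor}: response has zero variance; empty ranking",
            stacklevel=2,
        )
        return KinaseRanking(design.growth_factor, (), {"lambda": None})

    if config.standardize:
        Xs, _, sd = _standardize(X)
    else:
        Xs, sd = X, np.ones(X.shape[1])
    lambdas = _lambda_grid(Xs, y, config)

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((config.cv_folds, len(lambdas)))
    for f, (tr, va) in enumerate(kf.split(Xs)):
        ytr = y[tr]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # path ends may stop at max_iter
            _, coefs, _ = enet_path(
                Xs[tr],
                ytr - ytr.mean(),
                l1_ratio=config.alpha,
                alphas=lambdas,
                tol=1e-4,
                max_iter=2_000,
                precompute=True,
            )
        pred = Xs[va] @ coefs + ytr.mean()
        mse[f] = ((pred - y[va, None]) ** 2).mean(axis=0)
    cv_mse = mse.mean(axis=0)
    best = int(np.argmin(cv_mse))
    lam = float(lambdas[best])

    coef, intercept = elastic_net_fit(
        X, y, lam, config.alpha, standardize=config.standardize
    )
    nz = np.flatnonzero(coef != 0.0)
    order = sorted(nz, key=lambda j: (-abs(coef[j]), design.kinase_ids[j]))
    entries = tuple(
        (design.kinase_ids[j], float(coef[j]), r + 1) for r, j in enumerate(order)
    )
    diagnostics = {
        "lambda": lam,
        "lambda_grid": lambdas.tolist(),
        "cv_mse": cv_mse.tolist(),
        "intercept": intercept,
        "n_nonzero": len(entries),
        "alpha": config.alpha,
        "seed": seed,
    }
    return KinaseRanking(design.growth_factor, entries, diagnostics)


def intersect_rank_sum(rankings: Sequence[KinaseRanking]) -> IntersectionResult:
    """Kinases selected under every growth factor, ordered by rank sum."""
    if len(rankings) < 2:
        raise ValidationError("need at least two rankings to intersect")
    common = set(rankings[0].kinase_ids)
    for r in rankings[1:]:
        common &= set(r.kinase_ids)
    rows = []
    for k in common:
        ranks = tuple(r.rank_of(k) for r in rankings)
        rows.append((k, int(sum(ranks)), ranks))
    rows.sort(key=lambda t: (t[1], t[0]))
    return IntersectionResult(
        kinases=tuple(rows),
        growth_factors=tuple(r.growth_factor for r in rankings),
    )


def recovery_metrics(
    rankings: Sequence[KinaseRanking],
    intersection: IntersectionResult,
    truth: GroundTruth,
    top_n: int = 10,
) -> dict:
    """Compare KIR output with the generating ground truth.

    Reports, per growth factor, how many true kinases fall in the top
    ``top_n`` by |coefficient| and precision/recall of the non-zero set, and
    whether the shared kinases all appear in the intersection.
    """
    per_gf = {}
    for r in rankings:
        true_set = set(truth.weights.get(r.growth_factor, {}))
        top = set(r.kinase_ids[:top_n])
        selected = set(r.kinase_ids)
        per_gf[r.growth_factor] = {
            "n_true": len(true_set),
            "true_in_top": len(true_set & top),
            "precision": (len(true_set & selected) / len(selected))
            if selected
            else 0.0,
            "recall": (len(true_set & selected) / len(true_set)) if true_set else 1.0,
        }
    shared = set(truth.shared_kinases)
    return {
        "per_growth_factor": per_gf,
        "top_n": top_n,
        "shared_kinases": sorted(shared),
        "shared_recovered": sorted(shared & set(intersection.kinase_ids)),
        "all_shared_recovered": shared <= set(intersection.kinase_ids),
    }
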