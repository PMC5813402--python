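"""Sub-model construction: penalized Cox selection, set union, stepwise AIC.

Dimensionality reduction for p >> n survival data yields different gene
subsets depending on the selection route; each subset defines a sub-model
whose martingale residuals feed the rank-product consensus.  The penalized
path (Lasso / elastic net) is delegated to scikit-survival's coxnet; the
penalty strength is chosen by cross-validated partial likelihood
(Verweij-van Houwelingen), i.e. the held-out contribution
ll(all) - ll(train) summed over folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .survival_core import (
    CoxModelFit,
    SurvivalDataset,
    cox_log_partial_likelihood,
    fit_cox_ph,
    martingale_residuals,
)

__all__ = [
    "GeneSet",
    "SubModel",
    "select_penalized",
    "union_gene_sets",
    "stepwise_aic",
    "build_submodel",
    "null_log_partial_likelihood",
]

Provenance = Literal["lasso", "elastic_net", "union", "stepwise_aic", "fixed_list", "resample"]
LambdaRule = Literal["cv_min", "cv_1se", "fixed"]


@dataclass
class GeneSet:
    names: list[str]
    provenance: str

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate gene names in set")

    def __len__(self):
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass
class SubModel:
    label: str
    genes: GeneSet
    fit: CoxModelFit
    residuals: np.ndarray


def select_penalized(
    data: SurvivalDataset,
    mixing: float = 1.0,
    lambda_rule: LambdaRule = "cv_min",
    folds: int = 10,
    seed: int = 0,
    fixed_lambda: float | None = None,
    candidates: Sequence[str] | None = None,
    n_alphas: int = 50,
) -> GeneSet:
    """Genes with nonzero coefficient in a penalized Cox fit.

    ``mixing`` is the elastic-net mixing parameter: 1.0 is the Lasso, values
    in (0, 1) blend in an L2 penalty.  Covariates are standardized for the
    penalized fit.  An empty selection (full shrinkage) is a valid result,
    not an error.
    """
    if not 0.0 < mixing <= 1.0:
        raise ValueError("mixing must be in (0, 1]")
    if data.n_events == 0:
        raise ValueError("no events in the data")
    genes = list(candidates) if candidates is not None else list(data.gene_names)
    provenance = "lasso" if mixing == 1.0 else "elastic_net"
    if lambda_rule == "fixed":
        if fixed_lambda is None:
            raise ValueError("fixed_lambda required when lambda_rule='fixed'")
        if np.isinf(fixed_lambda):
            return GeneSet([], provenance)
        if fixed_lambda == 0.0:
            # no shrinkage: every coefficient is almost surely nonzero
            return GeneSet(genes, provenance)

    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    idx = data.gene_index(genes)
    X = data.X[:, idx]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0.0] = 1.0
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event=data.status.astype(bool), time=data.time)

    def _fit_path(Xf, yf, alphas=None):
        kw = dict(l1_ratio=mixing, alpha_min_ratio=0.01, n_alphas=n_alphas,
                  normalize=False, fit_baseline_model=False)
        if alphas is not None:
            kw["alphas"] = alphas
        model = CoxnetSurvivalAnalysis(**kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xf, yf)
        return model

    if lambda_rule == "fixed":
        model = _fit_path(Xs, y, alphas=[fixed_lambda])
        coefs = model.coef_[:, 0]
        return GeneSet([g for g, c in zip(genes, coefs) if c != 0.0], provenance)

    path = _fit_path(Xs, y)
    alphas = np.asarray(path.alphas_)
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(data.n) % folds)
    cvpl = np.zeros((folds, len(alphas)))
    for f in range(folds):
        train = fold_of != f
        if data.status[train].sum() == 0:
            continue
        try:
            m = _fit_path(Xs[train], Surv.from_arrays(
                event=data.status[train].astype(bool), time=data.time[train]), alphas=alphas)
        except Exception:
            continue
        for a in range(len(alphas)):
            beta = m.coef_[:, a]
            ll_all = cox_log_partial_likelihood(beta, Xs, data.time, data.status)
            ll_train = cox_log_partial_likelihood(
                beta, Xs[train], data.time[train], data.status[train])
            cvpl[f, a] = ll_all - ll_train
    mean_cv = cvpl.mean(axis=0)
    best = int(np.argmax(mean_cv))
    if lambda_rule == "cv_1se":
        se = cvpl.std(axis=0, ddof=1) / np.sqrt(folds)
        ok = mean_cv >= mean_cv[best] - se[best]
        best = int(np.flatnonzero(ok)[0])  # alphas_ are sorted decreasing
    elif lambda_rule != "cv_min":
        raise ValueError(f"unknown lambda_rule: {lambda_rule!r}")
    coefs = path.coef_[:, best]
    return GeneSet([g for g, c in zip(genes, coefs) if c != 0.0], provenance)


def union_gene_sets(sets: Sequence[GeneSet], dataset_order: Sequence[str] | None = None) -> GeneSet:
    """Set-theoretic union, ordered by the dataset gene order when given."""
    seen: dict[str, None] = {}
    for s in sets:
        for g in s:
            seen.setdefault(g, None)
    names = list(seen)
    if dataset_order is not None:
        pos = {g: i for i, g in enumerate(dataset_order)}
        names.sort(key=lambda g: pos.get(g, len(pos)))
    return GeneSet(names, "union")


def null_log_partial_likelihood(data: SurvivalDataset) -> float:
    """Breslow log partial likelihood of the covariate-free model."""
    ll = 0.0
    for t in np.unique(data.time[data.status == 1]):
        d = int(((data.time == t) & (data.status == 1)).sum())
        ll -= d * np.log(float((data.time >= t).sum()))
    return ll


def stepwise_aic(
    data: SurvivalDataset,
    candidates: GeneSet | Sequence[str],
    direction: Literal["backward", "forward", "both"] = "both",
    ties: str = "breslow",
) -> GeneSet:
    """Greedy single-gene add/drop search minimizing AIC = -2 ll + 2 |genes|.

    Starts from the full candidate model (backward/both) or the empty model
    (forward); ties in AIC are broken by candidate order, so the result is
    deterministic given the data and candidate ordering.  The empty model is
    a legal state (its AIC uses the covariate-free partial likelihood).
    """
    cand = list(candidates.names if isinstance(candidates, GeneSet) else candidates)
    null_aic = -2.0 * null_log_partial_likelihood(data)

    def model_aic(genes: list[str]) -> float:
        if not genes:
            return null_aic
        fit = fit_cox_ph(data, genes, ties=ties)
        return fit.aic

    if not cand:
        return GeneSet([], "stepwise_aic")
    current = [] if direction == "forward" else list(cand)
    try:
        current_aic = model_aic(current)
    except Exception as err:
        raise ValueError(
            "full candidate model could not be fitted; "
            f"use a smaller candidate set ({err})"
        ) from err
    while True:
        best_move, best_aic = None, current_aic
        moves: list[tuple[str, str]] = []
        if direction in ("backward", "both"):
            moves += [("drop", g) for g in cand if g in current]
        if direction in ("forward", "both"):
            moves += [("add", g) for g in cand if g not in current]
        for op, g in moves:
            trial = [x for x in current if x != g] if op == "drop" else current + [g]
            trial = [x for x in cand if x in trial]  # canonical candidate order
            try:
                a = model_aic(trial)
            except Exception:
                continue
            if a < best_aic - 1e-10:
                best_move, best_aic = (op, g), a
        if best_move is None:
            break
        op, g = best_move
        current = [x for x in current if x != g] if op == "drop" else current + [g]
        current = [x for x in cand if x in current]
        current_aic = best_aic
    return GeneSet(current, "stepwise_aic")


def build_submodel(data: SurvivalDataset, genes: GeneSet | Sequence[str], label: str) -> SubModel:
    """Fit a Cox sub-model on ``genes`` and attach its martingale residuals.

    Gene symbols absent from the expression matrix are dropped with a
    warning (mirroring list-based sub-models built from external gene
    catalogues); if none remain, that is an error.
    """
    names = list(genes.names if isinstance(genes, GeneSet) else genes)
    provenance = genes.provenance if isinstance(genes, GeneSet) else "fixed_list"
    present = [g for g in names if g in set(data.gene_names)]
    missing = [g for g in names if g not in set(data.gene_names)]
    if missing:
        warnings.warn(
            f"sub-model {label!r}: genes not in expression matrix, discarded: {missing}",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"sub-model {label!r}: no genes present in the data")
    fit = fit_cox_ph(data, present)
    res = martingale_residuals(fit, data)
    return SubModel(label=label, genes=GeneSet(present, provenance), fit=fit, residuals=res)
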