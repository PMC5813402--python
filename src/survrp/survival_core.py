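"""Clinical record cleaning, Cox model fitting, and martingale residuals.

The Cox proportional hazards model assumes a hazard h(t | x) = h0(t)
exp(beta' x) for covariates x (here, gene expression).  After fitting, the
martingale residual of subject i,

    r_i = delta_i - H0(t_i) * exp(beta' x_i),

is the observed minus model-expected number of events on (0, t_i]; it lies in
(-inf, 1].  Large negative residuals mark subjects who lived far longer than
their covariates predict (long-term survivors); values near one mark subjects
who died much earlier than predicted.  H0 is the Breslow step estimator of
the cumulative baseline hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "SurvivalDataset",
    "CoxModelFit",
    "ConvergenceError",
    "clean_clinical",
    "load_clinical",
    "load_expression",
    "assemble_dataset",
    "fit_cox_ph",
    "breslow_cumulative_hazard",
    "martingale_residuals",
    "cox_log_partial_likelihood",
]

Ties = Literal["breslow", "efron"]


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximized reliably."""


# ---------------------------------------------------------------------------
# clinical cleaning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    days_to_last_followup: int | None = None
    days_to_death: int | None = None
    vital_status: str | None = None  # "alive" / "deceased" / None


def clean_clinical(
    records: Sequence[ClinicalRecord],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop internally inconsistent clinical records.

    A record is kept iff (i) whenever both day attributes are present they
    agree, and (ii) it is not recorded as deceased with a missing
    days-to-death.  Records with no usable day field at all are dropped too.
    Returns (kept sample ids, [(dropped id, reason), ...]).
    """
    if not records:
        raise ValueError("no clinical records supplied")
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        fup, death = rec.days_to_last_followup, rec.days_to_death
        deceased = (rec.vital_status or "").strip().lower() in {"deceased", "dead"}
        if deceased and death is None:
            dropped.append((rec.sample_id, "deceased_missing_days"))
        elif fup is not None and death is not None and fup != death:
            dropped.append((rec.sample_id, "day_mismatch"))
        elif fup is None and death is None:
            dropped.append((rec.sample_id, "no_day_information"))
        else:
            kept.append(rec.sample_id)
    return kept, dropped


_DEFAULT_CLINICAL_COLUMNS = {
    "followup": "days_to_last_followup",
    "death": "days_to_death",
    "vital": "vital_status",
}


def load_clinical(
    path,
    sample_col: str = "sample_id",
    columns: dict[str, str] | None = None,
) -> list[ClinicalRecord]:
    """Read a clinical TSV/CSV into records (delimiter sniffed from suffix)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={sample_col: str})
    cols = dict(_DEFAULT_CLINICAL_COLUMNS)
    if columns:
        cols.update(columns)
    records = []
    for _, row in df.iterrows():
        def _day(col):
            v = row.get(col)
            if pd.isna(v):
                return None
            return int(v)

        vital = row.get(cols["vital"])
        records.append(
            ClinicalRecord(
                sample_id=str(row[sample_col]),
                days_to_last_followup=_day(cols["followup"]),
                days_to_death=_day(cols["death"]),
                vital_status=None if pd.isna(vital) else str(vital),
            )
        )
    return records


def load_expression(path, sample_col: str | None = None) -> pd.DataFrame:
    """Read a samples x genes expression matrix (first column = sample IDs)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# the dataset container
# ---------------------------------------------------------------------------


@dataclass
class SurvivalDataset:
    """Aligned survival times, event indicators and covariate matrix.

    ``time`` is in days, ``status`` is 1 for an observed event (death) and 0
    for censoring, and ``X`` holds one row of gene-expression covariates per
    sample.
    """

    sample_ids: list[str]
    time: np.ndarray
    status: np.ndarray
    X: np.ndarray
    gene_names: list[str]

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if n < 2:
            raise ValueError("need at least two samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.time.shape != (n,) or self.status.shape != (n,):
            raise ValueError("time/status must align with sample_ids")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be 0/1")
        if self.X.shape[0] != n or self.X.shape[1] != len(self.gene_names):
            raise ValueError("X shape must be (n samples, p genes)")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(
                "expression matrix contains missing values; impute or drop upstream"
            )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.gene_names)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in dataset: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)


def assemble_dataset(
    expression: pd.DataFrame,
    records: Sequence[ClinicalRecord],
    drop_inconsistent: bool = True,
) -> tuple[SurvivalDataset, list[tuple[str, str]]]:
    """Join an expression matrix with cleaned clinical records.

    Samples must appear in both tables; expression matrices stored
    genes x samples are auto-detected by ID overlap and transposed.
    Returns the dataset plus the list of dropped records.
    """
    by_id = {r.sample_id: r for r in records}
    overlap_rows = len(set(expression.index) & set(by_id))
    overlap_cols = len(set(map(str, expression.columns)) & set(by_id))
    if overlap_cols > overlap_rows:
        expression = expression.T
        expression.index = expression.index.astype(str)
    if drop_inconsistent:
        kept_ids, dropped = clean_clinical(list(records))
    else:
        kept_ids, dropped = [r.sample_id for r in records], []
    ids = [s for s in expression.index if s in set(kept_ids)]
    if not ids:
        raise ValueError(
            "no samples shared between expression matrix and clinical table; "
            f"expression ids look like {list(expression.index[:3])!r}"
        )
    time = np.empty(len(ids))
    status = np.empty(len(ids), dtype=int)
    for i, s in enumerate(ids):
        rec = by_id[s]
        deceased = (rec.vital_status or "").strip().lower() in {"deceased", "dead"}
        status[i] = 1 if deceased else 0
        day = rec.days_to_death if deceased else rec.days_to_last_followup
        if day is None:  # fall back to whichever field is present
            day = rec.days_to_death if rec.days_to_death is not None else rec.days_to_last_followup
        time[i] = float(day)
    keep = time > 0
    if not np.all(keep):
        for s in np.asarray(ids)[~keep]:
            dropped.append((str(s), "nonpositive_time"))
        ids = [s for s, k in zip(ids, keep) if k]
        time, status = time[keep], status[keep]
        expression = expression.loc[ids]
    data = SurvivalDataset(
        sample_ids=list(ids),
        time=time,
        status=status,
        X=expression.loc[ids].to_numpy(dtype=float),
        gene_names=[str(g) for g in expression.columns],
    )
    return data, dropped


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def _risk_structures(time: np.ndarray, status: np.ndarray):
    """Sorted unique event times, event counts and membership masks."""
    order = np.argsort(time, kind="stable")
    return order


def cox_log_partial_likelihood(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    ties: Ties = "breslow",
) -> float:
    """Log partial likelihood at ``beta`` (Breslow or Efron tie handling)."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[status == 1]):
        d_mask = (time == t) & (status == 1)
        at_risk = time >= t
        d = int(d_mask.sum())
        s_risk = w[at_risk].sum()
        ll += eta[d_mask].sum()
        if ties == "breslow" or d == 1:
            ll -= d * np.log(s_risk)
        elif ties == "efron":
            s_tied = w[d_mask].sum()
            for j in range(d):
                ll -= np.log(s_risk - (j / d) * s_tied)
        else:
            raise ValueError(f"unknown ties convention: {ties!r}")
    return float(ll)


def _breslow_score_info(beta, X, time, status):
    """Score vector and observed information for the Breslow partial likelihood."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    p = X.shape[1]
    score = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(time[status == 1]):
        d_mask = (time == t) & (status == 1)
        at_risk = time >= t
        d = int(d_mask.sum())
        wr = w[at_risk]
        Xr = X[at_risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        xbar = s1 / s0
        score += X[d_mask].sum(axis=0) - d * xbar
        s2 = (Xr * wr[:, None]).T @ Xr
        info += d * (s2 / s0 - np.outer(xbar, xbar))
    return score, info


@dataclass
class BreslowCumhaz:
    """Right-continuous non-decreasing step function H0(t), H0(0) = 0."""

    event_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        self.cum = np.cumsum(self.increments)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        values = np.concatenate(([0.0], self.cum))
        out = values[idx]
        return out if out.shape else float(out)


@dataclass
class CoxModelFit:
    genes: list[str]
    beta: np.ndarray
    baseline_cumhaz: BreslowCumhaz
    log_partial_likelihood: float
    n_params: int
    ties: str
    se: np.ndarray | None = None
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_partial_likelihood + 2.0 * self.n_params


def fit_cox_ph(
    data: SurvivalDataset,
    genes: Sequence[str] | None = None,
    ties: Ties = "breslow",
) -> CoxModelFit:
    """Maximize the Cox partial likelihood over the given gene subset.

    Constant (zero-variance) covariates leave the partial likelihood flat in
    their coefficient; they are assigned beta = 0 with a warning.  Raises
    ``ValueError`` when there are no events and ``ConvergenceError`` when the
    likelihood is monotone (separation), naming the offending covariates.
    """
    genes = list(genes) if genes is not None else list(data.gene_names)
    if not genes:
        raise ValueError("at least one gene is required")
    if data.n_events == 0:
        raise ValueError("no events in the data; a Cox model cannot be fitted")
    idx = data.gene_index(genes)
    X = data.X[:, idx]
    sd = X.std(axis=0)
    constant = sd == 0.0
    if int((~constant).sum()) >= max(data.n_events, 1) and (~constant).any():
        raise ValueError(
            f"{int((~constant).sum())} free covariates with only "
            f"{data.n_events} events; reduce the gene set"
        )
    dropped = [g for g, c in zip(genes, constant) if c]
    if dropped:
        warnings.warn(
            f"constant covariates assigned beta=0: {dropped}", stacklevel=2
        )
    beta = np.zeros(len(genes))
    active = ~constant
    if active.any():
        beta[active] = _maximize_partial_likelihood(
            X[:, active], data.time, data.status, ties,
            labels=[g for g, a in zip(genes, active) if a],
        )
    ll = cox_log_partial_likelihood(beta, X, data.time, data.status, ties)
    se = np.full(len(genes), np.nan)
    if active.any():
        _, info = _breslow_score_info(beta[active], X[:, active], data.time, data.status)
        try:
            cov = np.linalg.inv(info)
            se[active] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass
    H0 = _breslow_cumhaz_arrays(beta, X, data.time, data.status)
    return CoxModelFit(
        genes=genes,
        beta=beta,
        baseline_cumhaz=H0,
        log_partial_likelihood=ll,
        n_params=int(active.sum()),
        ties=ties,
        se=se,
        dropped_constant=dropped,
    )


def _maximize_partial_likelihood(X, time, status, ties, labels, tol=1e-9, max_iter=100):
    """Delegate optimization to scikit-survival, then verify the score norm."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=status.astype(bool), time=time)
    model = CoxPHSurvivalAnalysis(ties=ties, n_iter=max_iter, tol=tol, alpha=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model.fit(X, y)
        except Exception as err:  # singular information, overflow, ...
            raise ConvergenceError(
                f"Cox fit failed for covariates {labels}: {err}"
            ) from err
    beta = model.coef_
    if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 20):
        worst = [labels[i] for i in np.argsort(-np.abs(beta))[:3]]
        raise ConvergenceError(
            f"monotone likelihood (separation?) for covariates {worst}"
        )
    score, info = _breslow_score_info(beta, X, time, status) if ties == "breslow" else (None, None)
    if ties == "breslow" and score is not None:
        scale = max(1.0, float(np.abs(status).sum()))
        if np.linalg.norm(score) > 1e-4 * scale:
            worst = [labels[i] for i in np.argsort(-np.abs(score))[:3]]
            raise ConvergenceError(
                f"partial likelihood did not converge (score norm "
                f"{np.linalg.norm(score):.2e}); suspect covariates {worst}"
            )
    return beta


def _breslow_cumhaz_arrays(beta, X, time, status) -> BreslowCumhaz:
    w = np.exp(X @ np.asarray(beta, dtype=float))
    etimes = np.unique(time[status == 1])
    inc = np.empty(len(etimes))
    for j, t in enumerate(etimes):
        d = int(((time == t) & (status == 1)).sum())
        inc[j] = d / w[time >= t].sum()
    return BreslowCumhaz(event_times=etimes, increments=inc)


def breslow_cumulative_hazard(fit: CoxModelFit, data: SurvivalDataset) -> BreslowCumhaz:
    """Recompute the Breslow baseline cumulative hazard for ``fit`` on ``data``."""
    idx = data.gene_index(fit.genes)
    return _breslow_cumhaz_arrays(fit.beta, data.X[:, idx], data.time, data.status)


def martingale_residuals(fit: CoxModelFit, data: SurvivalDataset) -> np.ndarray:
    """r_i = delta_i - H0(t_i) exp(beta' x_i); values in (-inf, 1]."""
    idx = data.gene_index(fit.genes)
    eta = data.X[:, idx] @ fit.beta
    expected = fit.baseline_cumhaz(data.time) * np.exp(eta)
    return data.status - expected
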