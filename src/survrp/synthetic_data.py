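"""Synthetic survival cohorts with planted influential observations.

The generator emulates the shape of a large ovarian-cancer expression study:
hundreds of patients, thousands of correlated gene-expression covariates,
survival times in days from a proportional-hazards model with a sparse true
coefficient vector, independent censoring calibrated to a target rate, and a
small number of planted discrepant survivors.

Planted outliers perturb the recorded *time*, not the covariates: a
"long_survivor" is a high-risk patient whose recorded follow-up is inflated
by ``discrepancy_factor`` and censored; an "early_death" is a low-risk
patient whose recorded time is deflated and marked as an event.  This matches
the working definition of a survival outlier as an individual who lived far
longer (or died far sooner) than others with the same covariate pattern.

Times are rounded to whole days (>= 1), as in clinical follow-up tables, so
fixtures round-trip losslessly through the TSV readers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rank_product import RankMatrix
from .survival_core import SurvivalDataset, assemble_dataset, load_clinical, load_expression

__all__ = [
    "OutlierSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_null_ranks",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class OutlierSpec:
    type: str  # "long_survivor" or "early_death"
    count: int = 1
    discrepancy_factor: float = 10.0


@dataclass
class SyntheticSpec:
    """Cohort design parameters (defaults follow the emulated study's shape)."""

    n: int = 517
    p: int = 2000
    n_informative: int = 6
    beta_scale: float = 1.0
    block_size: int = 20
    block_rho: float = 0.3
    baseline: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    median_survival_days: float = 900.0
    censoring_rate: float = 0.45
    outliers: tuple[OutlierSpec, ...] = ()
    beta: tuple[float, ...] | None = None  # explicit coefficients (length p), overrides sparsity
    seed: int = 0

    def __post_init__(self):
        if self.beta is None and self.n_informative > self.p:
            raise ValueError("n_informative cannot exceed p")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if not 0.0 < self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in (0, 1)")
        if sum(o.count for o in self.outliers) > self.n:
            raise ValueError("more planted outliers than samples")


@dataclass
class SyntheticTruth:
    beta_true: np.ndarray
    outlier_ids: list[str]
    censor_times: np.ndarray
    latent_times: np.ndarray
    achieved_censoring: float


def _block_gaussian(rng, n, p, block_size, rho):
    """Standard-normal covariates with equicorrelated blocks."""
    X = rng.standard_normal((n, p))
    if rho <= 0.0 or block_size <= 1:
        return X
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        shared = rng.standard_normal(n)
        X[:, start:stop] = a * shared[:, None] + b * X[:, start:stop]
    return X


def _calibrate_censoring(rng, latent, target):
    """Exponential censoring rate theta with E[fraction censored] = target.

    P(C < t) = 1 - exp(-theta t); expected censored fraction is the mean of
    this over the latent event times, monotone in theta -> bisection.
    """
    def frac(theta):
        return float(np.mean(1.0 - np.exp(-theta * latent)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target and hi < 1e12:
        hi *= 10.0
    if frac(hi) < target:
        warnings.warn(f"target censoring {target} unattainable; achieved {frac(hi):.3f}")
        return hi
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def generate_cohort(spec: SyntheticSpec) -> tuple[SurvivalDataset, SyntheticTruth]:
    """Draw a cohort under proportional hazards with planted outliers."""
    rng = np.random.default_rng(spec.seed)
    X = _block_gaussian(rng, spec.n, spec.p, spec.block_size, spec.block_rho)
    if spec.beta is not None:
        beta = np.asarray(spec.beta, dtype=float)
        if beta.shape != (spec.p,):
            raise ValueError("explicit beta must have length p")
    else:
        beta = np.zeros(spec.p)
        informative = rng.choice(spec.p, size=spec.n_informative, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
        beta[informative] = signs * spec.beta_scale
    eta = X @ beta

    shape = 1.0 if spec.baseline == "exponential" else spec.weibull_shape
    # baseline scaled so the median *baseline* survival is median_survival_days
    h_med = np.log(2.0)
    scale = spec.median_survival_days / h_med ** (1.0 / shape)
    u = rng.uniform(size=spec.n)
    latent = scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)

    theta = _calibrate_censoring(rng, latent, spec.censoring_rate)
    censor = rng.exponential(1.0 / theta, size=spec.n)
    time = np.minimum(latent, censor)
    status = (latent <= censor).astype(int)

    ids = [f"S{i+1:04d}" for i in range(spec.n)]
    outlier_ids: list[str] = []
    taken: set[int] = set()
    order_desc = np.argsort(-eta)  # high risk first
    for ospec in spec.outliers:
        if ospec.discrepancy_factor <= 1.0:
            raise ValueError("discrepancy_factor must exceed 1")
        pool = order_desc if ospec.type == "long_survivor" else order_desc[::-1]
        picked = [i for i in pool if i not in taken][: ospec.count]
        for i in picked:
            taken.add(i)
            # Perturb the recorded time relative to the *typical* survival
            # scale: a long survivor is a high-risk patient recorded alive
            # at discrepancy_factor times the baseline median survival; an
            # early death is a low-risk patient dying at the baseline median
            # divided by the factor.  (Scaling the sample's own observed
            # time would barely move a high-risk patient, whose time is
            # short to begin with.)
            if ospec.type == "long_survivor":
                time[i] = spec.median_survival_days * ospec.discrepancy_factor
                status[i] = 0
            elif ospec.type == "early_death":
                time[i] = spec.median_survival_days / ospec.discrepancy_factor
                status[i] = 1
            else:
                raise ValueError(f"unknown outlier type: {ospec.type!r}")
            outlier_ids.append(ids[i])

    time = np.maximum(np.round(time), 1.0)  # whole days
    achieved = float(np.mean(status == 0))
    data = SurvivalDataset(
        sample_ids=ids,
        time=time,
        status=status,
        X=X,
        gene_names=[f"G{j+1:05d}" for j in range(spec.p)],
    )
    truth = SyntheticTruth(
        beta_true=beta,
        outlier_ids=outlier_ids,
        censor_times=censor,
        latent_times=latent,
        achieved_censoring=achieved,
    )
    return data, truth


def generate_null_ranks(n: int, k: int, seed: int = 0) -> RankMatrix:
    """k independent uniform permutations of {1..n} (the rank-product null)."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    rng = np.random.default_rng(seed)
    R = np.column_stack([rng.permutation(n) + 1 for _ in range(k)]).astype(float)
    return RankMatrix(R, [f"S{i+1:04d}" for i in range(n)], [f"null{j+1}" for j in range(k)])


def write_fixture(data: SurvivalDataset, truth: SyntheticTruth | None, directory) -> dict[str, Path]:
    """Write expression/clinical TSVs (plus truth JSON) that the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    expr = pd.DataFrame(data.X, index=pd.Index(data.sample_ids, name="sample_id"),
                        columns=data.gene_names)
    paths["expression"] = directory / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")

    rows = []
    for sid, t, s in zip(data.sample_ids, data.time, data.status):
        days = int(round(t))
        if s == 1:
            rows.append((sid, days, days, "deceased"))
        else:
            rows.append((sid, days, "", "alive"))
    clin = pd.DataFrame(rows, columns=["sample_id", "days_to_last_followup",
                                       "days_to_death", "vital_status"])
    paths["clinical"] = directory / "clinical.tsv"
    clin.to_csv(paths["clinical"], sep="\t", index=False)

    if truth is not None:
        nz = np.flatnonzero(truth.beta_true)
        payload = {
            "outlier_ids": truth.outlier_ids,
            "informative_genes": {data.gene_names[j]: float(truth.beta_true[j]) for j in nz},
            "achieved_censoring": truth.achieved_censoring,
        }
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_fixture(directory) -> tuple[SurvivalDataset, dict | None]:
    """Round-trip loader for :func:`write_fixture` output."""
    directory = Path(directory)
    expr = load_expression(directory / "expression.tsv")
    records = load_clinical(directory / "clinical.tsv")
    data, _dropped = assemble_dataset(expr, records)
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return data, truth
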