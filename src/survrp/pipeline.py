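"""End-to-end orchestration: clean -> sub-models -> residuals -> RP -> q-values.

The consensus table mirrors the usual reporting layout for this analysis:
one row per observation with its survival time and status, its martingale
residual rank under every sub-model, the rank product, the RP p-value and
the BH q-value, sorted by q ascending; observations with q <= alpha are the
flagged putative outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_selection import (
    GeneSet,
    SubModel,
    build_submodel,
    select_penalized,
    stepwise_aic,
    union_gene_sets,
)
from .multiple_testing import TestTable, bh_qvalues, declare_outliers
from .rank_product import (
    OutlyingnessMatrix,
    RankMatrix,
    rank_observations,
    rp_pvalues,
)
from .resampling_consensus import ResamplingConfig, run_resampling
from .survival_core import SurvivalDataset, assemble_dataset, load_clinical, load_expression

__all__ = ["AnalysisConfig", "OutlierReport", "run_full_analysis", "consensus_from_ranks", "read_gene_list"]

log = logging.getLogger(__name__)


def read_gene_list(path) -> list[str]:
    """One symbol per line; '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.append(sym)
    return out


@dataclass
class AnalysisConfig:
    expression: str
    clinical: str
    submodels: list[dict[str, Any]] = field(default_factory=list)
    direction: str = "ascending"
    tie_method: str = "midrank"
    rp_method: str = "auto"
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "survrp_out"
    resampling: dict[str, Any] | None = None
    clinical_columns: dict[str, str] | None = None

    def __post_init__(self):
        if not self.submodels and self.resampling is None:
            raise ValueError("configure at least one sub-model or enable resampling")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class OutlierReport:
    consensus: pd.DataFrame
    outliers: list[str]
    table: TestTable
    submodels: list[SubModel]
    dropped_records: list[tuple[str, str]]


def _build_configured_submodel(data: SurvivalDataset, spec: dict[str, Any], seed: int) -> SubModel:
    label = spec.get("label") or spec["source"]
    source = spec["source"]
    if source == "fixed_list":
        genes = spec.get("genes") or read_gene_list(spec["genes_file"])
        return build_submodel(data, GeneSet(list(dict.fromkeys(genes)), "fixed_list"), label)
    if source in ("lasso", "elastic_net"):
        mixing = spec.get("mixing", 1.0 if source == "lasso" else 0.5)
        sel = select_penalized(
            data, mixing=mixing, lambda_rule=spec.get("lambda_rule", "cv_min"),
            folds=spec.get("folds", 10), seed=seed,
            fixed_lambda=spec.get("fixed_lambda"),
        )
        if len(sel) == 0:
            raise ValueError(f"sub-model {label!r}: penalized selection returned no genes")
        return build_submodel(data, sel, label)
    if source == "union_stepwise":
        lasso = select_penalized(data, mixing=1.0, folds=spec.get("folds", 10), seed=seed)
        enet = select_penalized(
            data, mixing=spec.get("mixing", 0.5), folds=spec.get("folds", 10), seed=seed + 1
        )
        union = union_gene_sets([lasso, enet], dataset_order=data.gene_names)
        if len(union) == 0:
            raise ValueError(f"sub-model {label!r}: empty union of penalized selections")
        reduced = stepwise_aic(data, union, direction=spec.get("direction", "both"))
        if len(reduced) == 0:
            raise ValueError(f"sub-model {label!r}: stepwise AIC removed every gene")
        return build_submodel(data, reduced, label)
    raise ValueError(f"unknown sub-model source: {source!r}")


def consensus_from_ranks(
    R: RankMatrix,
    data: SurvivalDataset | None,
    rp_method: str = "auto",
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, TestTable, list[str]]:
    """RP p-values + BH q-values for a rank matrix, as a sorted report table."""
    results = rp_pvalues(R, method=rp_method, seed=seed)
    p = np.array([r.p_value for r in results])
    q = bh_qvalues(p, m=R.n)
    table = TestTable(sample_ids=list(R.sample_ids), p_values=p, q_values=q, m=R.n)
    outliers = declare_outliers(table, alpha=alpha)
    cols: dict[str, Any] = {"ID": R.sample_ids}
    if data is not None:
        pos = {s: i for i, s in enumerate(data.sample_ids)}
        cols["Time"] = [data.time[pos[s]] for s in R.sample_ids]
        cols["Status"] = [data.status[pos[s]] for s in R.sample_ids]
    for j, lab in enumerate(R.model_labels):
        cols[f"rank_{lab}"] = R.R[:, j]
    cols["RP"] = [r.rp for r in results]
    cols["p_value"] = p
    cols["q_value"] = q
    cols["outlier"] = q <= alpha
    df = pd.DataFrame(cols).sort_values("q_value", kind="stable").reset_index(drop=True)
    return df, table, outliers


def run_full_analysis(cfg: AnalysisConfig, data: SurvivalDataset | None = None) -> OutlierReport:
    """Run the whole consensus analysis and write report files.

    ``data`` may be supplied directly (bypassing file input) for programmatic
    use; otherwise the expression matrix and clinical table are read from the
    configured paths and cleaned.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dropped: list[tuple[str, str]] = []
    if data is None:
        expr = load_expression(cfg.expression)
        records = load_clinical(cfg.clinical, columns=cfg.clinical_columns)
        expr_ids = set(expr.index) | set(map(str, expr.columns))
        clin_ids = {r.sample_id for r in records}
        only_clin = sorted(clin_ids - expr_ids)
        if only_clin:
            raise ValueError(
                f"sample IDs in clinical table but not in expression matrix: {only_clin[:10]}"
                + (" ..." if len(only_clin) > 10 else "")
            )
        data, dropped = assemble_dataset(expr, records)

    submodels: list[SubModel] = []
    for i, spec in enumerate(cfg.submodels):
        sub = _build_configured_submodel(data, spec, seed=cfg.seed + 1000 * i)
        submodels.append(sub)

    columns = [s.residuals for s in submodels]
    labels = [s.label for s in submodels]
    if cfg.resampling is not None:
        rcfg = ResamplingConfig(seed=cfg.seed, **cfg.resampling)
        rmat = run_resampling(data, rcfg)
        Rall = np.column_stack(columns + [rmat.R[:, j] for j in range(rmat.k)]) if columns else rmat.R
        # residual columns are scores, resampling columns already ranks;
        # rank everything column-wise for a homogeneous matrix
        if columns:
            Z = OutlyingnessMatrix(Rall, list(data.sample_ids), labels + rmat.model_labels)
            R = rank_observations(Z, direction=cfg.direction, tie_method=cfg.tie_method)
        else:
            R = rmat
    else:
        Z = OutlyingnessMatrix(np.column_stack(columns), list(data.sample_ids), labels)
        R = rank_observations(Z, direction=cfg.direction, tie_method=cfg.tie_method)

    df, table, outliers = consensus_from_ranks(
        R, data, rp_method=cfg.rp_method, alpha=cfg.alpha, seed=cfg.seed
    )

    fmt = df.copy()
    if np.allclose(fmt["RP"], np.round(fmt["RP"])):
        fmt["RP"] = fmt["RP"].astype(np.int64)
    fmt["p_value"] = [f"{v:.2E}" for v in fmt["p_value"]]
    fmt["q_value"] = [f"{v:.4f}" for v in fmt["q_value"]]
    fmt.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    for s in submodels:
        pd.DataFrame({"ID": data.sample_ids, "martingale_residual": s.residuals}).to_csv(
            outdir / f"residuals_{s.label}.tsv", sep="\t", index=False
        )
    (outdir / "outliers.txt").write_text("".join(f"{s}\n" for s in outliers))
    _write_log(outdir / "run_log.txt", cfg, data, submodels, dropped, outliers)
    return OutlierReport(consensus=df, outliers=outliers, table=table,
                         submodels=submodels, dropped_records=dropped)


def _write_log(path, cfg, data, submodels, dropped, outliers):
    lines = [
        f"survrp {__version__}",
        f"seed: {cfg.seed}",
        f"samples: {data.n} (events: {data.n_events}), genes: {data.p}",
        f"config: {cfg}",
    ]
    for sid, reason in dropped:
        lines.append(f"dropped record: {sid} ({reason})")
    for s in submodels:
        lines.append(f"sub-model {s.label}: {len(s.genes)} genes "
                     f"(logPL={s.fit.log_partial_likelihood:.3f})")
    lines.append(f"outliers (q <= {cfg.alpha}): {', '.join(outliers) if outliers else 'none'}")
    Path(path).write_text("".join(f"{l}\n" for l in lines))
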