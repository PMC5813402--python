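"""Resampling consensus: many random-gene-subset sub-models feeding one RP test.

Each draw picks a random gene subset without replacement, runs penalized Cox
selection (elastic net) inside it, refits an unpenalized Cox model on the
selected genes, and ranks the martingale residuals.  Repeating this
``n_models`` times yields an n x n_models rank matrix whose rank-product
p-values measure how consistently each observation is flagged regardless of
which genes happened to be available.

Per-draw randomness is derived from the master seed with a counter-based
spawn, so columns are independent and insensitive to evaluation order, and
the full rank matrix is reproducible from the master seed alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model_selection import GeneSet, build_submodel, select_penalized
from .rank_product import RankMatrix
from .survival_core import SurvivalDataset

__all__ = ["ResamplingConfig", "resample_once", "run_resampling"]

log = logging.getLogger(__name__)


@dataclass
class ResamplingConfig:
    n_genes_per_draw: int = 1000
    n_models: int = 100
    mixing: float = 0.5
    lambda_rule: str = "cv_min"
    folds: int = 10
    seed: int = 0
    max_redraws: int = 5

    def __post_init__(self):
        if self.n_models < 2:
            raise ValueError("need at least two models")
        if self.n_genes_per_draw < 1:
            raise ValueError("n_genes_per_draw must be positive")


def _draw_rng(master_seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, counter]))


def resample_once(
    data: SurvivalDataset,
    cfg: ResamplingConfig,
    draw_seed: int,
) -> tuple[np.ndarray, GeneSet]:
    """One draw: gene subsample -> penalized selection -> refit -> ranks.

    Returns the ascending rank column (rank 1 = most negative martingale
    residual) and the selected gene set.  Draws whose penalized selection is
    empty are redrawn with fresh genes, up to ``cfg.max_redraws`` times.
    """
    if cfg.n_genes_per_draw > data.p:
        raise ValueError("n_genes_per_draw exceeds the number of genes")
    rng = _draw_rng(cfg.seed, draw_seed)
    last_err = None
    for attempt in range(cfg.max_redraws + 1):
        genes = [data.gene_names[j] for j in
                 rng.choice(data.p, size=cfg.n_genes_per_draw, replace=False)]
        cv_seed = int(rng.integers(0, 2**31 - 1))
        try:
            selected = select_penalized(
                data, mixing=cfg.mixing, lambda_rule=cfg.lambda_rule,
                folds=cfg.folds, seed=cv_seed, candidates=genes,
            )
        except Exception as err:  # pragma: no cover - surfaced after redraws
            last_err = err
            selected = GeneSet([], "resample")
        if len(selected) == 0:
            log.info("draw %s attempt %d: empty selection, redrawing", draw_seed, attempt)
            continue
        if len(selected) >= data.n_events:
            # keep the refit well-posed under heavy selection
            selected = GeneSet(selected.names[: data.n_events - 1], "resample")
        sub = build_submodel(data, GeneSet(selected.names, "resample"), f"resample-{draw_seed}")
        ranks = np.argsort(np.argsort(sub.residuals, kind="stable"), kind="stable") + 1.0
        return ranks, sub.genes
    raise RuntimeError(
        f"draw {draw_seed}: no genes selected after {cfg.max_redraws} redraws"
        + (f" (last error: {last_err})" if last_err else "")
    )


def run_resampling(data: SurvivalDataset, cfg: ResamplingConfig) -> RankMatrix:
    """Build the n x n_models rank matrix from independent draws."""
    columns = []
    labels = []
    for b in range(cfg.n_models):
        ranks, _genes = resample_once(data, cfg, draw_seed=b)
        columns.append(ranks)
        labels.append(f"model{b+1}")
    R = np.column_stack(columns)
    return RankMatrix(R, list(data.sample_ids), labels)
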