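"""Two-group per-gene differential expression between clusters.

Counts within each group are modeled as Poisson with a group rate; the null
is lambda_1 = lambda_2.  Two tests are provided:

* a two-sample t statistic with Poisson plug-in variances,
  t = (m1 - m2) / sqrt(m1/n1 + m2/n2), referred to the standard normal;
* a likelihood-ratio deviance, 2*(ll(m1) + ll(m2) - ll(pooled)),
  referred to chi^2 with 1 df.

Both are returned for every gene; Bonferroni adjustment is applied to the
chosen test's p-values at family size = number of genes.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CellLabels, CountMatrix

__all__ = ["de_table", "t_test_de", "poisson_lrt_de", "bonferroni", "write_de_table"]


def bonferroni(p_values: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Multiply each p by the family size (default: vector length), cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size must be >= number of p-values")
    return np.minimum(p * m, 1.0)


def _group_cells(m: CountMatrix, groups: CellLabels, group1: int, group2: int) -> tuple[np.ndarray, np.ndarray]:
    if groups.labels.shape[0] != m.n_cells:
        raise ValueError("labels do not match the cell axis")
    c1 = np.flatnonzero(groups.labels == group1)
    c2 = np.flatnonzero(groups.labels == group2)
    if c1.size == 0 or c2.size == 0:
        raise ValueError(f"groups {group1}/{group2} must both be nonempty")
    return c1, c2


def _poisson_ll_sum(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Row sums of Poisson logliks at per-row rate, dropping the X! constant.

    The constant cancels in the deviance; 0*log(0) = 0 at lam = 0 (where all
    counts are necessarily 0).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * np.log(lam)[:, None]
    term[np.broadcast_to(lam[:, None] == 0, term.shape)] = 0.0
    return term.sum(axis=1) - lam * counts.shape[1]


def de_table(
    m: CountMatrix,
    groups: CellLabels,
    group1: int = 0,
    group2: int = 1,
    test: Literal["lrt", "t"] = "lrt",
) -> pd.DataFrame:
    """Per-gene two-group DE table carrying both the t and the LRT statistics.

    ``test`` selects which p-value feeds the Bonferroni-adjusted column
    ``p_adj``.  Genes with both group means zero get t = 0, stat = 0, p = 1.
    The reported log2 fold change uses a pseudocount of 1/C for display only.
    """
    c1, c2 = _group_cells(m, groups, group1, group2)
    if test == "t" and (c1.size < 2 or c2.size < 2):
        raise ValueError("t-test needs >= 2 cells per group")
    x1 = m.subset(cells=c1).dense().astype(float)
    x2 = m.subset(cells=c2).dense().astype(float)
    n1, n2 = c1.size, c2.size
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    pooled = (n1 * m1 + n2 * m2) / (n1 + n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = (m1 - m2) / np.sqrt(m1 / n1 + m2 / n2)
    t_stat[~np.isfinite(t_stat)] = 0.0
    t_p = 2.0 * stats.norm.sf(np.abs(t_stat))

    lrt_stat = 2.0 * (
        _poisson_ll_sum(x1, m1) + _poisson_ll_sum(x2, m2)
        - _poisson_ll_sum(np.hstack([x1, x2]), pooled)
    )
    lrt_stat = np.maximum(lrt_stat, 0.0)
    lrt_p = stats.chi2.sf(lrt_stat, 1)

    eps = 1.0 / (n1 + n2)
    df = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "mean1": m1,
            "mean2": m2,
            "pooled_mean": pooled,
            "t_stat": t_stat,
            "t_p": t_p,
            "lrt_stat": lrt_stat,
            "lrt_p": lrt_p,
            "log2fc": np.log2((m1 + eps) / (m2 + eps)),
        }
    )
    df["p_adj"] = bonferroni(df["lrt_p" if test == "lrt" else "t_p"].to_numpy())
    return df


def t_test_de(m: CountMatrix, groups: CellLabels, group1: int = 0, group2: int = 1) -> pd.DataFrame:
    """DE table with ``p_adj`` driven by the plug-in t-test."""
    return de_table(m, groups, group1, group2, test="t")


def poisson_lrt_de(m: CountMatrix, groups: CellLabels, group1: int = 0, group2: int = 1) -> pd.DataFrame:
    """DE table with ``p_adj`` driven by the Poisson likelihood-ratio test."""
    return de_table(m, groups, group1, group2, test="lrt")


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
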