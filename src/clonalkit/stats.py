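"""Contingency-table statistics used across the pipeline.

Fisher's exact test for 2x2 tables (e.g. amplification status in primary
vs metastatic tumor cohorts) and a Monte-Carlo chi-square test for r x c
tables whose expected counts are too small for the asymptotic test (e.g.
ordinal tumor-burden scores across treatment groups).  The rank-sum
comparison lives in :mod:`clonalkit.phylogeny` and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .phylogeny import compare_branch_vafs as wilcoxon_rank_sum  # noqa: F401

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "chisq_monte_carlo",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(
    table: ContingencyTable2x2 | np.ndarray, two_sided: str = "min_likelihood"
) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    ``two_sided='min_likelihood'`` (default) sums the probabilities of
    every margin-consistent table whose hypergeometric probability does
    not exceed the observed table's.  ``'double_one_tail'`` doubles the
    smaller one-tailed p (capped at 1).  A table with a zero row or
    column margin carries no information and returns p = 1.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    if two_sided == "min_likelihood":
        return float(sps.fisher_exact(arr, alternative="two-sided")[1])
    if two_sided == "double_one_tail":
        p_less = float(sps.fisher_exact(arr, alternative="less")[1])
        p_greater = float(sps.fisher_exact(arr, alternative="greater")[1])
        return min(1.0, 2.0 * min(p_less, p_greater))
    raise ValueError(f"unknown two-sided convention {two_sided!r}")


def _chisq_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    mask = expected > 0
    return float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def chisq_monte_carlo(table, n_sim: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo chi-square p for an r x c table with fixed margins.

    Tables are sampled uniformly from the fixed-margin null (Patefield's
    algorithm) and the p value uses the add-one estimator
    ``(1 + #{chi2_sim >= chi2_obs}) / (n_sim + 1)``, which can never be
    zero.  Degenerate margins (a single non-empty row or column) give
    p = 1.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return 1.0
    expected = np.outer(rows, cols) / total
    observed_stat = _chisq_stat(obs, expected)
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows.astype(int), cols.astype(int))
    sims = sampler.rvs(n_sim, method="patefield", random_state=rng)
    stats = ((sims - expected) ** 2 / np.where(expected > 0, expected, 1.0))
    stats[:, expected == 0] = 0.0
    sim_stats = stats.sum(axis=(1, 2))
    n_extreme = int((sim_stats >= observed_stat - 1e-12).sum())
    return (1 + n_extreme) / (n_sim + 1)
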