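"""Pairwise anchor-vs-gene association screening.

For each candidate gene, a 2×2 contingency table against an anchor gene is
tested with Fisher's exact test (two-sided, minimum-likelihood convention)
and p-values are adjusted for the false-discovery rate by the
Benjamini-Hochberg step-up across the candidate family of that anchor.
Significance uses p_adj ≤ α (α = 0.05 by default).

A one-sample chi-squared test compares an observed mutation prevalence
against a published reference proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import MutationMatrix

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "contingency",
    "fisher_exact_two_sided",
    "odds_ratio",
    "bh_adjust",
    "screen",
    "prevalence_chi_squared",
    "write_association_tsv",
]


class AssociationError(ValueError):
    """Raised for invalid association inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: a = anchor+ gene+, b = anchor+ gene−, c = anchor− gene+,
    d = anchor− gene−."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise AssociationError(f"negative count {name}")
        if self.total < 1:
            raise AssociationError("contingency table must have at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class AssociationResult:
    anchor: str
    gene: str
    table: ContingencyTable
    odds_ratio: float
    p_raw: float
    p_adj: float
    significant: bool


def contingency(matrix: MutationMatrix, anchor: str, gene: str) -> ContingencyTable:
    """Cross-tabulate two gene columns of the cohort matrix."""
    if anchor == gene:
        raise AssociationError("anchor and gene must differ")
    x = matrix.column(anchor)
    y = matrix.column(gene)
    return ContingencyTable(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    Sums hypergeometric point probabilities, with fixed margins, of every
    table at most as likely as the observed one (relative tie tolerance
    1e-7).  Degenerate margins give p = 1 by convention.
    """
    if (table.a + table.b == 0 or table.c + table.d == 0
            or table.a + table.c == 0 or table.b + table.d == 0):
        return 1.0
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def odds_ratio(table: ContingencyTable) -> float:
    """Sample cross-product ratio a·d / (b·c).

    Infinity when b·c = 0 with a·d > 0; NaN when both products vanish.  No
    continuity correction is applied (the exact test stays exact).
    """
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j ≥ i}(p_(j) · m / j) over the ascending order
    statistics, capped at 1.  Hard error for values outside [0, 1].
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0.0) | (arr > 1.0)) or np.any(np.isnan(arr)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def screen(
    matrix: MutationMatrix,
    anchor: str,
    candidates: Iterable[str],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Fisher/FDR screen of an anchor against a candidate family.

    The BH adjustment runs across exactly this candidate family; a gene is
    significant iff its adjusted p-value is ≤ alpha.
    """
    candidates = list(candidates)
    if anchor in candidates:
        raise AssociationError("anchor must not be among the candidates")
    if not candidates:
        return []
    tables = [contingency(matrix, anchor, gene) for gene in candidates]
    p_raw = [fisher_exact_two_sided(t) for t in tables]
    p_adj = bh_adjust(p_raw)
    return [
        AssociationResult(
            anchor=anchor,
            gene=gene,
            table=t,
            odds_ratio=odds_ratio(t),
            p_raw=float(pr),
            p_adj=float(pa),
            significant=bool(pa <= alpha),
        )
        for gene, t, pr, pa in zip(candidates, tables, p_raw, p_adj)
    ]


def prevalence_chi_squared(
    observed_count: int, n: int, reference_proportion: float
) -> tuple[float, float]:
    """One-sample two-cell chi-squared test against a reference proportion.

    Returns (statistic, p) with 1 degree of freedom:
    Σ (obs − exp)² / exp over the mutated / unmutated cells.
    """
    if not 0 <= observed_count <= n:
        raise AssociationError("observed_count must lie in [0, n]")
    if not 0.0 < reference_proportion < 1.0:
        raise AssociationError("reference_proportion must lie strictly in (0, 1)")
    expected = np.array(
        [n * reference_proportion, n * (1.0 - reference_proportion)]
    )
    observed = np.array([observed_count, n - observed_count], dtype=float)
    statistic, p = stats.chisquare(observed, f_exp=expected)
    return float(statistic), float(p)


def write_association_tsv(
    results: Iterable[AssociationResult], path: str | Path
) -> None:
    results = list(results)
    frame = pd.DataFrame(
        {
            "anchor": [r.anchor for r in results],
            "gene": [r.gene for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [int(r.significant) for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
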