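"""Gene-set partitioning and nonparametric rate comparisons.

Genes are split into three mutually exclusive sets: approved drug targets
(ADT), essential non-targets (ESS) and the background of everything else
(ALL).  Rate ratios of the sets are compared pairwise with the two-sided
Mann–Whitney U test, and p-values are adjusted with the Benjamini–Yekutieli
step-up procedure across the whole family of tests (24 in the full
eight-species design).  ALL is background-only — targets and essentials are
removed — so the comparisons are not biased by overlapping membership.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneTable

logger = logging.getLogger(__name__)

LABELS = ("ADT", "ESS", "ALL")
COMPARISON_PAIRS = (("ADT", "ALL"), ("ADT", "ESS"), ("ESS", "ALL"))

# exact Mann-Whitney null up to this per-group size (no ties); beyond it the
# normal approximation with tie and continuity correction is used
EXACT_MAX_N = 8


@dataclass
class GeneSetPartition:
    """Mutually exclusive ADT/ESS/ALL labels covering the input genes."""

    labels: dict[str, str]

    def genes(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == label)

    def counts(self) -> dict[str, int]:
        c = Counter(self.labels.values())
        return {lab: c.get(lab, 0) for lab in LABELS}


def partition_genes(table: GeneTable) -> GeneSetPartition:
    """Assign every gene to exactly one of ADT, ESS, ALL.

    Drug targets are ADT regardless of essentiality; essential non-targets
    are ESS; the rest form the background set ALL.
    """
    labels: dict[str, str] = {}
    for rec in table.records:
        if rec.gene_id in labels:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        if rec.is_drug_target:
            labels[rec.gene_id] = "ADT"
        elif rec.is_essential:
            labels[rec.gene_id] = "ESS"
        else:
            labels[rec.gene_id] = "ALL"
    part = GeneSetPartition(labels)
    logger.info("partition counts: %s", part.counts())
    return part


def mann_whitney_u(x: Sequence[float], y: Sequence[float]
                   ) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` where U counts pairs in which x exceeds y (with half
    credit for ties).  The null distribution is exact when both groups are
    small (min n ≤ 8) and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used — mirroring
    R's ``wilcox.test`` switching rule in spirit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if min(x.size, y.size) <= EXACT_MAX_N and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_yekutieli(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Yekutieli step-up FDR adjustment, in input order.

    adj_(i) = min_{j ≥ i} min(1, m·c(m)·p_(j)/j) with c(m) = Σ 1/k, valid
    under arbitrary dependence of the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1].tolist()


def bootstrap_mean_ci(values: Sequence[float], n_resamples: int = 2000,
                      rng: Optional[np.random.Generator] = None,
                      level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(0)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    alpha = 100 * (1 - level) / 2
    low, high = np.percentile(means, [alpha, 100 - alpha])
    return float(low), float(high)


@dataclass
class GroupComparison:
    """One Mann–Whitney comparison between two gene sets of one species."""

    species: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    ci_a: tuple[float, float] = (float("nan"), float("nan"))
    ci_b: tuple[float, float] = (float("nan"), float("nan"))


def compare_groups(ratios: Mapping[str, float],
                   partition: GeneSetPartition,
                   species: str = "sim",
                   bootstrap_resamples: int = 2000,
                   seed: int = 0) -> list[GroupComparison]:
    """Run the three pairwise set comparisons for one species.

    ``ratios`` maps gene_id to its usable rate ratio; genes absent from the
    mapping (unusable estimates) are excluded.  Confidence intervals for
    set means come from a seeded percentile bootstrap.  ``p_adjusted`` is
    left NaN here — adjustment is applied jointly across the whole test
    family by :func:`adjust_comparisons`.
    """
    rng = np.random.default_rng(seed)
    values = {lab: np.array([ratios[g] for g in partition.genes(lab)
                             if g in ratios])
              for lab in LABELS}
    comparisons: list[GroupComparison] = []
    for a, b in COMPARISON_PAIRS:
        xa, xb = values[a], values[b]
        if xa.size < 2 or xb.size < 2:
            logger.warning("%s: skipping %s vs %s (set sizes %d, %d)",
                           species, a, b, xa.size, xb.size)
            continue
        u, p = mann_whitney_u(xa, xb)
        comparisons.append(GroupComparison(
            species=species, group_a=a, group_b=b,
            n_a=int(xa.size), n_b=int(xb.size),
            u_statistic=u, p_raw=p,
            mean_a=float(xa.mean()), mean_b=float(xb.mean()),
            ci_a=bootstrap_mean_ci(xa, bootstrap_resamples, rng),
            ci_b=bootstrap_mean_ci(xb, bootstrap_resamples, rng)))
    return comparisons


def adjust_comparisons(comparisons: Iterable[GroupComparison]
                       ) -> list[GroupComparison]:
    """Apply BY adjustment jointly across a family of comparisons, in place."""
    comparisons = list(comparisons)
    if not comparisons:
        return comparisons
    adjusted = benjamini_yekutieli([c.p_raw for c in comparisons])
    for comp, adj in zip(comparisons, adjusted):
        comp.p_adjusted = float(adj)
    return comparisons


def comparisons_to_frame(comparisons: Iterable[GroupComparison]
                         ) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "species": c.species, "group_a": c.group_a, "group_b": c.group_b,
            "n_a": c.n_a, "n_b": c.n_b, "U": c.u_statistic,
            "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
            "mean_a": c.mean_a, "ci_a_low": c.ci_a[0], "ci_a_high": c.ci_a[1],
            "mean_b": c.mean_b, "ci_b_low": c.ci_b[0], "ci_b_high": c.ci_b[1],
        })
    cols = ["species", "group_a", "group_b", "n_a", "n_b", "U", "p_raw",
            "p_adjusted", "mean_a", "ci_a_low", "ci_a_high", "mean_b",
            "ci_b_low", "ci_b_high"]
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "LABELS", "COMPARISON_PAIRS", "GeneSetPartition", "GroupComparison",
    "partition_genes", "mann_whitney_u", "benjamini_yekutieli",
    "bootstrap_mean_ci", "compare_groups", "adjust_comparisons",
    "comparisons_to_frame",
]
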