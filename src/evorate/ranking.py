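"""Genome-wide rate ranking, KO-group summaries, slow-decile selection.

Low ratio = slow evolution = strong purifying selection = attractive drug
target; rank 1 is therefore the slowest gene.  Percentiles use the mid-rank
convention (100·midrank/n).  KO orthology groups are summarised by the mean
and sample SD of their per-genome ratios, with SD fixed at 0 when a single
genome contributes.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedGene:
    gene_id: str
    ratio: float
    rank: int          # 1 = slowest; ordinal, ties broken by gene_id
    percentile: float  # 100 * midrank / n


def percentile_rank(estimates: Iterable[tuple[str, float]]
                    ) -> list[RankedGene]:
    """Rank genes ascending by ratio; ties receive mid-rank percentiles.

    The integer rank is ordinal (ties broken by gene_id) so ranks are a
    permutation of 1..n; the percentile uses the mid-rank, so equal ratios
    share a percentile.
    """
    items = sorted(estimates, key=lambda t: (t[1], t[0]))
    if not items:
        raise ValueError("no estimates to rank")
    n = len(items)
    midranks = rankdata([r for _, r in items], method="average")
    return [RankedGene(gene_id=g, ratio=float(r), rank=i + 1,
                       percentile=float(100.0 * mid / n))
            for i, ((g, r), mid) in enumerate(zip(items, midranks))]


@dataclass
class KoGroupSummary:
    """Mean ± sample SD of one KO orthology group across genomes."""

    ko_id: str
    gene_name: str
    per_genome_ratios: dict[str, float]
    mean: float
    sd: float


def summarize_ko_groups(assignments: Mapping[str, str],
                        per_genome_ratios: Mapping[str, Mapping[str, float]],
                        gene_names: Optional[Mapping[str, str]] = None,
                        ) -> list[KoGroupSummary]:
    """Summarise KO groups across genomes, sorted ascending by mean ratio.

    ``assignments`` maps gene_id to KO id; ``per_genome_ratios`` maps
    genome_id to its usable gene→ratio mapping.  A genome contributes one
    value per KO (the mean over its assigned usable genes, normally one).
    Slowest (lowest mean) groups sort first — the evolutionarily most
    attractive targets.
    """
    per_ko: dict[str, dict[str, float]] = {}
    for genome, ratios in per_genome_ratios.items():
        ko_values: dict[str, list[float]] = {}
        for gene, ratio in ratios.items():
            ko = assignments.get(gene)
            if ko is None:
                continue
            ko_values.setdefault(ko, []).append(ratio)
        for ko, vals in ko_values.items():
            per_ko.setdefault(ko, {})[genome] = sum(vals) / len(vals)
    summaries = []
    for ko in sorted(per_ko):
        vals = per_ko[ko]
        numbers = list(vals.values())
        mean = sum(numbers) / len(numbers)
        sd = statistics.stdev(numbers) if len(numbers) > 1 else 0.0
        summaries.append(KoGroupSummary(
            ko_id=ko, gene_name=(gene_names or {}).get(ko, ""),
            per_genome_ratios=dict(sorted(vals.items())),
            mean=mean, sd=sd))
    summaries.sort(key=lambda s: (s.mean, s.ko_id))
    return summaries


def select_slowest(ranked: list[RankedGene], fraction: float = 0.10
                   ) -> list[str]:
    """Select the slowest-evolving fraction of genes as the study set.

    Takes floor(fraction·n) genes with the smallest ratios; ties at the
    boundary are resolved deterministically by gene_id (logged).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ordered = sorted(ranked, key=lambda g: (g.ratio, g.gene_id))
    k = math.floor(fraction * len(ordered))
    if 0 < k < len(ordered) and ordered[k - 1].ratio == ordered[k].ratio:
        logger.info("study-set boundary tie at ratio %.6g broken by gene_id",
                    ordered[k].ratio)
    return [g.gene_id for g in ordered[:k]]


def ranking_to_frame(ranked: list[RankedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.ratio, g.rank, g.percentile) for g in ranked],
        columns=["gene_id", "ratio", "rank", "percentile"])


def ko_summary_to_frame(summaries: list[KoGroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.ko_id, s.gene_name, s.mean, s.sd, len(s.per_genome_ratios))
         for s in summaries],
        columns=["ko_id", "gene_name", "mean_ratio", "sd", "n_genomes"])


__all__ = [
    "RankedGene", "KoGroupSummary", "percentile_rank", "summarize_ko_groups",
    "select_slowest", "ranking_to_frame", "ko_summary_to_frame",
]
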