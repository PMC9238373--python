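"""Phylogenetically aggregated log-ratios between two internal nodes.

For a chosen numerator and denominator node, each sample's value is the
natural log of the ratio of summed counts across the tips under each node.
Because aggregation over a dense clade rarely sums to zero, these ratios
avoid the sample drop-out that plagues single-feature log-ratios; samples
with a zero sum on either side are nevertheless dropped and reported, never
pseudocounted.  Overlapping tip sets (one node ancestral to the other)
produce misleading ratios and are rejected outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny, tips_under

logger = logging.getLogger("phylorpca")

__all__ = ["LogRatioResult", "node_log_ratio", "lca_annotate"]


@dataclass
class LogRatioResult:
    """Per-sample aggregated log-ratio with provenance."""

    values: pd.Series  # natural-log ratio, dropped samples excluded
    numerator: str
    denominator: str
    numerator_tips: set[str]
    denominator_tips: set[str]
    numerator_sums: pd.Series
    denominator_sums: pd.Series
    dropped: list[str] = field(default_factory=list)


def node_log_ratio(
    table: pd.DataFrame, tree: Phylogeny, num: str, den: str
) -> LogRatioResult:
    """log(sum of counts under ``num`` / sum of counts under ``den``) per sample.

    Tips under either node that are absent from the table contribute zero.
    Raises if the two tip sets overlap (equivalently, if one node is an
    ancestor of the other) or if every sample is dropped.
    """
    num_tips = tips_under(tree, num)
    den_tips = tips_under(tree, den)
    shared = num_tips & den_tips
    if shared:
        raise ValueError(
            f"overlapping features between numerator and denominator: "
            f"{sorted(shared)[:5]}"
        )
    cols = set(table.columns)
    num_sums = table[sorted(num_tips & cols)].sum(axis=1)
    den_sums = table[sorted(den_tips & cols)].sum(axis=1)
    ok = (num_sums > 0) & (den_sums > 0)
    dropped = list(table.index[~ok])
    if not ok.any():
        raise ValueError("all samples dropped (zero numerator or denominator sum)")
    if dropped:
        logger.info("log-ratio %s/%s dropped %d samples", num, den, len(dropped))
    values = np.log(num_sums[ok] / den_sums[ok])
    values.name = f"log({num}/{den})"
    return LogRatioResult(
        values=values,
        numerator=num,
        denominator=den,
        numerator_tips=num_tips,
        denominator_tips=den_tips,
        numerator_sums=num_sums,
        denominator_sums=den_sums,
        dropped=dropped,
    )


def lca_annotate(tree: Phylogeny, node_id: str, taxonomy: dict[str, str]) -> str:
    """Longest common rank-prefix of the descendant tips' lineages.

    Lineages are semicolon-delimited rank strings (Greengenes style,
    ``k__...;p__...;...``).  Tips missing from ``taxonomy`` are skipped with
    a warning; if no tip has a lineage, raises.
    """
    tips = sorted(tips_under(tree, node_id))
    lineages = []
    for tip in tips:
        if tip in taxonomy:
            lineages.append([r.strip() for r in str(taxonomy[tip]).split(";")])
        else:
            warnings.warn(
                f"tip {tip!r} has no lineage; skipped", RuntimeWarning, stacklevel=2
            )
    if not lineages:
        raise ValueError(f"no taxonomy for any tip under {node_id!r}")
    prefix: list[str] = []
    for ranks in zip(*lineages):
        if all(r == ranks[0] for r in ranks):
            prefix.append(ranks[0])
        else:
            break
    return ";".join(prefix)
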