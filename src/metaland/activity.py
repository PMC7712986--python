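"""Gene activity from expression counts, and rule-based reaction partitions.

Raw read counts are scaled per sample by total coverage, thresholded
into binary gene activity (a gene is *active* when its scaled count
reaches the threshold, default 5 reads), and the gene rules of a
network are evaluated on each sample's activity to split rule-bearing
reactions into an expression-active set A and an expression-inactive
set I — the two sets the landscape MILP rewards for carrying /
not carrying flux.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gpr import GeneRule
from .network import MetabolicNetwork

__all__ = [
    "ActivityTable",
    "ReactionPartition",
    "read_counts_tsv",
    "scale_counts",
    "binarize",
    "evaluate_rule",
    "partition_reactions",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 5.0


@dataclass
class ActivityTable:
    """Binary genes x samples activity matrix plus the threshold used."""

    frame: pd.DataFrame  # genes x samples, entries in {0, 1}
    threshold: float = DEFAULT_THRESHOLD

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def sample_activity(self, sample: str) -> dict[str, int]:
        return self.frame[sample].astype(int).to_dict()


@dataclass
class ReactionPartition:
    """Rule-bearing reactions split by rule evaluation for one sample.

    A: rule true (expression supports activity); I: rule false;
    unconstrained: reactions without a rule.
    """

    A: tuple[str, ...]
    I: tuple[str, ...]
    unconstrained: tuple[str, ...]
    sample: str | None = None

    def __post_init__(self) -> None:
        sets = [set(self.A), set(self.I), set(self.unconstrained)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("partition sets must be disjoint")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate gene or sample ids in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in expression table")
    return df


def scale_counts(
    counts: pd.DataFrame, per_sample_totals: Sequence[float] | pd.Series | None = None
) -> pd.DataFrame:
    """Scale each sample by its total coverage, keeping count-like units.

    Each column is divided by its coverage total (by default the column
    sum, i.e. the area under the coverage curve) and multiplied by the
    median total, so a fixed read-count activity threshold stays
    meaningful after scaling.
    """
    if per_sample_totals is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(np.asarray(per_sample_totals, dtype=float), index=counts.columns)
    if len(totals) != counts.shape[1]:
        raise ValueError("need exactly one total per sample")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive coverage total for samples {bad}")
    return counts / totals * float(np.median(totals))


def binarize(counts: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> ActivityTable:
    """Threshold counts into binary activity: active iff count >= threshold."""
    if threshold < 0:
        raise ValueError("activity threshold must be non-negative")
    binary = (counts >= threshold).astype(np.int8)
    return ActivityTable(frame=binary, threshold=float(threshold))


_warned_missing: set[str] = set()


def evaluate_rule(rule: GeneRule, activity: Mapping[str, object]) -> bool:
    """Evaluate a DNF rule on one sample's gene activity.

    Genes missing from the activity mapping count as inactive; each
    missing gene is logged once per process so silent drop-outs in the
    expression table are visible.
    """
    missing = [g for g in rule.genes if g not in activity]
    for g in missing:
        if g not in _warned_missing:
            _warned_missing.add(g)
            log.warning("gene %s absent from expression table; treated as inactive", g)
    return rule.evaluate(activity)


def partition_reactions(
    net: MetabolicNetwork,
    activity: Mapping[str, object],
    sample: str | None = None,
) -> ReactionPartition:
    """Split reactions into A / I / unconstrained for one sample."""
    A, I, free = [], [], []
    for rid, rxn in net.reactions.items():
        if rxn.rule is None:
            free.append(rid)
        elif evaluate_rule(rxn.rule, activity):
            A.append(rid)
        else:
            I.append(rid)
    return ReactionPartition(A=tuple(A), I=tuple(I), unconstrained=tuple(free), sample=sample)
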