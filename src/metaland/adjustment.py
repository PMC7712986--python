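"""Rule + compartment aggregation of landscape matrices.

Reaction hubs sharing one gene rule inject dozens of identical columns
into a landscape matrix and dominate PCA and clustering.  The
adjustment collapses, within each gene rule, reactions with the same
compartment signature into one representative column whose value is the
mean member activity — keeping the biological signal (one column per
rule x compartment route) while removing the multiplicity artifact.

A reaction's compartment label has the form ``s1…sk-p1…pj``: the
alphabetically ordered compartment codes of its substrates, a dash, and
those of its products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .entropy import EntropyEnvelope  # noqa: F401  (re-exported context type)
from .network import MetabolicNetwork, Reaction, RuleGroup, rule_groups
from .stats import SelectionResult

__all__ = [
    "AdjustedMatrix",
    "compartment_label",
    "aggregate",
    "detect_redundant_groups",
]


@dataclass
class AdjustedMatrix:
    """Samples x aggregates activity matrix with values in [0, 1].

    ``groups`` maps each aggregate column to its member reaction ids;
    pass-through columns map to themselves.
    """

    frame: pd.DataFrame
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _side_label(compartments: set[str]) -> str:
    codes = sorted(compartments)
    # single-letter codes concatenate directly; longer codes need a
    # separator to stay unambiguous
    sep = "" if all(len(c) == 1 for c in codes) else ","
    return sep.join(codes)


def compartment_label(
    reaction: Reaction, net: MetabolicNetwork, canonical: bool = False
) -> str:
    """Compartment signature ``substrates-products`` of a reaction.

    Substrate side = sorted unique compartments of negative-coefficient
    metabolites, product side likewise for positive coefficients; an
    empty side renders as an empty string around the dash.  By default
    the written direction is kept; ``canonical=True`` puts the
    lexicographically smaller side first (useful when reversible
    reactions are written in arbitrary orientation).
    """
    subs = _side_label({net.metabolites[m].compartment for m in reaction.substrates})
    prods = _side_label({net.metabolites[m].compartment for m in reaction.products})
    if canonical and prods < subs:
        subs, prods = prods, subs
    return f"{subs}-{prods}"


def aggregate(
    matrix: pd.DataFrame | AdjustedMatrix,
    net: MetabolicNetwork,
    rules: set | None = None,
    canonical_labels: bool = False,
) -> AdjustedMatrix:
    """Average same-rule, same-compartment-label reaction columns.

    ``rules`` restricts aggregation to the given set of
    :class:`~metaland.gpr.GeneRule` keys (e.g. only groups flagged as
    redundant); ``None`` aggregates every rule group.  Rule-free
    reactions — and reactions of non-selected rules — pass through
    unchanged as singleton aggregates.  Aggregating an already adjusted
    matrix is a no-op (columns keep their aggregate identity).
    """
    if isinstance(matrix, AdjustedMatrix):
        return AdjustedMatrix(frame=matrix.frame.copy(), groups=dict(matrix.groups))

    buckets: dict[str, list[str]] = {}
    for col in matrix.columns:
        rxn = net.reactions.get(col)
        if rxn is None or rxn.rule is None or (rules is not None and rxn.rule not in rules):
            buckets.setdefault(col, []).append(col)
            continue
        label = compartment_label(rxn, net, canonical=canonical_labels)
        key = f"{rxn.rule.render()}@{label}"
        buckets.setdefault(key, []).append(col)

    out = {}
    groups = {}
    for key, members in buckets.items():
        if len(members) == 1:
            # singleton groups keep their original column identity
            key = members[0]
            out[key] = matrix[key].astype(float)
        else:
            out[key] = matrix[members].mean(axis=1)
        groups[key] = tuple(members)
    frame = pd.DataFrame(out, index=matrix.index)
    return AdjustedMatrix(frame=frame, groups=groups)


def detect_redundant_groups(
    selection: SelectionResult,
    group_entropies: pd.DataFrame,
    net: MetabolicNetwork,
    percentile_cut: float = 5.0,
    member_fraction: float = 0.5,
    min_size: int = 2,
) -> list[RuleGroup]:
    """Two-fold redundancy check over shared-rule reaction groups.

    A group is flagged for adjustment iff (a) at least
    ``member_fraction`` of its members appear in the PCA-loadings
    selection, and (b) its induced-entropy percentile against the
    size-matched random envelope is below ``percentile_cut``.
    Groups below ``min_size`` are never flagged: a single reaction
    cannot be a redundancy hub and aggregating it is a no-op.
    """
    selected = set(selection.selected_ids)
    by_rule = {g.rule.render(): g for g in rule_groups(net)}
    flagged: list[RuleGroup] = []
    for _, row in group_entropies.iterrows():
        grp = by_rule.get(row["rule"])
        if grp is None or grp.size < min_size:
            continue
        hit = sum(1 for r in grp.reactions if r in selected)
        if hit >= member_fraction * grp.size and row["percentile"] < percentile_cut:
            flagged.append(grp)
    return flagged
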