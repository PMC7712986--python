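"""Synthetic networks and activities for every stage of the workflow.

Three generators:

* :func:`fig1_network` — a six-reaction, five-metabolite toy network
  whose gene rules make one gene (G1) silence exactly two reactions.
* :func:`generate_hub_network` — a random sparse background network
  with planted *hubs*: groups of reactions sharing one gene rule and a
  private metabolite pool, densely wired inside and attached to the
  background by only a few link reactions.  This is the structure that
  produces low-entropy sub-networks and clustering artifacts.
* :func:`generate_random_activities` — i.i.d. Bernoulli gene activity,
  the null input on which any recovered cluster structure is an
  artifact of network topology rather than of the data.

:func:`artifact_benchmark` chains them end to end (random activities ->
landscapes -> PCA) and quantifies the artifact before and after the
aggregation adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .activity import ActivityTable, binarize
from .adjustment import aggregate, detect_redundant_groups
from .entropy import reaction_graph, rule_group_entropies
from .gpr import parse_gene_rule
from .landscape import MilpConfig, compute_landscapes
from .network import MetabolicNetwork, Metabolite, Reaction
from .stats import pca, select_variables

__all__ = [
    "HubSpec",
    "ArtifactReport",
    "fig1_network",
    "generate_hub_network",
    "generate_random_activities",
    "artifact_benchmark",
]

log = logging.getLogger(__name__)

BOUND = 10.0  # default flux bound magnitude for synthetic reactions


@dataclass(frozen=True)
class HubSpec:
    """Parameters of a planted-hub synthetic network.

    n_background_reactions
        Random metabolite-to-metabolite conversions, each gated by its
        own unique gene; every background metabolite also receives a
        reversible exchange so any single background reaction can carry
        flux on its own.
    n_hubs, hub_size
        Number and size of planted shared-rule hubs.  Hub sizes default
        to several dozen reactions, the scale at which shared-rule
        groups dominate a genome-scale reconstruction's statistics.
    internal_density
        Target probability that two hub members share a pool
        metabolite; 1.0 gives a fully interconnected hub.
    external_links
        Rule-free reversible reactions connecting each hub's pool to a
        background metabolite — the hub's only contact with the rest of
        the network.
    gene_prefix
        Hub h is gated by gene f"{gene_prefix}{h}".
    """

    n_background_reactions: int = 40
    n_hubs: int = 2
    hub_size: int = 40
    internal_density: float = 1.0
    external_links: int = 2
    seed: int = 0
    gene_prefix: str = "GH"

    def __post_init__(self) -> None:
        if self.n_hubs and self.hub_size < 2:
            raise ValueError("hub_size must be at least 2")
        if not 0.0 < self.internal_density <= 1.0:
            raise ValueError("internal_density must be in (0, 1]")
        if self.n_background_reactions < 1:
            raise ValueError("need at least one background reaction")

    def hub_gene(self, h: int) -> str:
        return f"{self.gene_prefix}{h + 1}"


@dataclass
class ArtifactReport:
    """Before/after quantification of the hub clustering artifact."""

    n_hubs: int
    expected_clusters: int
    pre_silhouette: float
    post_silhouette: float
    flagged_rules: tuple[str, ...]
    n_samples: int
    seed: int

    @property
    def artifact_present(self) -> bool:
        return self.pre_silhouette > 0.5

    @property
    def artifact_removed(self) -> bool:
        return self.post_silhouette < 0.25


def fig1_network() -> MetabolicNetwork:
    """Six reactions over five metabolites, five of them rule-gated by
    genes G1-G3; switching G1 off silences exactly R3 and R6 and stops
    all production of M5."""
    net = MetabolicNetwork()
    comps = {"M1": "c", "M2": "c", "M3": "c", "M4": "e", "M5": "e"}
    for mid, comp in comps.items():
        # M4/M5 leave the modelled system: boundary species, not balanced
        net.metabolites[mid] = Metabolite(id=mid, compartment=comp, is_boundary=comp == "e")

    def rxn(rid, stoich, rule=None, lb=0.0, ub=BOUND):
        net.reactions[rid] = Reaction(
            id=rid, stoich=stoich, lower_bound=lb, upper_bound=ub,
            rule=parse_gene_rule(rule) if rule else None,
        )

    rxn("R1", {"M1": 1.0})                              # uptake, rule-free
    rxn("R2", {"M1": -1.0, "M2": 1.0}, "G2")
    rxn("R3", {"M1": -1.0, "M2": 1.0}, "G1")
    rxn("R4", {"M2": -1.0, "M3": 1.0}, "G3")
    rxn("R5", {"M3": -1.0}, "G2 or G3")                 # export
    rxn("R6", {"M2": -1.0, "M4": 1.0, "M5": 1.0}, "G1 and G3")
    net.validate()
    return net


def _pool_size(density: float, hub_size: int) -> int:
    """Largest metabolite-pool size whose random pair wiring still meets
    the requested member-adjacency probability."""
    for s in range(2, max(3, hub_size + 1)):
        p_adj = 1.0 if s < 4 else 1.0 - comb(s - 2, 2) / comb(s, 2)
        if p_adj >= density:
            best = s
        else:
            break
    return best


def generate_hub_network(spec: HubSpec) -> MetabolicNetwork:
    """Build a background network with planted shared-rule hubs.

    Deterministic given ``spec`` (including its seed).  Hub members of
    hub h are named ``H{h}R{j}`` and gated by the single gene
    ``spec.hub_gene(h)``; background reactions carry unique genes.
    All bounds admit zero flux, so every per-sample MILP is feasible.
    """
    rng = np.random.default_rng(spec.seed)
    net = MetabolicNetwork()
    n_bg_met = max(3, spec.n_background_reactions // 2 + 2)
    for i in range(n_bg_met):
        mid = f"B{i}"
        net.metabolites[mid] = Metabolite(id=mid, compartment="c")

    # sparse random background: each reaction converts one background
    # metabolite into another and is gated by its own gene
    for j in range(spec.n_background_reactions):
        a, b = rng.choice(n_bg_met, size=2, replace=False)
        rid = f"BG{j}"
        net.reactions[rid] = Reaction(
            id=rid,
            stoich={f"B{a}": -1.0, f"B{b}": 1.0},
            lower_bound=-BOUND,
            upper_bound=BOUND,
            rule=parse_gene_rule(f"GB{j}"),
        )
    # reversible exchange per background metabolite: chains need not be
    # internally balanced, so one active gene suffices for one active flux
    for i in range(n_bg_met):
        rid = f"EX_B{i}"
        net.reactions[rid] = Reaction(
            id=rid, stoich={f"B{i}": -1.0}, lower_bound=-BOUND, upper_bound=BOUND
        )

    pool = _pool_size(spec.internal_density, spec.hub_size)
    for h in range(spec.n_hubs):
        pool_ids = [f"HP{h}M{k}" for k in range(pool)]
        for mid in pool_ids:
            net.metabolites[mid] = Metabolite(id=mid, compartment="h")
        rule = parse_gene_rule(spec.hub_gene(h))
        for j in range(spec.hub_size):
            if pool == 2:
                a, b = 0, 1
            else:
                a, b = rng.choice(pool, size=2, replace=False)
            rid = f"H{h}R{j}"
            net.reactions[rid] = Reaction(
                id=rid,
                stoich={pool_ids[a]: -1.0, pool_ids[b]: 1.0},
                lower_bound=-BOUND,
                upper_bound=BOUND,
                rule=rule,
            )
        targets = rng.choice(n_bg_met, size=spec.external_links, replace=False)
        for t, bt in enumerate(targets):
            rid = f"LNK{h}_{t}"
            net.reactions[rid] = Reaction(
                id=rid,
                stoich={pool_ids[0]: -1.0, f"B{bt}": 1.0},
                lower_bound=-BOUND,
                upper_bound=BOUND,
            )
    net.validate()
    return net


def generate_random_activities(
    n_samples: int, genes, p_active: float = 0.5, seed: int = 0
) -> ActivityTable:
    """Independent Bernoulli(p_active) gene activity per gene and sample."""
    if not 0.0 <= p_active <= 1.0:
        raise ValueError("p_active must be in [0, 1]")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    values = (rng.random((len(genes), n_samples)) < p_active).astype(np.int8)
    frame = pd.DataFrame(
        values, index=genes, columns=[f"S{i:03d}" for i in range(n_samples)]
    )
    return binarize(frame, threshold=0.5)


def _silhouette(scores: pd.DataFrame, labels: list) -> float:
    from sklearn.metrics import silhouette_score

    if len(set(labels)) < 2:
        return 0.0
    encoded = np.asarray([str(l) for l in labels])
    return float(silhouette_score(scores.to_numpy(), encoded))


def artifact_benchmark(
    spec: HubSpec,
    n_samples: int = 100,
    seed: int = 0,
    p_active: float = 0.5,
    pca_components: int = 3,
    baseline_samples: int = 500,
    config: MilpConfig | None = None,
) -> ArtifactReport:
    """End-to-end artifact run: random activities -> landscapes -> PCA.

    Samples are keyed by the ground-truth activity states of the hub
    genes (2^n_hubs combinations).  The pre-adjustment silhouette of
    that keying on the PCA scores measures how strongly the planted
    hubs alone cluster informationless data; the post-adjustment
    silhouette measures what remains after flagged rule groups are
    aggregated.
    """
    net = generate_hub_network(spec)
    genes = sorted(net.genes)
    acts = generate_random_activities(n_samples, genes, p_active=p_active, seed=seed)
    lands = compute_landscapes(net, acts, config=config)

    hub_genes = [spec.hub_gene(h) for h in range(spec.n_hubs)]
    labels = [
        tuple(int(acts.frame.loc[g, s]) for g in hub_genes) for s in acts.samples
    ]

    k = min(pca_components, len(lands) - 1, lands.shape[1])
    dec = pca(lands, k=k)
    pre = _silhouette(dec.scores, labels)

    graph = reaction_graph(net)
    ents = rule_group_entropies(net, graph, n_samples=baseline_samples, seed=seed)
    selection = select_variables(dec, f="frac:0.5", k=min(max(spec.n_hubs, 1), k))
    flagged = detect_redundant_groups(selection, ents, net)
    adjusted = aggregate(lands, net, rules={g.rule for g in flagged})

    k2 = min(pca_components, len(adjusted.frame) - 1, adjusted.frame.shape[1])
    dec2 = pca(adjusted.frame, k=k2)
    post = _silhouette(dec2.scores, labels)

    return ArtifactReport(
        n_hubs=spec.n_hubs,
        expected_clusters=2 ** spec.n_hubs,
        pre_silhouette=pre,
        post_silhouette=post,
        flagged_rules=tuple(g.rule.render() for g in flagged),
        n_samples=n_samples,
        seed=seed,
    )
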