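"""Constraint-based metabolic network model and I/O.

The network is a set of reactions over compartment-specific metabolites
— formally a Petri net whose transitions (reactions) may carry a
conditional Boolean gene rule.  Reversibility is encoded purely in the
flux bounds; reactions are never split into forward/backward pairs.

I/O: SBML (via cobrapy) for real genome-scale reconstructions, plus a
small JSON dialect used for fixtures and synthetic networks::

    {"metabolites": [{"id", "compartment", "boundary"?, "name"?}],
     "reactions":   [{"id", "stoich": {mid: coef}, "lb", "ub",
                      "rule"?, "kind"?}]}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import scipy.sparse as sp

from .gpr import GeneRule, RuleError, parse_gene_rule

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "RuleGroup",
    "NetworkError",
    "read_sbml",
    "read_json",
    "write_json",
    "stoichiometric_matrix",
    "rule_groups",
]

log = logging.getLogger(__name__)

KINDS = ("enzymatic", "transport", "exchange", "demand")


class NetworkError(ValueError):
    """Integrity or schema error in a metabolic network input."""


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    """A reaction: signed stoichiometry (negative = substrate), flux
    bounds, and an optional gene rule."""

    id: str
    stoich: dict[str, float]
    lower_bound: float
    upper_bound: float
    rule: GeneRule | None = None
    kind: str | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            if r.rule is not None:
                out |= r.rule.genes
        return out

    def validate(self) -> None:
        """Raise :class:`NetworkError` on any invariant violation."""
        for m in self.metabolites.values():
            if not m.compartment:
                raise NetworkError(f"metabolite {m.id!r} has an empty compartment")
        for r in self.reactions.values():
            if not r.stoich:
                raise NetworkError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise NetworkError(f"reaction {r.id!r} has lower_bound > upper_bound")
            for mid in r.stoich:
                if mid not in self.metabolites:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )

    def classify(self, reaction: Reaction) -> str:
        """Derive a reaction class when the input carried no tag.

        Priority: enzymatic (carries a gene rule), then exchange
        (touches a boundary metabolite or has single-sided
        stoichiometry — pure in/outflow across the system boundary),
        then transport (spans more than one compartment), else
        internal.  An explicit input tag always wins; demand reactions
        can only come from such a tag.
        """
        if reaction.kind is not None:
            return reaction.kind
        if reaction.rule is not None:
            return "enzymatic"
        coefs = list(reaction.stoich.values())
        boundary = any(self.metabolites[m].is_boundary for m in reaction.stoich)
        single_sided = all(c < 0 for c in coefs) or all(c > 0 for c in coefs)
        if boundary or single_sided:
            return "exchange"
        comps = {self.metabolites[m].compartment for m in reaction.stoich}
        if len(comps) > 1:
            return "transport"
        return "internal"

    def summary(self) -> dict[str, int]:
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "rule_bearing": sum(1 for r in self.reactions.values() if r.rule is not None),
            "genes": len(self.genes),
            "compartments": len(self.compartments),
        }


@dataclass
class RuleGroup:
    """Reactions sharing one (normalised) gene rule."""

    rule: GeneRule
    reactions: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------
# I/O

def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Load an SBML model (L3+fbc preferred, L2 notes accepted).

    SBML parsing is delegated to cobrapy; the cobra model is converted
    to the package's own network representation and GPR strings are
    re-parsed into normalised DNF.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # pragma: no cover - cobra error text varies
        raise NetworkError(f"malformed SBML in {path.name}: {exc}") from exc

    net = MetabolicNetwork()
    for m in model.metabolites:
        net.metabolites[m.id] = Metabolite(
            id=m.id,
            compartment=m.compartment or "?",
            name=m.name or "",
            is_boundary=bool(getattr(m, "boundary_condition", False)),
        )
    for r in model.reactions:
        rule_text = r.gene_reaction_rule
        rule = None
        if rule_text and rule_text.strip():
            try:
                rule = parse_gene_rule(rule_text)
            except RuleError as exc:
                raise RuleError(f"reaction {r.id!r}: {exc}") from exc
        net.reactions[r.id] = Reaction(
            id=r.id,
            stoich={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            rule=rule,
        )
    net.validate()
    s = net.summary()
    log.info(
        "loaded %s: %d reactions (%d rule-bearing), %d metabolites, %d genes",
        path.name, s["reactions"], s["rule_bearing"], s["metabolites"], s["genes"],
    )
    return net


def read_json(path: str | Path) -> MetabolicNetwork:
    """Load the JSON fixture dialect (see module docstring)."""
    with open(path) as fh:
        doc = json.load(fh)
    return network_from_dict(doc)


def network_from_dict(doc: Mapping) -> MetabolicNetwork:
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise NetworkError(f"network JSON missing key {key!r}")
    net = MetabolicNetwork()
    for m in doc["metabolites"]:
        if "id" not in m or "compartment" not in m:
            raise NetworkError(f"metabolite entry missing id/compartment: {m}")
        net.metabolites[m["id"]] = Metabolite(
            id=m["id"],
            compartment=m["compartment"],
            name=m.get("name", ""),
            is_boundary=bool(m.get("boundary", False)),
        )
    for r in doc["reactions"]:
        for key in ("id", "stoich", "lb", "ub"):
            if key not in r:
                raise NetworkError(f"reaction entry missing key {key!r}: {r}")
        rule = None
        if r.get("rule"):
            rule = parse_gene_rule(r["rule"])
        net.reactions[r["id"]] = Reaction(
            id=r["id"],
            stoich={k: float(v) for k, v in r["stoich"].items()},
            lower_bound=float(r["lb"]),
            upper_bound=float(r["ub"]),
            rule=rule,
            kind=r.get("kind"),
        )
    net.validate()
    return net


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                **({"name": m.name} if m.name else {}),
                **({"boundary": True} if m.is_boundary else {}),
            }
            for m in net.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                **({"rule": r.rule.render()} if r.rule is not None else {}),
                **({"kind": r.kind} if r.kind is not None else {}),
            }
            for r in net.reactions.values()
        ],
    }


def write_json(net: MetabolicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Derived structure

def stoichiometric_matrix(
    net: MetabolicNetwork, drop_boundary: bool = False
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Sparse stoichiometric matrix S (metabolites x reactions).

    Entry (i, j) is the signed coefficient of metabolite i in reaction
    j.  With ``drop_boundary=True`` rows for boundary metabolites are
    omitted (the steady-state constraint S.v = 0 only balances internal
    species).  Returns (S, metabolite_ids, reaction_ids).
    """
    met_ids = [
        m.id for m in net.metabolites.values() if not (drop_boundary and m.is_boundary)
    ]
    rxn_ids = list(net.reactions)
    midx = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for mid, coef in net.reactions[rid].stoich.items():
            i = midx.get(mid)
            if i is not None:
                rows.append(i)
                cols.append(j)
                vals.append(float(coef))
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return S, met_ids, rxn_ids


def rule_groups(net: MetabolicNetwork) -> list[RuleGroup]:
    """Partition rule-bearing reactions by normalised rule equality.

    Groups are returned sorted by descending size (ties broken by rule
    rendering, for determinism).
    """
    buckets: dict[GeneRule, list[str]] = {}
    for rid, r in net.reactions.items():
        if r.rule is not None:
            buckets.setdefault(r.rule, []).append(rid)
    groups = [RuleGroup(rule=rule, reactions=tuple(rids)) for rule, rids in buckets.items()]
    groups.sort(key=lambda g: (-g.size, g.rule.render()))
    return groups
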