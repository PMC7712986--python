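"""Independent oracles and random-instance generators for the tests.

The MILP oracle enumerates every indicator assignment and checks LP
feasibility of each with ``linprog`` — no code shared with the solver
path it validates.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from metaland.activity import ReactionPartition
from metaland.network import MetabolicNetwork, Metabolite, Reaction, stoichiometric_matrix


def brute_force_objective(
    net: MetabolicNetwork, partition: ReactionPartition, eps: float = 1.0
) -> float:
    """True optimum of the landscape MILP by exhaustive enumeration.

    Per A-reaction states: unrewarded / forward (v >= eps) / backward
    (v <= -eps); per I-reaction: free / silenced (v = 0).  For each
    assignment the flux polytope is checked for feasibility with an LP;
    the best feasible assignment's reward count is returned.
    """
    S, _, rxn_ids = stoichiometric_matrix(net, drop_boundary=True)
    Sd = S.toarray()
    base_bounds = {r: (net.reactions[r].lower_bound, net.reactions[r].upper_bound) for r in rxn_ids}

    A, I = list(partition.A), list(partition.I)
    assignments = []
    for a_states in itertools.product((0, 1, 2), repeat=len(A)):
        for i_states in itertools.product((0, 1), repeat=len(I)):
            reward = sum(1 for s in a_states if s) + sum(i_states)
            assignments.append((reward, a_states, i_states))
    assignments.sort(key=lambda t: -t[0])

    for reward, a_states, i_states in assignments:
        bounds = dict(base_bounds)
        ok = True
        for r, s in zip(A, a_states):
            lo, hi = bounds[r]
            if s == 1:
                lo = max(lo, eps)
            elif s == 2:
                hi = min(hi, -eps)
            if lo > hi:
                ok = False
                break
            bounds[r] = (lo, hi)
        if not ok:
            continue
        for r, s in zip(I, i_states):
            if s == 1:
                lo, hi = bounds[r]
                if lo > 0 or hi < 0:
                    ok = False
                    break
                bounds[r] = (0.0, 0.0)
        if not ok:
            continue
        res = linprog(
            c=np.zeros(len(rxn_ids)),
            A_eq=Sd if Sd.shape[0] else None,
            b_eq=np.zeros(Sd.shape[0]) if Sd.shape[0] else None,
            bounds=[bounds[r] for r in rxn_ids],
            method="highs",
        )
        if res.status == 0:
            return float(reward)
    return float("-inf")  # no feasible assignment (bounds exclude v = 0)


def random_small_network(
    rng: np.random.Generator,
    max_reactions: int = 8,
    max_constrained: int = 4,
) -> tuple[MetabolicNetwork, ReactionPartition]:
    """A random network of <= max_reactions with a random A/I split."""
    n_met = int(rng.integers(2, 5))
    n_rxn = int(rng.integers(2, max_reactions + 1))
    net = MetabolicNetwork()
    for i in range(n_met):
        net.metabolites[f"M{i}"] = Metabolite(id=f"M{i}", compartment="c")
    for j in range(n_rxn):
        kind = rng.random()
        if kind < 0.3:  # single-sided in/outflow
            mid = f"M{rng.integers(n_met)}"
            stoich = {mid: float(rng.choice([-1.0, 1.0]))}
        else:
            a, b = rng.choice(n_met, size=2, replace=False)
            stoich = {f"M{a}": -1.0, f"M{b}": 1.0}
        if rng.random() < 0.6:
            lb, ub = -10.0, 10.0
        else:
            lb, ub = 0.0, 10.0
        net.reactions[f"R{j}"] = Reaction(
            id=f"R{j}", stoich=stoich, lower_bound=lb, upper_bound=ub
        )
    rxns = list(net.reactions)
    n_con = int(rng.integers(0, min(max_constrained, n_rxn) + 1))
    chosen = list(rng.choice(rxns, size=n_con, replace=False))
    split = int(rng.integers(0, n_con + 1)) if n_con else 0
    A = tuple(chosen[:split])
    I = tuple(chosen[split:])
    free = tuple(r for r in rxns if r not in set(chosen))
    return net, ReactionPartition(A=A, I=I, unconstrained=free)


def random_binary_matrix(rng: np.random.Generator, m: int, n: int):
    import pandas as pd

    return pd.DataFrame(
        rng.integers(0, 2, size=(m, n)),
        index=[f"S{i}" for i in range(m)],
        columns=[f"R{j}" for j in range(n)],
    )
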