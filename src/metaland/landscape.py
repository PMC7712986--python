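"""Per-sample metabolic landscapes via a mixed-integer linear program.

For each sample the network's rule-bearing reactions are split into an
expression-active set A and an expression-inactive set I (see
:mod:`metaland.activity`).  A MILP then searches for a steady-state
flux distribution that agrees with the transcriptome on as many
reactions as possible:

    max   sum_{r in A} (y+_r + y-_r)  +  sum_{r in I} y+_r
    s.t.  S v = 0
          vmin <= v <= vmax
          vmin_r (1 - y+_r) <= v_r - eps * y+_r     r in A
          vmax_r (1 - y-_r) >= v_r + eps * y-_r     r in A
          vmin_r (1 - y+_r) <= v_r                  r in I
          vmax_r (1 - y+_r) >= v_r                  r in I
          v real, y binary

For r in A, y+_r = 1 forces forward flux v_r >= eps and y-_r = 1
forces backward flux v_r <= -eps (each rewarded once); for r in I,
y+_r = 1 collapses the bounds to v_r = 0.  The resulting binary vector
of reaction activity states (|v_r| >= eps) is the sample's *metabolic
landscape*.

The formulation is solved with HiGHS through scipy's ``milp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .activity import ActivityTable, ReactionPartition, partition_reactions
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "MilpConfig",
    "LandscapeProblem",
    "MilpSolution",
    "Landscape",
    "build_milp",
    "solve_landscape",
    "activity_states",
    "post_transcriptional_changes",
    "compute_landscape",
    "compute_landscapes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MilpConfig:
    """Solver configuration.

    epsilon
        Minimal flux magnitude (flux units) for a reaction to count as
        active; also the activation margin the indicator constraints
        enforce.  Default 1, the unit additive indicator term of the
        transcriptomic constraints.
    time_limit
        Wall-clock limit per solve, in seconds (None = no limit).
    mip_rel_gap
        Relative optimality gap tolerance passed to the solver.
    """

    epsilon: float = 1.0
    time_limit: float | None = None
    mip_rel_gap: float = 0.0
    minimise_l1_flux: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LandscapeProblem:
    """Assembled MILP: constraint matrices plus variable bookkeeping."""

    network: MetabolicNetwork
    partition: ReactionPartition
    config: MilpConfig
    c: np.ndarray                      # objective (minimisation sign)
    constraints: LinearConstraint
    bounds: Bounds
    integrality: np.ndarray
    rxn_ids: list[str]
    # variable index maps: reaction id -> column of the indicator
    y_plus: dict[str, int] = field(default_factory=dict)
    y_minus: dict[str, int] = field(default_factory=dict)

    @property
    def n_reactions(self) -> int:
        return len(self.rxn_ids)

    @property
    def max_objective(self) -> float:
        return float(len(self.y_plus) + len(self.y_minus))


@dataclass
class MilpSolution:
    v: pd.Series                       # flux per reaction
    y_plus: dict[str, int]
    y_minus: dict[str, int]
    objective: float
    status: str                        # optimal | infeasible | time_limit


@dataclass
class Landscape:
    """Binary reaction-activity vector (plus fluxes) for one sample."""

    sample: str | None
    activity: dict[str, int]
    fluxes: dict[str, float]


def build_milp(
    net: MetabolicNetwork, partition: ReactionPartition, config: MilpConfig | None = None
) -> LandscapeProblem:
    """Assemble the landscape MILP for one sample's partition.

    Variables are laid out deterministically: fluxes in network
    reaction order, then (y+, y-) per A-reaction, then y+ per
    I-reaction, so repeated builds are identical and solves
    reproducible.
    """
    config = config or MilpConfig()
    if not net.reactions:
        raise ValueError("cannot build a landscape MILP for an empty network")
    eps = config.epsilon
    S, _, rxn_ids = stoichiometric_matrix(net, drop_boundary=True)
    m = len(rxn_ids)
    ridx = {r: j for j, r in enumerate(rxn_ids)}

    A = [r for r in partition.A]
    I = [r for r in partition.I]
    n_var = m + 2 * len(A) + len(I)
    y_plus: dict[str, int] = {}
    y_minus: dict[str, int] = {}
    col = m
    for r in A:
        y_plus[r] = col
        y_minus[r] = col + 1
        col += 2
    for r in I:
        y_plus[r] = col
        col += 1

    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    for j, rid in enumerate(rxn_ids):
        rxn = net.reactions[rid]
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        if rid in set(A) and rxn.upper_bound < eps and rxn.lower_bound > -eps:
            log.warning(
                "reaction %s is in A but its bounds [%g, %g] cannot reach |v| >= %g",
                rid, rxn.lower_bound, rxn.upper_bound, eps,
            )

    integrality = np.zeros(n_var)
    integrality[m:] = 1

    rows: list[dict[int, float]] = []
    c_lo: list[float] = []
    c_hi: list[float] = []

    def add(row: dict[int, float], lo: float, hi: float) -> None:
        rows.append(row)
        c_lo.append(lo)
        c_hi.append(hi)

    # steady state: S v = 0 over internal metabolites
    Scoo = S.tocoo()
    eq_rows: dict[int, dict[int, float]] = {}
    for i, j, val in zip(Scoo.row, Scoo.col, Scoo.data):
        eq_rows.setdefault(i, {})[j] = val
    for i in sorted(eq_rows):
        add(eq_rows[i], 0.0, 0.0)

    for r in A:
        j = ridx[r]
        vmin = net.reactions[r].lower_bound
        vmax = net.reactions[r].upper_bound
        # vmin (1 - y+) <= v - eps y+   <=>   v + (vmin - eps) y+ >= vmin
        add({j: 1.0, y_plus[r]: vmin - eps}, vmin, np.inf)
        # vmax (1 - y-) >= v + eps y-   <=>   v + (vmax + eps) y- <= vmax
        add({j: 1.0, y_minus[r]: vmax + eps}, -np.inf, vmax)
    for r in I:
        j = ridx[r]
        vmin = net.reactions[r].lower_bound
        vmax = net.reactions[r].upper_bound
        # y+ = 1 collapses both to 0 <= v <= 0
        add({j: 1.0, y_plus[r]: vmin}, vmin, np.inf)
        add({j: 1.0, y_plus[r]: vmax}, -np.inf, vmax)

    data, ri, ci = [], [], []
    for k, row in enumerate(rows):
        for j, val in row.items():
            ri.append(k)
            ci.append(j)
            data.append(val)
    Amat = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n_var))

    c = np.zeros(n_var)
    c[m:] = -1.0  # maximise indicator sum

    return LandscapeProblem(
        network=net,
        partition=partition,
        config=config,
        c=c,
        constraints=LinearConstraint(Amat, np.array(c_lo), np.array(c_hi)),
        bounds=Bounds(lb, ub),
        integrality=integrality,
        rxn_ids=rxn_ids,
        y_plus=y_plus,
        y_minus=y_minus,
    )


def solve_landscape(problem: LandscapeProblem, config: MilpConfig | None = None) -> MilpSolution:
    """Solve the assembled MILP with HiGHS (single-threaded, deterministic)."""
    config = config or problem.config
    options: dict = {"mip_rel_gap": config.mip_rel_gap}
    if config.time_limit is not None:
        options["time_limit"] = config.time_limit
    res = milp(
        c=problem.c,
        constraints=problem.constraints,
        bounds=problem.bounds,
        integrality=problem.integrality,
        options=options,
    )
    if res.status == 0:
        status = "optimal"
    elif res.status == 2:
        status = "infeasible"
    elif res.status == 1:
        status = "time_limit"
    else:  # pragma: no cover
        status = "error"
    if res.x is None:
        return MilpSolution(
            v=pd.Series(np.nan, index=problem.rxn_ids),
            y_plus={}, y_minus={}, objective=float("nan"), status=status,
        )
    x = np.asarray(res.x)
    m = problem.n_reactions
    v = pd.Series(x[:m], index=problem.rxn_ids)
    yp = {r: int(round(x[j])) for r, j in problem.y_plus.items()}
    ym = {r: int(round(x[j])) for r, j in problem.y_minus.items()}
    objective = -float(res.fun) if res.fun is not None else float("nan")
    if config.minimise_l1_flux and status == "optimal":
        v = _l1_refine(problem, objective)
    return MilpSolution(v=v, y_plus=yp, y_minus=ym, objective=objective, status=status)


def _l1_refine(problem: LandscapeProblem, objective: float) -> pd.Series:
    """Re-solve with the indicator sum pinned at the optimum and the
    L1 norm of the flux vector minimised, for a canonical flux choice
    among alternate optima."""
    m = problem.n_reactions
    n = problem.c.size
    # augment with t_j >= |v_j|
    lb = np.concatenate([problem.bounds.lb, np.zeros(m)])
    ub = np.concatenate([problem.bounds.ub, np.full(m, np.inf)])
    integrality = np.concatenate([problem.integrality, np.zeros(m)])
    A_old = sp.csr_matrix(problem.constraints.A)
    A_aug = sp.hstack([A_old, sp.csr_matrix((A_old.shape[0], m))])
    blocks = [A_aug]
    lo = list(problem.constraints.lb)
    hi = list(problem.constraints.ub)
    eye_v = sp.identity(m, format="csr")
    zero_y = sp.csr_matrix((m, n - m))
    eye_t = sp.identity(m, format="csr")
    blocks.append(sp.hstack([eye_v, zero_y, -eye_t]))   # v - t <= 0
    lo += [-np.inf] * m
    hi += [0.0] * m
    blocks.append(sp.hstack([-eye_v, zero_y, -eye_t]))  # -v - t <= 0
    lo += [-np.inf] * m
    hi += [0.0] * m
    pin = sp.csr_matrix((-problem.c[None, :]))
    pin = sp.hstack([pin, sp.csr_matrix((1, m))])       # indicator sum = optimum
    blocks.append(pin)
    lo.append(objective)
    hi.append(objective)
    A_full = sp.vstack(blocks, format="csr")
    c = np.zeros(n + m)
    c[n:] = 1.0
    res = milp(
        c=c,
        constraints=LinearConstraint(A_full, np.array(lo), np.array(hi)),
        bounds=Bounds(lb, ub),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:  # pragma: no cover - pinned problem is feasible
        raise RuntimeError("L1 refinement solve failed")
    return pd.Series(np.asarray(res.x)[:m], index=problem.rxn_ids)


def activity_states(
    solution: MilpSolution,
    net: MetabolicNetwork,
    partition: ReactionPartition,
    config: MilpConfig | None = None,
) -> Landscape:
    """Derive the binary landscape from the optimal flux vector.

    A reaction is active iff |v_r| >= epsilon; the criterion applies
    uniformly to A, I and rule-free reactions, so reactions without a
    rule also receive a state.
    """
    config = config or MilpConfig()
    if solution.status != "optimal":
        raise ValueError(f"cannot derive a landscape from a {solution.status} solution")
    act = {r: int(abs(v) >= config.epsilon - 1e-9) for r, v in solution.v.items()}
    return Landscape(sample=partition.sample, activity=act, fluxes=solution.v.to_dict())


def post_transcriptional_changes(
    landscape: Landscape, partition: ReactionPartition
) -> set[tuple[str, str]]:
    """Reactions whose landscape state contradicts the expression call.

    A reaction in A that ends up inactive is reported as ("down"); a
    reaction in I that ends up active as ("up").  Rule-free reactions
    are never reported.
    """
    changes: set[tuple[str, str]] = set()
    for r in partition.A:
        if landscape.activity.get(r, 0) == 0:
            changes.add((r, "down"))
    for r in partition.I:
        if landscape.activity.get(r, 0) == 1:
            changes.add((r, "up"))
    return changes


def compute_landscape(
    net: MetabolicNetwork,
    activity: Mapping[str, object],
    config: MilpConfig | None = None,
    sample: str | None = None,
) -> Landscape:
    """Partition + build + solve + state extraction for one sample."""
    config = config or MilpConfig()
    part = partition_reactions(net, activity, sample=sample)
    problem = build_milp(net, part, config)
    sol = solve_landscape(problem, config)
    if sol.status != "optimal":
        raise RuntimeError(f"landscape MILP for sample {sample!r} ended {sol.status}")
    return activity_states(sol, net, part, config)


def compute_landscapes(
    net: MetabolicNetwork, activities: ActivityTable, config: MilpConfig | None = None
) -> pd.DataFrame:
    """Landscapes for every sample of an activity table.

    Returns a samples x reactions binary DataFrame (the input of the
    binary-statistics stage).
    """
    config = config or MilpConfig()
    rows = {}
    for sample in activities.samples:
        ls = compute_landscape(net, activities.sample_activity(sample), config, sample=sample)
        rows[sample] = ls.activity
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[list(net.reactions)].astype(np.int8)
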