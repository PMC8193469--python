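"""Exact analyses of logical networks.

* :func:`find_stable_states` — complete fixed-point enumeration by depth-first
  constraint search with generalized arc consistency over component domains
  (no state-space scan, no external solver).
* :func:`find_minimal_trap_spaces` — all inclusion-minimal sub-cubes closed
  under the asynchronous dynamics, by top-down refinement with a local,
  support-wise closure test and backtracking repair.
* :func:`reachable` — witness-path search in the asynchronous state-transition
  graph (best-first on level distance, exact within an explored-state budget).

Closure of a sub-cube is a local condition: a sub-cube S is a trap space iff
for every component fixed at level v in S, the component's target equals v at
every state of S — checkable by enumerating the assignments of the rule's
support that are compatible with S.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

from .network import (
    FREE,
    LogicalNetwork,
    NetworkError,
    State,
    StateSpaceTooLarge,
    Subspace,
)


# ---------------------------------------------------------------------------
# stable states
# ---------------------------------------------------------------------------

def find_stable_states(
    network: LogicalNetwork, input_clamp: dict[str, int] | None = None
) -> list[State]:
    """All states fixed under every rule, sorted lexicographically.

    ``input_clamp`` may pin input components to levels; unclamped inputs are
    enumerated over their full range (free-input wild type).
    """
    input_clamp = dict(input_clamp or {})
    for name, level in input_clamp.items():
        comp = network.component(name)
        if not comp.is_input:
            raise NetworkError(f"input_clamp names non-input component {name!r}")
        if not 0 <= level <= comp.max_level:
            raise NetworkError(f"input_clamp {name}={level} outside [0, {comp.max_level}]")

    comps = network.components
    n = len(comps)
    supports: list[list[int]] = []
    for c in comps:
        clauses = network.rules.get(c.name, [])
        sup = sorted(
            {network.index[s] for cl in clauses for s in cl.condition.support()} - {network.index[c.name]}
        ) if clauses else []
        supports.append(sup)
    targets = network._targets

    domains: list[set[int]] = []
    for i, c in enumerate(comps):
        if c.is_input and c.name in input_clamp:
            domains.append({input_clamp[c.name]})
        else:
            domains.append(set(range(c.max_level + 1)))

    def feasible(i: int, v: int, doms: list[set[int]]) -> bool:
        """Can component i be stable at level v, given current domains?

        Checks existence of a support assignment within the domains under
        which the target of i equals v (with i itself at v).
        """
        comp = comps[i]
        if comp.is_input:
            return True  # inputs hold any clamped value
        sup = supports[i]
        probe = [min(d) for d in doms]
        probe[i] = v
        f = targets[i]
        if not sup:
            return f(probe) == v
        for values in itertools.product(*(sorted(doms[j]) for j in sup)):
            for j, val in zip(sup, values):
                probe[j] = val
            if f(probe) == v:
                return True
        return False

    def propagate(doms: list[set[int]]) -> bool:
        changed = True
        while changed:
            changed = False
            for i in range(n):
                for v in sorted(doms[i]):
                    if not feasible(i, v, doms):
                        doms[i].discard(v)
                        changed = True
                if not doms[i]:
                    return False
        return True

    results: list[State] = []

    def search(doms: list[set[int]]):
        if not propagate(doms):
            return
        try:
            branch = min(
                (i for i in range(n) if len(doms[i]) > 1),
                key=lambda i: len(doms[i]),
            )
        except ValueError:
            state = tuple(next(iter(doms[i])) for i in range(n))
            if network.is_stable(state):
                results.append(state)
            return
        for v in sorted(doms[branch]):
            child = [set(d) for d in doms]
            child[branch] = {v}
            search(child)

    search(domains)
    return sorted(results)


# ---------------------------------------------------------------------------
# trap spaces
# ---------------------------------------------------------------------------

def _closure_violation(network: LogicalNetwork, fixing: dict[int, int]):
    """First fixed component whose target can leave its value inside the cube.

    Returns ``(i, free_support_indices)`` for a violated component i, or None
    when the sub-cube defined by ``fixing`` is closed.
    """
    comps = network.components
    targets = network._targets
    for i, v in fixing.items():
        comp = comps[i]
        if comp.is_input:
            continue  # inputs never move
        clauses = network.rules.get(comp.name, [])
        sup = sorted(
            {network.index[s] for cl in clauses for s in cl.condition.support()}
        ) if clauses else []
        free_sup = [j for j in sup if j not in fixing and j != i]
        probe = [fixing.get(j, 0) for j in range(len(comps))]
        probe[i] = v
        f = targets[i]
        violated = False
        if not free_sup:
            violated = f(probe) != v
        else:
            for values in itertools.product(
                *(range(comps[j].max_level + 1) for j in free_sup)
            ):
                for j, val in zip(free_sup, values):
                    probe[j] = val
                if f(probe) != v:
                    violated = True
                    break
        if violated:
            all_free = [j for j in sup if j not in fixing]
            return i, all_free
    return None


def _subspace_sort_key(sub: Subspace) -> tuple:
    return tuple(-1 if v is FREE else v for v in sub.key())


def _percolate(network: LogicalNetwork, fixing: dict[int, int]) -> dict[int, int]:
    """Extend a closed fixing with every component whose target is constant.

    Safe for minimal-trap enumeration: if a component's target is the constant
    v throughout the cube, any minimal trap space inside the cube fixes it at
    v (otherwise intersecting with {c=v} gives a strictly smaller closed cube).
    """
    comps = network.components
    targets = network._targets
    fixing = dict(fixing)
    changed = True
    while changed:
        changed = False
        for i, comp in enumerate(comps):
            if i in fixing or comp.is_input:
                continue
            clauses = network.rules.get(comp.name, [])
            sup = sorted(
                {network.index[s] for cl in clauses for s in cl.condition.support()}
            ) if clauses else []
            free_sup = [j for j in sup if j not in fixing]
            probe = [fixing.get(j, 0) for j in range(len(comps))]
            f = targets[i]
            if not free_sup:
                fixing[i] = f(probe)
                changed = True
                continue
            seen_vals = set()
            for values in itertools.product(
                *(range(comps[j].max_level + 1) for j in free_sup)
            ):
                for j, val in zip(free_sup, values):
                    probe[j] = val
                seen_vals.add(f(probe))
                if len(seen_vals) > 1:
                    break
            if len(seen_vals) == 1:
                fixing[i] = seen_vals.pop()
                changed = True
    return fixing


def find_minimal_trap_spaces(network: LogicalNetwork, max_nodes: int = 200_000) -> list[Subspace]:
    """All inclusion-minimal trap spaces of the asynchronous dynamics.

    Top-down search: starting from the full cube, repeatedly fix one more
    component and repair closure violations by fixing support components
    (backtracking over all repairs, so the enumeration is complete); closed
    cubes are tightened by percolation; sub-cubes with no proper closed
    refinement are minimal.  Minimality is re-checked by pairwise containment
    at the end.
    """
    comps = network.components
    n = len(comps)
    nodes_seen = 0
    memo: dict[tuple[frozenset, frozenset], tuple[frozenset, ...]] = {}

    def closed_extensions(fixing: dict[int, int], frozen: frozenset) -> tuple[frozenset, ...]:
        """Closed, percolated fixings extending ``fixing`` (repair search).

        When a fixed component's closure is violated, the first free support
        not yet marked frozen is branched over all its levels *and* over the
        option of staying free forever (frozen), so every closed extension —
        hence every minimal trap space below — is reachable.
        """
        nonlocal nodes_seen
        key = (frozenset(fixing.items()), frozen)
        if key in memo:
            return memo[key]
        nodes_seen += 1
        if nodes_seen > max_nodes:
            raise StateSpaceTooLarge("trap-space search exceeded its node budget")
        violation = _closure_violation(network, fixing)
        if violation is None:
            result = (frozenset(_percolate(network, fixing).items()),)
            memo[key] = result
            return result
        _, free_sup = violation
        candidates = [j for j in free_sup if j not in frozen]
        if not candidates:
            memo[key] = ()
            return ()
        d = candidates[0]
        out: list[frozenset] = []
        for u in range(comps[d].max_level + 1):
            child = dict(fixing)
            child[d] = u
            out.extend(closed_extensions(child, frozen))
        out.extend(closed_extensions(fixing, frozen | {d}))
        result = tuple(dict.fromkeys(out))
        memo[key] = result
        return result

    minimal: dict[frozenset, dict[int, int]] = {}
    visited: set[frozenset] = set()

    def refine(fixing: dict[int, int]):
        key = frozenset(fixing.items())
        if key in visited:
            return
        visited.add(key)
        found_proper = False
        for i in range(n):
            if i in fixing:
                continue
            for v in range(comps[i].max_level + 1):
                child = dict(fixing)
                child[i] = v
                for ext_key in closed_extensions(child, frozenset()):
                    if ext_key != key:
                        found_proper = True
                        refine(dict(ext_key))
        if not found_proper:
            minimal[key] = fixing

    refine(_percolate(network, {}))
    # containment filter: keep only sub-cubes not strictly containing another
    keys = list(minimal)
    keep = []
    for a in keys:
        if not any(b != a and b.issuperset(a) for b in keys):
            keep.append(a)
    subs = [
        Subspace(network, {comps[i].name: v for i, v in dict(k).items()}) for k in keep
    ]
    return sorted(subs, key=_subspace_sort_key)


def brute_force_trap_spaces(
    network: LogicalNetwork, guard: int = 1 << 18
) -> list[Subspace]:
    """Minimal trap spaces by scanning every sub-cube; test oracle only."""
    comps = network.components
    n_subcubes = 1
    for c in comps:
        n_subcubes *= c.max_level + 2
    if n_subcubes > guard:
        raise StateSpaceTooLarge(f"{n_subcubes} sub-cubes exceed guard {guard}")
    closed: list[dict[int, int]] = []
    options = [[FREE] + list(range(c.max_level + 1)) for c in comps]
    for choice in itertools.product(*options):
        fixing = {i: v for i, v in enumerate(choice) if v is not FREE}
        if _closure_violation(network, fixing) is None:
            closed.append(fixing)
    keys = [frozenset(f.items()) for f in closed]
    subs = []
    for f, k in zip(closed, keys):
        if not any(other != k and other.issuperset(k) for other in keys):
            subs.append(Subspace(network, {comps[i].name: v for i, v in f.items()}))
    return sorted(subs, key=_subspace_sort_key)


# ---------------------------------------------------------------------------
# reachability
# ---------------------------------------------------------------------------

@dataclass
class ReachabilityResult:
    """Outcome of a witness-path search in the asynchronous dynamics."""

    status: str  # "reachable", "not_reachable" or "inconclusive"
    path: list[State] = field(default_factory=list)
    states_explored: int = 0

    @property
    def reachable(self) -> bool:
        return self.status == "reachable"

    def __bool__(self):
        return self.reachable


def reachable(
    network: LogicalNetwork,
    source: State,
    goal: State | Subspace,
    budget: int = 500_000,
) -> ReachabilityResult:
    """Search the asynchronous transition graph for a path source -> goal.

    Best-first on the summed level distance to the goal, with a memoized
    visited set.  Exhausting the frontier proves non-reachability; hitting
    the explored-state budget is reported as inconclusive, never as
    "not reachable".
    """
    network.check_state(source)
    if isinstance(goal, Subspace):
        goal_fixed = {network.index[n]: v for n, v in goal.fixed.items()}
    else:
        network.check_state(goal)
        goal_fixed = dict(enumerate(goal))

    def h(state: State) -> int:
        return sum(abs(state[i] - v) for i, v in goal_fixed.items())

    def at_goal(state: State) -> bool:
        return all(state[i] == v for i, v in goal_fixed.items())

    if at_goal(source):
        return ReachabilityResult("reachable", [source], 1)

    counter = itertools.count()
    frontier = [(h(source), next(counter), source)]
    parents: dict[State, State | None] = {source: None}
    explored = 0
    while frontier:
        _, _, state = heapq.heappop(frontier)
        explored += 1
        if explored > budget:
            return ReachabilityResult("inconclusive", [], explored)
        for succ in network.asynchronous_successors(state):
            if succ in parents:
                continue
            parents[succ] = state
            if at_goal(succ):
                path = [succ]
                cur = state
                while cur is not None:
                    path.append(cur)
                    cur = parents[cur]
                return ReachabilityResult("reachable", path[::-1], explored)
            heapq.heappush(frontier, (h(succ), next(counter), succ))
    return ReachabilityResult("not_reachable", [], explored)
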