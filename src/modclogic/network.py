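"""Multilevel logical networks: components, rules, states and perturbations.

A network is a list of components (each with a maximum activity level and an
input flag) plus, for every non-input component, an ordered list of
``(condition, target_level)`` pairs.  At a given state the component's *target*
is the level of the unique condition that fires, or 0 when none does;
conditions for distinct target levels must be mutually exclusive, which is
checked exhaustively over the rule's (small) support at construction time.

Asynchronous dynamics move one component per transition by one level toward
its target.  Input components have no rules and never move.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .expressions import Expr, TRUE, parse_condition

State = tuple[int, ...]

FREE = None  # marker for unconstrained components in a Subspace


class NetworkError(ValueError):
    """Contract violation in a network definition or a supplied state."""


class StateSpaceTooLarge(RuntimeError):
    """Raised when an exhaustive scan would exceed its guard."""


@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self):
        if self.max_level < 1:
            raise NetworkError(f"component {self.name}: max_level must be >= 1")


@dataclass(frozen=True)
class Edge:
    """Signed regulatory edge, used for rule/graph consistency checks."""

    source: str
    target: str
    sign: str = "+"  # "+", "-" or "dual"
    threshold: int = 1

    def __post_init__(self):
        if self.sign not in ("+", "-", "dual"):
            raise NetworkError(f"edge {self.source}->{self.target}: bad sign {self.sign!r}")


@dataclass(frozen=True)
class RuleClause:
    condition: Expr
    target: int


@dataclass(frozen=True)
class Perturbation:
    """Clamp of one component to a fixed level; ``"NAME%LEVEL"`` dialect."""

    component: str
    level: int

    @classmethod
    def parse(cls, label: str) -> "Perturbation":
        if "%" not in label:
            raise NetworkError(f"perturbation label {label!r} is not of the form NAME%LEVEL")
        name, _, lev = label.partition("%")
        if not lev.isdigit():
            raise NetworkError(f"perturbation label {label!r}: level must be an integer")
        return cls(name, int(lev))

    @property
    def label(self) -> str:
        return f"{self.component}%{self.level}"


class Subspace:
    """A sub-cube of the state space: each component fixed or FREE."""

    def __init__(self, network: "LogicalNetwork", fixed: dict[str, int]):
        self.network = network
        for name, level in fixed.items():
            comp = network.component(name)
            if not 0 <= level <= comp.max_level:
                raise NetworkError(f"subspace fixes {name} at invalid level {level}")
        self.fixed = dict(fixed)

    def __contains__(self, state: State) -> bool:
        idx = self.network.index
        return all(state[idx[name]] == level for name, level in self.fixed.items())

    def is_state(self) -> bool:
        return len(self.fixed) == len(self.network.components)

    def to_state(self) -> State:
        if not self.is_state():
            raise NetworkError("subspace has free components; not a single state")
        return tuple(self.fixed[c.name] for c in self.network.components)

    def free_components(self) -> list[str]:
        return [c.name for c in self.network.components if c.name not in self.fixed]

    def size(self) -> int:
        n = 1
        for c in self.network.components:
            if c.name not in self.fixed:
                n *= c.max_level + 1
        return n

    def contains_subspace(self, other: "Subspace") -> bool:
        return all(other.fixed.get(name) == level for name, level in self.fixed.items())

    def key(self) -> tuple:
        return tuple(self.fixed.get(c.name, FREE) for c in self.network.components)

    def __eq__(self, other):
        return isinstance(other, Subspace) and self.key() == other.key()

    def __hash__(self):
        return hash(self.key())

    def __repr__(self):
        parts = [
            f"{c.name}={self.fixed[c.name]}" if c.name in self.fixed else f"{c.name}=*"
            for c in self.network.components
        ]
        return "Subspace(" + ", ".join(parts) + ")"


class LogicalNetwork:
    """A multilevel logical network with exclusivity-checked rules."""

    def __init__(
        self,
        components: list[Component],
        rules: dict[str, list[RuleClause]],
        edges: list[Edge] | None = None,
        check_edges: bool = True,
        clamps: dict[str, int] | None = None,
        _original: tuple | None = None,
    ):
        self.components = list(components)
        self.index = {c.name: i for i, c in enumerate(self.components)}
        if len(self.index) != len(self.components):
            raise NetworkError("duplicate component names")
        self.rules = {name: list(clauses) for name, clauses in rules.items()}
        self.edges = list(edges or [])
        self.clamps = dict(clamps or {})
        self._original = _original
        self._validate()
        if check_edges and self.edges:
            self._check_edge_consistency()
        self._targets = [self._compile_target(c) for c in self.components]

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_rule_strings(
        cls,
        components: list[Component],
        rules: dict[str, list[tuple[str, int]]],
        edges: list[Edge] | None = None,
        check_edges: bool = True,
    ) -> "LogicalNetwork":
        parsed = {
            name: [RuleClause(parse_condition(cond), level) for cond, level in clauses]
            for name, clauses in rules.items()
        }
        return cls(components, parsed, edges, check_edges=check_edges)

    def component(self, name: str) -> Component:
        try:
            return self.components[self.index[name]]
        except KeyError:
            raise NetworkError(f"unknown component {name!r}") from None

    @property
    def inputs(self) -> list[Component]:
        return [c for c in self.components if c.is_input]

    # -- validation ----------------------------------------------------------

    def _validate(self):
        for comp in self.components:
            clauses = self.rules.get(comp.name, [])
            if comp.is_input and clauses:
                raise NetworkError(f"input component {comp.name} must not carry rules")
            for clause in clauses:
                if not 0 <= clause.target <= comp.max_level:
                    raise NetworkError(
                        f"rule for {comp.name}: target level {clause.target} outside "
                        f"[0, {comp.max_level}]"
                    )
                for name in clause.condition.support():
                    if name not in self.index:
                        raise NetworkError(
                            f"rule for {comp.name} references unknown component {name!r}"
                        )
            self._check_exclusivity(comp, clauses)
        for name in self.rules:
            if name not in self.index:
                raise NetworkError(f"rules given for unknown component {name!r}")
        for edge in self.edges:
            for name in (edge.source, edge.target):
                if name not in self.index:
                    raise NetworkError(f"edge references unknown component {name!r}")
            if edge.threshold > self.component(edge.source).max_level:
                raise NetworkError(
                    f"edge {edge.source}->{edge.target}: threshold {edge.threshold} exceeds "
                    f"max level of {edge.source}"
                )

    def _support_assignments(self, names: list[str]):
        domains = [range(self.component(n).max_level + 1) for n in names]
        for values in itertools.product(*domains):
            yield dict(zip(names, values))

    def _check_exclusivity(self, comp: Component, clauses: list[RuleClause]):
        """Conditions of distinct clauses must never fire simultaneously."""
        if len(clauses) < 2:
            return
        support = sorted(set().union(*(c.condition.support() for c in clauses)))
        for assignment in self._support_assignments(support):
            firing = [c for c in clauses if c.condition.evaluate(assignment)]
            if len(firing) > 1:
                raise NetworkError(
                    f"rules for {comp.name} overlap: conditions for targets "
                    f"{[c.target for c in firing]} all fire at {assignment}"
                )

    def _check_edge_consistency(self):
        """Every rule regulator must appear as an edge with a compatible sign.

        A regulator used monotonically positively (raising it can only raise
        the target) needs a "+" or "dual" edge; negatively, "-" or "dual".
        """
        by_target: dict[str, dict[str, Edge]] = {}
        for e in self.edges:
            by_target.setdefault(e.target, {})[e.source] = e
        for comp in self.components:
            clauses = self.rules.get(comp.name, [])
            if not clauses:
                continue
            support = sorted(set().union(*(c.condition.support() for c in clauses)))
            for reg in support:
                edge = by_target.get(comp.name, {}).get(reg)
                if edge is None:
                    raise NetworkError(
                        f"rule for {comp.name} uses {reg} but no {reg}->{comp.name} edge is "
                        "declared"
                    )
                if edge.sign == "dual":
                    continue
                inc, dec = self._monotone_use(comp, clauses, support, reg)
                if inc and dec:
                    raise NetworkError(
                        f"{reg} is used dually in the rule for {comp.name}; mark the edge dual"
                    )
                if dec and edge.sign == "+":
                    raise NetworkError(
                        f"edge {reg}->{comp.name} is '+' but {reg} acts as an inhibitor"
                    )
                if inc and edge.sign == "-":
                    raise NetworkError(
                        f"edge {reg}->{comp.name} is '-' but {reg} acts as an activator"
                    )

    def _monotone_use(self, comp, clauses, support, reg):
        """Return (used_positively, used_negatively) for regulator ``reg``."""
        inc = dec = False
        others = [s for s in support if s != reg]
        max_reg = self.component(reg).max_level
        for assignment in self._support_assignments(others):
            prev = None
            for v in range(max_reg + 1):
                assignment[reg] = v
                target = 0
                for c in clauses:
                    if c.condition.evaluate(assignment):
                        target = c.target
                        break
                if prev is not None:
                    if target > prev:
                        inc = True
                    elif target < prev:
                        dec = True
                prev = target
            del assignment[reg]
        return inc, dec

    # -- semantics -----------------------------------------------------------

    def _compile_target(self, comp: Component):
        """Compile the component's target function to fast python code."""
        i = self.index[comp.name]
        if comp.is_input:
            return eval(f"lambda x: x[{i}]")  # inputs hold their clamped value
        if comp.name not in self.rules or not self.rules[comp.name]:
            return lambda x: 0  # no condition ever fires: default level 0
        parts = []
        for clause in self.rules[comp.name]:
            cond = clause.condition.to_python(self.index) if clause.condition is not TRUE else "True"
            parts.append(f"{clause.target} if {cond} else")
        code = "lambda x: " + " ".join(parts) + " 0"
        return eval(code)

    def check_state(self, state: State):
        if len(state) != len(self.components):
            raise NetworkError(
                f"state has {len(state)} entries, expected {len(self.components)}"
            )
        for comp, v in zip(self.components, state):
            if not 0 <= v <= comp.max_level:
                raise NetworkError(
                    f"component {comp.name}: level {v} outside [0, {comp.max_level}]"
                )

    def evaluate(self, state: State) -> State:
        """Target level of every component at ``state`` (inputs hold)."""
        self.check_state(state)
        return tuple(f(state) for f in self._targets)

    def is_stable(self, state: State) -> bool:
        return self.evaluate(state) == state

    def asynchronous_successors(self, state: State) -> list[State]:
        """One successor per component off-target, moved one level toward it."""
        self.check_state(state)
        succ = []
        for i, f in enumerate(self._targets):
            target = f(state)
            if target != state[i]:
                step = 1 if target > state[i] else -1
                succ.append(state[:i] + (state[i] + step,) + state[i + 1 :])
        return succ

    def state_space_size(self) -> int:
        n = 1
        for c in self.components:
            n *= c.max_level + 1
        return n

    def all_states(self):
        domains = [range(c.max_level + 1) for c in self.components]
        return itertools.product(*domains)

    # -- perturbations -------------------------------------------------------

    def apply_perturbations(self, perturbations: list[Perturbation]) -> "LogicalNetwork":
        """Return a copy with each perturbed component clamped (rules discarded)."""
        rules = {n: list(cl) for n, cl in self.rules.items()}
        components = list(self.components)
        clamps = dict(self.clamps)
        original = self._original or (
            list(self.components),
            {n: list(cl) for n, cl in self.rules.items()},
        )
        for p in perturbations:
            comp = self.component(p.component)
            if not 0 <= p.level <= comp.max_level:
                raise NetworkError(
                    f"perturbation {p.label}: level outside [0, {comp.max_level}]"
                )
            if comp.is_input:
                # clamping an input is expressed by fixing its value in analyses;
                # represent it as a non-input component with a constant rule.
                components[self.index[comp.name]] = replace(comp, is_input=False)
            rules[p.component] = [RuleClause(TRUE, p.level)] if p.level > 0 else []
            clamps[p.component] = p.level
        return LogicalNetwork(
            components, rules, self.edges, check_edges=False, clamps=clamps,
            _original=original,
        )

    def clear_perturbations(self) -> "LogicalNetwork":
        """Undo all clamps, restoring the original rule set (round trip)."""
        if not self.clamps or self._original is None:
            return self
        components, rules = self._original
        return LogicalNetwork(
            list(components),
            {n: list(cl) for n, cl in rules.items()},
            self.edges,
            check_edges=False,
        )

    # -- exhaustive reference scan (test oracle) ------------------------------

    def brute_force_stable_states(self, guard: int = 1 << 20) -> list[State]:
        """Exhaustive fixed-point scan; reference oracle for small networks."""
        if self.state_space_size() > guard:
            raise StateSpaceTooLarge(
                f"state space {self.state_space_size()} exceeds guard {guard}"
            )
        targets = self._targets
        out = []
        for state in self.all_states():
            for i, f in enumerate(targets):
                if f(state) != state[i]:
                    break
            else:
                out.append(state)
        return sorted(out)

    def __eq__(self, other):
        if not isinstance(other, LogicalNetwork):
            return NotImplemented
        return (
            self.components == other.components
            and {n: [(str(c.condition), c.target) for c in cl] for n, cl in self.rules.items()}
            == {n: [(str(c.condition), c.target) for c in cl] for n, cl in other.rules.items()}
            and set(self.edges) == set(other.edges)
        )

    def __repr__(self):
        return f"LogicalNetwork({len(self.components)} components, {len(self.edges)} edges)"
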