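"""Discrete Bayesian-network data model, validation, and exact inference.

A network is a DAG of :class:`Variable` nodes, each with a finite ordered
state space and one :class:`ConditionalTable` giving a distribution over the
node's states for every configuration of its parents.  Inference is exact:
:func:`posterior` marginalises the full joint by enumeration (the reference
path) and :func:`eliminate` runs variable elimination; on any network small
enough to enumerate the two agree to within ``ROW_SUM_TOL``.

Probabilities are stored linearly (not log-space): the networks this engine
is built for have a handful of nodes and probabilities far from the
underflow regime, so products of at most a few dozen factors are safe in
double precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

#: tolerance for row-sum, joint-normalisation and oracle-equivalence checks
ROW_SUM_TOL = 1e-9
#: rows whose sum is within this of 1 are renormalised on read; worse is rejected
NORMALIZE_TOL = 1e-6
#: largest joint size (number of configurations) enumerated during validation
MAX_ENUM_SIZE = 2 ** 20

#: evidence is a plain mapping from variable name to observed state label
Evidence = Mapping[str, str]


class NetworkError(ValueError):
    """Malformed network, table, or evidence."""


class InconsistentEvidenceError(NetworkError):
    """The supplied evidence has probability zero under the network."""


@dataclass(frozen=True)
class Variable:
    """A named node with an ordered, finite state space.

    State order is significant: it is preserved from the model definition,
    and the first listed state is the variable's reference state unless a
    builder overrides it.
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def card(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise NetworkError(
                f"variable {self.name!r} has no state {state!r}; "
                f"states are {list(self.states)}"
            ) from None


@dataclass(frozen=True)
class Distribution:
    """A probability distribution over one variable's states."""

    variable: str
    states: tuple[str, ...]
    probs: tuple[float, ...]

    def __getitem__(self, state: str) -> float:
        try:
            return self.probs[self.states.index(state)]
        except ValueError:
            raise KeyError(state) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states, self.probs))


def _normalize_rows(values: np.ndarray, where: str) -> np.ndarray:
    sums = values.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > NORMALIZE_TOL):
        bad = np.unravel_index(int(np.argmax(np.abs(sums - 1.0))), sums.shape)
        raise NetworkError(
            f"{where}: row {bad} sums to {sums[bad]:.6g}, "
            f"more than {NORMALIZE_TOL:g} away from 1"
        )
    return values / sums[..., None]


class ConditionalTable:
    """P(child | parents): one probability row per parent configuration.

    ``values`` has shape ``(card(parent_1), ..., card(parent_k), card(child))``
    with parents in their declared order; a root node's table has shape
    ``(card(child),)``.

    Parameters
    ----------
    child, parents
        The child variable and its (possibly empty) ordered parent list.
    values
        Either an array of the shape above or a mapping from a tuple of
        parent state labels to a sequence of child-state probabilities.
    normalize
        If true (the default for anything read from a file or built from
        published statistics), rows within ``NORMALIZE_TOL`` of summing to 1
        are renormalised and anything worse is rejected.  Pass ``False`` to
        store rows verbatim — :func:`validate_network` will then report any
        violation as a diagnostic instead.
    """

    __slots__ = ("child", "parents", "values")

    def __init__(
        self,
        child: Variable,
        parents: Sequence[Variable],
        values,
        *,
        normalize: bool = True,
    ) -> None:
        self.child = child
        self.parents = tuple(parents)
        shape = tuple(p.card for p in self.parents) + (child.card,)
        if isinstance(values, Mapping):
            arr = np.full(shape, np.nan)
            for config, row in values.items():
                if isinstance(config, str):
                    config = (config,)
                if len(config) != len(self.parents):
                    raise NetworkError(
                        f"table for {child.name!r}: configuration {config!r} "
                        f"does not match {len(self.parents)} parent(s)"
                    )
                idx = tuple(p.index(s) for p, s in zip(self.parents, config))
                arr[idx] = np.asarray(row, dtype=float)
            if np.isnan(arr).any():
                missing = [
                    tuple(p.states[i] for p, i in zip(self.parents, idx))
                    for idx in itertools.product(*(range(p.card) for p in self.parents))
                    if np.isnan(arr[idx]).any()
                ]
                raise NetworkError(
                    f"table for {child.name!r}: missing row(s) for parent "
                    f"configuration(s) {missing[:3]}"
                    + ("..." if len(missing) > 3 else "")
                )
            values = arr
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != shape:
                raise NetworkError(
                    f"table for {child.name!r}: values have shape "
                    f"{values.shape}, expected {shape}"
                )
        if normalize:
            values = _normalize_rows(values, f"table for {child.name!r}")
        self.values = values

    def row(self, config: Mapping[str, str] | Sequence[str]) -> np.ndarray:
        """Probability row for one parent configuration (labels or mapping)."""
        if isinstance(config, Mapping):
            config = [config[p.name] for p in self.parents]
        idx = tuple(p.index(s) for p, s in zip(self.parents, config))
        return self.values[idx]

    def parent_configs(self) -> Iterable[tuple[str, ...]]:
        for combo in itertools.product(*(p.states for p in self.parents)):
            yield combo


class Network:
    """A directed acyclic graph of variables with one table per variable."""

    def __init__(self, variables: Iterable[Variable], tables: Iterable[ConditionalTable]):
        self.variable_list: tuple[Variable, ...] = tuple(variables)
        self.variables: dict[str, Variable] = {}
        for v in self.variable_list:
            self.variables.setdefault(v.name, v)
        self.tables: dict[str, ConditionalTable] = {t.child.name: t for t in tables}

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for t in self.tables.values():
            for p in t.parents:
                g.add_edge(p.name, t.child.name)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # keep declaration order among unconstrained nodes for reproducibility
        pos = {name: i for i, name in enumerate(self.variables)}
        return sorted(order, key=lambda n: (self._depth(n), pos[n]))

    def _depth(self, name: str, _cache: dict | None = None) -> int:
        t = self.tables.get(name)
        if t is None or not t.parents:
            return 0
        return 1 + max(self._depth(p.name) for p in t.parents)

    def parents_of(self, name: str) -> tuple[str, ...]:
        return tuple(p.name for p in self.tables[name].parents)

    @property
    def joint_size(self) -> int:
        size = 1
        for v in self.variables.values():
            size *= v.card
        return size

    # -- evidence ----------------------------------------------------------

    def check_evidence(self, evidence: Evidence) -> None:
        for name, state in evidence.items():
            if name not in self.variables:
                raise NetworkError(f"evidence names unknown variable {name!r}")
            self.variables[name].index(state)


def validate_network(net: Network) -> list[str]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the network is well-formed.  Diagnostics name the
    offending variable (and parent configuration, for row-level problems).
    """
    diags: list[str] = []
    seen: set[str] = set()
    for v in net.variable_list:
        if v.name in seen:
            diags.append(f"duplicate variable name {v.name!r}")
        seen.add(v.name)
        if v.card < 2:
            diags.append(f"variable {v.name!r} has {v.card} state(s); need >= 2")
        if len(set(v.states)) != v.card:
            diags.append(f"variable {v.name!r} has duplicate state labels")
    for name in net.variables:
        if name not in net.tables:
            diags.append(f"variable {name!r} has no conditional table")
    for name, t in net.tables.items():
        if name not in net.variables:
            diags.append(f"table for unknown variable {name!r}")
        for p in t.parents:
            if p.name not in net.variables:
                diags.append(f"table for {name!r} references unknown parent {p.name!r}")
            elif net.variables[p.name] is not p and net.variables[p.name] != p:
                diags.append(f"table for {name!r}: parent {p.name!r} does not match "
                             "the network's variable of that name")
        if p_bad := [pn for pn in (p.name for p in t.parents) if pn == name]:
            diags.append(f"cycle: variable {name!r} is its own parent")
        sums = t.values.sum(axis=-1)
        for idx in np.ndindex(*sums.shape):
            if abs(sums[idx] - 1.0) > ROW_SUM_TOL:
                config = tuple(p.states[i] for p, i in zip(t.parents, idx))
                diags.append(
                    f"table for {name!r}, row {config}: sum {sums[idx]:.9g} != 1"
                )
        if np.any((t.values < -ROW_SUM_TOL) | (t.values > 1 + ROW_SUM_TOL)):
            diags.append(f"table for {name!r} has entries outside [0, 1]")
    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        diags.append("cycle: " + " -> ".join(e[0] for e in cyc) + f" -> {cyc[-1][1]}")
        return diags  # joint enumeration undefined on a cyclic graph
    if not diags and net.joint_size <= MAX_ENUM_SIZE and net.variables:
        _, joint = joint_array(net)
        total = joint.sum()
        if abs(total - 1.0) > ROW_SUM_TOL:
            diags.append(f"joint distribution sums to {total:.12g} != 1")
    return diags


# -- enumeration -----------------------------------------------------------


def joint_array(net: Network) -> tuple[list[str], np.ndarray]:
    """Full joint as an ndarray with one axis per variable.

    Axis order follows :meth:`Network.topological_order`.  Only usable when
    the joint has at most ``MAX_ENUM_SIZE`` configurations.
    """
    order = net.topological_order()
    if net.joint_size > MAX_ENUM_SIZE:
        raise NetworkError(
            f"joint has {net.joint_size} configurations; enumeration is "
            f"capped at {MAX_ENUM_SIZE}"
        )
    axis = {name: i for i, name in enumerate(order)}
    n = len(order)
    joint = np.ones((1,) * n)
    for name in order:
        t = net.tables[name]
        fvars = [p.name for p in t.parents] + [name]
        perm = sorted(range(len(fvars)), key=lambda i: axis[fvars[i]])
        arr = np.transpose(t.values, perm)
        shape = [1] * n
        for i in perm:
            shape[axis[fvars[i]]] = net.variables[fvars[i]].card
        joint = joint * arr.reshape(shape)
    return order, joint


def joint_probability(net: Network, full_assignment: Evidence) -> float:
    """P(X_1=x_1, ..., X_n=x_n): the product of the selected table entries.

    ``full_assignment`` must cover every variable.
    """
    missing = set(net.variables) - set(full_assignment)
    if missing:
        raise NetworkError(f"assignment missing variable(s) {sorted(missing)}")
    net.check_evidence(full_assignment)
    p = 1.0
    for name, t in net.tables.items():
        row = t.row(full_assignment)
        p *= row[t.child.index(full_assignment[name])]
    return float(p)


def posterior(net: Network, query: str, evidence: Evidence | None = None) -> Distribution:
    """P(query | evidence), exactly, by summing the enumerated joint.

    Zero-probability evidence raises :class:`InconsistentEvidenceError`
    rather than returning NaNs: in a decision-support setting an impossible
    observation is a modelling error the caller must see.
    """
    evidence = dict(evidence or {})
    if query not in net.variables:
        raise NetworkError(f"unknown query variable {query!r}")
    net.check_evidence(evidence)
    order, joint = joint_array(net)
    axis = {name: i for i, name in enumerate(order)}
    sel: list = [slice(None)] * len(order)
    for name, state in evidence.items():
        sel[axis[name]] = net.variables[name].index(state)
    sub = joint[tuple(sel)]
    kept = [n for n in order if n not in evidence]
    if query in evidence:
        total = float(sub.sum())
        if total <= 0.0:
            raise InconsistentEvidenceError(
                f"evidence {evidence} has probability zero"
            )
        qv = net.variables[query]
        probs = tuple(1.0 if s == evidence[query] else 0.0 for s in qv.states)
        return Distribution(query, qv.states, probs)
    qax = kept.index(query)
    marg = sub.sum(axis=tuple(i for i in range(sub.ndim) if i != qax))
    total = float(marg.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(f"evidence {evidence} has probability zero")
    return Distribution(query, net.variables[query].states, tuple(marg / total))


# -- variable elimination --------------------------------------------------


@dataclass
class _Factor:
    """A nonnegative table over a sorted tuple of variable names."""

    vars: tuple[str, ...]
    array: np.ndarray


def _axis_key(net: Network) -> dict[str, int]:
    return {name: i for i, name in enumerate(net.variables)}


def _restrict(f: _Factor, evidence_idx: Mapping[str, int]) -> _Factor:
    sel: list = [slice(None)] * len(f.vars)
    keep = []
    for i, v in enumerate(f.vars):
        if v in evidence_idx:
            sel[i] = evidence_idx[v]
        else:
            keep.append(v)
    return _Factor(tuple(keep), f.array[tuple(sel)])


def _multiply(f1: _Factor, f2: _Factor, key: Mapping[str, int]) -> _Factor:
    union = tuple(sorted(set(f1.vars) | set(f2.vars), key=key.__getitem__))

    def expand(f: _Factor) -> np.ndarray:
        shape = [1] * len(union)
        for i, v in enumerate(union):
            if v in f.vars:
                shape[i] = f.array.shape[f.vars.index(v)]
        # f.vars is sorted consistently with union, so a reshape suffices
        return f.array.reshape(shape)

    return _Factor(union, expand(f1) * expand(f2))


def _sum_out(f: _Factor, var: str) -> _Factor:
    i = f.vars.index(var)
    return _Factor(f.vars[:i] + f.vars[i + 1:], f.array.sum(axis=i))


def eliminate(net: Network, query: str, evidence: Evidence | None = None) -> Distribution:
    """P(query | evidence) by variable elimination (min-degree ordering).

    Agrees with :func:`posterior` to within ``ROW_SUM_TOL`` on any network
    both can handle; use this on networks too large to enumerate.
    """
    evidence = dict(evidence or {})
    if query not in net.variables:
        raise NetworkError(f"unknown query variable {query!r}")
    net.check_evidence(evidence)
    key = _axis_key(net)
    ev_idx = {n: net.variables[n].index(s) for n, s in evidence.items()}

    factors = []
    for name, t in net.tables.items():
        fvars = tuple(p.name for p in t.parents) + (name,)
        perm = sorted(range(len(fvars)), key=lambda i: key[fvars[i]])
        f = _Factor(tuple(fvars[i] for i in perm), np.transpose(t.values, perm))
        f = _restrict(f, ev_idx)
        factors.append(f)

    hidden = set(net.variables) - set(evidence) - {query}
    while hidden:
        # greedy min-degree: eliminate the variable joining fewest others
        def degree(v: str) -> int:
            nbrs: set[str] = set()
            for f in factors:
                if v in f.vars:
                    nbrs.update(f.vars)
            return len(nbrs - {v})

        v = min(sorted(hidden), key=degree)
        hidden.remove(v)
        touching = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f, key)
        factors = rest + [_sum_out(prod, v)]

    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f, key)
    total = float(result.array.sum())
    if total <= 0.0:
        raise InconsistentEvidenceError(f"evidence {evidence} has probability zero")
    qv = net.variables[query]
    if query in evidence:
        probs = tuple(1.0 if s == evidence[query] else 0.0 for s in qv.states)
        return Distribution(query, qv.states, probs)
    # all that remains is the query axis
    marg = result.array.reshape(qv.card)
    return Distribution(query, qv.states, tuple(marg / total))
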