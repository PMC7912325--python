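"""Shared fixtures and independent oracles.

``brute_posterior`` recomputes conditionals by looping over every full
assignment with plain Python arithmetic — deliberately independent of both
inference code paths so it can arbitrate between them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from alinet.model import build_ali_network, load_ali_spec
from alinet.network import ConditionalTable, Network, Variable


def brute_posterior(net: Network, query: str, evidence: dict) -> dict[str, float]:
    """P(query | evidence) by exhaustive summation over full assignments."""
    names = list(net.variables)
    spaces = [net.variables[n].states for n in names]
    acc = {s: 0.0 for s in net.variables[query].states}
    for combo in itertools.product(*spaces):
        assign = dict(zip(names, combo))
        if any(assign[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for n in names:
            t = net.tables[n]
            idx = tuple(pv.states.index(assign[pv.name]) for pv in t.parents)
            p *= float(t.values[idx][net.variables[n].states.index(assign[n])])
        acc[assign[query]] += p
    total = sum(acc.values())
    if total <= 0:
        raise ZeroDivisionError("evidence has probability zero")
    return {s: v / total for s, v in acc.items()}


def random_network(rng: np.random.Generator, max_nodes: int = 6, max_states: int = 4) -> Network:
    """A random small DAG with dense Dirichlet tables (strictly positive rows)."""
    n = int(rng.integers(1, max_nodes + 1))
    variables: list[Variable] = []
    tables: list[ConditionalTable] = []
    for i in range(n):
        card = int(rng.integers(2, max_states + 1))
        v = Variable(f"v{i}", tuple(f"s{j}" for j in range(card)))
        k = int(rng.integers(0, min(i, 3) + 1)) if i else 0
        parent_ids = sorted(rng.choice(i, size=k, replace=False)) if k else []
        pvars = [variables[j] for j in parent_ids]
        nrows = int(np.prod([p.card for p in pvars])) if pvars else 1
        rows = rng.dirichlet(np.ones(card), size=nrows)
        shape = tuple(p.card for p in pvars) + (card,)
        variables.append(v)
        tables.append(ConditionalTable(v, pvars, rows.reshape(shape)))
    return Network(variables, tables)


def random_evidence(rng: np.random.Generator, net: Network, max_vars: int = 3) -> dict:
    names = list(net.variables)
    k = int(rng.integers(0, min(max_vars, len(names)) + 1))
    chosen = rng.choice(names, size=k, replace=False) if k else []
    return {n: str(rng.choice(net.variables[n].states)) for n in chosen}


@pytest.fixture(scope="session")
def ali_net():
    net, _ = build_ali_network()
    return net


@pytest.fixture(scope="session")
def ali_spec():
    return load_ali_spec()


@pytest.fixture()
def two_node_net():
    """Exposure -> disease with P(exposed)=0.3, P(yes|exposed)=0.5, P(yes|ref)=0.1."""
    e = Variable("exposure", ("reference", "exposed"))
    d = Variable("disease", ("no", "yes"))
    te = ConditionalTable(e, [], [0.7, 0.3])
    td = ConditionalTable(d, [e], [[0.9, 0.1], [0.5, 0.5]])
    return Network([e, d], [te, td])
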