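"""One-way tornado sensitivity analysis of a target probability.

For each candidate node the analysis observes one state, records the target
probability, reverses the observed state (the other state of a binary node;
an explicitly supplied pair otherwise), records it again, and ranks
candidates by the absolute difference — the bar length of a tornado plot.
The metric is a pure function of the network and the context evidence:
no sampling, no seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .model import INTERMEDIATES, LOAD
from .network import Distribution, Evidence, Network, NetworkError, eliminate

#: documented convention: a quartile-coded node is reversed bottom vs top
QUARTILE_PAIR = ("Q1", "Q4")


@dataclass(frozen=True)
class TornadoEntry:
    node: str
    observed_state: str
    reversed_state: str
    p_with: float
    p_reversed: float

    @property
    def span(self) -> float:
        return abs(self.p_with - self.p_reversed)


def default_candidates(net: Network, exclude: Iterable[str] = (LOAD,)) -> list[tuple[str, str, str]]:
    """One candidate per node (minus exclusions), with a reversal pair.

    Binary nodes observe their second (non-reference) state against the
    first; quartile-coded nodes observe Q1 against Q4 (the documented
    convention).  Other multi-state nodes are skipped — supply an explicit
    pair for those.
    """
    out = []
    excluded = set(exclude)
    for name, var in net.variables.items():
        if name in excluded:
            continue
        if var.card == 2:
            out.append((name, var.states[1], var.states[0]))
        elif set(QUARTILE_PAIR) <= set(var.states):
            out.append((name, QUARTILE_PAIR[0], QUARTILE_PAIR[1]))
    return out


def exclude_intermediates(
    candidates: Sequence[tuple],
    intermediates: Iterable[str] = INTERMEDIATES,
) -> list[tuple]:
    """Drop intermediate medical outcomes from a candidate list.

    The intermediate outcomes sit between the biomarkers and the load node,
    so observing them directly would exert a disproportionate influence on
    the target; the sensitivity question is about the measurable biomarkers.
    Idempotent.
    """
    dropped = set(intermediates)
    return [c for c in candidates if c[0] not in dropped]


def tornado(
    net: Network,
    target: tuple[str, str],
    candidates: Sequence[tuple] | None = None,
    context: Evidence | None = None,
    method: Callable[..., Distribution] = eliminate,
) -> list[TornadoEntry]:
    """Ranked one-way sensitivity entries for ``target = (variable, state)``.

    ``candidates`` holds ``(node, observed_state)`` pairs — the node must
    then be binary — or explicit ``(node, observed_state, reversed_state)``
    triples.  Entries are sorted by span, descending, ties broken
    lexicographically by node name.
    """
    context = dict(context or {})
    tvar, tstate = target
    if tvar not in net.variables:
        raise NetworkError(f"unknown target variable {tvar!r}")
    net.variables[tvar].index(tstate)
    if candidates is None:
        candidates = default_candidates(net, exclude={tvar, *context})
    entries = []
    for cand in candidates:
        if len(cand) == 2:
            node, observed = cand
            var = net.variables[node]
            if var.card != 2:
                raise NetworkError(
                    f"candidate {node!r} has {var.card} states: no unique "
                    "reversal; supply (node, observed, reversed) explicitly"
                )
            reversed_state = next(s for s in var.states if s != observed)
        else:
            node, observed, reversed_state = cand
            net.variables[node].index(reversed_state)
        net.variables[node].index(observed)
        if node == tvar:
            raise NetworkError("target variable cannot be a candidate")
        p_with = method(net, tvar, {**context, node: observed})[tstate]
        p_rev = method(net, tvar, {**context, node: reversed_state})[tstate]
        entries.append(TornadoEntry(node, observed, reversed_state, p_with, p_rev))
    entries.sort(key=lambda e: (-e.span, e.node))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tabular view (node, state, p_with, p_reversed, span) for reports/plots."""
    return pd.DataFrame(
        [
            {
                "node": e.node,
                "state": e.observed_state,
                "reversed_state": e.reversed_state,
                "p_with": e.p_with,
                "p_reversed": e.p_reversed,
                "span": e.span,
            }
            for e in entries
        ]
    )
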