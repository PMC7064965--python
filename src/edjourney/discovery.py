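"""Process discovery: journey extraction, the directly-follows graph,
and succession-rule mining for anticipated procedures.

The directly-follows graph counts immediate succession (the process
chart of all observed journeys); anticipation rules use *eventual*
follows — the consequent occurring anywhere later in the journey —
because anticipation cares about eventual occurrence, not adjacency.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from datetime import datetime

from .event_log import EventLog

START = "__START__"
END = "__END__"


@dataclass(frozen=True)
class AnticipationRule:
    """Mined "A is followed by B" rule.

    support: number of journeys containing the antecedent;
    confidence: fraction of those in which the consequent occurs
    somewhere after an occurrence of the antecedent.
    """

    antecedent: str
    consequent: str
    support: int
    confidence: float


@dataclass
class JourneyGraph:
    """Frequency-annotated directly-follows graph over procedures."""

    nodes: Counter
    edges: Counter  # (a, b) -> immediate-succession count
    start: Counter  # first procedure of each journey
    end: Counter  # last procedure of each journey

    def __eq__(self, other):
        return (
            isinstance(other, JourneyGraph)
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.start == other.start
            and self.end == other.end
        )


def extract_journeys(log: EventLog) -> dict[str, list[str]]:
    """One ordered procedure sequence per patient.

    Events are ordered by order time, ties broken by completion time
    then procedure name, which makes the result deterministic even for
    simultaneous orders.  An event with no timestamp at all cannot be
    placed and raises ValueError.
    """
    far = datetime.max
    per_patient: dict[str, list] = {pid: [] for pid in log.patients}
    for e in log.events:
        anchor = e.ordered_at or e.started_at or e.completed_at
        if anchor is None:
            raise ValueError(
                f"event for patient {e.patient_id} ({e.activity}) has no timestamps; cannot order"
            )
        label = e.procedure or e.activity
        per_patient.setdefault(e.patient_id, []).append(
            (anchor, e.completed_at or far, label)
        )
    return {
        pid: [label for _, _, label in sorted(items)]
        for pid, items in per_patient.items()
    }


def build_graph(journeys) -> JourneyGraph:
    """Count directly-follows transitions over all journeys.

    ``journeys`` is a mapping patient -> sequence or an iterable of
    sequences; empty journeys contribute nothing.
    """
    seqs = journeys.values() if isinstance(journeys, dict) else journeys
    g = JourneyGraph(Counter(), Counter(), Counter(), Counter())
    for seq in seqs:
        if not seq:
            continue
        g.start[seq[0]] += 1
        g.end[seq[-1]] += 1
        for label in seq:
            g.nodes[label] += 1
        for a, b in zip(seq, seq[1:]):
            g.edges[(a, b)] += 1
    return g


def mine_rules(
    journeys,
    min_support: int = 20,
    min_confidence: float = 0.9,
) -> list[AnticipationRule]:
    """All (A, B) pairs, A != B, with support(A) >= min_support and
    eventual-follows confidence >= min_confidence.

    Sorted by confidence descending, then support descending, then
    (antecedent, consequent) lexicographically.
    """
    if not 0.0 < min_confidence <= 1.0:
        raise ValueError("min_confidence must be in (0, 1]")
    seqs = list(journeys.values() if isinstance(journeys, dict) else journeys)
    antecedent_support: Counter = Counter()
    followed: Counter = Counter()  # (a, b) -> journeys where b occurs after a
    for seq in seqs:
        seen = set(seq)
        for a in seen:
            antecedent_support[a] += 1
        first_pos = {}
        for i, x in enumerate(seq):
            first_pos.setdefault(x, i)
        pairs = set()
        for a, ia in first_pos.items():
            for j in range(ia + 1, len(seq)):
                b = seq[j]
                if b != a:
                    pairs.add((a, b))
        for pair in pairs:
            followed[pair] += 1
    rules = []
    for (a, b), n_followed in followed.items():
        support = antecedent_support[a]
        if support < min_support:
            continue
        confidence = n_followed / support
        if confidence >= min_confidence:
            rules.append(AnticipationRule(a, b, support, confidence))
    rules.sort(key=lambda r: (-r.confidence, -r.support, r.antecedent, r.consequent))
    return rules


# ----------------------------------------------------------------------
# Export
# ----------------------------------------------------------------------

def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def export_graph(graph: JourneyGraph, format: str = "dot") -> str:
    """Serialize the graph as Graphviz DOT or as JSON (lossless)."""
    if format == "dot":
        lines = ["digraph journeys {", "  rankdir=LR;"]
        lines.append(f'  {_dot_quote(START)} [shape=circle, label="start"];')
        lines.append(f'  {_dot_quote(END)} [shape=doublecircle, label="end"];')
        for node, count in sorted(graph.nodes.items()):
            lines.append(f'  {_dot_quote(node)} [label="{node}\\n{count}"];')
        for node, count in sorted(graph.start.items()):
            lines.append(f"  {_dot_quote(START)} -> {_dot_quote(node)} [label={count}];")
        for (a, b), count in sorted(graph.edges.items()):
            lines.append(f"  {_dot_quote(a)} -> {_dot_quote(b)} [label={count}];")
        for node, count in sorted(graph.end.items()):
            lines.append(f"  {_dot_quote(node)} -> {_dot_quote(END)} [label={count}];")
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "nodes": dict(graph.nodes),
            "edges": [[a, b, c] for (a, b), c in sorted(graph.edges.items())],
            "start": dict(graph.start),
            "end": dict(graph.end),
        }
        return json.dumps(doc, indent=1)
    raise ValueError(f"unknown format {format!r}")


def graph_from_json(text: str) -> JourneyGraph:
    doc = json.loads(text)
    return JourneyGraph(
        nodes=Counter(doc["nodes"]),
        edges=Counter({(a, b): c for a, b, c in doc["edges"]}),
        start=Counter(doc["start"]),
        end=Counter(doc["end"]),
    )


def parse_dot_nodes(dot: str) -> set[str]:
    """Node names declared in a DOT export (excluding pseudo-nodes)."""
    names = set(re.findall(r'^\s*"((?:[^"\\]|\\.)*)"\s*\[', dot, flags=re.M))
    return {n for n in names if n not in (START, END)}
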