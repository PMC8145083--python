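"""Per-slice word graph: sentence fusion, TextRank, and candidate paths.

Every templated statement of a slice is added to a shared directed graph
as a chain START -> w1 -> ... -> wk -> END. Content words with the same
lowercase form (and the same within-sentence occurrence index, so a word
appearing twice in one statement never folds a chain into a cycle) merge
into a single node; stopwords merge only under a guarded rule (an
existing node is reused only when the neighboring context coincides).
Because statements share template and content words, the graph fuses
questions and answers from different pairs, and every START -> END path
is a candidate summary sentence.

Word importance is computed with TextRank's damped update; a path's
informativeness is the sum of its words' importance scores. Candidate
paths are enumerated in order of total edge cost, where an edge traversed
by many statements is cheap (cost 1/count), so heavily shared fusions
rank first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._text import is_stopword
from .transcripts import Statement

__all__ = [
    "START",
    "END",
    "PathCandidate",
    "build_graph",
    "textrank",
    "informativeness",
    "enumerate_paths",
    "write_edgelist",
]

START = "__START__"
END = "__END__"


@dataclass
class PathCandidate:
    """A START->END word path (dummies excluded) with its scores."""

    words: tuple[str, ...]
    nodes: tuple[Hashable, ...]
    cost: float
    I: float = 0.0
    Q: float = 0.0

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def combined(self) -> float:
        return (self.I + self.Q) / self.n_words

    @property
    def text(self) -> str:
        return " ".join(self.words)


def _occurrence_indexed(tokens: Sequence[str]) -> list[tuple[str, int]]:
    seen: dict[str, int] = {}
    out = []
    for t in tokens:
        seen[t] = seen.get(t, 0) + 1
        out.append((t, seen[t]))
    return out


def build_graph(slice_statements: Sequence[Statement]) -> nx.DiGraph:
    """Fuse the statements of one slice into a word graph.

    Node keys: ``START``/``END`` strings, ``("w", token, occ)`` for content
    words, ``("s", token, occ, sid)`` for unmerged stopword occurrences.
    Every node carries a ``token`` attribute; edges carry a traversal
    ``count``.
    """
    if not slice_statements:
        raise ValueError("build_graph requires a non-empty slice")
    graph = nx.DiGraph()
    graph.add_node(START, token=START)
    graph.add_node(END, token=END)

    def bump(u: Hashable, v: Hashable) -> None:
        if graph.has_edge(u, v):
            graph[u][v]["count"] += 1
        else:
            graph.add_edge(u, v, count=1)

    for sid, statement in enumerate(slice_statements):
        tokens = statement.tokens()
        if not tokens:
            continue
        indexed = _occurrence_indexed(tokens)
        node_seq: list[Hashable] = [START]
        for pos, (token, occ) in enumerate(indexed):
            right_token = indexed[pos + 1][0] if pos + 1 < len(indexed) else END
            if not is_stopword(token):
                key: Hashable = ("w", token, occ)
                if key not in graph:
                    graph.add_node(key, token=token)
            else:
                key = _merge_stopword(
                    graph, token, node_seq[-1], right_token, sid, occ
                )
            node_seq.append(key)
        node_seq.append(END)
        for u, v in zip(node_seq, node_seq[1:]):
            bump(u, v)
    return graph


def _merge_stopword(
    graph: nx.DiGraph,
    token: str,
    left_node: Hashable,
    right_token: str,
    sid: int,
    occ: int,
) -> Hashable:
    """Guarded stopword merging: reuse an existing node for this token only
    if the left neighbor already feeds it and it already leads to a node
    with the upcoming right token. Otherwise a fresh per-statement node."""
    for node in graph.nodes:
        if not (isinstance(node, tuple) and node[0] == "s" and node[1] == token):
            continue
        left_ok = graph.has_edge(left_node, node)
        right_ok = any(
            graph.nodes[succ]["token"] == right_token
            for succ in graph.successors(node)
        )
        if left_ok and right_ok:
            return node
    key = ("s", token, occ, sid)
    graph.add_node(key, token=token)
    return key


def textrank(
    graph: nx.DiGraph,
    d: float = 0.78,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> dict[Hashable, float]:
    """Damped iterative node importance.

    Imp(v_i) = (1 - d) + d * sum_{v_j in In(v_i)} Imp(v_j) / |Out(v_j)|,
    iterated from all-ones until the max change is below ``tol``. The
    dummy START/END nodes take part in the iteration (they carry flow) but
    are excluded from the returned map.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"damping factor must be in (0, 1), got {d}")
    nodes = list(graph.nodes)
    imp = {n: 1.0 for n in nodes}
    out_deg = {n: graph.out_degree(n) for n in nodes}
    converged = False
    for _ in range(max_iter):
        nxt = {}
        delta = 0.0
        for v in nodes:
            s = sum(imp[u] / out_deg[u] for u in graph.predecessors(v))
            nxt[v] = (1.0 - d) + d * s
            delta = max(delta, abs(nxt[v] - imp[v]))
        imp = nxt
        if delta < tol:
            converged = True
            break
    if not converged:
        import logging

        logging.getLogger(__name__).warning(
            "textrank did not converge in %d iterations (delta > %g)",
            max_iter,
            tol,
        )
    return {n: imp[n] for n in nodes if n not in (START, END)}


def textrank_dense(graph: nx.DiGraph, d: float = 0.78) -> dict[Hashable, float]:
    """Closed-form fixed point of the TextRank update via a dense linear
    solve; an independent cross-check for small graphs."""
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[idx[v], idx[u]] = 1.0 / graph.out_degree(u)
    x = np.linalg.solve(np.eye(n) - d * A, (1.0 - d) * np.ones(n))
    return {node: float(x[idx[node]]) for node in nodes if node not in (START, END)}


def informativeness(
    candidate: PathCandidate | Sequence[Hashable],
    importance: Mapping[Hashable, float],
) -> float:
    """Sum of the path's word importance scores (dummies excluded)."""
    nodes = candidate.nodes if isinstance(candidate, PathCandidate) else candidate
    total = 0.0
    for node in nodes:
        if node in (START, END):
            continue
        if node not in importance:
            raise KeyError(f"unscored word node {node!r}")
        total += importance[node]
    return total


def _path_cost(graph: nx.DiGraph, path: Sequence[Hashable]) -> float:
    return sum(1.0 / graph[u][v]["count"] for u, v in zip(path, path[1:]))


def enumerate_paths(
    graph: nx.DiGraph,
    K: int = 100,
    min_len: int = 8,
    max_pulls: int | None = None,
) -> list[PathCandidate]:
    """Up to K distinct START->END paths by ascending total edge cost.

    Edge cost is 1/traversal_count, so fusions shared by many statements
    come first. Paths shorter than ``min_len`` words are discarded. Ties
    in cost are broken lexicographically on the word sequence, making the
    order fully deterministic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    for u, v in graph.edges:
        graph[u][v]["cost"] = 1.0 / graph[u][v]["count"]
    if max_pulls is None:
        max_pulls = 50 * K + 1000

    collected: list[tuple[float, tuple[str, ...], tuple[Hashable, ...]]] = []
    n_valid = 0
    kth_cost = None
    gen = nx.shortest_simple_paths(graph, START, END, weight="cost")
    for path in itertools.islice(gen, max_pulls):
        cost = _path_cost(graph, path)
        words = tuple(
            graph.nodes[n]["token"] for n in path if n not in (START, END)
        )
        if len(words) < min_len:
            continue
        collected.append((cost, words, tuple(path)))
        n_valid += 1
        if n_valid == K:
            kth_cost = sorted(c for c, _, _ in collected)[K - 1]
        # keep pulling equal-cost paths past K so lexicographic
        # tie-breaking is independent of generator order
        if kth_cost is not None and cost > kth_cost + 1e-9:
            break
    collected.sort(key=lambda item: (round(item[0], 9), item[1]))
    return [
        PathCandidate(words=w, nodes=nodes, cost=c)
        for c, w, nodes in collected[:K]
    ]


def write_edgelist(graph: nx.DiGraph, path) -> None:
    """Dump the graph as ``token<TAB>token<TAB>count`` lines."""
    from pathlib import Path

    lines = [
        f"{graph.nodes[u]['token']}\t{graph.nodes[v]['token']}\t{d['count']}\n"
        for u, v, d in graph.edges(data=True)
    ]
    Path(path).write_text("".join(lines), encoding="utf-8")


def write_dot(graph: nx.DiGraph, path) -> None:
    """Dump the graph in Graphviz DOT form for visualization; edge labels
    carry traversal counts."""
    from pathlib import Path

    ids = {n: f"n{i}" for i, n in enumerate(graph.nodes)}
    out = ["digraph wordgraph {"]
    for n, nid in ids.items():
        label = graph.nodes[n]["token"].replace('"', r"\"")
        out.append(f'  {nid} [label="{label}"];')
    for u, v, d in graph.edges(data=True):
        out.append(f'  {ids[u]} -> {ids[v]} [label="{d["count"]}"];')
    out.append("}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
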