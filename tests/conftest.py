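"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's matching machinery: driver
counts and control centralities are checked against the numeric generic rank
of the Kalman controllability matrix with random edge weights, and shortest
paths against exhaustive path enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from tepcontrol.synthetic import load_reference_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_reference_fixtures()


@pytest.fixture(scope="session")
def toys(fixtures):
    return fixtures["toy_graphs"]


def random_digraph(n: int, p: float, seed: int, self_loops: bool = False) -> nx.DiGraph:
    """Erdos-Renyi digraph over string labels n00..; always includes all nodes."""
    rng = np.random.default_rng(seed)
    net = nx.DiGraph()
    labels = [f"n{i:02d}" for i in range(n)]
    net.add_nodes_from(labels)
    for u in labels:
        for v in labels:
            if u == v and not self_loops:
                continue
            if rng.random() < p:
                net.add_edge(u, v, sign=1)
    return net


def kalman_generic_rank(net: nx.DiGraph, input_nodes, draws: int = 5, seed: int = 0) -> int:
    """Generic rank of [B, AB, ..., A^{n-1}B] with random edge weights.

    The generic (structural) rank is the maximum over weight draws; a handful
    of draws suffices since non-maximal rank sits on a measure-zero variety.
    """
    nodes = sorted(net.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(draws):
        a = np.zeros((n, n))
        for u, v in net.edges():
            a[idx[v], idx[u]] = rng.uniform(0.2, 1.8)
        b = np.zeros((n, len(input_nodes)))
        for j, v in enumerate(input_nodes):
            b[idx[v], j] = 1.0
        blocks = [b]
        for _ in range(n - 1):
            blocks.append(a @ blocks[-1])
        rank = np.linalg.matrix_rank(np.hstack(blocks), tol=1e-9)
        best = max(best, int(rank))
    return best


def brute_min_drivers(net: nx.DiGraph, draws: int = 5, seed: int = 0) -> int:
    """Smallest number of independent input signals achieving full generic rank.

    One input signal may wire into several nodes (a dense generic B column),
    so the minimum input count is found by raising k until [B, AB, ...] with a
    random dense n-by-k B reaches full rank.
    """
    nodes = sorted(net.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rng = np.random.default_rng(seed)
    for k in range(1, n + 1):
        for _ in range(draws):
            a = np.zeros((n, n))
            for u, v in net.edges():
                a[idx[v], idx[u]] = rng.uniform(0.2, 1.8)
            b = rng.uniform(0.2, 1.8, size=(n, k))
            blocks = [b]
            for _ in range(n - 1):
                blocks.append(a @ blocks[-1])
            if np.linalg.matrix_rank(np.hstack(blocks), tol=1e-9) == n:
                return k
    return n


def brute_min_weight_path(net, weights, source, target):
    """Exhaustive minimum-weight simple path with lexicographic tie-break."""

    def w(u, v):
        return weights[(u, v)] if (u, v) in weights else weights[(v, u)]

    best = None
    for path in nx.all_simple_paths(net, source, target):
        cost = sum(w(u, v) for u, v in zip(path, path[1:]))
        key = (cost, tuple(path))
        if best is None or key < best:
            best = key
    return best
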