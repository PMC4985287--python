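"""Fitness graphs, adaptive walks, basins, and evolutionary accessibility.

The directed fitness graph has one node per genotype with a fitness
value and an edge u -> v whenever u and v are one allowed substitution
apart and w(v) > w(u); peaks are nodes with out-degree 0.  Adaptive
walks fix one beneficial substitution at a time until a peak, with the
step chosen by one of three fixation models:

    greedy      the largest fitness gain fixes (clonal interference limit)
    correlated  P(k) = (w_k - w_i) / sum_n (w_n - w_i)   (SSWM)
    equal       P(k) = 1/M over the M fitter neighbors

Each step of a realized walk is classified against the walk's own
endpoint by the change in Hamming distance: towards (-1),
conversion (0), or detour (+1) — the latter two are the indirect-step
signatures of extra-dimensional bypass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .landscape import (
    AminoAcidAdjacency,
    FitnessLandscape,
    IMPUTED,
    LandscapeError,
    hamming_distance,
    logger,
    neighbors,
)
from .subgraphs import CORRELATED, EQUAL, FIXATION_MODELS, GREEDY

INACCESSIBLE = "inaccessible"
DIRECT = "direct"
INDIRECT_REQUIRED = "indirect_required"


def build_graph(
    ls: FitnessLandscape,
    adjacency: AminoAcidAdjacency | None = None,
    include_imputed: bool = True,
) -> nx.DiGraph:
    """Directed fitness graph over all genotypes with a fitness value."""
    if not ls.entries:
        raise LandscapeError("empty landscape")
    if adjacency is None:
        adjacency = AminoAcidAdjacency.full(ls.alphabet)
    g = nx.DiGraph()
    for gt, w in ls.entries.items():
        if not include_imputed and ls.origin.get(gt) == IMPUTED:
            continue
        g.add_node(gt, fitness=w)
    for gt in g.nodes:
        w = g.nodes[gt]["fitness"]
        for nb in neighbors(gt, adjacency):
            if nb in g and g.nodes[nb]["fitness"] > w:
                g.add_edge(gt, nb)
    logger.info("build_graph: %d nodes, %d edges (%s adjacency)",
                g.number_of_nodes(), g.number_of_edges(), adjacency.mode)
    return g


def find_peaks(g: nx.DiGraph) -> list[str]:
    """Local maxima (out-degree 0), sorted by fitness descending."""
    peaks = [n for n, deg in g.out_degree() if deg == 0]
    return sorted(peaks, key=lambda n: (-g.nodes[n]["fitness"], n))


def fixation_probabilities(g: nx.DiGraph, node: str, model: str) -> dict[str, float]:
    """Probability of each fitter neighbor fixing next; empty at a peak."""
    if model not in FIXATION_MODELS:
        raise LandscapeError(f"unknown fixation model {model!r}")
    succ = sorted(g.successors(node))
    if not succ:
        return {}
    if model == EQUAL:
        return {k: 1.0 / len(succ) for k in succ}
    w_i = g.nodes[node]["fitness"]
    gains = {k: g.nodes[k]["fitness"] - w_i for k in succ}
    if model == CORRELATED:
        total = sum(gains.values())
        return {k: v / total for k, v in gains.items()}
    best = max(gains.values())
    winner = min(k for k, v in gains.items() if v == best)  # lexicographic tie-break
    return {k: (1.0 if k == winner else 0.0) for k in succ}


@dataclass
class AdaptiveWalk:
    """One realized walk ending at a peak, with its step classes."""

    path: list[str]
    n_towards: int
    n_conversion: int
    n_detour: int

    @property
    def endpoint(self) -> str:
        return self.path[-1]

    @property
    def length(self) -> int:
        return len(self.path) - 1


def _classify_steps(path: list[str]) -> tuple[int, int, int]:
    end = path[-1]
    towards = conversion = detour = 0
    for u, v in zip(path, path[1:]):
        delta = hamming_distance(v, end) - hamming_distance(u, end)
        if delta == -1:
            towards += 1
        elif delta == 0:
            conversion += 1
        else:
            detour += 1
    return towards, conversion, detour


def simulate_walks(
    g: nx.DiGraph,
    start: str,
    model: str,
    n: int = 1000,
    seed: int = 0,
) -> list[AdaptiveWalk]:
    """Sample n adaptive walks from ``start`` until a peak is reached."""
    if start not in g:
        raise LandscapeError(f"start genotype {start} not in graph")
    rng = np.random.default_rng(seed)
    cache: dict[str, tuple[list[str], np.ndarray]] = {}

    def options(node: str):
        if node not in cache:
            probs = fixation_probabilities(g, node, model)
            ks = list(probs)
            cache[node] = (ks, np.array([probs[k] for k in ks]))
        return cache[node]

    walks = []
    for _ in range(n):
        path = [start]
        while True:
            ks, p = options(path[-1])
            if not ks:
                break
            path.append(ks[int(rng.choice(len(ks), p=p))])
        walks.append(AdaptiveWalk(path, *_classify_steps(path)))
    return walks


def summarize_walks(walks: list[AdaptiveWalk]) -> dict:
    """Mean length and step-class fractions over a set of walks."""
    lengths = [w.length for w in walks]
    steps = sum(lengths)
    tot = lambda attr: sum(getattr(w, attr) for w in walks)
    return {
        "n_walks": len(walks),
        "mean_length": float(np.mean(lengths)) if walks else float("nan"),
        "fraction_towards": tot("n_towards") / steps if steps else float("nan"),
        "fraction_conversion": tot("n_conversion") / steps if steps else float("nan"),
        "fraction_detour": tot("n_detour") / steps if steps else float("nan"),
    }


def expected_walk_lengths(g: nx.DiGraph, model: str) -> dict[str, float]:
    """Exact expected adaptive-walk length from every node (no sampling).

    Dynamic programming over the acyclic fitness graph:
    E[L(v)] = 1 + sum_k P(v -> k) E[L(k)], E[L(peak)] = 0.
    """
    out: dict[str, float] = {}
    for node in reversed(list(nx.topological_sort(g))):
        probs = fixation_probabilities(g, node, model)
        out[node] = sum(p * (1.0 + out[k]) for k, p in probs.items())
    return out


def genetic_distance(a: str, b: str, adjacency: AminoAcidAdjacency) -> int:
    """Minimum allowed substitutions turning a into b, summed per site."""
    return sum(adjacency.step_distance(x, y) for x, y in zip(a, b))


def accessibility(
    g: nx.DiGraph,
    start: str,
    targets: list[str],
    distance: str = "hamming",
    adjacency: AminoAcidAdjacency | None = None,
) -> dict[str, str]:
    """Classify each target: inaccessible / direct / indirect_required.

    A target is direct when the shortest fitness-increasing path equals
    the (Hamming or genetic-code) distance, indirect_required when the
    shortest path is longer, inaccessible when no monotone path exists.
    """
    if distance not in ("hamming", "genetic"):
        raise LandscapeError("distance must be 'hamming' or 'genetic'")
    if distance == "genetic" and adjacency is None:
        raise LandscapeError("genetic distance needs an adjacency matrix")
    lengths = nx.single_source_shortest_path_length(g, start)
    out = {}
    for t in targets:
        if t not in lengths:
            out[t] = INACCESSIBLE
            continue
        d = (
            hamming_distance(start, t)
            if distance == "hamming"
            else genetic_distance(start, t, adjacency)
        )
        out[t] = DIRECT if lengths[t] == d else INDIRECT_REQUIRED
    return out


@dataclass
class BasinMap:
    """Partition of the graph into greedy basins of attraction."""

    basins: dict[str, set]

    @property
    def sizes(self) -> dict[str, int]:
        return {p: len(s) for p, s in self.basins.items()}

    def coverage(self, peaks) -> float:
        """Fraction of all nodes whose greedy ascent ends at one of ``peaks``."""
        total = sum(len(s) for s in self.basins.values())
        covered = sum(len(self.basins.get(p, ())) for p in peaks)
        return covered / total if total else float("nan")


def greedy_basins(g: nx.DiGraph) -> BasinMap:
    """Deterministic greedy ascent from every node (ties lexicographic)."""
    target: dict[str, str] = {}

    def ascend(node: str) -> str:
        trail = []
        while node not in target:
            succ = list(g.successors(node))
            if not succ:
                target[node] = node
                break
            trail.append(node)
            best = max(g.nodes[k]["fitness"] for k in succ)
            node = min(k for k in succ if g.nodes[k]["fitness"] == best)
        peak = target[node]
        for t in trail:
            target[t] = peak
        return peak

    basins: dict[str, set] = {}
    for node in g.nodes:
        basins.setdefault(ascend(node), set()).add(node)
    return BasinMap(basins)


def outcome_entropy(
    g: nx.DiGraph, start: str, model: str = CORRELATED, n: int = 1000, seed: int = 0
) -> float:
    """Shannon entropy (nats) of endpoint-peak frequencies over n walks."""
    walks = simulate_walks(g, start, model, n, seed)
    ends: dict[str, int] = {}
    for w in walks:
        ends[w.endpoint] = ends.get(w.endpoint, 0) + 1
    return -sum((c / n) * math.log(c / n) for c in ends.values())
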