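"""Diallelic subgraphs, direct-path accessibility, and path realization.

A diallelic subgraph is the 2^d-variant sub-hypercube spanned by two
genotypes differing at d sites (each site restricted to its two
observed alleles).  Within a subgraph whose destination is the unique
fitness peak, a direct path is one of the d! orderings of the d
substitutions; it is accessible when fitness increases strictly at
every step.  Realization probabilities multiply per-step fixation
probabilities (greedy / correlated / equal models) along each path and
are then normalized over the d! direct paths; the skew of that
distribution is summarized by a Gini index.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import FitnessLandscape, LandscapeError, hamming_distance

GREEDY = "greedy"
CORRELATED = "correlated"
EQUAL = "equal"
FIXATION_MODELS = (GREEDY, CORRELATED, EQUAL)


@dataclass
class DiallelicSubgraph:
    """2^d fitness values between ``source`` and ``destination``.

    ``fitness[mask]`` is the fitness of the variant carrying the
    destination allele at exactly the differing positions whose bit is
    set in ``mask`` (bit t <-> ``positions[t]``); NaN marks a missing
    member.  Source is mask 0, destination is mask 2^d - 1.
    """

    source: str
    destination: str
    positions: tuple[int, ...]
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (2 ** self.d,):
            raise LandscapeError(f"expected {2 ** self.d} fitness values")

    @property
    def d(self) -> int:
        return len(self.positions)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.fitness)))

    def genotype(self, mask: int) -> str:
        g = list(self.source)
        for t, p in enumerate(self.positions):
            if mask & (1 << t):
                g[p] = self.destination[p]
        return "".join(g)

    def local_maxima(self) -> list[int]:
        """Masks with no strictly fitter neighbor inside the subgraph."""
        out = []
        for mask in range(2 ** self.d):
            f = self.fitness[mask]
            if not np.isfinite(f):
                continue
            fitter = any(
                np.isfinite(self.fitness[mask ^ (1 << t)])
                and self.fitness[mask ^ (1 << t)] > f
                for t in range(self.d)
            )
            if not fitter:
                out.append(mask)
        return out


def extract_subgraph(ls: FitnessLandscape, source: str, destination: str) -> DiallelicSubgraph:
    """Build the sub-hypercube between two genotypes of a landscape."""
    if len(source) != len(destination):
        raise LandscapeError("source and destination must have equal length")
    positions = tuple(i for i, (x, y) in enumerate(zip(source, destination)) if x != y)
    if not positions:
        raise LandscapeError("source and destination are identical")
    fitness = np.full(2 ** len(positions), np.nan)
    sub = DiallelicSubgraph(source, destination, positions, fitness)
    for mask in range(2 ** len(positions)):
        w = ls.get(sub.genotype(mask))
        if w is not None:
            sub.fitness[mask] = w
    return sub


def enumerate_single_peak_subgraphs(
    ls: FitnessLandscape,
    source: str,
    direction: str = "from_source",
    fitness_window: tuple[float, float] | None = None,
    require_reachable: bool = False,
) -> list[DiallelicSubgraph]:
    """Complete subgraphs to maximally distant genotypes with a unique peak.

    Scans every genotype differing from ``source`` at all L sites
    (optionally restricted to that genotype's fitness window), keeps
    the subgraphs with no missing member in which the adaptation
    endpoint (the distant genotype for ``from_source``, the source
    itself for ``to_source``) is the only local fitness maximum.
    Returned subgraphs are oriented so mask 0 is the adaptation start
    and the full mask the endpoint, whichever the direction.  With
    ``require_reachable`` the endpoint must additionally be reachable
    from the start by some strictly fitness-increasing path inside the
    subgraph.
    """
    if direction not in ("from_source", "to_source"):
        raise LandscapeError("direction must be 'from_source' or 'to_source'")
    L = ls.L
    alt = {aa: [x for x in ls.alphabet if x != aa] for aa in set(source)}
    out = []
    full = 2 ** L - 1
    for combo in itertools.product(*(alt[aa] for aa in source)):
        dest = "".join(combo)
        w_dest = ls.get(dest)
        if w_dest is None:
            continue
        if fitness_window is not None and not (fitness_window[0] <= w_dest <= fitness_window[1]):
            continue
        if direction == "from_source":
            sub = extract_subgraph(ls, source, dest)
        else:
            sub = extract_subgraph(ls, dest, source)
        if not sub.complete:
            continue
        if sub.local_maxima() != [full]:
            continue
        if require_reachable and not _monotone_reachable(sub, 0, full):
            continue
        out.append(sub)
    return out


def _monotone_reachable(sub: DiallelicSubgraph, start: int, goal: int) -> bool:
    """True if a strictly fitness-increasing walk start -> goal exists."""
    seen = {start}
    stack = [start]
    while stack:
        m = stack.pop()
        if m == goal:
            return True
        for t in range(sub.d):
            nb = m ^ (1 << t)
            if nb not in seen and sub.fitness[nb] > sub.fitness[m]:
                seen.add(nb)
                stack.append(nb)
    return False


def accessible_direct_paths(sub: DiallelicSubgraph) -> int:
    """Count substitution orderings with strictly increasing fitness."""
    if not sub.complete:
        raise LandscapeError("subgraph has missing members")
    d = sub.d
    n = 0
    for order in itertools.permutations(range(d)):
        mask, ok = 0, True
        for t in order:
            nxt = mask | (1 << t)
            if not sub.fitness[nxt] > sub.fitness[mask]:
                ok = False
                break
            mask = nxt
        n += ok
    return n


def _fitter_neighbors(sub: DiallelicSubgraph, mask: int) -> list[int]:
    return [
        mask ^ (1 << t)
        for t in range(sub.d)
        if sub.fitness[mask ^ (1 << t)] > sub.fitness[mask]
    ]


def step_probability(sub: DiallelicSubgraph, mask: int, nxt: int, model: str) -> float:
    """Fixation probability of the step mask -> nxt within the subgraph.

    The denominator runs over all fitter neighbors of ``mask`` inside
    the subgraph (including backward bit-flips).  Deleterious or
    neutral steps have probability 0.  Greedy ties are broken toward
    the lexicographically smallest genotype.
    """
    fitter = _fitter_neighbors(sub, mask)
    if nxt not in fitter:
        return 0.0
    if model == EQUAL:
        return 1.0 / len(fitter)
    if model == CORRELATED:
        gains = [sub.fitness[k] - sub.fitness[mask] for k in fitter]
        return (sub.fitness[nxt] - sub.fitness[mask]) / sum(gains)
    if model == GREEDY:
        best = max(fitter, key=lambda k: (sub.fitness[k], sub.genotype(k)))
        ties = [k for k in fitter if sub.fitness[k] == sub.fitness[best]]
        pick = min(ties, key=sub.genotype)
        return 1.0 if nxt == pick else 0.0
    raise LandscapeError(f"unknown fixation model {model!r}")


@dataclass
class PathDistribution:
    """Realization probabilities of the d! direct paths of a subgraph."""

    paths: list[tuple[int, ...]]
    probabilities: np.ndarray
    accessible_count: int
    all_zero: bool

    @property
    def gini(self) -> float:
        return gini_index(self.probabilities)


def path_probabilities(sub: DiallelicSubgraph, model: str = CORRELATED) -> PathDistribution:
    """Per-path realization probabilities, normalized over direct paths."""
    if not sub.complete:
        raise LandscapeError("subgraph has missing members")
    d = sub.d
    paths, probs = [], []
    for order in itertools.permutations(range(d)):
        mask, p = 0, 1.0
        for t in order:
            nxt = mask | (1 << t)
            p *= step_probability(sub, mask, nxt, model)
            if p == 0.0:
                break
            mask = nxt
        paths.append(order)
        probs.append(p)
    probs = np.array(probs)
    total = probs.sum()
    all_zero = total == 0.0
    if not all_zero:
        probs = probs / total
    return PathDistribution(paths, probs, int(np.count_nonzero(probs)), all_zero)


def gini_index(probabilities) -> float:
    """Skew of a path-probability distribution, in [0, 1].

    Probabilities are sorted descending (inaccessible paths enter as
    0), cumulated into A_1..A_t, and scored as
    (2*sum(A_1..A_{t-1}) + A_t - t) / (t - 1): 0 for a uniform
    distribution, 1 when a single path carries everything.
    """
    p = np.asarray(probabilities, dtype=float)
    t = p.size
    if t < 2:
        raise LandscapeError("Gini index needs at least two paths")
    if np.any(p < 0):
        raise LandscapeError("negative probability")
    total = p.sum()
    if total == 0:
        raise LandscapeError("all-zero path distribution has no Gini index")
    p = np.sort(p)[::-1] / total
    A = np.cumsum(p)
    return float((2.0 * A[:-1].sum() + A[-1] - t) / (t - 1))
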