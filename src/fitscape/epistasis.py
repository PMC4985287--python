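"""Pairwise epistasis: magnitude, sign classification, and ruggedness.

Epistasis between two substitutions a and b on a background BG is the
deviation of the double mutant's log fitness from additivity:

    eps = ln(w_ab/w_BG) - ln(w_a/w_BG) - ln(w_b/w_BG)

Because the assay cannot distinguish fitness values below a detection
limit (~0.01 relative to WT), raw eps near that limit is unreliable;
three adjustment rules zero out or one-sidedly clip eps when any of
the four variants sits below the limit.

A quad is classified by whether each mutation's fitness effect keeps
its sign across the partner's backgrounds: neither flip = magnitude,
one flip = sign, both flips = reciprocal sign.  The ruggedness of a
2^d sub-hypercube is f_sign + 2*f_reciprocal over its quads.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .landscape import FitnessLandscape, LandscapeError

DETECTION_LIMIT = 0.01

MAGNITUDE = "magnitude"
SIGN = "sign"
RECIPROCAL_SIGN = "reciprocal_sign"
UNDEFINED = "undefined"


class UndefinedEpistasis(ValueError):
    """Raw epsilon is undefined (a fitness value <= 0)."""


def epsilon(w_ab: float, w_a: float, w_b: float, w_bg: float) -> float:
    """Raw relative epistasis; requires all four fitness values > 0."""
    if min(w_ab, w_a, w_b, w_bg) <= 0:
        raise UndefinedEpistasis(
            f"epsilon undefined for fitness values ({w_ab}, {w_a}, {w_b}, {w_bg})"
        )
    return math.log(w_ab / w_bg) - math.log(w_a / w_bg) - math.log(w_b / w_bg)


def epsilon_adjusted(
    w_ab: float,
    w_a: float,
    w_b: float,
    w_bg: float,
    detection_limit: float = DETECTION_LIMIT,
) -> float:
    """Detection-limit-adjusted epistasis.

    Rule 1: if every mutant's fitness relative to the background is
    below the limit, epistasis is 0 (nothing is resolvable).
    Rule 2: if either single mutant is at the limit, keep only eps > 0
    (its true fitness may be lower than recorded, so negative eps may
    be an artifact).
    Rule 3: if the double mutant is at the limit, keep only eps < 0.
    Rules 2 and 3 together force 0.  Otherwise raw eps is returned.

    Fitness values of exactly 0 are floored at the detection limit
    inside the logarithm; any such value necessarily triggers a rule,
    which then clips the sign of the result.
    """
    if detection_limit <= 0:
        raise LandscapeError("detection_limit must be > 0")
    for w in (w_ab, w_a, w_b, w_bg):
        if w < 0 or not np.isfinite(w):
            raise LandscapeError(f"fitness values must be finite and >= 0, got {w}")
    lim = detection_limit
    if w_bg > 0 and max(w_ab / w_bg, w_a / w_bg, w_b / w_bg) < lim:
        return 0.0  # Rule 1
    floor = lambda w: max(w, lim)
    rel = lambda w: max(w, lim) / max(w_bg, lim)
    eps = math.log(rel(w_ab)) - math.log(rel(w_a)) - math.log(rel(w_b))
    rule2 = min(w_a, w_b, floor(w_a) / floor(w_bg), floor(w_b) / floor(w_bg)) < lim
    rule3 = min(w_ab, floor(w_ab) / floor(w_bg)) < lim
    if rule2 and rule3:
        return 0.0
    if rule2:
        return max(0.0, eps)
    if rule3:
        return min(0.0, eps)
    return eps


def classify(w_bg: float, w_a: float, w_b: float, w_ab: float) -> str:
    """Type of the quad: magnitude, sign, or reciprocal sign.

    A mutation 'flips' when its effect is strictly positive on one of
    the partner's backgrounds and strictly negative on the other; a
    zero effect on either background never counts as a flip (ties are
    magnitude).
    """
    for w in (w_bg, w_a, w_b, w_ab):
        if w is None or not np.isfinite(w):
            return UNDEFINED
    flip_a = (w_a - w_bg) * (w_ab - w_b) < 0
    flip_b = (w_b - w_bg) * (w_ab - w_a) < 0
    if flip_a and flip_b:
        return RECIPROCAL_SIGN
    if flip_a or flip_b:
        return SIGN
    return MAGNITUDE


@dataclass
class EpistasisQuad:
    """One pairwise interaction: four variants on a 2x2 hypercube face.

    ``positions`` are 0-based site indices; ``a`` and ``b`` the mutant
    amino acids at those positions relative to ``background``.
    """

    background: str
    positions: tuple[int, int]
    a: str
    b: str
    w_bg: float
    w_a: float
    w_b: float
    w_ab: float
    epsilon_raw: float | None
    epsilon_adjusted: float
    type: str

    @property
    def g_a(self) -> str:
        i = self.positions[0]
        return self.background[:i] + self.a + self.background[i + 1:]

    @property
    def g_b(self) -> str:
        j = self.positions[1]
        return self.background[:j] + self.b + self.background[j + 1:]

    @property
    def g_ab(self) -> str:
        i, j = self.positions
        g = self.background[:i] + self.a + self.background[i + 1:]
        return g[:j] + self.b + g[j + 1:]


def make_quad(
    ls: FitnessLandscape,
    background: str,
    pos_i: int,
    pos_j: int,
    a: str,
    b: str,
    detection_limit: float = DETECTION_LIMIT,
) -> EpistasisQuad | None:
    """Assemble a quad from a landscape; None if any member is missing."""
    if pos_i >= pos_j:
        raise LandscapeError("positions must satisfy pos_i < pos_j")
    if a == background[pos_i] or b == background[pos_j]:
        raise LandscapeError("substitutions must differ from the background alleles")
    g_a = background[:pos_i] + a + background[pos_i + 1:]
    g_b = background[:pos_j] + b + background[pos_j + 1:]
    g_ab = g_a[:pos_j] + b + g_a[pos_j + 1:]
    ws = [ls.get(g) for g in (background, g_a, g_b, g_ab)]
    if any(w is None for w in ws):
        return None
    w_bg, w_a, w_b, w_ab = ws
    try:
        raw = epsilon(w_ab, w_a, w_b, w_bg)
    except UndefinedEpistasis:
        raw = None
    adj = epsilon_adjusted(w_ab, w_a, w_b, w_bg, detection_limit)
    return EpistasisQuad(
        background, (pos_i, pos_j), a, b, w_bg, w_a, w_b, w_ab,
        raw, adj, classify(w_bg, w_a, w_b, w_ab),
    )


@dataclass
class NeighborhoodClasses:
    n_total: int
    n_classifiable: int
    counts: dict
    fractions: dict


def classify_neighborhood(
    ls: FitnessLandscape,
    center: str | None = None,
    sample_size: int | None = None,
    seed: int = 0,
    detection_limit: float = DETECTION_LIMIT,
) -> NeighborhoodClasses:
    """Epistasis-type fractions around a center, or over a random sample.

    Center mode enumerates every 2x2 face containing ``center`` as the
    background (all site pairs x all substitution pairs).  Sample mode
    draws (background, site pair, substitution pair) uniformly with
    replacement.  Quads with a missing member count toward ``n_total``
    but not toward the classified fractions.
    """
    quads: list[EpistasisQuad | None] = []
    alphabet = ls.alphabet
    L = ls.L
    if center is not None:
        for i, j in itertools.combinations(range(L), 2):
            for a in alphabet:
                if a == center[i]:
                    continue
                for b in alphabet:
                    if b == center[j]:
                        continue
                    quads.append(make_quad(ls, center, i, j, a, b, detection_limit))
    elif sample_size is not None:
        rng = np.random.default_rng(seed)
        pairs = list(itertools.combinations(range(L), 2))
        space = len(alphabet) ** L
        for _ in range(sample_size):
            idx = int(rng.integers(space))
            bg = "".join(
                alphabet[(idx // len(alphabet) ** p) % len(alphabet)] for p in range(L)
            )
            i, j = pairs[int(rng.integers(len(pairs)))]
            a = alphabet[int(rng.integers(len(alphabet) - 1))]
            b = alphabet[int(rng.integers(len(alphabet) - 1))]
            # skip the background allele without biasing the draw
            a = a if a != bg[i] else alphabet[-1]
            b = b if b != bg[j] else alphabet[-1]
            if bg in ls.missing:
                quads.append(None)
                continue
            quads.append(make_quad(ls, bg, i, j, a, b, detection_limit))
    else:
        raise LandscapeError("give either a center genotype or a sample_size")
    counts = {MAGNITUDE: 0, SIGN: 0, RECIPROCAL_SIGN: 0}
    n_cls = 0
    for q in quads:
        if q is None or q.type == UNDEFINED:
            continue
        counts[q.type] += 1
        n_cls += 1
    if n_cls == 0:
        raise LandscapeError("no classifiable quads")
    fractions = {k: v / n_cls for k, v in counts.items()}
    return NeighborhoodClasses(len(quads), n_cls, counts, fractions)


@dataclass
class RuggednessScore:
    f_magnitude: float
    f_sign: float
    f_reciprocal: float
    n_quads: int

    @property
    def score(self) -> float:
        """Ruggedness = f_sign + 2*f_reciprocal, in [0, 2]."""
        return self.f_sign + 2.0 * self.f_reciprocal


def ruggedness(sub) -> RuggednessScore:
    """Classify all C(d,2) * 2^(d-2) quads of a complete diallelic subgraph.

    For d = 4 that is 6 site pairs x 4 backgrounds = 24 quads.
    """
    if not sub.complete:
        raise LandscapeError("ruggedness requires a complete subgraph")
    d = sub.d
    f = sub.fitness
    counts = {MAGNITUDE: 0, SIGN: 0, RECIPROCAL_SIGN: 0}
    n = 0
    for p, q in itertools.combinations(range(d), 2):
        rest = [r for r in range(d) if r not in (p, q)]
        for bits in itertools.product((0, 1), repeat=len(rest)):
            bg = sum(b << r for r, b in zip(rest, bits))
            t = classify(f[bg], f[bg | (1 << p)], f[bg | (1 << q)], f[bg | (1 << p) | (1 << q)])
            if t != UNDEFINED:
                counts[t] += 1
                n += 1
    if n == 0:
        raise LandscapeError("no classifiable quads in subgraph")
    return RuggednessScore(
        counts[MAGNITUDE] / n, counts[SIGN] / n, counts[RECIPROCAL_SIGN] / n, n
    )
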