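"""Extra-dimensional bypass of reciprocal sign epistasis.

When both direct orderings across a reciprocal-sign 2x2 face are
blocked, adaptation can still reach the double mutant by leaving the
face: a *conversion* bypass substitutes one interacting site with a
third amino acid (00 -> 20 -> 21 -> 11), a *detour* bypass gains and
later loses a mutation at an additional site
(000 -> 100 -> 110/101 -> 111 -> 011).  On the 3-site Boolean cube a
Taylor expansion

    f(z1, z2, z3) = a0 + a1 z1 + a2 z2 + a3 z3
                    + a12 z1 z2 + a13 z1 z3 + a23 z2 z3 + a123 z1 z2 z3

makes the role of higher-order epistasis explicit: for the detour
scenarios in which the lifted face turns to magnitude epistasis (B) or
to sign epistasis with the third-site gain beneficial on the remaining
deleterious single mutant (C), the edge inequalities force a123 < 0,
i.e. a three-way interaction is mathematically required; for the other
sign scenario (D) the edges are satisfiable with a123 = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .epistasis import (
    DETECTION_LIMIT,
    MAGNITUDE,
    RECIPROCAL_SIGN,
    SIGN,
    EpistasisQuad,
    classify,
    make_quad,
)
from .landscape import FitnessLandscape, LandscapeError

SCENARIO_B = "B"
SCENARIO_C = "C"
SCENARIO_D = "D"


@dataclass
class TaylorCube:
    """Taylor coefficients of a 3-site diallelic cube.

    Index convention follows f_{z3 z2 z1}: sites 1 and 2 are the
    interacting pair, site 3 the extra (detour) site, so f001 is the
    site-1 single mutant and f100 the third-site single mutant.
    """

    f000: float
    f001: float
    f010: float
    f011: float
    f100: float
    f101: float
    f110: float
    f111: float

    @property
    def a0(self) -> float:
        return self.f000

    @property
    def a1(self) -> float:
        return self.f001 - self.f000

    @property
    def a2(self) -> float:
        return self.f010 - self.f000

    @property
    def a3(self) -> float:
        return self.f100 - self.f000

    @property
    def a12(self) -> float:
        return self.f011 - self.f010 - self.f001 + self.f000

    @property
    def a13(self) -> float:
        return self.f101 - self.f100 - self.f001 + self.f000

    @property
    def a23(self) -> float:
        return self.f110 - self.f100 - self.f010 + self.f000

    @property
    def a123(self) -> float:
        return (
            self.f111 - self.f110 - self.f101 - self.f011
            + self.f100 + self.f010 + self.f001 - self.f000
        )

    def reconstruct(self) -> dict[str, float]:
        """Rebuild the 8 fitness values from the coefficients (exact)."""
        a = self
        return {
            "f000": a.a0,
            "f001": a.a0 + a.a1,
            "f010": a.a0 + a.a2,
            "f100": a.a0 + a.a3,
            "f011": a.a0 + a.a1 + a.a2 + a.a12,
            "f101": a.a0 + a.a1 + a.a3 + a.a13,
            "f110": a.a0 + a.a2 + a.a3 + a.a23,
            "f111": a.a0 + a.a1 + a.a2 + a.a3 + a.a12 + a.a13 + a.a23 + a.a123,
        }


def taylor_coefficients(fitness_values) -> TaylorCube:
    """TaylorCube from 8 values ordered f000, f001, ... f111 (f_{z3 z2 z1})."""
    vals = [float(v) for v in fitness_values]
    if len(vals) != 8 or not all(np.isfinite(vals)):
        raise LandscapeError("need 8 finite fitness values")
    return TaylorCube(*vals)


def _scenario_inequalities(cube: TaylorCube, scenario: str) -> list[tuple[str, bool]]:
    c = cube
    common = [
        ("f001 < f000", c.f001 < c.f000),
        ("f010 < f000", c.f010 < c.f000),
        ("f011 > f001", c.f011 > c.f001),
        ("f011 > f010", c.f011 > c.f010),
        ("f100 > f000", c.f100 > c.f000),
        ("f111 < f011", c.f111 < c.f011),
    ]
    if scenario == SCENARIO_B:
        extra = [("f101 > f100", c.f101 > c.f100), ("f110 > f100", c.f110 > c.f100)]
    elif scenario == SCENARIO_C:
        # a tie (f101 == f001, i.e. a3 + a13 == 0) still forces a123 < 0,
        # so C admits the non-strict inequality
        extra = [
            ("f110 > f100", c.f110 > c.f100),
            ("f101 >= f001", c.f101 >= c.f001),
        ]
    elif scenario == SCENARIO_D:
        extra = [
            ("f110 > f100", c.f110 > c.f100),
            ("f101 < f001", c.f101 < c.f001),
        ]
    else:
        raise LandscapeError(f"unknown scenario {scenario!r}")
    return common + extra


def verify_necessity(cube: TaylorCube, scenario: str, tol: float = 1e-12) -> bool:
    """Whether the scenario's edge inequalities force a123 != 0.

    Scenarios B and C return True (and the cube must indeed satisfy
    a123 < 0, which is checked); scenario D returns False — a
    three-way term is not required there.  Raises if the cube violates
    the scenario's defining inequalities.
    """
    checks = _scenario_inequalities(cube, scenario)
    bad = [name for name, ok in checks if not ok]
    if bad:
        raise LandscapeError(f"cube violates scenario-{scenario} inequalities: {bad}")
    if scenario in (SCENARIO_B, SCENARIO_C):
        if cube.a123 > -tol:
            raise AssertionError(
                f"scenario-{scenario} cube with a123 = {cube.a123} contradicts the theorem"
            )
        return True
    return False


@dataclass
class BypassReport:
    """Outcome of testing every bypass candidate around one focal quad."""

    quad: EpistasisQuad
    kind: str  # "conversion" or "detour"
    found: list  # conversion: (position, aa); detour: (position, aa, scenario)
    n_candidates: int
    n_skipped_missing: int

    @property
    def success(self) -> bool:
        return bool(self.found)

    @property
    def count(self) -> int:
        return len(self.found)


def is_reciprocal_trap(quad: EpistasisQuad) -> bool:
    """The canonical reciprocal-sign trap: both single mutants deleterious,
    double mutant fitter than the background, so every direct ordering is
    blocked and only an extra dimension can rescue adaptation."""
    return (
        quad.type == RECIPROCAL_SIGN
        and quad.w_ab > quad.w_bg
        and quad.w_a < quad.w_bg
        and quad.w_b < quad.w_bg
    )


def _require_reciprocal(quad: EpistasisQuad) -> None:
    if quad.type != RECIPROCAL_SIGN:
        raise LandscapeError("focal quad is not reciprocal sign epistasis")
    if not is_reciprocal_trap(quad):
        raise LandscapeError(
            "bypass analysis needs the reciprocal trap: deleterious singles, "
            "double mutant fitter than the background"
        )


def _increasing(ws) -> bool:
    return all(
        a is not None and b is not None and b > a for a, b in zip(ws, ws[1:])
    )


def find_conversion_bypasses(ls: FitnessLandscape, quad: EpistasisQuad) -> BypassReport:
    """Bypass via a third amino acid at one of the two interacting sites.

    For each alternative amino acid c at site i (or j), the candidate
    path is BG -> BG[i=c] -> BG[i=c, j=b] -> ab (the conversion is
    gained, the partner mutation fixed, then the conversion replaced by
    the focal allele); success requires strictly increasing fitness.
    At most 2*(A-2) candidates exist for an A-letter alphabet (36 for
    the 20 amino acids).  Candidates with a missing intermediate are
    skipped and counted.
    """
    _require_reciprocal(quad)
    i, j = quad.positions
    bg = quad.background
    found, n_cand, n_skip = [], 0, 0
    for pos, own, other_pos, other_aa in (
        (i, quad.a, j, quad.b),
        (j, quad.b, i, quad.a),
    ):
        for c in ls.alphabet:
            if c == bg[pos] or c == own:
                continue
            n_cand += 1
            g1 = bg[:pos] + c + bg[pos + 1:]
            g2 = g1[:other_pos] + other_aa + g1[other_pos + 1:]
            w1, w2 = ls.get(g1), ls.get(g2)
            if w1 is None or w2 is None:
                n_skip += 1
                continue
            if _increasing([quad.w_bg, w1, w2, quad.w_ab]):
                found.append((pos, c))
    return BypassReport(quad, "conversion", found, n_cand, n_skip)


def _detour_scenario(
    w_a: float, w_b: float, w_l: float, w_la: float, w_lb: float, w_lab: float
) -> tuple[str, str]:
    """Scenario of a successful detour and the cube orientation certifying it.

    Returns (scenario, slot2) where slot2 in {"a", "b"} names the focal
    mutation placed in the z2 slot of the Taylor cube: the one whose
    lifted single mutant carries an ascending route (f110 > f100 and
    f111 > f110).  Scenario B when the lifted face shows magnitude
    epistasis; otherwise C when some valid orientation has the
    third-site gain beneficial on the other focal single mutant
    (f101 > f001, i.e. a3 + a13 > 0), else D.
    """
    lifted_type = classify(w_l, w_la, w_lb, w_lab)
    # orientations whose z2 single carries the ascending lifted route,
    # paired with the yellow-edge test f101 > f001 for that orientation
    options = []
    if w_la > w_l and w_lab > w_la:
        options.append(("a", w_lb >= w_b))
    if w_lb > w_l and w_lab > w_lb:
        options.append(("b", w_la >= w_a))
    if not options:
        raise LandscapeError("no ascending route through the lifted face")
    if lifted_type == MAGNITUDE:
        return SCENARIO_B, options[0][0]
    for slot2, yellow in options:
        if yellow:
            return SCENARIO_C, slot2
    return SCENARIO_D, options[0][0]


def find_detour_bypasses(ls: FitnessLandscape, quad: EpistasisQuad) -> BypassReport:
    """Bypass via gaining, then losing, a mutation at a third site.

    For each third position p and amino acid m there, the candidate
    path is BG -> +m -> +m+a or +m+b -> +m+a+b -> ab; success requires
    a strictly increasing route through either intermediate.  At most
    (A-1)*(L-2) candidates exist (38 for the 20-letter, 4-site space).
    Each success is classified by the epistasis type of the focal pair
    on the lifted (+m) background: magnitude -> scenario B; sign ->
    scenario C when the third-site gain is beneficial on the background
    of the still-deleterious focal single mutant, D otherwise.
    """
    _require_reciprocal(quad)
    if ls.L < 3:
        raise LandscapeError("detour bypass needs at least 3 sites")
    i, j = quad.positions
    bg = quad.background
    found, n_cand, n_skip = [], 0, 0
    for p in range(ls.L):
        if p in (i, j):
            continue
        for m in ls.alphabet:
            if m == bg[p]:
                continue
            n_cand += 1
            lift = bg[:p] + m + bg[p + 1:]
            lift_a = lift[:i] + quad.a + lift[i + 1:]
            lift_b = lift[:j] + quad.b + lift[j + 1:]
            lift_ab = lift_a[:j] + quad.b + lift_a[j + 1:]
            ws = [ls.get(g) for g in (lift, lift_a, lift_b, lift_ab)]
            if any(w is None for w in ws):
                n_skip += 1
                continue
            w_l, w_la, w_lb, w_lab = ws
            ok_via_a = _increasing([quad.w_bg, w_l, w_la, w_lab, quad.w_ab])
            ok_via_b = _increasing([quad.w_bg, w_l, w_lb, w_lab, quad.w_ab])
            if not (ok_via_a or ok_via_b):
                continue
            scenario, _ = _detour_scenario(
                quad.w_a, quad.w_b, w_l, w_la, w_lb, w_lab
            )
            found.append((p, m, scenario))
    return BypassReport(quad, "detour", found, n_cand, n_skip)


def cube_for_detour(ls: FitnessLandscape, quad: EpistasisQuad, p: int, m: str) -> TaylorCube:
    """The 3-site Taylor cube behind one detour candidate (focal pair + site p).

    The cube is oriented per :func:`_detour_scenario`: the focal
    mutation carrying the ascending lifted route takes the z2 slot, so
    the scenario's defining inequalities read off the named f-values.
    """
    i, j = quad.positions
    bg = quad.background
    lift = bg[:p] + m + bg[p + 1:]
    lift_a = lift[:i] + quad.a + lift[i + 1:]
    lift_b = lift[:j] + quad.b + lift[j + 1:]
    lift_ab = lift_a[:j] + quad.b + lift_a[j + 1:]
    names = [bg, quad.g_a, quad.g_b, quad.g_ab, lift, lift_a, lift_b, lift_ab]
    ws = [ls.get(g) for g in names]
    if any(w is None for w in ws):
        raise LandscapeError("cube member missing")
    w_bg, w_a, w_b, w_ab, w_l, w_la, w_lb, w_lab = ws
    _, slot2 = _detour_scenario(w_a, w_b, w_l, w_la, w_lb, w_lab)
    if slot2 == "a":
        w_a, w_b, w_la, w_lb = w_b, w_a, w_lb, w_la
    return taylor_coefficients([w_bg, w_a, w_b, w_ab, w_l, w_la, w_lb, w_lab])


@dataclass
class BypassSurvey:
    """Sampled-quad bypass statistics over a landscape."""

    n_sampled: int
    n_reciprocal: int
    n_tested: int
    n_complete_candidates: dict
    conversion_success: int
    detour_success: int
    conversion_success_complete: int
    detour_success_complete: int
    conversion_counts: list
    detour_counts: list

    def summary(self) -> dict:
        def frac(k, n):
            return k / n if n else float("nan")

        return {
            "n_sampled": self.n_sampled,
            "n_reciprocal": self.n_reciprocal,
            "conversion_success_fraction": frac(self.conversion_success, self.n_tested),
            "conversion_success_fraction_complete": frac(
                self.conversion_success_complete, self.n_complete_candidates["conversion"]
            ),
            "detour_success_fraction": frac(self.detour_success, self.n_tested),
            "detour_success_fraction_complete": frac(
                self.detour_success_complete, self.n_complete_candidates["detour"]
            ),
            "mean_conversion_bypasses": float(np.mean(self.conversion_counts))
            if self.conversion_counts
            else float("nan"),
            "mean_detour_bypasses": float(np.mean(self.detour_counts))
            if self.detour_counts
            else float("nan"),
        }


def survey_bypasses(
    ls: FitnessLandscape,
    n_samples: int,
    seed: int = 0,
    detection_limit: float = DETECTION_LIMIT,
) -> BypassSurvey:
    """Sample 2x2 faces, keep adaptive reciprocal-sign quads, test bypasses.

    Faces are drawn uniformly over (background, site pair, substitution
    pair) with replacement; a quad enters the test set when it is
    classifiable, reciprocal sign, and its double mutant is fitter than
    its background.  Success fractions are reported against both the
    full test set and the subset whose candidate lists had no missing
    intermediates.
    """
    rng = np.random.default_rng(seed)
    alphabet = ls.alphabet
    L = ls.L
    pairs = list(itertools.combinations(range(L), 2))
    space = len(alphabet) ** L
    n_reciprocal = n_tested = 0
    conv_succ = det_succ = conv_succ_c = det_succ_c = 0
    complete = {"conversion": 0, "detour": 0}
    conv_counts, det_counts = [], []
    for _ in range(n_samples):
        idx = int(rng.integers(space))
        bg = "".join(alphabet[(idx // len(alphabet) ** p) % len(alphabet)] for p in range(L))
        i, j = pairs[int(rng.integers(len(pairs)))]
        a = alphabet[int(rng.integers(len(alphabet) - 1))]
        b = alphabet[int(rng.integers(len(alphabet) - 1))]
        a = a if a != bg[i] else alphabet[-1]
        b = b if b != bg[j] else alphabet[-1]
        if bg in ls.missing:
            continue
        quad = make_quad(ls, bg, i, j, a, b, detection_limit)
        if quad is None or quad.type != RECIPROCAL_SIGN:
            continue
        n_reciprocal += 1
        if not is_reciprocal_trap(quad):
            continue
        n_tested += 1
        conv = find_conversion_bypasses(ls, quad)
        det = find_detour_bypasses(ls, quad)
        conv_succ += conv.success
        det_succ += det.success
        conv_counts.append(conv.count)
        det_counts.append(det.count)
        if conv.n_skipped_missing == 0:
            complete["conversion"] += 1
            conv_succ_c += conv.success
        if det.n_skipped_missing == 0:
            complete["detour"] += 1
            det_succ_c += det.success
    return BypassSurvey(
        n_samples, n_reciprocal, n_tested, complete,
        conv_succ, det_succ, conv_succ_c, det_succ_c, conv_counts, det_counts,
    )
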