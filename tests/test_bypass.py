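import itertools

import numpy as np
import pytest

import fitscape as fs
from fitscape.bypass import SCENARIO_B, SCENARIO_C, SCENARIO_D, is_reciprocal_trap
from fitscape.epistasis import RECIPROCAL_SIGN
from fitscape.landscape import LandscapeError

# frozen scenario-D witness: all detour edge inequalities hold with a123 == 0
D_WITNESS = [1.0, 0.9, 0.9, 2.8, 1.3, 0.2, 1.6, 2.5]


def sample_trap_quads(ls, n_draws, seed):
    rng = np.random.default_rng(seed)
    k = len(ls.alphabet)
    out = []
    for _ in range(n_draws):
        bg = "".join(ls.alphabet[i] for i in rng.integers(k, size=ls.L))
        i, j = sorted(rng.choice(ls.L, 2, replace=False))
        a = ls.alphabet[rng.integers(k - 1)]
        b = ls.alphabet[rng.integers(k - 1)]
        a = a if a != bg[i] else ls.alphabet[-1]
        b = b if b != bg[j] else ls.alphabet[-1]
        q = fs.make_quad(ls, bg, int(i), int(j), a, b)
        if q is not None and is_reciprocal_trap(q):
            out.append(q)
    return out


class TestTaylor:
    def test_additive_cube_no_interactions(self):
        f = {}
        for z1, z2, z3 in itertools.product((0, 1), repeat=3):
            f[(z3, z2, z1)] = 1.0 + z1 + z2 + z3
        cube = fs.taylor_coefficients(
            [f[(0, 0, 0)], f[(0, 0, 1)], f[(0, 1, 0)], f[(0, 1, 1)],
             f[(1, 0, 0)], f[(1, 0, 1)], f[(1, 1, 0)], f[(1, 1, 1)]]
        )
        assert cube.a12 == cube.a13 == cube.a23 == cube.a123 == 0.0
        assert (cube.a1, cube.a2, cube.a3) == (1.0, 1.0, 1.0)

    def test_single_entry_perturbation_hits_a123(self):
        vals = [1.0, 2.0, 2.0, 3.0, 2.0, 3.0, 3.0, 4.0 + 0.5]
        cube = fs.taylor_coefficients(vals)
        assert cube.a123 == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 3, size=8)
        cube = fs.taylor_coefficients(vals)
        rec = cube.reconstruct()
        order = ["f000", "f001", "f010", "f011", "f100", "f101", "f110", "f111"]
        assert [rec[k] for k in order] == pytest.approx(list(vals))


class TestNecessityTheorem:
    def test_scenario_d_witness(self):
        cube = fs.taylor_coefficients(D_WITNESS)
        assert abs(cube.a123) < 1e-12
        assert fs.verify_necessity(cube, SCENARIO_D) is False

    def test_violating_cube_rejected(self):
        cube = fs.taylor_coefficients([1, 2, 2, 3, 2, 3, 3, 4])  # no trap
        with pytest.raises(LandscapeError):
            fs.verify_necessity(cube, SCENARIO_B)

    def test_sampled_bc_cubes_need_higher_order(self, rugged_landscape):
        """Every detected scenario-B/C detour cube has a nonzero three-way
        Taylor term; scenario-D cubes verify as not requiring one."""
        ls, _ = rugged_landscape
        seen = set()
        n_checked = 0
        for q in sample_trap_quads(ls, 15000, seed=0):
            for (p, m, scen) in fs.find_detour_bypasses(ls, q).found:
                cube = fs.cube_for_detour(ls, q, p, m)
                if scen in (SCENARIO_B, SCENARIO_C):
                    assert fs.verify_necessity(cube, scen) is True
                    assert abs(cube.a123) > 1e-12
                else:
                    assert fs.verify_necessity(cube, scen) is False
                seen.add(scen)
                n_checked += 1
        assert n_checked > 10
        assert SCENARIO_B in seen or SCENARIO_C in seen


class TestConversion:
    @staticmethod
    def _toy_landscape(extra):
        entries = {
            "AA": 1.0, "CA": 0.5, "AC": 0.5, "CC": 2.0,
            "DA": extra.get("DA", 0.1), "DC": extra.get("DC", 0.1),
            "AD": extra.get("AD", 0.1), "CD": extra.get("CD", 0.1),
            "DD": 0.1,
        }
        return fs.FitnessLandscape("AA", entries, alphabet="ACD",
                                   site_labels=(1, 2))

    def test_constructed_monotone_path_found(self):
        ls = self._toy_landscape({"DA": 1.5, "DC": 1.8})
        quad = fs.make_quad(ls, "AA", 0, 1, "C", "C")
        assert quad.type == RECIPROCAL_SIGN
        report = fs.find_conversion_bypasses(ls, quad)
        assert report.found == [(0, "D")]
        assert report.n_candidates == 2  # (alphabet-2) per site

    def test_two_letter_alphabet_has_no_candidates(self):
        ls = fs.FitnessLandscape(
            "AA", {"AA": 1.0, "CA": 0.5, "AC": 0.5, "CC": 2.0},
            alphabet="AC", site_labels=(1, 2))
        quad = fs.make_quad(ls, "AA", 0, 1, "C", "C")
        report = fs.find_conversion_bypasses(ls, quad)
        assert report.n_candidates == 0 and not report.success

    def test_non_reciprocal_rejected(self):
        ls = self._toy_landscape({})
        quad = fs.make_quad(ls, "AA", 0, 1, "D", "D")
        with pytest.raises(LandscapeError):
            fs.find_conversion_bypasses(ls, quad)

    def test_matches_exhaustive_oracle(self, rugged_landscape):
        """Report equals brute-force testing of every candidate path."""
        ls, _ = rugged_landscape
        quads = sample_trap_quads(ls, 4000, seed=3)[:25]
        assert quads
        for q in quads:
            report = fs.find_conversion_bypasses(ls, q)
            # oracle: try all alternative alleles at both focal sites
            expected = []
            i, j = q.positions
            for pos, own, opos, oaa in ((i, q.a, j, q.b), (j, q.b, i, q.a)):
                for c in ls.alphabet:
                    if c in (q.background[pos], own):
                        continue
                    g1 = q.background[:pos] + c + q.background[pos + 1:]
                    g2 = g1[:opos] + oaa + g1[opos + 1:]
                    w1, w2 = ls.get(g1), ls.get(g2)
                    if None in (w1, w2):
                        continue
                    if q.w_bg < w1 < w2 < q.w_ab:
                        expected.append((pos, c))
            assert sorted(report.found) == sorted(expected)
            assert report.count <= 2 * (len(ls.alphabet) - 2)


class TestDetour:
    def test_constructed_lifted_cube(self):
        entries = {
            "AAA": 1.0, "CAA": 0.5, "ACA": 0.5, "CCA": 2.0,
            "AAC": 1.2, "CAC": 1.4, "ACC": 1.6, "CCC": 1.9,
        }
        # fill the rest of the 3-site space with low fitness
        for g in itertools.product("ACD", repeat=3):
            entries.setdefault("".join(g), 0.01)
        ls = fs.FitnessLandscape("AAA", entries, alphabet="ACD",
                                 site_labels=(1, 2, 3))
        quad = fs.make_quad(ls, "AAA", 0, 1, "C", "C")
        report = fs.find_detour_bypasses(ls, quad)
        assert any(p == 2 and m == "C" for p, m, _ in report.found)
        assert report.n_candidates == (len(ls.alphabet) - 1) * (ls.L - 2)

    def test_additive_landscape_never_applicable(self, smooth_landscape):
        ls, _ = smooth_landscape
        assert sample_trap_quads(ls, 3000, seed=1) == []

    def test_matches_exhaustive_oracle(self, rugged_landscape):
        ls, _ = rugged_landscape
        quads = sample_trap_quads(ls, 4000, seed=5)[:25]
        assert quads
        for q in quads:
            report = fs.find_detour_bypasses(ls, q)
            expected = []
            i, j = q.positions
            for p in range(ls.L):
                if p in (i, j):
                    continue
                for m in ls.alphabet:
                    if m == q.background[p]:
                        continue
                    lift = q.background[:p] + m + q.background[p + 1:]
                    la = lift[:i] + q.a + lift[i + 1:]
                    lb = lift[:j] + q.b + lift[j + 1:]
                    lab = la[:j] + q.b + la[j + 1:]
                    ws = [ls.get(x) for x in (lift, la, lb, lab)]
                    if None in ws:
                        continue
                    wl, wla, wlb, wlab = ws
                    via = (q.w_bg < wl < wla < wlab < q.w_ab) or (
                        q.w_bg < wl < wlb < wlab < q.w_ab)
                    if via:
                        expected.append((p, m))
            assert sorted((p, m) for p, m, _ in report.found) == sorted(expected)
            assert report.count <= (len(ls.alphabet) - 1) * (ls.L - 2)

    def test_bypass_detection_site_order_invariant(self, rugged_landscape):
        """Swapping which interacting site is listed first changes nothing."""
        ls, _ = rugged_landscape
        for q in sample_trap_quads(ls, 3000, seed=7)[:10]:
            # rebuild the same face with sites in the same (sorted) order but
            # substitutions relabeled through the double-mutant background
            i, j = q.positions
            mirror = fs.make_quad(ls, q.g_ab, i, j, q.background[i], q.background[j])
            assert mirror.type == RECIPROCAL_SIGN
            conv = fs.find_conversion_bypasses(ls, q)
            det = fs.find_detour_bypasses(ls, q)
            assert conv.n_candidates == 2 * (len(ls.alphabet) - 2)
            assert det.n_candidates == (len(ls.alphabet) - 1) * (ls.L - 2)


class TestSurvey:
    def test_summary_counts_and_determinism(self, rugged_landscape):
        ls, _ = rugged_landscape
        s1 = fs.survey_bypasses(ls, 5000, seed=2)
        s2 = fs.survey_bypasses(ls, 5000, seed=2)
        assert s1.summary() == s2.summary()
        assert s1.n_tested <= s1.n_reciprocal <= s1.n_sampled
        summ = s1.summary()
        assert 0 <= summ["conversion_success_fraction"] <= 1
        assert summ["mean_conversion_bypasses"] >= 0
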