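"""Pairwise epistasis: magnitude, detection-limit rules, classification.

Builds 2x2 fitness faces, quantifies epistasis as the deviation of the
double mutant's log fitness from additivity, and shows how the
detection-limit rules clip unreliable values near the assay floor
(w ~ 0.01).  A neighborhood scan then reports the mix of magnitude /
sign / reciprocal-sign interactions around the wild type.
"""

import fitscape as fs

# a positively epistatic face: each single halves fitness, the double
# only halves it once more instead of quartering it
eps = fs.epsilon(w_ab=0.5, w_a=0.5, w_b=0.5, w_bg=1.0)
print(f"positive epistasis: eps = {eps:.3f} (ln 2)")

# near the detection limit the raw value is not trusted
adj = fs.epsilon_adjusted(w_ab=0.005, w_a=0.005, w_b=0.005, w_bg=1.0)
print(f"all variants at the floor -> adjusted eps = {adj} (rule 1)")
adj = fs.epsilon_adjusted(w_ab=0.009, w_a=0.02, w_b=0.02, w_bg=1.0)
print(f"double mutant at the floor, positive raw eps -> {adj} (rule 3 clips)")

# classification by fitness ranking across backgrounds
for vals, label in [((1, 2, 3, 4), "both effects keep sign"),
                    ((1, 0.5, 2, 4), "one effect flips"),
                    ((1, 0.5, 0.5, 2), "both effects flip")]:
    print(f"  {vals} -> {fs.classify(*vals)} ({label})")

spec = fs.SyntheticSpec(alphabet_size=8, seed=5, additive_sd=1.2,
                        pairwise_density=0.25, pairwise_sd=1.5,
                        threeway_density=0.3, threeway_sd=1.0,
                        lethal_fraction=0.1, missing_fraction=0.0)
ls, _ = fs.generate_landscape(spec)
res = fs.classify_neighborhood(ls, center=ls.wt)
print(f"\nWT neighborhood: {res.n_classifiable}/{res.n_total} faces classifiable")
for t, f in res.fractions.items():
    print(f"  {t}: {f:.1%}")
print("Reciprocal sign epistasis marks faces where no direct ordering of "
      "the two substitutions is monotonically adaptive.")
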