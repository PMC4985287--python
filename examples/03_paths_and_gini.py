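"""Direct-path accessibility and path-realization skew within subgraphs.

Enumerates the diallelic subgraphs in which the endpoint is the only
fitness peak, counts the substitution orderings with monotonically
increasing fitness (of the d! = 24 possible at distance 4), computes
each path's realization probability under the strong-selection
weak-mutation (correlated) fixation model, and summarizes the skew with
a Gini index: 0 = all paths equally likely, 1 = one path dominates.
"""

import numpy as np

import fitscape as fs

spec = fs.SyntheticSpec(alphabet_size=8, seed=1, additive_sd=1.2,
                        pairwise_density=0.25, pairwise_sd=1.5,
                        threeway_density=0.3, threeway_sd=1.0,
                        lethal_fraction=0.197, missing_fraction=0.066,
                        noise_sd=0.05)
ls, _ = fs.generate_landscape(spec)

subs = fs.enumerate_single_peak_subgraphs(ls, ls.wt, "to_source",
                                          fitness_window=(0.01, 1.0))
print(f"{len(subs)} complete subgraphs in which WT is the only peak "
      "(adaptation from a deleterious quadruple-distance variant back to WT)")

for sub in subs[:5]:
    n_acc = fs.accessible_direct_paths(sub)
    dist = fs.path_probabilities(sub, fs.CORRELATED)
    print(f"  {sub.source} -> {sub.destination}: {n_acc}/24 direct paths "
          f"accessible, Gini {dist.gini:.3f}")

ginis = [fs.path_probabilities(s, fs.CORRELATED).gini for s in subs]
counts = [fs.accessible_direct_paths(s) for s in subs]
print(f"\nmean accessible direct paths {np.mean(counts):.1f}, "
      f"mean Gini {np.mean(ginis):.3f}")
print("High Gini means a handful of orderings capture nearly all "
      "realizations even when many paths are formally accessible.")
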