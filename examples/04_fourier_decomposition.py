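"""Walsh/Fourier decomposition of subgraphs into epistatic orders.

Transforms a 2^4 subgraph into 16 coefficients indexed by site subsets
(order 0 = mean, 1 = main effects, 2 = pairwise, 3-4 = higher-order),
reconstructs fitness from truncated expansions, screens all complete
subgraphs for the strongest higher-order contribution, and shows the
amino-acid composition of the implicated destinations.
"""

import numpy as np

import fitscape as fs

spec = fs.SyntheticSpec(alphabet_size=8, seed=21, additive_mean=0.0,
                        additive_sd=0.1, pairwise_density=0.0,
                        threeway_density=0.5, threeway_sd=1.5,
                        threeway_sites=(39, 41, 54), lethal_fraction=0.0,
                        missing_fraction=0.0, noise_sd=0.0)
ls, _ = fs.generate_landscape(spec)

dest = ls.alphabet[1] * ls.L
sub = fs.extract_subgraph(ls, ls.wt, dest)
spectrum = fs.fourier_transform(sub)
print(f"subgraph {ls.wt} -> {dest}: variance share by order "
      f"{np.round(spectrum.variance_by_order(), 3)} (orders 1..4)")
for order in range(5):
    rec = fs.truncated_reconstruction(spectrum, order)
    print(f"  truncated at order {order}: variance explained "
          f"{rec.variance_explained:.4f}")

screen = fs.higher_order_screen(ls, ls.wt, quantile=0.02)
print(f"\nscreened {screen.n_complete} complete subgraphs; bottom 2% by "
      f"order-2 variance explained = {len(screen.selected)} subgraphs")
print("amino-acid frequencies of their destinations (rows=aa, cols=site):")
pfm = screen.pfm.loc[screen.pfm.sum(axis=1) > 0]
print(pfm.round(2).to_string())
print("Sites carrying the seeded three-way interactions show skewed "
      "composition; the spare site stays near-uniform.")

flat = fs.remove_higher_order(sub)
print(f"\nafter zeroing orders 3-4, ruggedness {fs.ruggedness(sub).score:.2f} "
      f"-> {fs.ruggedness(flat).score:.2f} and accessible direct paths "
      f"{fs.accessible_direct_paths(sub)} -> {fs.accessible_direct_paths(flat)}")
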