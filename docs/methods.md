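# Methods

## Scope and model

The package analyzes fitness landscapes over a small number of protein
sites: each genotype is an L-letter string over the 20 amino acids (default
L = 4, site labels 39/40/41/54 of protein GB1), and fitness is the
WT-relative enrichment ratio between an input and a selected sequencing
pool. The analysis stack — epistasis quantification and classification,
diallelic-subgraph path analysis, Walsh/Fourier decomposition,
extra-dimensional bypass detection, sparse log-linear imputation, and
adaptive-walk simulation — assumes only that fitness values are
nonnegative reals with WT anchored at 1 and that adaptation proceeds by
single-substitution steps of strictly increasing fitness (the
strong-selection weak-mutation regime; drift, tunneling and recombination
are out of scope).

## Fitness from counts

`compute_fitness` implements the enrichment ratio with a read-depth filter:
variants with fewer than `min_input` (default 10) input reads are moved to
the missing set rather than assigned a noisy value. WT fitness is pinned to
exactly 1.0 by construction. "Lethal" means w == 0.0 exactly; values in
(0, 0.01) are below the assay's detection limit but are kept as-is. The
×1.159 cross-study recalibration of single-mutant fitness used in the
original GB1 analysis requires the earlier study's data and is not applied;
`FitnessLandscape.replace_fitness` is the hook for supplying externally
recalibrated values for any genotype subset.

## Epistasis and detection-limit rules

Raw epistasis is ε = ln(w_ab/w_BG) − ln(w_a/w_BG) − ln(w_b/w_BG). Three
rules guard against artifacts near the detection limit (0.01, configurable):

1. if max(w_ab/w_BG, w_a/w_BG, w_b/w_BG) < limit → ε = 0;
2. if min(w_a, w_b, w_a/w_BG, w_b/w_BG) < limit → ε = max(0, ε);
3. if min(w_ab, w_ab/w_BG) < limit → ε = min(0, ε);
rules 2 and 3 together → 0.

Fitness values of exactly 0 would make the logarithm diverge, so inside the
adjusted computation they are floored at the detection limit; any such
value necessarily triggers rule 2 or 3, which then clips the sign, keeping
outputs finite without inventing magnitude.

Classification ranks the four fitness values: mutation *a* "flips" when
(w_a − w_BG) and (w_ab − w_b) have strictly opposite signs. Two flips =
reciprocal sign, one = sign, none = magnitude. Exact ties count as "no
flip" (a zero effect has no sign to reverse), so tied quads classify as
magnitude. Quads containing zeros are classified with the zeros in place.
Ruggedness of a 2^d subgraph is f_sign + 2·f_reciprocal over its
C(d,2)·2^(d−2) faces (24 for d = 4).

## Subgraphs, direct paths, Gini

A diallelic subgraph restricts each of d differing sites to its two
observed alleles (2^d variants; only complete subgraphs are analyzed).
`enumerate_single_peak_subgraphs` keeps subgraphs whose adaptation endpoint
is the unique local maximum; subgraphs are returned oriented so the walk
starts at bitmask 0 and ends at the full mask regardless of direction
(from a source outward, or from distant variants back to the source). An
optional flag additionally requires the endpoint to be monotonically
reachable, since the two filters answer different questions and the
original analysis used both phrasings.

Accessibility of a direct path demands strictly increasing fitness at every
step; a tie blocks, because the fixation probability of a neutral mutation
is 0 under all three models. Step probabilities within a subgraph use only
the subgraph's own fitter neighbors in the denominator (including backward
bit-flips, matching the subgraph-restricted graph), and the d! direct-path
probabilities are renormalized before the Gini index

    G = (2·Σ_{n=1..t−1} A_n + A_t − t) / (t − 1)

over descending-sorted probabilities with inaccessible paths included as 0.

## Fourier/Walsh decomposition

With source mapped to z = 0 and destination to z = 1, f(z) =
Σ_k f̂(k)(−1)^{z·k} and f̂(k) = 2^{−d} Σ_z f(z)(−1)^{z·k}. The transform is
applied to raw fitness (not log), as in the original analysis. "Fraction of
variance explained" by an order-m truncation is reported two ways, since
the source analyses used a correlation framing without disambiguating:
the squared Pearson correlation between truncation and input (the primary
measure) and the Parseval share of non-constant Walsh power at orders ≤ m.
The higher-order screen ranks all complete source→destination subgraphs by
order-2 variance explained, ascending, with ties broken by destination
string so the ranking is deterministic without a seed.

One consequence of decomposing raw fitness worth knowing: a landscape that
is perfectly additive on *log* fitness (multiplicative in w) still has
higher-order Walsh content, because exp() curvature turns large single-site
effects into apparent interactions at every site. The three-way-enrichment
demonstration therefore uses small additive effects with dominant seeded
three-way terms.

## Bypass and the higher-order-necessity theorem

Bypass analysis conditions on the canonical reciprocal-sign trap: both
single mutants deleterious and the double mutant fitter than the
background, so that every direct ordering is blocked. (A reciprocal-sign
face can also have both singles beneficial and the double blocked at the
last step; the bypass scenario taxonomy does not apply there.) Paths
through missing or zero-fitness intermediates fail — a lethal genotype
cannot host an adapting population.

Conversion bypass tests, for each alternative amino acid c at either
interacting site, the route BG → BG[i=c] → BG[i=c, j=b] → ab (≤ 2·(A−2)
candidates, 36 for 20 letters). Detour bypass tests, per third site and
amino acid, 000 → 100 → {110 or 101} → 111 → 011 (≤ (A−1)·(L−2)
candidates, 38 for the 4-site, 20-letter space).

On the 3-cube the fitness expands exactly as a Taylor polynomial with
interaction coefficients α₁₂, α₁₃, α₂₃, α₁₂₃. Successful detours are
classified by the epistasis type of the focal pair on the lifted (third-site
mutant) background: magnitude → scenario B; sign → C or D, distinguished by
the sign of α₃+α₁₃ for the cube orientation in which the z₂ mutation
carries the ascending route. A tie (α₃+α₁₃ = 0, which occurs when lethal
variants tie at zero) is classed as C, because the C conclusion only needs
α₃+α₁₃ ≥ 0. `verify_necessity` checks the defining edge inequalities and
confirms α₁₂₃ < 0 for B and C; for D a frozen witness cube satisfies every
inequality with α₁₂₃ = 0, showing three-way epistasis is not forced there.

## Imputation

Design matrix: binary indicators for the 19·L single mutations, 19²·C(L,2)
mutation pairs, and 19³ three-way combinations on sites 39/41/54 (the site
triple where higher-order epistasis concentrates), 9102 coefficients in all
for the default space. Indicators are left unstandardized and the intercept
unpenalized. The response is natural-log fitness; lethal variants are
excluded from fitting and never overwritten, and imputation cannot produce
an exact 0. The lasso objective matches scikit-learn's
(1/2n)‖y − Xβ‖² + λ‖β‖₁ parameterization. Cross-validation MSE is computed
on the log scale (the fit's response) with genotype-level seeded folds. The
penalty is chosen by CV over a small grid by default; λ = 10⁻⁴ — the value
chosen by CV in the original GB1 analysis at its data scale — can be forced
via `chosen_lambda`. On synthetic instances the CV choice matters: at
~15,000 genotypes with noise σ = 0.05 the CV-minimizing λ = 10⁻⁵ recovers
ground-truth coefficient signs at ~98%, whereas 10⁻⁴ over-shrinks small
interaction terms.

## Adaptive walks

The fitness graph has an edge u→v iff the substitution is allowed by the
adjacency (all 19·L substitutions, or only those reachable by a single
nucleotide change under the standard genetic code — built by brute force
over the 61 sense codons, giving ≈ 6–7 allowed partners per amino acid),
HD(u,v) = 1, and w(v) > w(u). Peaks are nodes of out-degree 0. Fixation
models: greedy (probability 1 on the largest gain; ties broken toward the
lexicographically smallest genotype so basins form a true partition),
correlated (probability ∝ fitness gain), equal (uniform over beneficial
neighbors). Walk steps are classified against the walk's own realized
endpoint by the change in Hamming distance (towards −1, conversion 0,
detour +1). Besides sampling, `expected_walk_lengths` computes the exact
expected length from every node by dynamic programming over the acyclic
graph; the selection-strength ordering (greedy ≤ correlated ≤ equal) is a
landscape-averaged statement and is asserted on that exact expectation —
a single start at finite sample size can invert correlated vs equal.
Accessibility compares the shortest monotone path length against the
Hamming (or genetic-code) distance: equal → direct, longer →
indirect-required, unreachable → inaccessible. Outcome entropy is the
Shannon entropy (nats) of endpoint frequencies over n = 1000 simulated
walks, with 0·ln 0 ≡ 0.

## Synthetic landscapes

`generate_landscape` draws log-fitness from the same model the imputation
fits: per-site effects Normal(additive_mean, additive_sd²), sparse pairwise
terms (Bernoulli(density) × Normal(0, sd²)), three-way terms on one site
triple, and Gaussian noise. Defaults emulate the study conditions: L = 4,
20 letters, 19.7% lethal (imposed after the draw by overwriting with 0,
since the log-linear model is fit on non-lethal variants only), 6.6%
missing, noise σ = 0.05, and three-way structure confined to sites
39/41/54. `additive_mean` defaults to −1.0 on log fitness so that, as in
real deep mutational scans, mutations are deleterious on average and WT
sits near the top of the landscape — zero-mean effects would make half the
space beneficial. WT receives no noise and is anchored at exactly 1.
`generate_counts` inverts the enrichment estimator: Dirichlet-perturbed
input frequencies (concentration 50 around uniform — a fairly even
library), multinomial input reads, selected reads multinomial with weights
frequency × fitness. All randomness flows through one seeded generator per
call; equal seeds give identical output, entry for entry.

What the generator does **not** emulate: sequencing error at the nucleotide
level, PCR jackpotting, correlated replicate structure, and any real
biophysics (stability thresholds, binding curves) behind the GB1
measurements. Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under the stated generative model,
not that the biological conclusions transfer to any particular protein.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on scaled-down
alphabets — 8 letters (4096 genotypes) for graph/path/bypass analyses and
oracle comparisons, 11 letters (14,641 genotypes) for imputation recovery —
sizes at which every oracle (exhaustive path enumeration, local-maximum
scans, exact Markov absorption probabilities, direct evaluation of the
Walsh sum) is itself cheap to evaluate. Fitness I/O round-trips at full
double precision (`float_precision="round_trip"` on read). Comparisons for
"lethal" use w == 0 exactly and "beneficial" w > 1 strictly. Walk-endpoint
agreement with exact absorption probabilities is asserted within three
standard errors at n = 1000. The theorem check uses |α₁₂₃| > 10⁻¹² as the
nonzero criterion.

## Known limitations

- Bypass scenario classification presumes the canonical trap configuration;
  other reciprocal-sign geometries are detected but not classified.
- The Fourier screen's variance measure on raw fitness conflates
  multiplicative curvature with genuine higher-order interaction when
  single-site effects are large (see above).
- Lethal variants are excluded from the imputation fit, so imputed values
  for variants that are truly lethal will be small positive numbers rather
  than 0.
- The genetic-code adjacency considers single-nucleotide steps between
  sense codons only; codon-usage context within a real gene is ignored.
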