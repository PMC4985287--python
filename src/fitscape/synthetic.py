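"""Synthetic fitness landscapes with known epistatic ground truth.

The generator draws log-fitness from the same sparse log-linear model
used for imputation: a sum of single-site effects, sparse pairwise
interaction terms, and (optionally) three-way interaction terms
localized to one site triple, plus Gaussian noise.  A configurable
fraction of variants is made lethal (fitness overwritten with 0) and
another fraction is withheld as missing, mimicking the read-depth
filter of a deep mutational scan.  Default fractions follow the study
conditions: 19.7% lethal, 6.6% missing.

Count tables can be simulated from any landscape by drawing input-pool
frequencies from a Dirichlet and selected-pool reads multinomially with
probabilities proportional to frequency x fitness — the inverse of the
enrichment-ratio fitness estimator.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .landscape import (
    AMINO_ACIDS,
    DEFAULT_SITES,
    CountRecord,
    FitnessLandscape,
    LandscapeError,
)
from .imputation import ModelCoefficients


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic landscape draw.

    Effect scales are on natural-log fitness; single-site effects are
    deleterious on average (``additive_mean`` < 0) so that, as in real
    deep mutational scans, the wild type sits near the top of the
    landscape and only a small minority of variants is beneficial.
    ``threeway_sites`` names
    the (single) site triple carrying third-order terms, echoing the
    concentration of higher-order epistasis on sites 39/41/54 in the
    GB1 data; set ``threeway_density`` to 0 for a pairwise-only
    landscape.
    """

    L: int = 4
    alphabet_size: int = 20
    additive_mean: float = -1.0
    additive_sd: float = 1.0
    pairwise_density: float = 0.05
    pairwise_sd: float = 0.5
    threeway_sites: tuple[int, int, int] | None = (39, 41, 54)
    threeway_density: float = 0.05
    threeway_sd: float = 0.5
    lethal_fraction: float = 0.197
    missing_fraction: float = 0.066
    noise_sd: float = 0.05
    seed: int = 0
    site_labels: tuple[int, ...] = DEFAULT_SITES

    def __post_init__(self) -> None:
        if self.L < 2:
            raise LandscapeError("L must be >= 2")
        if not 2 <= self.alphabet_size <= 20:
            raise LandscapeError("alphabet_size must be in [2, 20]")
        for name in ("lethal_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise LandscapeError(f"{name} must be in [0, 1)")
        for name in ("pairwise_density", "threeway_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise LandscapeError(f"{name} must be in [0, 1]")
        if len(self.site_labels) < self.L:
            self.site_labels = tuple(range(self.L))
        else:
            self.site_labels = tuple(self.site_labels[: self.L])
        if self.threeway_sites is not None:
            if self.L < 3:
                raise LandscapeError("threeway_sites given but L < 3")
            if not set(self.threeway_sites) <= set(self.site_labels):
                raise LandscapeError(
                    f"threeway_sites {self.threeway_sites} not among site labels {self.site_labels}"
                )

    @property
    def alphabet(self) -> str:
        return AMINO_ACIDS[: self.alphabet_size]

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("threeway_sites", "site_labels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def generate_landscape(spec: SyntheticSpec) -> tuple[FitnessLandscape, ModelCoefficients]:
    """Draw a landscape and return it with its ground-truth coefficients.

    WT is the first alphabet letter at every site, anchored at fitness
    exactly 1 (its log-fitness intercept is 0 and WT receives no noise,
    so downstream WT-relative statistics are exact).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = spec.alphabet
    wt = alphabet[0] * spec.L
    sites = spec.site_labels

    singles: dict[tuple[int, str], float] = {}
    for s in sites:
        for aa in alphabet[1:]:
            singles[(s, aa)] = rng.normal(spec.additive_mean, spec.additive_sd)

    pairs: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    for si, sj in itertools.combinations(sites, 2):
        for ai in alphabet[1:]:
            for aj in alphabet[1:]:
                if rng.random() < spec.pairwise_density:
                    pairs[((si, ai), (sj, aj))] = rng.normal(0.0, spec.pairwise_sd)

    triples: dict[tuple[tuple[int, str], ...], float] = {}
    if spec.threeway_sites is not None and spec.threeway_density > 0:
        t = tuple(sorted(spec.threeway_sites))
        for combo in itertools.product(alphabet[1:], repeat=3):
            if rng.random() < spec.threeway_density:
                key = tuple((s, aa) for s, aa in zip(t, combo))
                triples[key] = rng.normal(0.0, spec.threeway_sd)

    coeffs = ModelCoefficients(
        intercept=0.0,
        singles=singles,
        pairs=pairs,
        triples=triples,
        site_labels=sites,
        alphabet=alphabet,
        wt=wt,
        threeway_sites=tuple(sorted(spec.threeway_sites)) if spec.threeway_sites else None,
        lam=0.0,
    )

    genotypes = ["".join(t) for t in itertools.product(alphabet, repeat=spec.L)]
    log_w = coeffs.predict_log(genotypes)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=len(genotypes))
        log_w = log_w + noise
    entries = {g: float(np.exp(lw)) for g, lw in zip(genotypes, log_w)}
    entries[wt] = 1.0

    non_wt = [g for g in genotypes if g != wt]
    n_lethal = int(round(spec.lethal_fraction * len(non_wt)))
    lethal = rng.choice(len(non_wt), size=n_lethal, replace=False) if n_lethal else []
    for idx in lethal:
        entries[non_wt[idx]] = 0.0

    n_missing = int(round(spec.missing_fraction * len(non_wt)))
    missing: set[str] = set()
    if n_missing:
        for idx in rng.choice(len(non_wt), size=n_missing, replace=False):
            missing.add(non_wt[idx])
        for g in missing:
            del entries[g]

    ls = FitnessLandscape(wt, entries, missing, alphabet=alphabet, site_labels=sites)
    return ls, coeffs


def generate_counts(
    ls: FitnessLandscape,
    depth_input: int,
    depth_selected: int,
    seed: int,
    dirichlet_concentration: float = 50.0,
) -> list[CountRecord]:
    """Simulate input/selected read counts consistent with a landscape.

    Input-pool genotype frequencies are Dirichlet-perturbed around
    uniform (larger ``dirichlet_concentration`` = more even library);
    selected-pool sampling weights each genotype by frequency x fitness.
    """
    if ls.wt in ls.missing:
        raise LandscapeError("WT must not be missing")
    if depth_input <= 0 or depth_selected <= 0:
        raise LandscapeError("sequencing depths must be positive")
    rng = np.random.default_rng(seed)
    genotypes = sorted(ls.entries)
    w = np.array([ls.entries[g] for g in genotypes])
    freq = rng.dirichlet(np.full(len(genotypes), dirichlet_concentration))
    counts_in = rng.multinomial(depth_input, freq)
    sel_weights = freq * w
    total = sel_weights.sum()
    if total == 0:
        raise LandscapeError("all fitness values are zero; selected pool is empty")
    counts_sel = rng.multinomial(depth_selected, sel_weights / total)
    return [
        CountRecord(g, int(ci), int(cs))
        for g, ci, cs in zip(genotypes, counts_in, counts_sel)
    ]
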