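"""Walsh/Fourier decomposition of diallelic subgraphs into epistatic orders.

Writing a subgraph member as a binary vector z (1 = destination allele),
fitness decomposes as

    f(z) = sum_k  f_hat(k) * (-1)^(z . k)
    f_hat(k) = 2^-d * sum_z f(z) * (-1)^(z . k)

where k ranges over site subsets.  |k| = 0 is the mean, |k| = 1 the
main effects, |k| = 2 pairwise epistasis, and |k| >= 3 higher-order
epistasis.  Truncating the expansion at order m and correlating the
reconstruction with the measured fitness quantifies how much of the
landscape the first m orders explain; subgraphs where the order-2
reconstruction falls short carry higher-order epistasis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import FitnessLandscape, LandscapeError
from .subgraphs import DiallelicSubgraph, extract_subgraph


def _sign_matrix(d: int) -> np.ndarray:
    """S[z, k] = (-1)^popcount(z & k); its own inverse up to 1/2^d."""
    n = 2 ** d
    z = np.arange(n)
    pc = np.array([bin(z[i] & k).count("1") for i in range(n) for k in range(n)])
    return np.where(pc.reshape(n, n) % 2 == 0, 1.0, -1.0)


_SIGN_CACHE: dict[int, np.ndarray] = {}


def sign_matrix(d: int) -> np.ndarray:
    if d not in _SIGN_CACHE:
        _SIGN_CACHE[d] = _sign_matrix(d)
    return _SIGN_CACHE[d]


def subset_order(k: int) -> int:
    return bin(k).count("1")


@dataclass
class FourierSpectrum:
    """2^d Walsh coefficients of a subgraph, indexed by subset bitmask."""

    d: int
    coefficients: np.ndarray

    @property
    def orders(self) -> np.ndarray:
        return np.array([subset_order(k) for k in range(2 ** self.d)])

    def reconstruct(self, max_order: int | None = None) -> np.ndarray:
        """Inverse transform, optionally truncated to |k| <= max_order."""
        c = self.coefficients.copy()
        if max_order is not None:
            c[self.orders > max_order] = 0.0
        return sign_matrix(self.d) @ c

    def variance_by_order(self) -> np.ndarray:
        """Fraction of non-constant Walsh power per order 1..d (sums to 1)."""
        power = self.coefficients ** 2
        orders = self.orders
        total = power[orders >= 1].sum()
        out = np.zeros(self.d + 1)
        for o in range(1, self.d + 1):
            out[o] = power[orders == o].sum()
        if total > 0:
            out /= total
        return out[1:]


def fourier_transform(sub: DiallelicSubgraph) -> FourierSpectrum:
    """Walsh coefficients of a complete subgraph (source at z = 0)."""
    if not sub.complete:
        raise LandscapeError("Fourier transform requires a complete subgraph")
    d = sub.d
    coeffs = sign_matrix(d) @ sub.fitness / (2 ** d)
    return FourierSpectrum(d, coeffs)


@dataclass
class TruncatedReconstruction:
    fitness: np.ndarray
    max_order: int
    variance_explained: float  # squared Pearson correlation with the input
    parseval_share: float      # share of non-constant Walsh power retained


def truncated_reconstruction(
    spectrum: FourierSpectrum, max_order: int
) -> TruncatedReconstruction:
    """Order-limited reconstruction and its variance-explained measures."""
    if not 0 <= max_order <= spectrum.d:
        raise LandscapeError(f"max_order must be in [0, {spectrum.d}]")
    full = spectrum.reconstruct()
    trunc = spectrum.reconstruct(max_order)
    if np.std(trunc) == 0 or np.std(full) == 0:
        r2 = 1.0 if np.std(full) == 0 else 0.0
    else:
        r2 = float(np.corrcoef(trunc, full)[0, 1] ** 2)
    power = spectrum.coefficients ** 2
    orders = spectrum.orders
    denom = power[orders >= 1].sum()
    share = float(power[(orders >= 1) & (orders <= max_order)].sum() / denom) if denom > 0 else 1.0
    return TruncatedReconstruction(trunc, max_order, r2, share)


def remove_higher_order(sub: DiallelicSubgraph) -> DiallelicSubgraph:
    """Subgraph rebuilt from orders <= 2 only (third order and beyond zeroed)."""
    spec = fourier_transform(sub)
    return DiallelicSubgraph(
        sub.source, sub.destination, sub.positions, spec.reconstruct(max_order=2)
    )


def position_frequency_matrix(genotypes: list[str], alphabet: str) -> pd.DataFrame:
    """Amino-acid frequencies per position; each column sums to 1."""
    if not genotypes:
        raise LandscapeError("no genotypes")
    L = len(genotypes[0])
    counts = np.zeros((len(alphabet), L))
    index = {aa: i for i, aa in enumerate(alphabet)}
    for g in genotypes:
        for p, aa in enumerate(g):
            counts[index[aa], p] += 1
    return pd.DataFrame(counts / len(genotypes), index=list(alphabet), columns=range(L))


@dataclass
class HigherOrderScreen:
    """Complete max-distance subgraphs ranked by order-2 variance explained."""

    destinations: list[str]          # ranked ascending by ve2 (ties lexicographic)
    variance_explained_order2: np.ndarray
    selected: list[str]              # the bottom-quantile destinations
    selected_significant: bool       # any selected subgraph short of ve2 == 1
    pfm: pd.DataFrame
    n_complete: int


def higher_order_screen(
    ls: FitnessLandscape,
    source: str,
    quantile: float = 0.001,
    tol: float = 1e-9,
) -> HigherOrderScreen:
    """Find the subgraphs with the largest higher-order fitness contribution.

    For every complete subgraph between ``source`` and a genotype
    differing at all L sites, computes the fraction of fitness variance
    explained by the order-2 truncation (squared Pearson correlation);
    the bottom ``quantile`` of that ranking is where higher-order
    epistasis matters most.  Returns the ranking plus the amino-acid
    frequency matrix of the selected destinations.
    """
    if not 0 < quantile < 1:
        raise LandscapeError("quantile must be in (0, 1)")
    alt = [[x for x in ls.alphabet if x != aa] for aa in source]
    rows = []
    for combo in itertools.product(*alt):
        dest = "".join(combo)
        if ls.get(dest) is None:
            continue
        sub = extract_subgraph(ls, source, dest)
        if not sub.complete:
            continue
        spec = fourier_transform(sub)
        rows.append((dest, truncated_reconstruction(spec, 2).variance_explained))
    if not rows:
        raise LandscapeError("no complete subgraphs from source")
    rows.sort(key=lambda r: (r[1], r[0]))
    n_sel = max(1, int(round(quantile * len(rows))))
    destinations = [r[0] for r in rows]
    ve2 = np.array([r[1] for r in rows])
    selected = destinations[:n_sel]
    return HigherOrderScreen(
        destinations,
        ve2,
        selected,
        bool(np.any(ve2[:n_sel] < 1.0 - tol)),
        position_frequency_matrix(selected, ls.alphabet),
        len(rows),
    )
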