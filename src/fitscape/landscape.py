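"""Core domain types for combinatorial protein fitness landscapes.

A genotype is a fixed-length string over the 20 canonical amino acids,
one letter per mutagenized site (default site labels 39, 40, 41, 54 of
protein GB1).  Fitness is the enrichment of a variant between an input
and a selected sequencing pool, relative to wild type:

    w_i = (count_sel_i / count_in_i) / (count_sel_WT / count_in_WT)

so that w_WT == 1 by construction, w == 0 marks a lethal variant and
w > 1 a beneficial one.  Variants whose input count falls below a
read-depth filter carry no fitness value and live in the ``missing``
set; the imputation module can fill them in later.
"""

from __future__ import annotations

import itertools
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fitscape")
if not logger.handlers:  # default: counts of parsed/filtered variants to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Site labels of the four mutagenized positions in protein GB1.
DEFAULT_SITES = (39, 40, 41, 54)

MEASURED = "measured"
IMPUTED = "imputed"


class LandscapeError(ValueError):
    """Unrecoverable input error (bad genotype, absent WT, duplicate rows)."""


def validate_genotype(g: str, L: int | None = None, alphabet: str = AMINO_ACIDS) -> str:
    if not isinstance(g, str) or (L is not None and len(g) != L):
        raise LandscapeError(f"genotype {g!r} does not have length {L}")
    bad = set(g) - set(alphabet)
    if bad:
        raise LandscapeError(f"genotype {g!r} contains letters outside the alphabet: {sorted(bad)}")
    return g


def hamming_distance(a: str, b: str) -> int:
    """Number of sites at which two equal-length genotypes differ."""
    if len(a) != len(b):
        raise LandscapeError(f"length mismatch: {a!r} vs {b!r}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class CountRecord:
    """Read counts of one variant in the input and selected pools."""

    genotype: str
    count_input: int
    count_selected: int

    def __post_init__(self) -> None:
        if self.count_input < 0 or self.count_selected < 0:
            raise LandscapeError(f"negative count for {self.genotype}")


class AminoAcidAdjacency:
    """Allowed single-step amino-acid substitutions.

    ``full`` mode allows every substitution (protein space: 19*L
    neighbors); ``genetic_code`` mode allows only pairs of amino acids
    with codons one nucleotide apart, which thins the neighborhood to
    roughly 6 per site.
    """

    def __init__(self, matrix: np.ndarray, mode: str, alphabet: str = AMINO_ACIDS):
        matrix = np.asarray(matrix, dtype=bool)
        n = len(alphabet)
        if matrix.shape != (n, n):
            raise LandscapeError(f"adjacency must be {n}x{n}")
        if not np.array_equal(matrix, matrix.T):
            raise LandscapeError("adjacency must be symmetric")
        if matrix.diagonal().any():
            raise LandscapeError("adjacency diagonal must be False")
        self.matrix = matrix
        self.mode = mode
        self.alphabet = alphabet
        self._index = {aa: i for i, aa in enumerate(alphabet)}

    @classmethod
    def full(cls, alphabet: str = AMINO_ACIDS) -> "AminoAcidAdjacency":
        n = len(alphabet)
        return cls(~np.eye(n, dtype=bool), "full", alphabet)

    def allowed(self, a: str, b: str) -> bool:
        return bool(self.matrix[self._index[a], self._index[b]])

    def partners(self, a: str) -> list[str]:
        row = self.matrix[self._index[a]]
        return [self.alphabet[j] for j in np.flatnonzero(row)]

    def step_distance(self, a: str, b: str) -> int:
        """Shortest number of allowed substitutions turning ``a`` into ``b``."""
        if a == b:
            return 0
        dist = self._pairwise_distances()
        d = dist[self._index[a], self._index[b]]
        if not np.isfinite(d):
            raise LandscapeError(f"{a}->{b} unreachable under {self.mode} adjacency")
        return int(d)

    def _pairwise_distances(self) -> np.ndarray:
        if not hasattr(self, "_dist_cache"):
            from scipy.sparse.csgraph import shortest_path

            self._dist_cache = shortest_path(self.matrix.astype(float), unweighted=True)
        return self._dist_cache


def genetic_code_adjacency() -> AminoAcidAdjacency:
    """Adjacency between amino acids whose codons differ at one nucleotide.

    Built by brute force over the 61 sense codons of the standard
    genetic code; paths through stop codons are not considered.
    """
    from Bio.Data.CodonTable import standard_dna_table

    codons_by_aa: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in standard_dna_table.forward_table.items():
        codons_by_aa[aa].append(codon)
    n = len(AMINO_ACIDS)
    matrix = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i >= j:
                continue
            hit = any(
                sum(x != y for x, y in zip(ca, cb)) == 1
                for ca in codons_by_aa[a]
                for cb in codons_by_aa[b]
            )
            matrix[i, j] = matrix[j, i] = hit
    return AminoAcidAdjacency(matrix, "genetic_code")


def neighbors(g: str, adjacency: AminoAcidAdjacency | None = None,
              alphabet: str | None = None) -> list[str]:
    """All genotypes one allowed substitution away from ``g``.

    With full adjacency this is exactly 19*L genotypes for the
    20-letter alphabet (e.g. 38 for L=2).
    """
    if adjacency is None:
        adjacency = AminoAcidAdjacency.full(alphabet or AMINO_ACIDS)
    out = []
    for i, aa in enumerate(g):
        for sub in adjacency.partners(aa):
            out.append(g[:i] + sub + g[i + 1:])
    return out


@dataclass
class LandscapeSummary:
    n_measured: int
    n_missing: int
    n_imputed: int
    fraction_beneficial: float
    fraction_lethal: float
    fraction_measured: float
    fraction_missing: float
    wt_percentile: float


class FitnessLandscape:
    """Genotype -> fitness map over a full combinatorial space ``alphabet^L``.

    Every genotype of the space is either present (with a ``measured``
    or ``imputed`` origin flag) or a member of ``missing``.
    """

    def __init__(
        self,
        wt: str,
        entries: Mapping[str, float],
        missing: Iterable[str] = (),
        origin: Mapping[str, str] | None = None,
        alphabet: str = AMINO_ACIDS,
        site_labels: Sequence[int] = DEFAULT_SITES,
    ):
        self.alphabet = alphabet
        self.L = len(wt)
        self.site_labels = tuple(site_labels[: self.L]) if len(site_labels) >= self.L else tuple(
            range(self.L)
        )
        if len(self.site_labels) != self.L or list(self.site_labels) != sorted(set(self.site_labels)):
            raise LandscapeError("site labels must be strictly increasing, one per site")
        validate_genotype(wt, self.L, alphabet)
        self.wt = wt
        self.entries: dict[str, float] = {}
        for g, w in entries.items():
            validate_genotype(g, self.L, alphabet)
            if w < 0 or not np.isfinite(w):
                raise LandscapeError(f"fitness of {g} must be finite and >= 0, got {w}")
            self.entries[g] = float(w)
        self.missing: set[str] = set(missing)
        overlap = self.missing & self.entries.keys()
        if overlap:
            raise LandscapeError(f"genotypes both present and missing: {sorted(overlap)[:5]}")
        self.origin: dict[str, str] = dict(origin) if origin is not None else {
            g: MEASURED for g in self.entries
        }

    # -- basic protocol ------------------------------------------------
    def __contains__(self, g: str) -> bool:
        return g in self.entries

    def __getitem__(self, g: str) -> float:
        return self.entries[g]

    def get(self, g: str, default=None):
        return self.entries.get(g, default)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    @property
    def space_size(self) -> int:
        return len(self.alphabet) ** self.L

    def genotype_space(self) -> Iterator[str]:
        for tup in itertools.product(self.alphabet, repeat=self.L):
            yield "".join(tup)

    def is_complete(self) -> bool:
        return not self.missing and len(self.entries) == self.space_size

    def site_index(self, label: int) -> int:
        return self.site_labels.index(label)

    def replace_fitness(self, replacements: Mapping[str, float]) -> "FitnessLandscape":
        """Return a copy with fitness values overridden for a genotype subset.

        Hook for supplying externally re-calibrated values (e.g. single
        mutants re-referenced to a higher-coverage experiment).
        """
        entries = dict(self.entries)
        for g, w in replacements.items():
            validate_genotype(g, self.L, self.alphabet)
            entries[g] = float(w)
        missing = self.missing - replacements.keys()
        origin = dict(self.origin)
        for g in replacements:
            origin[g] = MEASURED
        return FitnessLandscape(self.wt, entries, missing, origin, self.alphabet, self.site_labels)

    def summarize(self) -> LandscapeSummary:
        return summarize_landscape(self)


def compute_fitness(
    counts: Iterable[CountRecord],
    wt: str,
    min_input: int = 10,
    alphabet: str = AMINO_ACIDS,
    site_labels: Sequence[int] = DEFAULT_SITES,
) -> FitnessLandscape:
    """Fitness relative to WT from input/selected read counts.

    Variants with ``count_input < min_input`` are filtered to the
    missing set to reduce noise (default threshold 10 reads).  The WT
    record must itself pass the filter and have a nonzero selected
    count.  WT fitness is pinned to exactly 1.
    """
    records = list(counts)
    seen: set[str] = set()
    for r in records:
        if r.genotype in seen:
            raise LandscapeError(f"duplicate genotype in count table: {r.genotype}")
        seen.add(r.genotype)
    by_g = {r.genotype: r for r in records}
    wt_rec = by_g.get(wt)
    if wt_rec is None:
        raise LandscapeError(f"WT {wt} absent from count table")
    if wt_rec.count_input < max(min_input, 1) or wt_rec.count_selected <= 0:
        raise LandscapeError(
            f"WT counts unusable (input={wt_rec.count_input}, selected={wt_rec.count_selected})"
        )
    wt_ratio = wt_rec.count_selected / wt_rec.count_input
    entries: dict[str, float] = {}
    n_filtered = 0
    for r in records:
        validate_genotype(r.genotype, len(wt), alphabet)
        if r.count_input < min_input:
            n_filtered += 1
            continue
        entries[r.genotype] = (r.count_selected / r.count_input) / wt_ratio
    entries[wt] = 1.0
    space = set("".join(t) for t in itertools.product(alphabet, repeat=len(wt)))
    missing = space - entries.keys()
    logger.info(
        "compute_fitness: parsed %d records, filtered %d (input < %d), retained %d, missing %d",
        len(records), n_filtered, min_input, len(entries), len(missing),
    )
    return FitnessLandscape(wt, entries, missing, alphabet=alphabet, site_labels=site_labels)


def summarize_landscape(ls: FitnessLandscape) -> LandscapeSummary:
    """Fractions of beneficial (w > 1), lethal (w == 0) and missing variants.

    The WT percentile is the share of entries strictly fitter than WT
    (WT sits in the top ``wt_percentile`` of the landscape).
    """
    if not ls.entries:
        raise LandscapeError("empty landscape")
    w = np.fromiter(ls.entries.values(), dtype=float, count=len(ls.entries))
    w_wt = ls.entries.get(ls.wt, 1.0)
    n = len(w)
    n_imputed = sum(1 for g in ls.entries if ls.origin.get(g) == IMPUTED)
    return LandscapeSummary(
        n_measured=n - n_imputed,
        n_missing=len(ls.missing),
        n_imputed=n_imputed,
        fraction_beneficial=float(np.mean(w > 1)),
        fraction_lethal=float(np.mean(w == 0)),
        fraction_measured=(n - n_imputed) / ls.space_size,
        fraction_missing=len(ls.missing) / ls.space_size,
        wt_percentile=float(np.mean(w > w_wt)),
    )


# -- I/O ---------------------------------------------------------------

def read_counts(path) -> list[CountRecord]:
    """Read a tab-separated count table (genotype, count_input, count_selected)."""
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    required = {"genotype", "count_input", "count_selected"}
    if not required <= set(df.columns):
        raise LandscapeError(f"count table needs columns {sorted(required)}")
    return [
        CountRecord(str(r.genotype), int(r.count_input), int(r.count_selected))
        for r in df.itertuples(index=False)
    ]


def write_counts(records: Iterable[CountRecord], path) -> None:
    pd.DataFrame(
        [(r.genotype, r.count_input, r.count_selected) for r in records],
        columns=["genotype", "count_input", "count_selected"],
    ).to_csv(path, sep="\t", index=False)


def write_landscape(ls: FitnessLandscape, path) -> None:
    """Write genotype/fitness/origin TSV; missing genotypes get an empty fitness."""
    rows = [(g, repr(w), ls.origin.get(g, MEASURED)) for g, w in sorted(ls.entries.items())]
    rows += [(g, "", "missing") for g in sorted(ls.missing)]
    df = pd.DataFrame(rows, columns=["genotype", "fitness", "origin"])
    header = f"#wt={ls.wt}\talphabet={ls.alphabet}\tsites={','.join(map(str, ls.site_labels))}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_landscape(path, wt: str | None = None) -> FitnessLandscape:
    """Read a landscape TSV written by :func:`write_landscape`.

    Plain genotype/fitness tables (no header comment, no origin column)
    are accepted too, in which case ``wt`` must be given.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for kv in first[1:].strip().split("\t"):
                k, _, v = kv.partition("=")
                meta[k] = v
            df = pd.read_csv(fh, sep="\t", dtype={"genotype": str},
                             float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"genotype": str},
                             float_precision="round_trip")
    if "fitness" not in df.columns or "genotype" not in df.columns:
        raise LandscapeError("landscape table needs 'genotype' and 'fitness' columns")
    wt = meta.get("wt", wt)
    if wt is None:
        raise LandscapeError("WT genotype not recorded in file and not supplied")
    alphabet = meta.get("alphabet", AMINO_ACIDS)
    sites = tuple(int(s) for s in meta["sites"].split(",")) if "sites" in meta else DEFAULT_SITES
    entries: dict[str, float] = {}
    origin: dict[str, str] = {}
    missing: set[str] = set()
    has_origin = "origin" in df.columns
    for r in df.itertuples(index=False):
        g = str(r.genotype)
        flag = str(r.origin) if has_origin else MEASURED
        if flag == "missing" or pd.isna(r.fitness):
            missing.add(g)
            continue
        entries[g] = float(r.fitness)
        origin[g] = flag
    space = set("".join(t) for t in itertools.product(alphabet, repeat=len(wt)))
    missing |= space - entries.keys()
    return FitnessLandscape(wt, entries, missing, origin, alphabet, sites)
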