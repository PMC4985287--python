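"""Sparse log-linear fitness model and imputation of missing variants.

The model writes natural-log fitness as an intercept (log fitness of
WT) plus main effects of single mutations, pairwise interaction terms
for every pair of mutations, and three-way interaction terms restricted
to one site triple (39/41/54 by default, where higher-order epistasis
concentrates in the GB1 data):

    log f = a0 + sum_i b_i M_i + sum_j g_j P_j + sum_k d_k T_k

with binary indicators M/P/T for the presence of each (combination of)
mutation(s).  For four sites over the 20-letter alphabet this gives
1 + 76 + 2166 + 6859 = 9102 coefficients.  Coefficients are fitted by
L1-penalized (lasso) least squares on the non-lethal measured variants,
with the penalty chosen by 10-fold cross-validation; missing variants
then receive exp(predicted log fitness).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .landscape import (
    AMINO_ACIDS,
    DEFAULT_SITES,
    IMPUTED,
    MEASURED,
    FitnessLandscape,
    LandscapeError,
)

DEFAULT_THREEWAY_SITES = (39, 41, 54)

# a column is a tuple of (site_label, mutant_aa) pairs: length 1 for a
# single-mutation indicator, 2 for a pairwise term, 3 for a three-way term
Column = tuple[tuple[int, str], ...]


def design_columns(
    wt: str,
    site_labels=DEFAULT_SITES,
    alphabet: str = AMINO_ACIDS,
    threeway_sites=DEFAULT_THREEWAY_SITES,
) -> list[Column]:
    """Ordered list of indicator columns (singles, then pairs, then triples)."""
    sites = tuple(site_labels[: len(wt)])
    muts_by_site = {
        s: [aa for aa in alphabet if aa != wt[i]] for i, s in enumerate(sites)
    }
    cols: list[Column] = []
    for s in sites:
        cols += [((s, aa),) for aa in muts_by_site[s]]
    for si, sj in itertools.combinations(sites, 2):
        cols += [
            ((si, ai), (sj, aj))
            for ai in muts_by_site[si]
            for aj in muts_by_site[sj]
        ]
    if threeway_sites is not None:
        t = tuple(sorted(threeway_sites))
        if not set(t) <= set(sites):
            raise LandscapeError(f"threeway_sites {t} not among site labels {sites}")
        cols += [
            tuple(zip(t, combo))
            for combo in itertools.product(*(muts_by_site[s] for s in t))
        ]
    return cols


def build_design(
    genotypes: list[str],
    wt: str,
    site_labels=DEFAULT_SITES,
    alphabet: str = AMINO_ACIDS,
    threeway_sites=DEFAULT_THREEWAY_SITES,
) -> tuple[sp.csr_matrix, list[Column]]:
    """Binary design matrix (no intercept column); WT maps to an all-zero row."""
    sites = tuple(site_labels[: len(wt)])
    cols = design_columns(wt, sites, alphabet, threeway_sites)
    index = {c: j for j, c in enumerate(cols)}
    tset = set(sorted(threeway_sites)) if threeway_sites is not None else set()
    rows, col_idx = [], []
    for i, g in enumerate(genotypes):
        muts = tuple(
            (s, aa) for s, w_aa, aa in zip(sites, wt, g) if aa != w_aa
        )
        for m in muts:
            rows.append(i)
            col_idx.append(index[(m,)])
        for pair in itertools.combinations(muts, 2):
            rows.append(i)
            col_idx.append(index[pair])
        if tset:
            tmuts = tuple(m for m in muts if m[0] in tset)
            if len(tmuts) == 3:
                rows.append(i)
                col_idx.append(index[tmuts])
    data = np.ones(len(rows), dtype=float)
    X = sp.csr_matrix(
        (data, (rows, col_idx)), shape=(len(genotypes), len(cols))
    )
    return X, cols


@dataclass
class ModelCoefficients:
    """Fitted (or ground-truth) coefficients of the log-linear model.

    Dictionaries hold only the stored (typically nonzero) terms, keyed
    by ``(site_label, mutant_aa)`` tuples.
    """

    intercept: float
    singles: dict
    pairs: dict
    triples: dict
    site_labels: tuple
    alphabet: str
    wt: str
    threeway_sites: tuple | None
    lam: float = 0.0

    @property
    def n_coefficients(self) -> int:
        """Total coefficient count of the full model (intercept included)."""
        return 1 + len(
            design_columns(self.wt, self.site_labels, self.alphabet, self.threeway_sites)
        )

    def as_dict(self) -> dict[Column, float]:
        out: dict[Column, float] = {}
        for k, v in self.singles.items():
            out[(tuple(k),)] = v
        for k, v in self.pairs.items():
            out[tuple(tuple(p) for p in k)] = v
        for k, v in self.triples.items():
            out[tuple(tuple(p) for p in k)] = v
        return out

    def vector(self, cols: list[Column]) -> np.ndarray:
        d = self.as_dict()
        return np.array([d.get(c, 0.0) for c in cols])

    def predict_log(self, genotypes: list[str]) -> np.ndarray:
        X, cols = build_design(
            list(genotypes), self.wt, self.site_labels, self.alphabet, self.threeway_sites
        )
        return self.intercept + X @ self.vector(cols)

    def predict(self, genotypes: list[str]) -> np.ndarray:
        return np.exp(self.predict_log(genotypes))

    # -- sparse JSON serialization ------------------------------------
    def _name(self, col: Column) -> str:
        wt_at = {s: self.wt[i] for i, s in enumerate(self.site_labels[: len(self.wt)])}
        if len(col) < 3:
            return "|".join(f"{s}{wt_at[s]}>{aa}" for s, aa in col)
        return "|".join(f"{s}{aa}" for s, aa in col)

    def to_json(self, path) -> None:
        named = {self._name(c): v for c, v in self.as_dict().items() if v != 0.0}
        payload = {
            "intercept": self.intercept,
            "lambda": self.lam,
            "wt": self.wt,
            "alphabet": self.alphabet,
            "site_labels": list(self.site_labels),
            "threeway_sites": list(self.threeway_sites) if self.threeway_sites else None,
            "response": "log_fitness",
            "coefficients": named,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelCoefficients":
        with open(path) as fh:
            d = json.load(fh)
        singles, pairs, triples = {}, {}, {}
        for name, v in d["coefficients"].items():
            parts = name.split("|")
            terms = []
            for p in parts:
                if ">" in p:
                    lhs, aa = p.split(">")
                    site = int(lhs[:-1])
                else:
                    site, aa = int(p[:-1]), p[-1]
                terms.append((site, aa))
            key = tuple(terms)
            if len(key) == 1:
                singles[key[0]] = v
            elif len(key) == 2:
                pairs[key] = v
            else:
                triples[key] = v
        return cls(
            intercept=d["intercept"],
            singles=singles,
            pairs=pairs,
            triples=triples,
            site_labels=tuple(d["site_labels"]),
            alphabet=d["alphabet"],
            wt=d["wt"],
            threeway_sites=tuple(d["threeway_sites"]) if d["threeway_sites"] else None,
            lam=d["lambda"],
        )


@dataclass
class CVReport:
    lambdas: list[float]
    cv_mse: list[float]
    cv_mse_sd: list[float]
    chosen_lambda: float
    n_fit: int
    response: str = "log_fitness"
    nonzero_counts: list[int] = field(default_factory=list)


def _fit_at_lambda(X, y, lam: float, max_iter: int = 5000):
    """Lasso at penalty ``lam`` ((1/2n)*SSE + lam*L1); OLS when lam == 0."""
    if lam == 0.0:
        from sklearn.linear_model import LinearRegression

        m = LinearRegression().fit(X, y)
        return m.intercept_, m.coef_
    from sklearn.linear_model import Lasso

    m = Lasso(alpha=lam, fit_intercept=True, max_iter=max_iter, tol=1e-6).fit(X, y)
    return m.intercept_, m.coef_


def fit_l1(
    ls: FitnessLandscape,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
    chosen_lambda: float | None = 1e-4,
    threeway_sites=DEFAULT_THREEWAY_SITES,
) -> tuple[ModelCoefficients, CVReport]:
    """Lasso fit of the log-linear model on non-lethal measured variants.

    Cross-validation MSE (on the log-fitness response) is computed per
    grid penalty; the reported coefficients are refitted on all rows at
    ``chosen_lambda`` (default 1e-4, the study's choice), or at the
    CV-minimizing penalty when ``chosen_lambda`` is None.
    """
    fit_genotypes = sorted(
        g
        for g, w in ls.entries.items()
        if w > 0 and ls.origin.get(g, MEASURED) == MEASURED
    )
    if len(fit_genotypes) < max(folds, 2):
        raise LandscapeError(f"only {len(fit_genotypes)} usable rows for a {folds}-fold fit")
    if threeway_sites is not None and len(ls.site_labels) < 3:
        threeway_sites = None
    if threeway_sites is not None and not set(threeway_sites) <= set(ls.site_labels):
        threeway_sites = None
    y = np.log([ls.entries[g] for g in fit_genotypes])
    X, cols = build_design(fit_genotypes, ls.wt, ls.site_labels, ls.alphabet, threeway_sites)

    lambdas = list(lambda_grid) if lambda_grid is not None else [1e-4]
    cv_mse, cv_sd, nnz = [], [], []
    if folds >= 2 and lambdas:
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(np.arange(len(y))))
        for lam in lambdas:
            fold_mse = []
            for train, test in splits:
                b0, b = _fit_at_lambda(X[train], y[train], lam)
                pred = b0 + X[test] @ b
                fold_mse.append(float(np.mean((y[test] - pred) ** 2)))
            cv_mse.append(float(np.mean(fold_mse)))
            cv_sd.append(float(np.std(fold_mse)))

    if chosen_lambda is None:
        chosen_lambda = lambdas[int(np.argmin(cv_mse))]
    b0, b = _fit_at_lambda(X, y, chosen_lambda)
    for lam in lambdas:
        _, bl = _fit_at_lambda(X, y, lam)
        nnz.append(int(np.count_nonzero(bl)))

    singles, pairs, triples = {}, {}, {}
    for c, v in zip(cols, b):
        if v == 0.0:
            continue
        if len(c) == 1:
            singles[c[0]] = float(v)
        elif len(c) == 2:
            pairs[c] = float(v)
        else:
            triples[c] = float(v)
    coeffs = ModelCoefficients(
        intercept=float(b0),
        singles=singles,
        pairs=pairs,
        triples=triples,
        site_labels=tuple(ls.site_labels),
        alphabet=ls.alphabet,
        wt=ls.wt,
        threeway_sites=tuple(sorted(threeway_sites)) if threeway_sites else None,
        lam=float(chosen_lambda),
    )
    report = CVReport(lambdas, cv_mse, cv_sd, float(chosen_lambda), len(y), nonzero_counts=nnz)
    return coeffs, report


def impute(ls: FitnessLandscape, coeffs: ModelCoefficients) -> FitnessLandscape:
    """Fill every missing genotype with exp(predicted log fitness).

    Measured entries are untouched; imputed entries are flagged
    ``imputed``.  Imputation never produces an exact 0 (lethality is
    outside the log-linear model's range).
    """
    if not ls.missing:
        return ls
    targets = sorted(ls.missing)
    pred = np.exp(coeffs.predict_log(targets))
    entries = dict(ls.entries)
    origin = dict(ls.origin)
    for g, w in zip(targets, pred):
        entries[g] = float(w)
        origin[g] = IMPUTED
    return FitnessLandscape(ls.wt, entries, set(), origin, ls.alphabet, ls.site_labels)
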