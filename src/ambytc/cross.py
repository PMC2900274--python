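"""Direct interspecies comparison on zero-mismatch probe-sets.

Each gene's log2 expression over both species is fit with a quadratic
dummy-variable model — intercept, species offset S, time T, T^2, and the
interactions ST, ST^2 — on centred days.  Significant models (BH FDR on
the overall F p-value) are reduced by hierarchical backward selection;
genes are retained when the reduced model keeps a species-dependent term,
the full model explains R^2 >= 0.50, and the species differ >= 1.5-fold at
some sampling day.  The module also carries the heatmap computation: row
centring/scaling, |1 - r| correlation distance and average-linkage
hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .stats import bh_fdr, ols

#: Non-intercept terms of the full species-dummy model, in design order.
TERMS = ("S", "T", "ST", "T2", "ST2")

def _dependents(term: str) -> tuple:
    """Terms whose presence freezes ``term`` (marginality/hierarchy rule).

    The species main effect is frozen by any species x time interaction; a
    polynomial term T^k by T^(k+1) and by its own interaction ST^k.
    Interactions themselves are freely removable.  Dependents absent from
    the current model are simply ignored by the caller.
    """
    if term == "S":
        return tuple(f"ST{k}" if k > 1 else "ST" for k in range(1, 5))
    if term.startswith("ST"):
        return ()
    if term.startswith("T"):
        k = int(term[1:] or 1)
        return (f"T{k + 1}", f"ST{k}" if k > 1 else "ST")
    return ()


def species_design(t, species, degree: int = 2):
    """Design matrix for the species-dummy polynomial model.

    ``species`` is a 0/1 dummy (0 = reference species); time is centred.
    Returns ``(X, term_names, centre)`` with term names ``S, T, ST, T2,
    ST2, ...`` up to the requested polynomial degree.
    """
    t = np.asarray(t, float)
    s = np.asarray(species, float)
    if set(np.unique(s)) != {0.0, 1.0}:
        raise ValueError("both species (dummy levels 0 and 1) must be present")
    centre = t.mean()
    tc = t - centre
    cols = [np.ones_like(tc), s]
    names = ["S"]
    for d in range(1, degree + 1):
        suffix = "" if d == 1 else str(d)
        cols.append(tc**d)
        names.append(f"T{suffix}")
        cols.append(s * tc**d)
        names.append(f"ST{suffix}")
    return np.column_stack(cols), tuple(names), centre


@dataclass
class SpeciesModelFit:
    """Full and backward-reduced species-dummy polynomial fit."""

    coef: dict
    p_terms: dict
    p_overall: float
    r2: float
    df_resid: int
    centre: float
    terms: tuple
    reduced_terms: tuple | None = None
    reduced_coef: dict | None = None
    reduced_p: dict | None = None
    degenerate: bool = False


def fit_species_model(y, t, species, degree: int = 2) -> SpeciesModelFit:
    """OLS fit of the full species-dummy model for one gene."""
    y = np.asarray(y, float)
    X, names, centre = species_design(t, species, degree)
    res = ols(X, y)
    labels = ("Intercept",) + names
    return SpeciesModelFit(
        coef=dict(zip(labels, res.coef)),
        p_terms=dict(zip(labels, res.p_coef)),
        p_overall=float(res.p_overall),
        r2=float(res.r2),
        df_resid=res.df_resid,
        centre=centre,
        terms=names,
        degenerate=bool(res.degenerate),
    )


def backward_select(y, t, species, alpha: float = 0.05, degree: int = 2):
    """Hierarchical backward elimination on the species-dummy model.

    Elimination applies to significant models: when the full model's
    overall F-test exceeds ``alpha`` the gene is null and the intercept-only
    model is returned outright.  Otherwise the least significant removable
    term with p > alpha is dropped and the model refit, repeatedly; a term
    is frozen while any interaction or higher polynomial containing it
    remains, and the intercept is never removed.  Returns ``(terms, coef,
    p_terms)`` of the surviving model (possibly intercept-only: empty term
    tuple).
    """
    y = np.asarray(y, float)
    X_full, names, _ = species_design(t, species, degree)
    full = ols(X_full, y)
    if full.p_overall > alpha:
        return (), {"Intercept": float(np.mean(y))}, {"Intercept": 0.0}
    cols = {name: X_full[:, i + 1] for i, name in enumerate(names)}
    current = list(names)
    while True:
        X = np.column_stack([np.ones(len(y))] + [cols[n] for n in current]) \
            if current else np.ones((len(y), 1))
        res = ols(X, y)
        p = dict(zip(["Intercept"] + current, res.p_coef))
        removable = [
            n for n in current
            if p[n] > alpha and not any(d in current for d in _dependents(n))
        ]
        if not removable:
            coef = dict(zip(["Intercept"] + current, res.coef))
            return tuple(current), coef, p
        worst = max(removable, key=lambda n: p[n])
        current.remove(worst)


class SpeciesComparisonDEG(BaseEstimator):
    """Direct interspecies DEG screen on zero-mismatch probe-sets.

    Retention requires all four criteria: (1) BH-FDR-rejected overall
    model p at rate ``q``; (2) a species-dependent term (S, ST or ST^2)
    surviving backward selection at ``alpha``; (3) full-model
    R^2 >= ``r2_min``; (4) a >= ``fold_threshold`` interspecies difference
    of day means at one or more sampling days.

    Fitted attributes
    -----------------
    results_ : per-gene DataFrame of model statistics, criteria verdicts,
        interspecies folds and which-species-higher summaries.
    degs_ : the retained subset.
    """

    def __init__(self, q: float = 0.05, alpha: float = 0.05,
                 r2_min: float = 0.50, fold_threshold: float = 1.5):
        self.q = q
        self.alpha = alpha
        self.r2_min = r2_min
        self.fold_threshold = fold_threshold

    def fit(self, matrix: pd.DataFrame, samples: pd.DataFrame,
            passlist: list | None = None):
        if passlist is not None:
            missing = set(matrix.index) - set(passlist)
            if missing:
                warnings.warn(
                    f"{len(missing)} probe-sets not on the compatibility "
                    "pass-list were dropped before the direct comparison")
                matrix = matrix.loc[[g for g in matrix.index if g in set(passlist)]]
        samples = (samples.set_index("sample_id").loc[list(matrix.columns)]
                   .rename_axis("sample_id").reset_index())
        sp_levels = sorted(samples["species"].unique())
        if len(sp_levels) != 2:
            raise ValueError("exactly two species required")
        ref, other = sp_levels  # dummy: 0 = first label alphabetically
        dummy = (samples["species"] == other).to_numpy(float)
        t = samples["dph"].to_numpy(float)
        X, names, centre = species_design(t, dummy, degree=2)
        Y = matrix.to_numpy(float).T
        full = ols(X, Y)
        reject, p_adj = bh_fdr(full.p_overall, self.q)

        days = sorted(samples["dph"].unique())
        mean_ref = {d: matrix[samples.loc[(samples["dph"] == d) & (samples["species"] == ref),
                                          "sample_id"]].mean(axis=1) for d in days}
        mean_other = {d: matrix[samples.loc[(samples["dph"] == d) & (samples["species"] == other),
                                            "sample_id"]].mean(axis=1) for d in days}
        diffs = pd.concat([mean_other[d] - mean_ref[d] for d in days], axis=1)
        diffs.columns = days
        max_fold = 2.0 ** diffs.abs().max(axis=1)

        species_terms = {"S", "ST", "ST2"}
        rows = []
        for g, gid in enumerate(matrix.index):
            if reject[g]:
                terms, coef, _ = backward_select(Y[:, g], t, dummy, self.alpha)
            else:
                terms, coef = (), {}
            has_species = bool(species_terms & set(terms))
            d = diffs.loc[gid]
            higher = other if (d > 0).all() else (ref if (d < 0).all() else "mixed")
            rows.append({
                "probeset_id": gid,
                "p_overall": full.p_overall[g],
                "p_adj": p_adj[g],
                "r2": full.r2[g],
                "screen_rejected": bool(reject[g]),
                "reduced_terms": ";".join(terms),
                "species_term_retained": has_species,
                "r2_pass": full.r2[g] >= self.r2_min,
                "max_fold": float(max_fold.loc[gid]),
                "fold_pass": bool(max_fold.loc[gid] >= self.fold_threshold),
                "higher_species": higher,
            })
        results = pd.DataFrame(rows).set_index("probeset_id")
        results["is_deg"] = (
            results["screen_rejected"] & results["species_term_retained"]
            & results["r2_pass"] & results["fold_pass"]
        )
        self.species_levels_ = (ref, other)
        self.results_ = results
        self.degs_ = results[results["is_deg"]].copy()
        self.n_degs_ = int(results["is_deg"].sum())
        return self


def identify_direct_degs(matrix: pd.DataFrame, samples: pd.DataFrame,
                         q: float = 0.05, alpha: float = 0.05,
                         r2_min: float = 0.50, fc: float = 1.5,
                         passlist: list | None = None) -> pd.DataFrame:
    """Functional form of :class:`SpeciesComparisonDEG`."""
    est = SpeciesComparisonDEG(q=q, alpha=alpha, r2_min=r2_min,
                               fold_threshold=fc).fit(matrix, samples, passlist)
    return est.degs_


def center_scale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize to mean 0, (sample) SD 1; zero-SD rows become zeros."""
    X = np.asarray(matrix, float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows scaled to zero")
        sd[flat] = 1.0
    out = (X - mean) / sd
    out[flat] = 0.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise column distance |1 - Pearson r| over genes."""
    X = np.asarray(matrix, float)
    if (X.std(axis=0) == 0).any():
        raise ValueError("zero-variance column: correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    d = np.abs(1.0 - r)
    np.fill_diagonal(d, 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)
    return d


def hcluster(distance: pd.DataFrame, linkage: str = "average"):
    """Agglomerative clustering of a precomputed distance matrix.

    Returns ``(Z, leaf_order)``: the scipy linkage matrix (merge heights
    as cophenetic distances) and the dendrogram leaf order (labels when the
    input is a DataFrame).  Equal-height ties break deterministically on
    the lowest condensed index, scipy's convention.
    """
    labels = list(distance.columns) if isinstance(distance, pd.DataFrame) else None
    D = np.asarray(distance, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    Z = sch.linkage(squareform(D, checks=False), method=linkage)
    order = sch.leaves_list(Z)
    if labels is not None:
        return Z, [labels[i] for i in order]
    return Z, list(order)


def linkage_to_newick(Z, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with heights."""
    tree = sch.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
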