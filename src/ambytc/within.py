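"""Within-species temporal DEG screen.

Each species' expression matrix is screened gene-by-gene with a quadratic
regression of log2 abundance on days post hatching.  Overall-model F
p-values are corrected by Benjamini-Hochberg FDR (alpha0 tier); genes
passing the screen are classified into the nine temporal profiles by
coefficient significance at alpha1 and the vertex rule, and retained only
if they change >= 1.5-fold versus the 42 dph baseline at some later day.
The two species' DEG lists are then partitioned into shared/unique sets
with profile and direction concordance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .profiles import DIRECTION, ProfileClass, classify_coefficients
from .stats import bh_fdr, ols


@dataclass
class RegressionFit:
    """Per-gene quadratic fit, reported in the uncentred parameterization."""

    b0: float
    b1: float
    b2: float
    p_b0: float
    p_b1: float
    p_b2: float
    t_b1: float
    t_b2: float
    p_overall: float
    r2: float
    df_resid: int
    t_centre: float
    t_range: tuple[float, float]
    degenerate: bool = False


def _quadratic_design(t: np.ndarray):
    centre = t.mean()
    tc = t - centre
    return np.column_stack([np.ones_like(tc), tc, tc**2]), centre


def _uncentre(coef: np.ndarray, centre: float) -> np.ndarray:
    """Map (b0c, b1c, b2) on centred time back to the raw-day polynomial."""
    b0c, b1c, b2 = coef
    return np.array([b0c - b1c * centre + b2 * centre**2, b1c - 2 * b2 * centre, b2])


def fit_quadratic(y, t) -> RegressionFit:
    """OLS quadratic regression of log2 expression on (centred) days.

    Requires >= 4 observations over >= 3 distinct days.  A zero-variance
    response is flagged degenerate with overall p = 1.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if y.size < 4 or np.unique(t).size < 3:
        raise ValueError("need >= 4 observations spanning >= 3 distinct days")
    X, centre = _quadratic_design(t)
    res = ols(X, y)
    b = _uncentre(res.coef, centre)
    return RegressionFit(
        b0=float(b[0]), b1=float(b[1]), b2=float(b[2]),
        p_b0=float(res.p_coef[0]), p_b1=float(res.p_coef[1]), p_b2=float(res.p_coef[2]),
        t_b1=float(res.tstat[1]), t_b2=float(res.tstat[2]),
        p_overall=float(res.p_overall), r2=float(res.r2), df_resid=res.df_resid,
        t_centre=float(centre), t_range=(float(t.min()), float(t.max())),
        degenerate=bool(res.degenerate),
    )


def fit_quadratic_matrix(matrix: pd.DataFrame, t) -> pd.DataFrame:
    """Vectorised :func:`fit_quadratic` over all rows of a matrix."""
    t = np.asarray(t, float)
    X, centre = _quadratic_design(t)
    res = ols(X, matrix.to_numpy(float).T)
    b = np.column_stack([_uncentre(res.coef[:, g], centre) for g in range(matrix.shape[0])])
    return pd.DataFrame(
        {
            "b0": b[0], "b1": b[1], "b2": b[2],
            "p_b1": res.p_coef[1], "p_b2": res.p_coef[2],
            "t_b1": res.tstat[1], "t_b2": res.tstat[2],
            "p_overall": res.p_overall, "r2": res.r2,
            "degenerate": res.degenerate,
        },
        index=matrix.index,
    )


def classify_profile(fit: RegressionFit, alpha1: float = 0.05,
                     screen_passed: bool = True) -> ProfileClass:
    """Nine-way temporal profile classification of a quadratic fit.

    Genes failing the screen are flat.  Otherwise the quadratic coefficient
    is treated as real when its t-test p <= alpha1; transient classes
    (QV/QC) require the vertex strictly inside the sampled interval.  When
    the screen passed but neither coefficient is individually significant,
    the coefficient with the larger |t| drives the shape (warned; rare).
    """
    if not screen_passed or fit.degenerate:
        return ProfileClass.FLAT
    b2_sig = fit.p_b2 <= alpha1
    b1_sig = fit.p_b1 <= alpha1
    if not b2_sig and not b1_sig:
        warnings.warn("screen passed without an individually significant "
                      "coefficient; classifying by larger |t|")
        b2_sig = abs(fit.t_b2) >= abs(fit.t_b1)
        b1_sig = not b2_sig
    return classify_coefficients(
        fit.b1, fit.b2, fit.t_range[0], fit.t_range[1],
        use_quadratic=b2_sig, use_linear=True,
    )


def fold_change_filter(matrix: pd.DataFrame, samples: pd.DataFrame,
                       baseline_day: int = 42, threshold: float = 1.5):
    """Max linear-scale fold change of day means versus the baseline day.

    Folds are direction-agnostic (``2**|mean_log2(day) -
    mean_log2(baseline)|``).  Returns ``(pass_mask, max_fold)`` Series.
    """
    days = sorted(samples["dph"].unique())
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day} absent from sample sheet")
    day_means = {
        day: matrix[samples.loc[samples["dph"] == day, "sample_id"]].mean(axis=1)
        for day in days
    }
    base = day_means[baseline_day]
    folds = pd.concat(
        [2.0 ** (day_means[d] - base).abs() for d in days if d != baseline_day], axis=1
    )
    max_fold = folds.max(axis=1)
    return max_fold >= threshold, max_fold


class WithinSpeciesDEG(BaseEstimator):
    """Single-species temporal DEG screen (quadratic regression tier).

    Parameters mirror the study's retention rule: BH FDR at ``q`` on the
    overall-model p-values, per-coefficient classification at ``alpha1``,
    and a >= ``fold_threshold`` change versus ``baseline_day``.

    Fitted attributes
    -----------------
    results_ : DataFrame with per-gene fit statistics, adjusted p, profile
        class, direction, max fold and the retention verdict.
    degs_ : the retained subset of ``results_``.
    """

    def __init__(self, q: float = 0.05, alpha1: float = 0.05,
                 fold_threshold: float = 1.5, baseline_day: int = 42):
        self.q = q
        self.alpha1 = alpha1
        self.fold_threshold = fold_threshold
        self.baseline_day = baseline_day

    def fit(self, matrix: pd.DataFrame, samples: pd.DataFrame):
        if samples["species"].nunique() != 1:
            raise ValueError("matrix must contain a single species")
        samples = (samples.set_index("sample_id").loc[list(matrix.columns)]
                   .rename_axis("sample_id").reset_index())
        t = samples["dph"].to_numpy(float)
        t_lo, t_hi = float(t.min()), float(t.max())
        fits = fit_quadratic_matrix(matrix, t)
        reject, p_adj = bh_fdr(fits["p_overall"].to_numpy(), self.q)
        fc_pass, max_fold = fold_change_filter(
            matrix, samples, self.baseline_day, self.fold_threshold
        )
        profiles, directions = [], []
        for gid, row in fits.iterrows():
            fit = RegressionFit(
                b0=row["b0"], b1=row["b1"], b2=row["b2"],
                p_b0=0.0, p_b1=row["p_b1"], p_b2=row["p_b2"],
                t_b1=row["t_b1"], t_b2=row["t_b2"],
                p_overall=row["p_overall"], r2=row["r2"], df_resid=0,
                t_centre=t.mean(), t_range=(t_lo, t_hi),
                degenerate=bool(row["degenerate"]),
            )
            cls = classify_profile(fit, self.alpha1,
                                   screen_passed=bool(reject[fits.index.get_loc(gid)]))
            profiles.append(cls.value)
            directions.append(DIRECTION[cls])
        results = fits.copy()
        results["p_adj"] = p_adj
        results["screen_rejected"] = reject
        results["max_fold"] = max_fold
        results["fold_pass"] = fc_pass
        results["profile"] = profiles
        results["direction"] = directions
        results["species"] = samples["species"].iloc[0]
        results["is_deg"] = (
            results["screen_rejected"] & results["fold_pass"]
            & (results["profile"] != ProfileClass.FLAT.value)
        )
        # per-day mean log2 values for reporting
        for day in sorted(samples["dph"].unique()):
            cols = samples.loc[samples["dph"] == day, "sample_id"]
            results[f"mean_log2_{day}"] = matrix[cols].mean(axis=1)
        self.results_ = results
        self.degs_ = results[results["is_deg"]].copy()
        self.n_degs_ = int(results["is_deg"].sum())
        return self


def identify_degs(matrix: pd.DataFrame, samples: pd.DataFrame, q: float = 0.05,
                  alpha1: float = 0.05, fc: float = 1.5, baseline: int = 42) -> pd.DataFrame:
    """DEG table for one species (functional form of the estimator)."""
    est = WithinSpeciesDEG(q=q, alpha1=alpha1, fold_threshold=fc,
                           baseline_day=baseline).fit(matrix, samples)
    return est.degs_


def partition_venn(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> dict:
    """Shared/unique DEG partition with profile and direction concordance.

    Concordance is computed over the shared set: the fraction with
    identical profile class, and the fraction with the same generalized
    direction (up / down / transient).  Empty intersections report NaN.
    """
    ids_a, ids_b = list(degs_a.index), list(degs_b.index)
    for name, ids in (("A", ids_a), ("B", ids_b)):
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in DEG list {name}")
    shared = [g for g in ids_a if g in set(ids_b)]
    unique_a = [g for g in ids_a if g not in set(ids_b)]
    unique_b = [g for g in ids_b if g not in set(ids_a)]
    if shared:
        same_profile = float(np.mean(
            degs_a.loc[shared, "profile"].to_numpy()
            == degs_b.loc[shared, "profile"].to_numpy()))
        same_direction = float(np.mean(
            degs_a.loc[shared, "direction"].to_numpy()
            == degs_b.loc[shared, "direction"].to_numpy()))
    else:
        same_profile = same_direction = float("nan")
    return {
        "shared": shared,
        "unique_a": unique_a,
        "unique_b": unique_b,
        "n_shared": len(shared),
        "n_unique_a": len(unique_a),
        "n_unique_b": len(unique_b),
        "profile_concordance": same_profile,
        "direction_concordance": same_direction,
    }
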