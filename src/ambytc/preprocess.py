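"""Probe-level QC and RMA-style preprocessing.

Raw oligonucleotide array intensities (perfect-match PM and mismatch MM
probes grouped into probe-sets) are turned into a probe-set x sample log2
expression matrix by the standard robust multi-array average stages:
normal+exponential background correction, quantile normalization of PM
intensities, and per-probe-set median-polish summarization.  Present/absent
detection calls (one-sided Wilcoxon signed-rank test on PM/MM
discrimination scores) drive the absent-probe-set filter, and replicate
correlation summaries provide the numeric QC surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class ProbeLevelDataset:
    """PM/MM probe intensities for every array of a study.

    ``pm`` and ``mm`` are DataFrames indexed by ``(probeset_id,
    probe_index)`` with one column per array (sample id); ``samples`` is the
    sample sheet (``sample_id``, ``species``, ``dph``, ``replicate``).
    """

    pm: pd.DataFrame
    mm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.pm.index.equals(self.mm.index):
            raise ValueError("PM and MM tables must share a probe index")
        if list(self.pm.columns) != list(self.mm.columns):
            raise ValueError("PM and MM tables must share array columns")
        missing = set(self.pm.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"arrays missing from sample sheet: {sorted(missing)}")
        for name, tab in (("PM", self.pm), ("MM", self.mm)):
            vals = tab.to_numpy()
            if not np.isfinite(vals).all() or (vals <= 0).any():
                raise ValueError(f"{name} intensities must be finite and > 0")

    @property
    def probeset_ids(self) -> list:
        return list(self.pm.index.get_level_values(0).unique())

    def to_frame(self) -> pd.DataFrame:
        """Long/wide TSV layout: probeset_id, probe_index, PM_<id>, MM_<id>."""
        pm = self.pm.add_prefix("PM_")
        mm = self.mm.add_prefix("MM_")
        return pd.concat([pm, mm], axis=1).reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, samples: pd.DataFrame) -> "ProbeLevelDataset":
        frame = frame.set_index(["probeset_id", "probe_index"])
        pm = frame[[c for c in frame.columns if c.startswith("PM_")]]
        mm = frame[[c for c in frame.columns if c.startswith("MM_")]]
        pm.columns = [c[3:] for c in pm.columns]
        mm.columns = [c[3:] for c in mm.columns]
        return cls(pm=pm, mm=mm, samples=samples)


def background_correct(pm, fallback_eps: float = 1.0) -> np.ndarray | pd.DataFrame:
    """Normal+exponential convolution background correction, per array.

    Each array's intensities are modelled as ``X = S + B`` with signal
    ``S ~ Exp(1/theta)`` and optical noise ``B ~ N(mu, sigma^2)``;
    parameters are estimated by method of moments (the exponential carries
    all the skewness: ``theta = (m3/2)^(1/3)``) and each observation is
    replaced by ``E[S | X = x]``, which is strictly positive and increasing
    in ``x``.  Arrays where the moment estimates are infeasible (negative
    skewness or variance deficit — e.g. a constant array) fall back to
    subtracting ``min - fallback_eps``.
    """
    values = np.asarray(pm, float)
    if values.ndim == 1:
        out = _normexp_correct(values, fallback_eps)
    else:
        out = np.column_stack(
            [_normexp_correct(values[:, j], fallback_eps) for j in range(values.shape[1])]
        )
    if isinstance(pm, pd.DataFrame):
        return pd.DataFrame(out, index=pm.index, columns=pm.columns)
    return out


def normexp_conditional_mean(x, mu: float, sigma: float, theta: float) -> np.ndarray:
    """``E[S | S + B = x]`` for ``S ~ Exp(1/theta)``, ``B ~ N(mu, sigma^2)``.

    The normexp posterior mean; strictly positive and increasing in ``x``,
    and approaching ``x - mu - sigma^2/theta`` for large signals (so the
    correction vanishes as ``mu, sigma -> 0``).
    """
    x = np.asarray(x, float)
    mu_sx = x - mu - sigma**2 / theta
    z = mu_sx / sigma
    # E[S|X] = mu_sx + sigma * phi(z)/Phi(z); log-space ratio for stability
    return mu_sx + sigma * np.exp(sps.norm.logpdf(z) - sps.norm.logcdf(z))


def _normexp_correct(x: np.ndarray, fallback_eps: float) -> np.ndarray:
    if not np.isfinite(x).all() or (x <= 0).any():
        raise ValueError("intensities must be finite and > 0")
    m = x.mean()
    v = x.var()
    m3 = ((x - m) ** 3).mean()
    if m3 <= 0 or v <= 0:
        return x - (x.min() - fallback_eps)
    theta = (m3 / 2.0) ** (1.0 / 3.0)
    sigma2 = v - theta**2
    if sigma2 <= 0:
        return x - (x.min() - fallback_eps)
    return normexp_conditional_mean(x, m - theta, np.sqrt(sigma2), theta)


def quantile_normalize(matrix):
    """Force every column onto the mean empirical distribution.

    After normalization each column's sorted vector equals the row-wise
    mean of the sorted input columns; ties within a column receive the mean
    of the normalized values their positions span.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite values are not supported")
    n, k = X.shape
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = mean_sorted
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if uniq.size < n:  # average over tied positions
            sums = np.bincount(inv, weights=assigned)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def median_polish(block, tol: float = 1e-12, max_iter: int = 1000):
    """Tukey median polish of an additive probes x arrays model.

    Iterates row and column median sweeps until the total absolute residual
    changes by less than ``tol`` (or ``max_iter`` passes).  Returns
    ``(overall, row_effects, col_effects, residuals)``.
    """
    r = np.array(block, float)
    if r.ndim != 2:
        raise ValueError("block must be 2-D")
    nr, nc = r.shape
    overall = 0.0
    rows = np.zeros(nr)
    cols = np.zeros(nc)
    for _ in range(max_iter):
        prev = r.copy()
        rdelta = np.median(r, axis=1)
        r -= rdelta[:, None]
        rows += rdelta
        delta = np.median(cols)
        cols -= delta
        overall += delta
        cdelta = np.median(r, axis=0)
        r -= cdelta[None, :]
        cols += cdelta
        delta = np.median(rows)
        rows -= delta
        overall += delta
        if np.abs(r - prev).max() < tol:
            break
    return overall, rows, cols, r


def summarize_median_polish(log2_pm_block) -> np.ndarray:
    """Per-array probe-set summary: median-polish overall + array effect."""
    block = np.asarray(log2_pm_block, float)
    if block.shape[0] == 1:
        return block[0].copy()
    overall, _, cols, _ = median_polish(block)
    return overall + cols


def detection_call(
    pm,
    mm,
    tau: float = 0.015,
    alpha_present: float = 0.04,
    alpha_absent: float = 0.06,
):
    """Present/marginal/absent detection call for one probe-set on one array.

    Discrimination scores ``d_j = (PM_j - MM_j)/(PM_j + MM_j)`` are tested
    against ``tau`` by a one-sided Wilcoxon signed-rank test; the p-value is
    thresholded at ``alpha_present`` (present) and ``alpha_absent``
    (marginal), otherwise absent.  Returns ``(p, call)``.
    """
    pm = np.asarray(pm, float)
    mm = np.asarray(mm, float)
    if pm.shape != mm.shape or pm.ndim != 1:
        raise ValueError("PM and MM must be equal-length vectors")
    denom = pm + mm
    if (denom == 0).any():
        raise ValueError("PM + MM must be non-zero for every probe")
    d = (pm - mm) / denom - tau
    if np.all(d == 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(d, alternative="greater", zero_method="zsplit").pvalue)
    if p < alpha_present:
        call = "present"
    elif p < alpha_absent:
        call = "marginal"
    else:
        call = "absent"
    return p, call


def detection_calls(dataset: ProbeLevelDataset, **kwargs) -> pd.DataFrame:
    """Detection call table (probe-set x array) of ``p:call`` pairs.

    Returns a DataFrame with a two-level column index ``(field, array)``
    where field is ``p`` or ``call``.
    """
    arrays = list(dataset.pm.columns)
    pm_groups = dataset.pm.groupby(level=0, sort=False)
    records_p, records_c, ids = [], [], []
    for ps_id, pm_block in pm_groups:
        mm_block = dataset.mm.loc[ps_id]
        pvals, calls = [], []
        for a in arrays:
            p, call = detection_call(pm_block[a].to_numpy(), mm_block[a].to_numpy(), **kwargs)
            pvals.append(p)
            calls.append(call)
        records_p.append(pvals)
        records_c.append(calls)
        ids.append(ps_id)
    p_df = pd.DataFrame(records_p, index=ids, columns=arrays)
    c_df = pd.DataFrame(records_c, index=ids, columns=arrays)
    return pd.concat({"p": p_df, "call": c_df}, axis=1)


def filter_absent(calls: pd.DataFrame, matrix: pd.DataFrame, max_absent_fraction: float = 0.75):
    """Drop probe-sets called absent on strictly more than the given
    fraction of the matrix's arrays.

    ``calls`` is the output of :func:`detection_calls` (only its ``call``
    block is used).  Returns ``(filtered_matrix, report)`` where the report
    lists per-probe-set absent fractions and the dropped ids.
    """
    call_block = calls["call"] if isinstance(calls.columns, pd.MultiIndex) else calls
    if not set(matrix.index) <= set(call_block.index):
        raise ValueError("detection calls do not cover every matrix row")
    if not set(matrix.columns) <= set(call_block.columns):
        raise ValueError("detection calls do not cover every matrix column")
    sub = call_block.loc[matrix.index, matrix.columns]
    absent_frac = (sub == "absent").mean(axis=1)
    dropped = absent_frac.index[absent_frac > max_absent_fraction]
    report = pd.DataFrame(
        {"absent_fraction": absent_frac, "dropped": absent_frac > max_absent_fraction}
    )
    return matrix.drop(index=dropped), report


def replicate_correlation(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean pairwise Pearson r among replicate arrays per species x day cell.

    Zero-variance columns make r undefined; such pairs are reported as NaN
    with a warning.  The table carries one row per cell plus the study-wide
    minimum via ``.attrs['min_mean_r']``.
    """
    rows = []
    for (species, day), cell in samples.groupby(["species", "dph"], sort=True):
        ids = [c for c in cell["sample_id"] if c in matrix.columns]
        if len(ids) < 2:
            raise ValueError(f"cell {species}/{day} has < 2 replicates")
        sub = matrix[ids].to_numpy()
        sds = sub.std(axis=0)
        if (sds == 0).any():
            warnings.warn(f"zero-variance replicate in cell {species}/{day}; r undefined")
            mean_r = np.nan
        else:
            corr = np.corrcoef(sub, rowvar=False)
            iu = np.triu_indices(len(ids), 1)
            mean_r = float(corr[iu].mean())
        rows.append({"species": species, "dph": day, "n_replicates": len(ids), "mean_r": mean_r})
    out = pd.DataFrame(rows)
    valid = out["mean_r"].dropna()
    out.attrs["min_mean_r"] = float(valid.min()) if len(valid) else np.nan
    return out


class RMA(TransformerMixin, BaseEstimator):
    """Robust multi-array average preprocessor.

    Composes normexp background correction, log2 transformation, quantile
    normalization across arrays, and per-probe-set median-polish
    summarization of PM intensities into an expression matrix.  Stateless
    and deterministic; ``fit`` only validates.

    Parameters
    ----------
    background : bool
        Apply normexp background correction (the optical-noise model stage).
    normalize : bool
        Apply quantile normalization across arrays.
    """

    def __init__(self, background: bool = True, normalize: bool = True):
        self.background = background
        self.normalize = normalize

    def fit(self, dataset: ProbeLevelDataset, y=None):
        if not isinstance(dataset, ProbeLevelDataset):
            raise TypeError("RMA expects a ProbeLevelDataset")
        self.n_probesets_ = len(dataset.probeset_ids)
        self.n_arrays_ = dataset.pm.shape[1]
        return self

    def transform(self, dataset: ProbeLevelDataset) -> pd.DataFrame:
        self.fit(dataset)
        pm = dataset.pm
        if self.background:
            pm = background_correct(pm)
        log2_pm = np.log2(pm)
        if self.normalize:
            log2_pm = quantile_normalize(log2_pm)
        ids, rows = [], []
        for ps_id, block in log2_pm.groupby(level=0, sort=False):
            ids.append(ps_id)
            rows.append(summarize_median_polish(block.to_numpy()))
        return pd.DataFrame(rows, index=pd.Index(ids, name="probeset_id"),
                            columns=dataset.pm.columns)


def rma(dataset: ProbeLevelDataset, background: bool = True, normalize: bool = True) -> pd.DataFrame:
    """Functional form of :class:`RMA`."""
    return RMA(background=background, normalize=normalize).fit_transform(dataset)
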