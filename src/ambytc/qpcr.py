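"""qPCR quantification: dilution-series efficiencies, Pfaffl relative
expression ratios, and the cubic species-profile GLM.

Relative expression follows the efficiency-corrected ratio
``R = E_target^(dCt_target) / E_ref^(dCt_ref)`` with
``dCt = Ct(calibrator) - Ct(sample)``; amplification efficiencies come
from linear regression of Ct on log10 template amount over a serial
dilution (``E = 10^(-1/slope)``).  Log2 ratios are then modelled by a
cubic polynomial of day with species dummy terms, simplified by the same
hierarchical backward selection used for the array comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cross import backward_select, fit_species_model
from .stats import ols

REFERENCE_GENE = "tif1"


@dataclass
class EfficiencyEstimate:
    gene: str
    species: str
    efficiency: float
    slope: float
    r2: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("dilution-series slope must be negative "
                             "(no amplification signal)")


def estimate_efficiency(amounts, cts, gene: str = "", species: str = "") -> EfficiencyEstimate:
    """Amplification efficiency from a serial dilution series.

    Regresses Ct on log10(template amount); ``E = 10^(-1/slope)``.  Needs
    >= 3 dilution points spanning >= 2 orders of magnitude.
    """
    amounts = np.asarray(amounts, float)
    cts = np.asarray(cts, float)
    if amounts.size < 3:
        raise ValueError("need >= 3 dilution points")
    if (amounts <= 0).any():
        raise ValueError("template amounts must be positive")
    logs = np.log10(amounts)
    if logs.max() - logs.min() < 2.0:
        raise ValueError("dilution series must span >= 2 orders of magnitude")
    res = ols(np.column_stack([np.ones_like(logs), logs]), cts)
    slope = float(res.coef[1])
    return EfficiencyEstimate(gene=gene, species=species,
                              efficiency=float(10.0 ** (-1.0 / slope)),
                              slope=slope, r2=float(res.r2))


def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected relative expression ratio.

    ``dct = Ct(calibrator) - Ct(sample)`` for the target and reference
    assays.  With both efficiencies equal to 2 this reduces to the
    classical ``2^-ddCt``.
    """
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency {e} outside (1, 2]")
    return float(e_target**dct_target / e_ref**dct_ref)


def check_reference_invariance(ct_table: pd.DataFrame,
                               reference_gene: str = REFERENCE_GENE,
                               alpha: float = 0.05) -> float:
    """One-way F-test of reference-gene Ct across species x day cells.

    The Pfaffl normalization assumes the reference gene is invariant; a
    significant cell effect is reported as a warning, not an error.
    Returns the test p-value.
    """
    ref = ct_table[(ct_table["gene"] == reference_gene) & ~ct_table["is_control"]]
    groups = [g["ct"].to_numpy() for _, g in ref.groupby(["species", "dph"])]
    if len(groups) < 2:
        raise ValueError("reference gene needs >= 2 species x day cells")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.f_oneway(*groups).pvalue)
    if np.isnan(p):  # zero within- and between-cell variance: invariant
        p = 1.0
    if p < alpha:
        warnings.warn(f"reference gene {reference_gene} varies across cells "
                      f"(one-way p = {p:.3g}); ratios may be biased")
    return p


def pfaffl_table(
    ct_table: pd.DataFrame,
    efficiencies: dict,
    reference_gene: str = REFERENCE_GENE,
    calibrator: tuple = ("axolotl", 28),
) -> pd.DataFrame:
    """Per-pool relative expression ratios for every target gene.

    ``efficiencies`` maps ``(gene, species)`` to E.  The calibrator Ct is
    the mean Ct of the calibrator species x day cell for each assay; every
    well's ratio is normalized to the reference gene on the same pool.
    """
    tab = ct_table[~ct_table["is_control"]].copy()
    cal_sp, cal_day = calibrator
    cal = tab[(tab["species"] == cal_sp) & (tab["dph"] == cal_day)]
    if cal.empty:
        raise ValueError(f"calibrator cell {calibrator} missing from Ct table")
    cal_ct = cal.groupby("gene")["ct"].mean()

    ref_ct = tab[tab["gene"] == reference_gene].set_index(
        ["species", "dph", "replicate"])["ct"]
    rows = []
    for row in tab[tab["gene"] != reference_gene].itertuples(index=False):
        if row.gene not in cal_ct.index:
            raise ValueError(f"no calibrator Ct for gene {row.gene}")
        e_t = efficiencies[(row.gene, row.species)]
        e_r = efficiencies[(reference_gene, row.species)]
        dct_t = cal_ct[row.gene] - row.ct
        dct_r = cal_ct[reference_gene] - ref_ct[(row.species, row.dph, row.replicate)]
        ratio = pfaffl_ratio(e_t, dct_t, e_r, dct_r)
        rows.append({"gene": row.gene, "species": row.species, "dph": row.dph,
                     "replicate": row.replicate, "ratio": ratio,
                     "log2_ratio": float(np.log2(ratio))})
    return pd.DataFrame(rows)


def fit_qpcr_glm(log2_ratios, t, species, alpha: float = 0.05) -> dict:
    """Cubic species-profile GLM on log2 relative expression.

    Fits ``log2(R) ~ S + T + ST + T^2 + ST^2 + T^3 + ST^3`` on centred
    days, then applies hierarchical backward elimination at ``alpha``.
    Reports the surviving terms, whether the species' profiles remain
    statistically distinct (any species term retained — the separate
    trend-lines criterion), and per-species fitted coefficients.
    """
    y = np.asarray(log2_ratios, float)
    t = np.asarray(t, float)
    s = np.asarray(species, float)
    full = fit_species_model(y, t, s, degree=3)
    terms, coef, p = backward_select(y, t, s, alpha=alpha, degree=3)
    centre = full.centre

    def curve(dummy_val):
        out = dict.fromkeys(("c0", "c1", "c2", "c3"), 0.0)
        out["c0"] = coef.get("Intercept", 0.0) + dummy_val * coef.get("S", 0.0)
        for k, key in ((1, "c1"), (2, "c2"), (3, "c3")):
            tname = "T" if k == 1 else f"T{k}"
            sname = "ST" if k == 1 else f"ST{k}"
            out[key] = coef.get(tname, 0.0) + dummy_val * coef.get(sname, 0.0)
        return out

    species_terms = {n for n in terms if n.startswith("S")}
    return {
        "full": full,
        "reduced_terms": terms,
        "reduced_coef": coef,
        "reduced_p": p,
        "species_distinct": bool(species_terms),
        "centre": centre,
        "curve_reference": curve(0.0),
        "curve_other": curve(1.0),
    }
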