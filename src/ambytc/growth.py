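"""Larval growth model: species-specific quadratic of snout-vent length.

``SVL ~ b0 + S + T + ST + T^2 + ST^2`` with a species dummy on centred
days — the same six-term design as the expression comparison, fit to
morphometric records.  Reports coefficient significance for every term
and the model R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cross import SpeciesModelFit, fit_species_model


def fit_growth_model(svl_table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Fit the species-quadratic growth GLM to an SVL record table.

    ``svl_table`` needs ``species``, ``dph`` and ``svl`` columns with both
    species present over >= 3 days each.  Returns the full fit, the
    per-term significance verdicts at ``alpha``, and whether all terms are
    significant (the fully species-distinct growth pattern).
    """
    species = sorted(svl_table["species"].unique())
    if len(species) != 2:
        missing = "second species" if len(species) == 1 else "species labels"
        raise ValueError(f"exactly two species required; missing {missing}: {species}")
    for sp in species:
        if svl_table.loc[svl_table["species"] == sp, "dph"].nunique() < 3:
            raise ValueError(f"species {sp} sampled on < 3 days")
    dummy = (svl_table["species"] == species[1]).to_numpy(float)
    fit: SpeciesModelFit = fit_species_model(
        svl_table["svl"].to_numpy(float), svl_table["dph"].to_numpy(float),
        dummy, degree=2)
    significant = {term: bool(p <= alpha) for term, p in fit.p_terms.items()}
    return {
        "fit": fit,
        "r2": fit.r2,
        "significant": significant,
        "all_terms_significant": all(significant.values()),
        "species_levels": tuple(species),
    }
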