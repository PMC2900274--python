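"""GO biological-process over-representation by the EASE score.

The EASE score is a conservative variant of the one-sided Fisher exact
test: one observed list hit is removed before computing the hypergeometric
upper tail, which penalizes categories supported by a single gene.
Enrichment runs against a fixed annotated background (the chip's 3728
human-orthologous genes in the original design), with a minimum hit count
and an EASE threshold; terms with identical hit sets are collapsed to the
most specific (smallest-background) representative.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

DEFAULT_BACKGROUND_SIZE = 3728


def ease_score(list_hits: int, list_size: int, bg_hits: int, bg_size: int) -> float:
    """EASE score: hypergeometric upper tail with one list hit removed.

    ``P(X >= L - 1)`` for ``X ~ HG(N=bg_size, K=bg_hits, n=list_size)``;
    lists with ``L <= 1`` score 1 by construction.
    """
    L, n, B, N = int(list_hits), int(list_size), int(bg_hits), int(bg_size)
    if not (0 <= L <= min(n, B)) or n > N or B > N or min(n, B, N) < 0:
        raise ValueError(f"inconsistent contingency counts L={L}, n={n}, B={B}, N={N}")
    if L <= 1:
        return 1.0
    return float(hypergeom.sf(L - 2, N, B, n))


def fisher_upper_tail(list_hits: int, list_size: int, bg_hits: int, bg_size: int) -> float:
    """Ordinary one-sided Fisher exact upper tail, for comparison."""
    if list_hits == 0:
        return 1.0
    return float(hypergeom.sf(list_hits - 1, bg_size, bg_hits, list_size))


def enrich(
    deg_ids,
    annotation: pd.DataFrame,
    count_threshold: int = 2,
    ease_threshold: float = 0.05,
    bg_size: int | None = None,
) -> pd.DataFrame:
    """EASE over-representation of annotation terms in a DEG list.

    ``annotation`` maps genes to terms (columns ``gene_id``, ``term_id``,
    optional ``term_name``); the background is every annotated gene (or a
    stated ``bg_size``).  Terms need >= ``count_threshold`` list hits and
    EASE p <= ``ease_threshold``; identical-hit-set terms are collapsed
    keeping the smallest-background one.  Sorted by p.
    """
    cols = ["term_id", "term_name", "list_hits", "list_size", "bg_hits",
            "bg_size", "ease_p"]
    background = set(annotation["gene_id"])
    N = bg_size if bg_size is not None else len(background)
    deg = set(deg_ids) & background
    if not deg:
        return pd.DataFrame(columns=cols)
    n = len(deg)
    names = (annotation.drop_duplicates("term_id").set_index("term_id")["term_name"]
             if "term_name" in annotation.columns else None)
    rows = []
    for term, genes in annotation.groupby("term_id")["gene_id"]:
        members = set(genes)
        hits = deg & members
        L = len(hits)
        if L < count_threshold:
            continue
        p = ease_score(L, n, len(members), N)
        if p > ease_threshold:
            continue
        rows.append({"term_id": term,
                     "term_name": names[term] if names is not None else term,
                     "list_hits": L, "list_size": n, "bg_hits": len(members),
                     "bg_size": N, "ease_p": p,
                     "_hit_set": frozenset(hits)})
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    # collapse terms whose hit sets coincide; keep the most specific term
    out = (out.sort_values(["bg_hits", "term_id"])
              .drop_duplicates("_hit_set", keep="first")
              .drop(columns="_hit_set")
              .sort_values(["ease_p", "term_id"])
              .reset_index(drop=True))
    return out
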