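"""Cross-species probe compatibility filtering.

Heterologous hybridization confounds direct interspecies expression
comparison wherever the probe target sequence has diverged, so only
probe-sets whose every probe footprint shows zero predicted mismatches
between the two species' ortholog contigs are admitted to the direct
comparison.  Mismatches are projected from precomputed pairwise alignments
onto probe footprints; the conservative rule treats gap columns and
unaligned footprint positions as mismatches.  Probe-sets built from
identical probe multisets are additionally flagged as redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment anchored on the source contig.

    ``aligned_a`` / ``aligned_b`` are equal-length gapped sequences;
    ``a_start`` is the source-contig coordinate (0-based) of the first
    non-gap character of ``aligned_a``.
    """

    aligned_a: str
    aligned_b: str
    a_start: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        if self.a_start < 0:
            raise ValueError("a_start must be non-negative")

    def source_columns(self) -> np.ndarray:
        """Alignment column index of each source position covered."""
        chars = np.frombuffer(self.aligned_a.encode(), dtype="S1")
        return np.nonzero(chars != b"-")[0]


def project_probe_mismatches(alignment: PairwiseAlignment, probes: pd.DataFrame) -> pd.DataFrame:
    """Count predicted mismatches inside each probe footprint.

    ``probes`` is BED-like (``start``, ``end`` 0-based half-open on the
    source contig, plus ``probeset_id`` and ``probe_index``).  A probe's MM
    count is the number of alignment columns spanned by its footprint where
    the two sequences differ or either has a gap, plus one per footprint
    position falling outside the aligned span.  Probes entirely outside the
    alignment are flagged uncovered and get MM = footprint length.
    """
    a = np.frombuffer(alignment.aligned_a.upper().encode(), dtype="S1")
    b = np.frombuffer(alignment.aligned_b.upper().encode(), dtype="S1")
    bad = (a != b) | (a == b"-") | (b == b"-")
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    src_cols = alignment.source_columns()
    n_src = src_cols.size
    a_start = alignment.a_start
    a_end = a_start + n_src

    out = []
    for row in probes.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start < 0 or end <= start:
            raise ValueError(f"invalid footprint [{start}, {end})")
        length = end - start
        cov_lo = max(start, a_start)
        cov_hi = min(end, a_end)
        if cov_lo >= cov_hi:
            warnings.warn(
                f"probe {row.probeset_id}/{row.probe_index} outside alignment "
                "span; counted as fully mismatched"
            )
            mm, uncovered = length, True
        else:
            c_lo = src_cols[cov_lo - a_start]
            c_hi = src_cols[cov_hi - 1 - a_start]
            mm = int(bad_cum[c_hi + 1] - bad_cum[c_lo])
            mm += (cov_lo - start) + (end - cov_hi)  # unaligned overhang
            uncovered = cov_lo > start or cov_hi < end
            if uncovered:
                warnings.warn(
                    f"probe {row.probeset_id}/{row.probe_index} partially "
                    "outside alignment span; overhang counted as mismatched"
                )
        out.append(
            {
                "probeset_id": row.probeset_id,
                "probe_index": row.probe_index,
                "mm": mm,
                "uncovered": uncovered,
            }
        )
    return pd.DataFrame(out)


def probeset_compat(per_probe_mm: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-probe MM counts into per-probe-set verdicts.

    A probe-set passes iff no probe has > 0 MM (zero predicted sequence
    divergence across every footprint).
    """
    if (per_probe_mm["mm"] < 0).any():
        raise ValueError("negative mismatch counts")
    grouped = per_probe_mm.groupby("probeset_id", sort=False)["mm"]
    out = pd.DataFrame(
        {
            "n_probes_with_mm": grouped.apply(lambda s: int((s > 0).sum())),
            "sum_mm": grouped.sum(),
        }
    )
    out["pass"] = out["n_probes_with_mm"] == 0
    return out.reset_index()


def select_zero_mismatch(compat: pd.DataFrame) -> list:
    """Ids of probe-sets usable for direct interspecies comparison."""
    return compat.loc[compat["n_probes_with_mm"] == 0, "probeset_id"].tolist()


def find_redundant_probesets(probe_sequences: pd.DataFrame):
    """Group probe-sets whose probe-sequence multisets are identical.

    ``probe_sequences`` needs ``probeset_id`` and ``sequence`` columns.
    Returns ``(groups, redundant_ids)``: identity groups of size > 1
    (sorted id lists) and the flagged members (all but the
    lexicographically smallest id of each group).
    """
    if probe_sequences["sequence"].isna().any():
        raise ValueError("every probe needs a sequence")
    keys = (
        probe_sequences.groupby("probeset_id", sort=False)["sequence"]
        .apply(lambda s: tuple(sorted(s)))
    )
    by_key: dict[tuple, list] = {}
    for ps_id, key in keys.items():
        by_key.setdefault(key, []).append(ps_id)
    groups = [sorted(ids) for ids in by_key.values() if len(ids) > 1]
    groups.sort()
    redundant = [ps for grp in groups for ps in grp[1:]]
    return groups, redundant
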