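"""Synthetic study generator with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
probe-set level log2 expression trajectories planted in the nine temporal
profile classes (with optional species offsets and species x time
interactions), probe-level PM/MM intensities feeding the RMA stage, aligned
ortholog contig pairs with planted substitutions/gaps for the probe
compatibility filter, qPCR Ct plates with dilution series and gene x
species amplification efficiencies, and snout-vent-length growth records.

All generators are deterministic functions of an explicit seed and record a
truth table; planted profile classes are verified against the classifier's
own sign/vertex rule before being emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign
from .preprocess import ProbeLevelDataset
from .profiles import ProfileClass, classify_coefficients

_BASES = np.array(list("ACGT"))

#: Default mixture over profile classes: mostly flat (null) genes with the
#: eight change classes equally represented, giving ~16% planted DEGs.
DEFAULT_PROFILE_MIX = {ProfileClass.FLAT: 0.84, **{c: 0.02 for c in ProfileClass if c is not ProfileClass.FLAT}}


def _plant_coefficients(rng, cls: ProfileClass, effect: float, t_lo: float, t_hi: float):
    """Draw uncentred (b0, b1, b2) realizing a profile class.

    ``effect`` is the planted log2 amplitude: endpoint-to-endpoint change
    for linear classes, vertex-to-interval depth for transients.  Monotone
    quadratics carry curvature amplitude 0.75*effect with the vertex placed
    1.5-1.8 half-ranges outside the sampled interval, so curvature and
    direction are simultaneously identifiable.
    """
    c = 0.5 * (t_lo + t_hi)
    half = 0.5 * (t_hi - t_lo)
    span = t_hi - t_lo
    b0 = rng.uniform(6.0, 12.0)
    if cls is ProfileClass.FLAT:
        b1c, b2 = 0.0, 0.0
    elif cls in (ProfileClass.LU, ProfileClass.LD):
        b1c = effect / span * (1.0 if cls is ProfileClass.LU else -1.0)
        b2 = 0.0
    elif cls in (ProfileClass.QV, ProfileClass.QC):
        b2 = effect / half**2 * (1.0 if cls is ProfileClass.QV else -1.0)
        vertex = rng.uniform(-0.5, 0.5) * half
        b1c = -2.0 * b2 * vertex
    else:
        qmag = 0.75 * effect / half**2
        m = rng.uniform(1.5, 1.8)
        sign_b2 = 1.0 if cls in (ProfileClass.QLVU, ProfileClass.QLVD) else -1.0
        up = cls in (ProfileClass.QLVU, ProfileClass.QLCU)
        b2 = sign_b2 * qmag
        # increasing profiles need the vertex left of the interval for
        # convex shapes and right of it for concave shapes (and vice versa)
        vertex = (-m if (up == (b2 > 0)) else m) * half
        b1c = -2.0 * b2 * vertex
    # back-transform from the interval-centred parameterization
    b1 = b1c - 2.0 * b2 * c
    b0u = b0 - b1c * c + b2 * c**2
    got = classify_coefficients(b1, b2, t_lo, t_hi)
    if got is not cls:  # generator self-consistency guarantee
        raise AssertionError(f"planted {cls} classifies as {got}")
    return b0u, b1, b2


def make_sample_sheet(design: StudyDesign) -> pd.DataFrame:
    rows = [
        {
            "sample_id": design.sample_id(sp, day, rep),
            "species": sp,
            "dph": day,
            "replicate": rep,
        }
        for sp in design.species_labels
        for day in design.array_days
        for rep in range(1, design.replicates_per_cell + 1)
    ]
    return pd.DataFrame(rows)


def generate_expression_study(
    design: StudyDesign,
    effect_size: float = 1.5,
    noise_sd: float = 0.25,
    profile_mix: dict | None = None,
    offset_fraction: float = 0.0,
    offset_log2: float = 1.0,
    tiger_higher_fraction: float = 0.84,
    interaction_fraction: float = 0.0,
    seed: int | None = None,
):
    """Plant per-gene quadratic log2 trajectories and simulate the study.

    Returns ``(matrix, samples, truth)``: a probe-set x sample log2
    expression DataFrame, the sample sheet, and a per gene x species truth
    table (profile class, uncentred coefficients, signed species offset
    ``tiger - axolotl`` in log2 units, interaction flag).

    ``profile_mix`` gives the proportions of genes planted in each profile
    class; ``offset_fraction`` of genes additionally carry a species-
    constant log2 offset of ``offset_log2`` (tiger-higher with probability
    ``tiger_higher_fraction``); ``interaction_fraction`` of genes get an
    independently drawn profile in the second species.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mix = dict(DEFAULT_PROFILE_MIX if profile_mix is None else profile_mix)
    mix = {ProfileClass(k): float(v) for k, v in mix.items()}
    probs = np.array([mix.get(c, 0.0) for c in ProfileClass])
    if (probs < 0).any():
        raise ValueError("profile_mix entries must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("profile_mix proportions must sum to 1")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    days = np.array(design.array_days, float)
    t_lo, t_hi = days[0], days[-1]
    samples = make_sample_sheet(design)
    t_per_sample = samples["dph"].to_numpy(float)
    is_tiger = (samples["species"] == design.species_labels[1]).to_numpy()

    classes = list(ProfileClass)
    gene_ids = [f"PS{i:05d}" for i in range(design.n_probesets)]
    truth_rows = []
    Y = np.empty((design.n_probesets, len(samples)))
    for g, gid in enumerate(gene_ids):
        cls_a = classes[rng.choice(len(classes), p=probs)]
        interacting = rng.random() < interaction_fraction
        coefs = {design.species_labels[0]: (cls_a, _plant_coefficients(rng, cls_a, effect_size, t_lo, t_hi))}
        if interacting:
            cls_b = classes[rng.choice(len(classes), p=probs)]
            coefs[design.species_labels[1]] = (cls_b, _plant_coefficients(rng, cls_b, effect_size, t_lo, t_hi))
        else:
            coefs[design.species_labels[1]] = coefs[design.species_labels[0]]
        if rng.random() < offset_fraction:
            offset = offset_log2 if rng.random() < tiger_higher_fraction else -offset_log2
        else:
            offset = 0.0
        for sp in design.species_labels:
            cls, (b0, b1, b2) = coefs[sp]
            truth_rows.append(
                {
                    "probeset_id": gid,
                    "species": sp,
                    "profile": cls.value,
                    "b0": b0,
                    "b1": b1,
                    "b2": b2,
                    "species_offset": offset,
                    "interaction": interacting,
                }
            )
        _, (b0a, b1a, b2a) = coefs[design.species_labels[0]]
        _, (b0t, b1t, b2t) = coefs[design.species_labels[1]]
        mean_a = b0a + b1a * t_per_sample + b2a * t_per_sample**2
        mean_t = b0t + b1t * t_per_sample + b2t * t_per_sample**2 + offset
        Y[g] = np.where(is_tiger, mean_t, mean_a)
    if noise_sd > 0:
        Y += rng.normal(0.0, noise_sd, size=Y.shape)
    matrix = pd.DataFrame(Y, index=pd.Index(gene_ids, name="probeset_id"),
                          columns=samples["sample_id"])
    truth = pd.DataFrame(truth_rows)
    return matrix, samples, truth


def generate_probe_level(
    design: StudyDesign,
    target_matrix: pd.DataFrame,
    affinity_sd: float = 0.5,
    background_mean: float = 50.0,
    background_sd: float = 10.0,
    mm_specificity: float = 0.3,
    seed: int | None = None,
) -> ProbeLevelDataset:
    """Expand a target log2 expression matrix into PM/MM probe intensities.

    ``PM = 2**(target + affinity) + background`` with per-probe affinities
    drawn N(0, affinity_sd) and additive optical background
    N(background_mean, background_sd); ``MM`` carries ``mm_specificity``
    of the specific signal plus its own background draw, so probe-sets at
    background level have symmetric PM/MM discrimination scores.
    """
    if target_matrix.shape[0] != design.n_probesets:
        raise ValueError("target matrix row count does not match design")
    vals = target_matrix.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("target matrix must be finite")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo, hi = design.probes_per_set
    n_probes = rng.integers(lo, hi + 1, size=design.n_probesets)
    samples = make_sample_sheet(design)
    arrays = list(target_matrix.columns)

    index_tuples, pm_rows, mm_rows = [], [], []
    for g, gid in enumerate(target_matrix.index):
        affinities = rng.normal(0.0, affinity_sd, size=n_probes[g]) if affinity_sd > 0 else np.zeros(n_probes[g])
        specific = 2.0 ** (vals[g][None, :] + affinities[:, None])
        bg_pm = background_mean + (rng.normal(0.0, background_sd, size=specific.shape) if background_sd > 0 else 0.0)
        bg_mm = background_mean + (rng.normal(0.0, background_sd, size=specific.shape) if background_sd > 0 else 0.0)
        pm = np.clip(specific + bg_pm, 1e-6, None)
        mm = np.clip(mm_specificity * specific + bg_mm, 1e-6, None)
        for j in range(n_probes[g]):
            index_tuples.append((gid, j))
        pm_rows.append(pm)
        mm_rows.append(mm)
    index = pd.MultiIndex.from_tuples(index_tuples, names=["probeset_id", "probe_index"])
    pm_df = pd.DataFrame(np.vstack(pm_rows), index=index, columns=arrays)
    mm_df = pd.DataFrame(np.vstack(mm_rows), index=index, columns=arrays)
    return ProbeLevelDataset(pm=pm_df, mm=mm_df, samples=samples)


def random_mismatch_plan(
    design: StudyDesign,
    fraction_with_mm: float = 0.4,
    max_substitutions: int = 3,
    seed: int | None = None,
) -> dict:
    """Plan planting substitutions in a random subset of probe-sets.

    Positions are expressed on the source contig laid out by
    :func:`generate_ortholog_pairs` (probes tiled in order with 0-7 nt
    spacers); positions may fall inside footprints, in spacers, or past the
    last probe — all are legal plantings.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    plan = {}
    for g in range(design.n_probesets):
        gid = f"PS{g:05d}"
        if rng.random() < fraction_with_mm:
            n_sub = int(rng.integers(1, max_substitutions + 1))
            # contig length is not known yet; positions are drawn as
            # fractions and resolved by the generator
            plan[gid] = list(rng.random(n_sub))
        else:
            plan[gid] = []
    return plan


def generate_ortholog_pairs(
    design: StudyDesign,
    mismatch_plan: dict | None = None,
    deletion_plan: dict | None = None,
    insertion_plan: dict | None = None,
    coverage: dict | None = None,
    seed: int | None = None,
):
    """Build aligned ortholog contig pairs with planted divergence.

    For each probe-set the probes are tiled along a source contig
    (25-mers with random 0-7 nt spacers); the partner sequence starts as a
    copy and receives planted substitutions (``mismatch_plan``: contig
    positions, or fractions of contig length in [0,1)), single-base
    deletions (gap in the partner), insertions (gap column in the source),
    and optional restriction of the alignment to a sub-span of the contig
    (``coverage``: probeset_id -> (start, end)), leaving probes outside it
    uncovered.

    Returns ``(alignments, probes, truth)``: a DataFrame of aligned
    sequence pairs (``probeset_id, aligned_a, aligned_b, a_start``), a
    BED-like probe coordinate table (0-based half-open), and a per-probe
    truth table of projected mismatch counts under the conservative rule
    (diverged or gapped alignment columns inside the footprint count 1
    each; uncovered footprint positions count 1 each).  The truth scan is a
    direct per-column walk, independent of the projection module.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    mismatch_plan = mismatch_plan or {}
    deletion_plan = deletion_plan or {}
    insertion_plan = insertion_plan or {}
    coverage = coverage or {}
    lo, hi = design.probes_per_set
    L = design.probe_length

    aln_rows, probe_rows, truth_rows = [], [], []
    for g in range(design.n_probesets):
        gid = f"PS{g:05d}"
        k = int(rng.integers(lo, hi + 1))
        starts, pos = [], 0
        for _ in range(k):
            pos += int(rng.integers(0, 8))
            starts.append(pos)
            pos += L
        contig_len = pos + int(rng.integers(0, 8))
        seq_a = rng.choice(_BASES, size=contig_len)

        subs = []
        for p in mismatch_plan.get(gid, []):
            p = int(p * contig_len) if isinstance(p, float) and 0 <= p < 1 else int(p)
            if not 0 <= p < contig_len:
                raise ValueError(f"substitution position {p} outside contig {gid}")
            subs.append(p)
        dels = [int(p) for p in deletion_plan.get(gid, [])]
        ins = [int(p) for p in insertion_plan.get(gid, [])]
        if any(not 0 <= p < contig_len for p in dels + ins):
            raise ValueError(f"gap position outside contig {gid}")

        seq_b = seq_a.copy()
        for p in set(subs):
            choices = _BASES[_BASES != seq_a[p]]
            seq_b[p] = rng.choice(choices)

        a_start, a_end = coverage.get(gid, (0, contig_len))
        if a_start < 0 or a_end > contig_len or a_start >= a_end:
            raise ValueError(f"invalid coverage span for {gid}")
        for s in starts:
            if s + L > contig_len:
                raise ValueError(f"probe footprint past contig end in {gid}")

        # build alignment columns over the covered span
        cols_a, cols_b, col_src = [], [], []
        del_set, ins_set = set(dels), set(ins)
        for p in range(a_start, a_end):
            if p in ins_set:  # insertion in partner before this base
                cols_a.append("-")
                cols_b.append(rng.choice(_BASES))
                col_src.append(None)
            cols_a.append(seq_a[p])
            cols_b.append("-" if p in del_set else seq_b[p])
            col_src.append(p)
        aligned_a = "".join(cols_a)
        aligned_b = "".join(cols_b)
        aln_rows.append({"probeset_id": gid, "aligned_a": aligned_a,
                         "aligned_b": aligned_b, "a_start": a_start})

        # independent truth: walk columns, mark diverged/gapped source
        # positions, count insertion columns between footprint positions
        src_to_col = {p: i for i, p in enumerate(col_src) if p is not None}
        bad_col = [ca != cb or ca == "-" or cb == "-" for ca, cb in zip(cols_a, cols_b)]
        for j, s in enumerate(starts):
            mm = 0
            footprint = range(s, s + L)
            covered = [p for p in footprint if p in src_to_col]
            if not covered:
                mm = L
            else:
                c_lo = src_to_col[covered[0]]
                c_hi = src_to_col[covered[-1]]
                mm += sum(1 for p in footprint if p not in src_to_col)  # uncovered
                mm += sum(1 for c in range(c_lo, c_hi + 1) if bad_col[c])
            probe_rows.append({"contig": gid, "start": s, "end": s + L,
                               "probeset_id": gid, "probe_index": j})
            truth_rows.append({"probeset_id": gid, "probe_index": j, "mm": mm})
    alignments = pd.DataFrame(aln_rows)
    probes = pd.DataFrame(probe_rows)
    truth = pd.DataFrame(truth_rows)
    return alignments, probes, truth


REFERENCE_GENE = "tif1"


def generate_qpcr_plates(
    design: StudyDesign,
    efficiencies: dict | None = None,
    planted_log2_profiles: dict | None = None,
    genes: tuple = ("nr3c2", "nr3c1", "pomc", "crhr1"),
    noise_sd: float = 0.15,
    dilution_points: int = 5,
    seed: int | None = None,
):
    """Simulate qPCR Ct plates plus per gene x species dilution series.

    ``Ct = intercept - log2(template * 2**expr) / log2(E) + noise`` with a
    gene-specific assay intercept shared across species;
    ``planted_log2_profiles`` maps ``(gene, species)`` to cubic
    coefficients ``(c0, c1, c2, c3)`` of log2 expression on centred days.
    A reference gene with flat, species-equal expression is always
    included.  Plates are blocked by day with both species present; two
    template-free control wells per plate carry no Ct.

    Returns ``(ct_table, dilution_table, truth)``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    all_genes = list(genes)
    if REFERENCE_GENE not in all_genes:
        all_genes.append(REFERENCE_GENE)
    days = np.array(design.qpcr_days, float)
    centre = days.mean()

    eff = dict(efficiencies or {})
    profiles = dict(planted_log2_profiles or {})
    for gene in all_genes:
        shared = None
        for sp in design.species_labels:
            key = (gene, sp)
            if key not in eff:
                eff[key] = float(rng.uniform(1.7, 2.0))
            if not 1.0 < eff[key] <= 2.0:
                raise ValueError(f"efficiency for {key} must be in (1, 2]")
            if gene == REFERENCE_GENE:
                if shared is None:
                    shared = (float(rng.uniform(2.0, 4.0)), 0.0, 0.0, 0.0)
                profiles[key] = shared  # flat and species-equal by construction
            elif key not in profiles:
                profiles[key] = (
                    float(rng.uniform(0.0, 3.0)),
                    float(rng.uniform(-0.05, 0.05)),
                    float(rng.uniform(-2e-3, 2e-3)),
                    float(rng.uniform(-4e-5, 4e-5)),
                )
    intercepts = {gene: float(rng.uniform(22.0, 28.0)) for gene in all_genes}

    def expr(gene, sp, day):
        c0, c1, c2, c3 = profiles[(gene, sp)]
        x = day - centre
        return c0 + c1 * x + c2 * x**2 + c3 * x**3

    ct_rows = []
    for day in design.qpcr_days:
        plate = f"plate_{int(day):02d}"
        for gene in all_genes:
            for sp in design.species_labels:
                e = eff[(gene, sp)]
                for rep in range(1, design.replicates_per_cell + 1):
                    ct = intercepts[gene] - expr(gene, sp, day) / np.log2(e)
                    if noise_sd > 0:
                        ct += rng.normal(0.0, noise_sd)
                    ct_rows.append({"gene": gene, "species": sp, "dph": int(day),
                                    "replicate": rep, "plate": plate,
                                    "ct": float(ct), "is_control": False})
        for ctrl in range(2):  # template-free controls, no amplification
            ct_rows.append({"gene": "NTC", "species": "none", "dph": int(day),
                            "replicate": ctrl + 1, "plate": plate,
                            "ct": np.nan, "is_control": True})

    dil_rows = []
    amounts = 10.0 ** -np.arange(dilution_points)
    for gene in all_genes:
        for sp in design.species_labels:
            e = eff[(gene, sp)]
            base = expr(gene, sp, design.qpcr_days[0])
            for amt in amounts:
                ct = intercepts[gene] - (np.log2(amt) + base) / np.log2(e)
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                dil_rows.append({"gene": gene, "species": sp,
                                 "amount": float(amt), "ct": float(ct)})

    truth = {
        "efficiencies": eff,
        "profiles": profiles,
        "intercepts": intercepts,
        "centre_day": float(centre),
        "reference_gene": REFERENCE_GENE,
    }
    return pd.DataFrame(ct_rows), pd.DataFrame(dil_rows), truth


def generate_growth_data(
    design: StudyDesign,
    planted: dict | None = None,
    noise_sd: float = 2.0,
    n_per_cell: int = 30,
    seed: int | None = None,
):
    """Simulate snout-vent-length (mm) records under species quadratics.

    ``planted`` maps species to uncentred ``(b0, b1, b2)`` day
    polynomials; the default has tiger larvae larger with decelerating
    growth and axolotls growing linearly, echoing the biology the growth
    model is meant to detect.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ax, tg = design.species_labels
    planted = planted or {ax: (10.0, 0.32, 0.0016), tg: (12.0, 0.85, -0.0045)}
    rows = []
    for sp in design.species_labels:
        b0, b1, b2 = planted[sp]
        for day in design.qpcr_days:
            mean = b0 + b1 * day + b2 * day**2
            svl = mean + (rng.normal(0.0, noise_sd, size=n_per_cell) if noise_sd > 0 else np.zeros(n_per_cell))
            for i, v in enumerate(svl):
                rows.append({"species": sp, "dph": int(day),
                             "individual": i + 1, "svl": float(v)})
    return pd.DataFrame(rows), {"coefficients": planted, "noise_sd": noise_sd}
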