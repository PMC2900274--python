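# ambytc

Comparative time-course transcriptomics of paedomorphic and metamorphic
salamander brain development.

The Mexican axolotl (*Ambystoma mexicanum*) never undergoes anatomical
metamorphosis: it keeps its larval body plan into adulthood
(paedomorphosis), while its close relative the eastern tiger salamander
(*A. tigrinum tigrinum*) transforms into a terrestrial adult.  Comparing
brain gene expression between larvae of the two species over matched days
post hatching (dph) asks when and how their developmental programs
diverge.  `ambytc` implements the full analysis chain for such a
two-species expression time course — from raw oligonucleotide-array probe
intensities to differentially expressed gene (DEG) lists, temporal profile
classes, GO enrichment and qPCR validation — together with a synthetic
data generator that plants known truth, so every stage is testable without
any array download.  It is aimed at computational biologists who want a
tested, reusable reference implementation of this classic analysis design.

## What it computes

**Preprocessing (RMA).**  Probe-set × sample log2 expression matrices via
the robust multi-array average stages: normal+exponential background
correction (method-of-moments normexp, `E[S | S+B = x]` with
`S ~ Exp(1/θ)`, `B ~ N(μ, σ²)`), quantile normalization across arrays, and
Tukey median-polish summarization per probe-set.  Present/marginal/absent
detection calls use the one-sided Wilcoxon signed-rank test on
discrimination scores `d_j = (PM_j − MM_j)/(PM_j + MM_j)` against
τ = 0.015; probe-sets absent on > 75 % of arrays are filtered, and
replicate quality is summarized by mean pairwise Pearson *r* per
species × day cell.

**Within-species temporal screen.**  Per gene and species, the quadratic
regression

> y<sub>ij</sub> = β₀ + β₁ T<sub>i</sub> + β₂ T²<sub>i</sub> + ε<sub>ij</sub>

on centred days, with the overall F p-value screened by Benjamini–
Hochberg FDR at q = 0.05 (the α₀ tier).  Screened genes are classified
into nine temporal profiles — flat, LU/LD (linear up/down),
QLVU/QLCU/QLVD/QLCD (monotone quadratics by direction and curvature), and
QV/QC (transient valley/peak, vertex strictly inside the sampled
interval) — using coefficient t-tests at α₁ = 0.05 and the vertex rule,
and retained only if they change ≥ 1.5-fold versus the 42 dph baseline at
some later day.  DEG lists from the two species are partitioned into
shared/unique sets with profile and direction concordance.

**Cross-species direct comparison.**  Probe-sets first pass a sequence
compatibility filter: mismatches between the two species' ortholog contigs
are projected from pairwise alignments onto each 25-mer probe footprint,
and only probe-sets with zero mismatches across all probes are compared
directly (gap columns and unaligned footprint positions count as
mismatches; identical probe-sets are flagged redundant).  Each passing
gene is then fit with the species-dummy model

> y<sub>tij</sub> = β₀ + S<sub>t</sub> + T<sub>i</sub> + (ST)<sub>ti</sub> + T²<sub>i</sub> + (ST²)<sub>ti</sub> + ε<sub>tij</sub>

reduced by hierarchical backward selection (α = 0.05), and retained when
(1) the overall p survives BH FDR, (2) a species-dependent term (S, ST or
ST²) survives selection, (3) full-model R² ≥ 0.50 and (4) the species
differ ≥ 1.5-fold at some day.  The heatmap computation (row
centre/scale, |1 − r| Pearson distance, average-linkage clustering with a
Newick export) accompanies the screen.

**Downstream.**  qPCR relative expression by the Pfaffl ratio
`R = E_target^ΔCt_target / E_ref^ΔCt_ref` with amplification efficiencies
from dilution-series regression (`E = 10^(−1/slope)`), modelled by a cubic
species-dummy GLM with backward selection; GO biological-process
enrichment by the EASE score (one-sided Fisher exact tail with one list
hit removed; count threshold 2, EASE threshold 0.05, fixed annotated
background); and the snout-vent-length growth model, the same quadratic
species-dummy design fit to morphometric records.

## Worked example

```python
import warnings
import ambytc as at
from ambytc import ProfileClass, StudyDesign

design = StudyDesign(n_probesets=500, seed=42)
mix = {ProfileClass.FLAT: 0.8,
       **{c: 0.2 / 8 for c in ProfileClass if c is not ProfileClass.FLAT}}
matrix, samples, truth = at.generate_expression_study(
    design, effect_size=1.5, noise_sd=0.25, profile_mix=mix, seed=42)

degs = {}
for species in design.species_labels:
    sub = samples[samples["species"] == species]
    degs[species] = at.identify_degs(matrix[sub["sample_id"]], sub)
    print(f"{species}: {len(degs[species])} DEGs")

venn = at.partition_venn(degs["axolotl"], degs["tiger"])
print(f"shared: {venn['n_shared']}, unique axolotl: {venn['n_unique_a']}, "
      f"unique tiger: {venn['n_unique_b']}")
print(f"profile concordance: {venn['profile_concordance']:.0%}, "
      f"direction concordance: {venn['direction_concordance']:.0%}")
```

prints

```
axolotl: 107 DEGs
tiger: 108 DEGs
shared: 107, unique axolotl: 0, unique tiger: 1
profile concordance: 95%, direction concordance: 98%
```

Of the 500 simulated genes, 20 % were planted with a non-flat temporal
profile (log2 amplitude 1.5, noise SD 0.25) identically in both species;
each species' screen recovers essentially all of them, the two DEG lists
coincide up to FDR-level noise, and the shared genes carry the same
profile class in 95 % of cases and the same generalized direction
(up / down / transient) in 98 % — the concordance summaries the package
computes for any pair of DEG lists.

A command-line surface mirrors the library: `ambytc synth`, `ambytc rma`,
`ambytc degscan within|direct`, `ambytc probecompat`, `ambytc qpcr`,
`ambytc enrich`, `ambytc growth` — each reading and writing plain TSV /
FASTA.  Run any subcommand with `--help` for options.

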