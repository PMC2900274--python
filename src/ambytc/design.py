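"""Study design description for the two-species larval time course."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the comparative larval brain study.

    Two species — a paedomorphic axolotl line and a metamorphic tiger
    salamander line — are sampled as replicate whole-brain RNA pools at
    fixed days post hatching (dph).  Arrays cover four days, qPCR extends
    the series to six.
    """

    species_labels: tuple[str, str] = ("axolotl", "tiger")
    array_days: tuple[int, ...] = (42, 56, 70, 84)
    qpcr_days: tuple[int, ...] = (28, 42, 56, 70, 84, 98)
    replicates_per_cell: int = 3
    n_probesets: int = 500
    probes_per_set: tuple[int, int] = (11, 20)
    probe_length: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_labels) != 2:
            raise ValueError("exactly two species labels are required")
        for days in (self.array_days, self.qpcr_days):
            if list(days) != sorted(set(days)):
                raise ValueError(f"days must be strictly increasing: {days}")
        if len(self.array_days) < 3:
            raise ValueError("need >= 3 timepoints (quadratic unidentifiable)")
        if not set(self.array_days) <= set(self.qpcr_days):
            raise ValueError("array_days must be a subset of qpcr_days")
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        if self.n_probesets < 1:
            raise ValueError("n_probesets must be positive")
        lo, hi = self.probes_per_set
        if not (1 <= lo <= hi):
            raise ValueError("invalid probes_per_set range")

    @property
    def n_arrays(self) -> int:
        return 2 * len(self.array_days) * self.replicates_per_cell

    def sample_id(self, species: str, day: int, rep: int) -> str:
        prefix = "AM" if species == self.species_labels[0] else "AT"
        return f"{prefix}_{day:02d}_{rep}"
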