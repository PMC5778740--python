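"""Core containers for the methylation DMR pipeline.

Coordinates are 1-based inclusive throughout (Illumina manifest convention);
BED export converts to 0-based half-open in :mod:`methdmr.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "Sea")
GENE_FEATURES = ("TSS1500", "TSS200", "Body", "Intergenic")

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "island_relation",
    "gene_feature",
    "nearest_gene",
    "dnase_hs",
]


@dataclass(frozen=True)
class ProbeAnnotation:
    """One CpG probe's genomic coordinates and regulatory annotations."""

    probe_id: str
    chrom: str
    pos: int  # 1-based bp
    island_relation: str
    gene_feature: str
    nearest_gene: Optional[str]
    dnase_hs: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.island_relation not in ISLAND_RELATIONS:
            raise ValueError(f"unknown island_relation {self.island_relation!r}")
        if self.gene_feature not in GENE_FEATURES:
            raise ValueError(f"unknown gene_feature {self.gene_feature!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One sample's phenotype and technical covariates.

    Either ``status`` or the three ID-Migraine item responses must be present;
    the classifier in :mod:`methdmr.simulate` derives status from the items.
    """

    sample_id: str
    status: Optional[Literal["case", "control"]]
    id_migraine_items: Optional[tuple[bool, bool, bool]]  # photophobia, nausea, disability
    cohort: Literal["adult", "adolescent"]
    age: float
    sex: Literal["F", "M"]
    chip: str
    chip_position: str

    def __post_init__(self) -> None:
        if self.status is None and self.id_migraine_items is None:
            raise ValueError("one of status / id_migraine_items required")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class MethylationDataset:
    """Beta matrix + detection P + sample sheet: the pipeline's central container.

    ``beta`` and ``detection_p`` are probes x samples DataFrames indexed by
    probe_id with sample_id columns. Missing measurements are NaN in ``beta``.
    """

    manifest: pd.DataFrame  # MANIFEST_COLUMNS, sorted by (chrom, pos)
    samples: pd.DataFrame  # sample sheet, one row per sample
    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.manifest["probe_id"].is_unique:
            raise ValueError("duplicate probe_id in manifest")
        if list(self.beta.index) != list(self.manifest["probe_id"]):
            raise ValueError("beta rows must match manifest probe order")
        if list(self.beta.columns) != list(self.samples["sample_id"]):
            raise ValueError("beta columns must match sample sheet order")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("non-missing beta values must lie in [0, 1]")
        if self.detection_p is not None and self.detection_p.shape != self.beta.shape:
            raise ValueError("detection_p shape must match beta")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, keep: np.ndarray) -> "MethylationDataset":
        """Return a dataset restricted to a boolean probe mask (order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        return MethylationDataset(
            manifest=self.manifest.loc[keep].reset_index(drop=True),
            samples=self.samples,
            beta=self.beta.loc[keep],
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep],
        )


@dataclass(frozen=True)
class SpikeSpec:
    """A ground-truth differential region spiked into simulated data."""

    chrom: str
    start: int
    end: int
    delta_beta: float
    n_probes_min: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if abs(self.delta_beta) > 0.25:
            raise ValueError("|delta_beta| must be <= 0.25")


@dataclass
class CellTypeConfig:
    """Statistical structure of the leukocyte mixture folded into beta values.

    ``dirichlet_concentration`` sets the between-sample variability of cell
    proportions; ``case_control_shift`` is added to case samples' proportions
    (then renormalised) to inject composition confounding. Defaults model the
    six major whole-blood leukocyte subtypes (granulocytes dominant at ~53%,
    then CD4 T, CD8 T, B, monocytes, NK); simulating fewer mixture components
    than the corrector's K leaves spare rank that can absorb true signal.
    """

    n_cell_types: int = 6
    dirichlet_concentration: Sequence[float] = (9.0, 3.0, 2.0, 1.5, 1.0, 0.5)
    informative_fraction: float = 0.30
    profile_sd: float = 0.15
    case_control_shift: Sequence[float] = (0.0,) * 6

    def __post_init__(self) -> None:
        if len(self.dirichlet_concentration) != self.n_cell_types:
            raise ValueError("dirichlet_concentration length must equal n_cell_types")
        if len(self.case_control_shift) != self.n_cell_types:
            raise ValueError("case_control_shift length must equal n_cell_types")


@dataclass
class QCReport:
    """Probe-filter accounting; a probe failing both rules is counted once."""

    n_probes_in: int
    n_removed_missing: int
    n_removed_detection: int
    n_removed_total: int
    n_probes_out: int
    max_missing: int
    max_detection_fail: int
    detection_alpha: float

    def __post_init__(self) -> None:
        if self.n_probes_out != self.n_probes_in - self.n_removed_total:
            raise ValueError("QC counts do not reconcile")


@dataclass
class DMRegion:
    """A merged, direction-classified differentially methylated region."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str] = field(default_factory=list)
    p: float = np.nan
    fdr_q: float = np.nan
    direction: str = "ambiguous"  # hypomethylated / hypermethylated / ambiguous
    source_window_count: int = 0
    nearest_genes: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)
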