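"""Domain types shared by every pipeline stage.

The atomic quantification unit is the peptide-spectrum match (PSM): one
fragmentation spectrum assigned to a peptide sequence, carrying the MS1
precursor intensity and the ten TMT reporter-ion intensities of its plex.
A plex design maps reporter channels to samples and designates exactly one
pooled reference (bridge) channel per plex; ratios to that channel are what
make plexes comparable.

Missing reporter intensities are represented as ``None``/NaN, never zero:
the downstream normalization log2-transforms intensities, so a measured
zero and a dropout must stay distinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PsmRecord",
    "PlexChannel",
    "PlexDesign",
    "QuantMatrix",
    "ClinicalAnnotation",
    "DesignError",
    "SchemaError",
]


class DesignError(ValueError):
    """Raised when a plex design violates its structural invariants."""


class SchemaError(ValueError):
    """Raised when a table is missing a required column or malformed."""


@dataclass
class PsmRecord:
    """One peptide-spectrum match with reporter intensities and QC metadata.

    ``reporter`` holds one entry per channel of the plex (``None`` = missing,
    not measured-zero). ``assignment`` is ``unique`` or ``razor``; both are
    used for quantification. ``purity`` is the precursor-ion purity in [0, 1].
    """

    plex_id: str
    run_id: str
    spectrum_id: str
    peptide: str
    charge: int
    entry_id: str
    assignment: str = "unique"
    is_contaminant: bool = False
    has_tmt_label: bool = True
    ms1_intensity: float = 0.0
    reporter: list[float | None] = field(default_factory=list)
    purity: float = 1.0
    psm_probability: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if self.ms1_intensity < 0:
            raise ValueError("ms1_intensity must be nonnegative")

    def summed_reporter(self) -> float:
        """Summed reporter-ion intensity across all channels (missing -> 0)."""
        return float(sum(v for v in self.reporter if v is not None and not math.isnan(v)))

    def peptide_ion(self) -> tuple[str, str, str, int]:
        """The redundancy key: same MS run, peptide sequence (incl. mods), charge."""
        return (self.plex_id, self.run_id, self.peptide, self.charge)


@dataclass(frozen=True)
class PlexChannel:
    channel_label: str
    sample_id: str
    role: str  # individual | bridge_pool | validation_pool | reference
    phenotype: str = "n/a"  # CTL | PDR | n/a


@dataclass
class PlexDesign:
    """Channel -> sample map for one TMT plex with one designated reference."""

    plex_id: str
    channels: list[PlexChannel]

    def __post_init__(self) -> None:
        refs = [c for c in self.channels if c.role == "reference"]
        if len(refs) != 1:
            raise DesignError(
                f"plex {self.plex_id}: exactly one reference channel required, "
                f"found {len(refs)}"
            )
        ids = [c.sample_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise DesignError(f"plex {self.plex_id}: duplicate sample_id within plex")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def reference_channel(self) -> PlexChannel:
        return next(c for c in self.channels if c.role == "reference")

    @property
    def reference_index(self) -> int:
        return next(i for i, c in enumerate(self.channels) if c.role == "reference")

    def sample_channels(self) -> list[PlexChannel]:
        """All non-reference channels, in channel order."""
        return [c for c in self.channels if c.role != "reference"]

    def global_sample_id(self, channel: PlexChannel) -> str:
        """Globally unique column identifier 'plexID.channelLabel->sampleID'."""
        return f"{self.plex_id}.{channel.channel_label}->{channel.sample_id}"


@dataclass
class QuantMatrix:
    """Entries x samples matrix of log2 quantities with missingness (NaN).

    ``kind`` distinguishes the pipeline stage the values came from:
    raw reference ratios, MAD-normalized ratios, absolute log2 abundances,
    or per-sample Z scores.
    """

    values: pd.DataFrame  # index = entry_ids, columns = sample_ids
    level: str = "gene"  # gene | protein | peptide
    kind: str = "ratio"  # ratio | normalized_ratio | abundance | zscore

    def __post_init__(self) -> None:
        if self.kind == "abundance":
            arr = self.values.to_numpy(dtype=float)
            if np.isneginf(arr).any():
                raise ValueError("abundance matrix must not contain -inf")

    @property
    def entry_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), level=self.level, kind=self.kind)


@dataclass
class ClinicalAnnotation:
    """Per-sample clinical measurements (hemoglobin in g/dL)."""

    sample_id: str
    phenotype: str  # CTL | PDR
    hemoglobin: float = float("nan")
    bilirubin: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isnan(self.hemoglobin) and self.hemoglobin < 0:
            raise ValueError("hemoglobin must be nonnegative")


def clinical_frame(annotations: Sequence[ClinicalAnnotation]) -> pd.DataFrame:
    """Tabular view of a clinical annotation set."""
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "phenotype": [a.phenotype for a in annotations],
            "hemoglobin": [a.hemoglobin for a in annotations],
            "bilirubin": [a.bilirubin for a in annotations],
        }
    )
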