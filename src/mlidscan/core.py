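"""Core data model for methylation-array MLID analysis.

The central containers are:

* :class:`ProbeRecord` — one array probe (CpG) with its locus, Infinium
  design type and QC flags.
* :class:`BetaMatrix` — probes × samples methylation fractions (β values in
  [0, 1]) with sample roles (control / patient) and an optional aligned
  detection p-value matrix.
* :class:`IdmrRegion` — a named imprinted differentially methylated region
  (iDMR): a closed genomic interval with the methylated parental allele.

Coordinates are 1-based, fully closed intervals on genome build hg19 by
default; the build is carried as a tag and never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd

DEFAULT_GENOME_BUILD = "hg19"

#: Region names treated as polymorphically imprinted in the general
#: population and therefore excluded from MLID verdicts by default.
POLYMORPHIC_REGIONS = ("VTRNA2-1",)


class DesignType(str, Enum):
    """Infinium probe chemistry: type I (two beads) or type II (one bead)."""

    I = "I"
    II = "II"


class CgiContext(str, Enum):
    island = "island"
    shore = "shore"
    shelf = "shelf"
    open_sea = "open_sea"


class GenicContext(str, Enum):
    promoter = "promoter"
    body = "body"
    utr3 = "3utr"
    intergenic = "intergenic"


class SampleRole(str, Enum):
    control = "control"
    patient = "patient"


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to ``chr``-prefixed strings."""
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True)
class ProbeRecord:
    """A single array probe and its annotation."""

    probe_id: str
    chrom: str
    pos: int  # 1-based bp
    design_type: DesignType = DesignType.II
    snp_flag: bool = False
    cross_reactive_flag: bool = False
    cgi_context: CgiContext = CgiContext.open_sea
    genic_context: GenicContext = GenicContext.intergenic

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "design_type", DesignType(self.design_type))
        object.__setattr__(self, "cgi_context", CgiContext(self.cgi_context))
        object.__setattr__(self, "genic_context", GenicContext(self.genic_context))


@dataclass(frozen=True)
class IdmrRegion:
    """A named imprinted DMR interval (1-based, closed)."""

    name: str
    chrom: str
    start: int
    end: int
    methylated_allele: str  # "maternal" | "paternal"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.methylated_allele not in ("maternal", "paternal"):
            raise ValueError(
                f"region {self.name}: methylated_allele must be maternal/paternal,"
                f" got {self.methylated_allele!r}"
            )

    @property
    def width(self) -> int:
        """Interval width in bp (closed interval: end − start + 1)."""
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.start <= pos <= self.end


class BetaMatrix:
    """Probes × samples methylation fractions with sample roles.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids, entries are
        β in [0, 1] (NaN allowed as explicit missing).
    sample_roles
        Mapping sample id → "control" or "patient"; must cover all columns.
    detection_p
        Optional detection p-value matrix aligned to ``values``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_roles: Mapping[str, str],
        detection_p: Optional[pd.DataFrame] = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        finite = values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.nansum((finite < 0) | (finite > 1))
        if bad:
            raise ValueError(f"{int(bad)} beta values outside [0, 1]")
        missing_roles = [s for s in values.columns if s not in sample_roles]
        if missing_roles:
            raise ValueError(f"samples without a role: {missing_roles}")
        values.index = values.index.rename("probe_id")
        self.values = values
        self.sample_roles = {s: SampleRole(sample_roles[s]) for s in values.columns}
        if detection_p is not None:
            detection_p = detection_p.reindex(index=values.index, columns=values.columns)
        self.detection_p = detection_p

    # -- basic views ---------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_with_role(self, role: SampleRole | str) -> list[str]:
        role = SampleRole(role)
        return [s for s, r in self.sample_roles.items() if r == role]

    @property
    def control_ids(self) -> list[str]:
        return self.samples_with_role(SampleRole.control)

    @property
    def patient_ids(self) -> list[str]:
        return self.samples_with_role(SampleRole.patient)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        probe_ids = [p for p in probe_ids]
        det = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[probe_ids], dict(self.sample_roles), det)

    def require_roles(self) -> None:
        """Analysis entry points need at least one control and one patient."""
        if not self.control_ids or not self.patient_ids:
            raise ValueError("analysis requires >= 1 control and >= 1 patient sample")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples, "
            f"{len(self.control_ids)} controls / {len(self.patient_ids)} patients)"
        )
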