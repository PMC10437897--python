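"""Probe-level quality control applied before any statistics.

Rules are applied sequentially in a fixed, documented order —
detection → SNP → cross-reactive → sex chromosomes → missing values —
and a probe is counted against the *first* rule it trips, so the report
is deterministic and the per-rule counts sum to the number removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .core import BetaMatrix, ProbeRecord

DetectionMode = Literal["any_sample", "all_samples"]

RULE_ORDER = ("detection", "snp", "cross_reactive", "sex_chromosome", "missing")


@dataclass
class FilterReport:
    """Per-rule removal counts; ``removed + retained == input``."""

    input_probes: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def __post_init__(self) -> None:
        for rule in RULE_ORDER:
            self.removed.setdefault(rule, 0)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input_probes": self.input_probes,
            "removed": dict(self.removed),
            "retained": self.retained,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def filter_probes(
    beta: BetaMatrix,
    manifest: Sequence[ProbeRecord],
    detection_threshold: float = 0.05,
    mode: DetectionMode = "any_sample",
) -> tuple[BetaMatrix, FilterReport]:
    """Drop probes failing detection, SNP / cross-reactivity flags, sex
    chromosomes, then missing values.

    The detection rule drops a probe whose detection p ≥ ``detection_threshold``
    in any sample (``mode="any_sample"``, the strict default) or in every
    sample (``"all_samples"``). Probes absent from the manifest raise.
    Filtering is idempotent and independent of probe order.
    """
    by_id = {p.probe_id: p for p in manifest}
    unknown = [pid for pid in beta.probe_ids if pid not in by_id]
    if unknown:
        raise ValueError(f"probes missing from manifest: {unknown[:5]}")

    report = FilterReport(input_probes=len(beta.probe_ids))
    keep: list[str] = []
    values = beta.values
    det = beta.detection_p

    for pid in beta.probe_ids:
        rec = by_id[pid]
        if det is not None:
            failing = det.loc[pid].to_numpy() >= detection_threshold
            tripped = failing.any() if mode == "any_sample" else failing.all()
            if tripped:
                report.removed["detection"] += 1
                continue
        if rec.snp_flag:
            report.removed["snp"] += 1
            continue
        if rec.cross_reactive_flag:
            report.removed["cross_reactive"] += 1
            continue
        if rec.chrom in ("chrX", "chrY"):
            report.removed["sex_chromosome"] += 1
            continue
        if np.isnan(values.loc[pid].to_numpy()).any():
            report.removed["missing"] += 1
            continue
        keep.append(pid)

    report.retained = len(keep)
    return beta.subset_probes(keep), report
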