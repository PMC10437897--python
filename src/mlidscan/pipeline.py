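"""End-to-end orchestration: QC → normalization → single-case → regions →
MLID, plus cohort summaries, with deterministic file outputs.

:func:`analyze_cohort` is the in-memory entry point used by both the CLI
and tests; :func:`run_pipeline` wraps it with file I/O, a run-metadata
sidecar and per-stage logging of the probe funnel.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmiq import bmiq_normalize_sample
from .cohort import cluster_samples, group_dmps, summarize_patient_counts
from .core import BetaMatrix, IdmrRegion, ProbeRecord
from .io import (
    load_beta_matrix,
    load_idmr_catalog,
    load_manifest,
    load_roles,
    map_probes_to_regions,
)
from .qc import FilterReport, filter_probes
from .regions import (
    ICR1,
    ICR2,
    MIN_CONSECUTIVE,
    MIN_SIGNIFICANT,
    MlidReport,
    RegionCall,
    assign_epigenotype,
    call_all_regions,
    classify_mlid,
    region_calls_frame,
)
from .singlecase import DELTA_THRESHOLD, P_THRESHOLD, call_dmps

log = logging.getLogger("mlidscan")


@dataclass
class RunConfig:
    """File paths, thresholds and switches for one pipeline run."""

    beta_path: str
    roles_path: str
    manifest_path: str
    catalog_path: str
    output_dir: str
    detection_p_path: Optional[str] = None
    delta_threshold: float = DELTA_THRESHOLD
    p_threshold: float = P_THRESHOLD
    min_significant: int = MIN_SIGNIFICANT
    min_consecutive: int = MIN_CONSECUTIVE
    detection_threshold: float = 0.05
    detection_mode: str = "any_sample"
    normalize: bool = True
    icr1_name: str = ICR1
    icr2_name: str = ICR2
    seed: int = 0
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        for name in (
            "delta_threshold",
            "p_threshold",
            "min_significant",
            "min_consecutive",
            "detection_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CohortResult:
    """Everything one analysis run produces, in memory."""

    beta: BetaMatrix  # filtered (and normalized, if enabled)
    filter_report: FilterReport
    per_patient_calls: dict[str, pd.DataFrame]
    region_calls: dict[str, list[RegionCall]]
    mlid_reports: dict[str, MlidReport]
    group_dmp_table: pd.DataFrame
    cluster_labels: Optional[dict[str, int]]
    patient_counts: pd.DataFrame


def normalize_matrix(beta: BetaMatrix, manifest: Sequence[ProbeRecord]) -> BetaMatrix:
    """BMIQ-normalize every sample of a matrix in place of its values."""
    by_id = {p.probe_id: p for p in manifest}
    design = [by_id[pid].design_type for pid in beta.probe_ids]
    values = beta.values.copy()
    for sample in beta.sample_ids:
        values[sample] = bmiq_normalize_sample(values[sample].to_numpy(), design)
    return BetaMatrix(values, dict(beta.sample_roles), beta.detection_p)


def analyze_cohort(
    beta: BetaMatrix,
    manifest: Sequence[ProbeRecord],
    catalog: Sequence[IdmrRegion],
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    min_significant: int = MIN_SIGNIFICANT,
    min_consecutive: int = MIN_CONSECUTIVE,
    detection_threshold: float = 0.05,
    detection_mode: str = "any_sample",
    normalize: bool = True,
    icr1_name: str = ICR1,
    icr2_name: str = ICR2,
) -> CohortResult:
    """Run the full analysis on an in-memory cohort."""
    beta.require_roles()
    filtered, report = filter_probes(
        beta, manifest, detection_threshold=detection_threshold, mode=detection_mode
    )
    log.info(
        "qc: %d probes in, %d retained (%s)",
        report.input_probes,
        report.retained,
        report.removed,
    )
    if normalize:
        filtered = normalize_matrix(filtered, manifest)
        log.info("bmiq: normalized %d samples", len(filtered.sample_ids))

    mapping = map_probes_to_regions(
        [p for p in manifest if p.probe_id in set(filtered.probe_ids)], catalog
    )

    per_patient_calls: dict[str, pd.DataFrame] = {}
    region_calls: dict[str, list[RegionCall]] = {}
    mlid_reports: dict[str, MlidReport] = {}
    for patient in filtered.patient_ids:
        calls = call_dmps(
            filtered, patient, delta_threshold=delta_threshold, p_threshold=p_threshold
        )
        per_patient_calls[patient] = calls
        rcalls = call_all_regions(
            catalog,
            mapping,
            calls,
            min_significant=min_significant,
            min_consecutive=min_consecutive,
        )
        region_calls[patient] = rcalls
        epi = assign_epigenotype(rcalls, icr1_name=icr1_name, icr2_name=icr2_name)
        mlid_reports[patient] = classify_mlid(rcalls, epi)

    dmp_set = group_dmps(
        filtered, delta_threshold=delta_threshold, p_threshold=p_threshold
    )
    labels = None
    if len(dmp_set) >= 2:
        labels = cluster_samples(filtered, dmp_set).labels
    counts = summarize_patient_counts(per_patient_calls)
    return CohortResult(
        beta=filtered,
        filter_report=report,
        per_patient_calls=per_patient_calls,
        region_calls=region_calls,
        mlid_reports=mlid_reports,
        group_dmp_table=dmp_set.table,
        cluster_labels=labels,
        patient_counts=counts,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run the pipeline from files per ``config``; returns the output dir.

    Outputs: ``filter_report.json``, per-patient ``dmp_<id>.tsv`` and
    ``regions_<id>.tsv``, ``mlid_<id>.json``, ``group_dmps.tsv``,
    ``cluster_labels.tsv``, ``patient_counts.tsv`` and ``run_metadata.json``.
    Any stage error aborts before partial outputs are written.
    """
    for name in ("beta_path", "roles_path", "manifest_path", "catalog_path"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p} does not exist")

    roles = load_roles(config.roles_path)
    beta = load_beta_matrix(
        config.beta_path, roles, detection_p_path=config.detection_p_path
    )
    manifest = load_manifest(config.manifest_path)
    catalog = load_idmr_catalog(config.catalog_path)

    result = analyze_cohort(
        beta,
        manifest,
        catalog,
        delta_threshold=config.delta_threshold,
        p_threshold=config.p_threshold,
        min_significant=config.min_significant,
        min_consecutive=config.min_consecutive,
        detection_threshold=config.detection_threshold,
        detection_mode=config.detection_mode,
        normalize=config.normalize,
        icr1_name=config.icr1_name,
        icr2_name=config.icr2_name,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.filter_report.save_json(out / "filter_report.json")
    for patient, calls in result.per_patient_calls.items():
        calls.to_csv(out / f"dmp_{patient}.tsv", sep="\t", float_format="%.10g")
        region_calls_frame(result.region_calls[patient]).to_csv(
            out / f"regions_{patient}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        result.mlid_reports[patient].save_json(out / f"mlid_{patient}.json")
    result.group_dmp_table.to_csv(out / "group_dmps.tsv", sep="\t", float_format="%.10g")
    if result.cluster_labels is not None:
        pd.Series(result.cluster_labels, name="cluster").rename_axis("sample_id").to_csv(
            out / "cluster_labels.tsv", sep="\t"
        )
    result.patient_counts.to_csv(out / "patient_counts.tsv", sep="\t")
    metadata = {
        "mlidscan_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_probes_input": result.filter_report.input_probes,
        "n_probes_retained": result.filter_report.retained,
        "mlid_positive": sorted(
            p for p, r in result.mlid_reports.items() if r.mlid
        ),
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return out
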