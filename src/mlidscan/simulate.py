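"""EPIC-like synthetic cohorts with planted epimutations.

The generator emulates the study design this pipeline targets: a small
control group (default 4), a cohort of imprinting-disorder patients, iDMR
probes sitting near half-methylation (β ≈ 0.5, the hallmark of a
monoallelically methylated region in a bulk leukocyte sample), and a
genome-wide background of mostly fully methylated / unmethylated CpGs.

Epimutations are planted as a shift of the mean β at a region's probes:
loss of methylation (LoM) moves the mean down, gain (GoM) up, attenuated
linearly by the mosaic cell fraction — a mixture of ``mosaic_fraction``
cells carrying the epimutation and ``1 − mosaic_fraction`` normal cells has
mean ``μ + direction · effect · mosaic_fraction``.

Noise is beta-distributed (moment-matched shape parameters) so values
respect [0, 1] without clipping. Infinium type II probes are passed through
a fixed monotone logit-shrink compression toward mid-range, mimicking the
well-known type II dynamic-range compression that BMIQ corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import BetaMatrix, CgiContext, DesignType, GenicContext, IdmrRegion, ProbeRecord

Direction = Literal["LoM", "GoM"]

#: logit-shrink factor of the fixed Infinium II compression map
TYPE2_LOGIT_SHRINK = 0.8


@dataclass(frozen=True)
class PlantedEvent:
    """A planted epimutation: one patient, one region, one direction."""

    patient_id: str
    region_name: str
    direction: Direction
    effect_size: float  # |Δβ| at full mosaic fraction, in (0, 0.5]
    mosaic_fraction: float = 1.0  # affected cell fraction, in (0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.effect_size <= 0.5:
            raise ValueError(f"effect_size must be in (0, 0.5], got {self.effect_size}")
        if not 0 < self.mosaic_fraction <= 1:
            raise ValueError(
                f"mosaic_fraction must be in (0, 1], got {self.mosaic_fraction}"
            )

    @property
    def signed_shift(self) -> float:
        sign = -1.0 if self.direction == "LoM" else 1.0
        return sign * self.effect_size * self.mosaic_fraction


@dataclass
class SyntheticCohortConfig:
    """Study-design knobs for a synthetic cohort.

    Defaults mirror the targeted study conditions: 4 controls, iDMR probes
    centred at β = 0.5 with per-probe sd 0.02, and a small per-entry
    detection-failure probability.
    """

    n_controls: int = 4
    n_patients: int = 6
    probes_per_region: int = 8
    n_background_probes: int = 200
    control_idmr_mean: float = 0.5
    control_sd: float = 0.02
    planted_events: Sequence[PlantedEvent] = field(default_factory=tuple)
    type2_fraction: float = 0.5
    detection_fail_rate: float = 0.002
    snp_fraction: float = 0.02
    cross_reactive_fraction: float = 0.02
    sex_chromosome_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        events = [
            e if isinstance(e, PlantedEvent) else PlantedEvent(**e)
            for e in self.planted_events
        ]
        self.planted_events = tuple(events)
        for e in self.planted_events:
            lo = self.control_idmr_mean - e.effect_size
            hi = self.control_idmr_mean + e.effect_size
            if not (0 <= lo and hi <= 1):
                raise ValueError(
                    f"control_idmr_mean ± effect_size leaves [0,1] for event {e}"
                )


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b) shape parameters for a given mean and sd.

    ``a = μ·(μ(1−μ)/σ² − 1)``, ``b = (1−μ)·(μ(1−μ)/σ² − 1)``; requires
    ``σ² < μ(1−μ)``, which holds for every mean/sd pair used here.
    """
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    var = sd * sd
    limit = mean * (1 - mean)
    if var >= limit:
        var = 0.99 * limit
    nu = limit / var - 1.0
    return mean * nu, (1 - mean) * nu


def compress_type2(beta: np.ndarray, shrink: float = TYPE2_LOGIT_SHRINK) -> np.ndarray:
    """Fixed monotone Infinium II compression: shrink of the logit.

    ``β' = expit(shrink · logit(β))`` with ``shrink < 1`` pulls values
    toward 0.5, mimicking the reduced dynamic range of type II probes.
    """
    eps = 1e-12
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    logit = np.log(b / (1 - b))
    return 1.0 / (1.0 + np.exp(-shrink * logit))


def region_probe_positions(region: IdmrRegion, k: int) -> np.ndarray:
    """Evenly spaced probe positions inside a region (closed form).

    For ``k`` probes in ``[start, end]``: ``pos_i = round(start +
    i·(end−start)/(k−1))`` for ``i = 0..k−1`` (the midpoint for k = 1).
    """
    if k < 1:
        raise ValueError("need at least one probe per region")
    if region.width < k:
        raise ValueError(
            f"region {region.name} ({region.width} bp) too narrow for {k} probes"
        )
    if k == 1:
        return np.array([(region.start + region.end) // 2])
    i = np.arange(k)
    return np.rint(region.start + i * (region.end - region.start) / (k - 1)).astype(int)


def generate_manifest(
    config: SyntheticCohortConfig, catalog: Sequence[IdmrRegion]
) -> list[ProbeRecord]:
    """Synthetic probe manifest: evenly spaced probes in each catalog
    region plus background probes outside all regions.

    Design types are i.i.d. type II with probability ``type2_fraction``.
    Configurable fractions of *background* probes are SNP-flagged,
    cross-reactive, or placed on chrX/chrY so the QC stage has work to do.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(config.seed)
    probes: list[ProbeRecord] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"cg{idx:08d}"

    for region in catalog:
        for pos in region_probe_positions(region, config.probes_per_region):
            probes.append(
                ProbeRecord(
                    probe_id=next_id(),
                    chrom=region.chrom,
                    pos=int(pos),
                    design_type=_draw_design(rng, config.type2_fraction),
                    cgi_context=CgiContext.island,
                    genic_context=GenicContext.promoter,
                )
            )

    # background probes live on a chromosome arm far from every catalog
    # region (chr2 is free in the bundled catalog; offset dodges clashes)
    n_bg = config.n_background_probes
    sex = rng.random(n_bg) < config.sex_chromosome_fraction
    snp = rng.random(n_bg) < config.snp_fraction
    cross = rng.random(n_bg) < config.cross_reactive_fraction
    for j in range(n_bg):
        chrom = ("chrX" if rng.random() < 0.5 else "chrY") if sex[j] else "chr2"
        probes.append(
            ProbeRecord(
                probe_id=next_id(),
                chrom=chrom,
                pos=10_000_000 + j * 1_000,
                design_type=_draw_design(rng, config.type2_fraction),
                snp_flag=bool(snp[j]),
                cross_reactive_flag=bool(cross[j]),
            )
        )
    return probes


def _draw_design(rng: np.random.Generator, type2_fraction: float) -> DesignType:
    return DesignType.II if rng.random() < type2_fraction else DesignType.I


def generate_cohort(
    config: SyntheticCohortConfig,
    manifest: Sequence[ProbeRecord],
    catalog: Sequence[IdmrRegion],
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Draw a cohort β matrix plus the planted-truth table.

    Returns ``(beta, truth)`` where ``truth`` has one row per planted
    event with the realized mean Δβ over the region's probes, measured on
    the underlying (pre type II compression) values — the ground-truth
    magnitude of the epimutation itself.
    """
    from .io import map_probes_to_regions

    rng = np.random.default_rng(config.seed)
    sample_ids = [f"C{i+1}" for i in range(config.n_controls)] + [
        f"P{i+1}" for i in range(config.n_patients)
    ]
    roles = {s: ("control" if s.startswith("C") else "patient") for s in sample_ids}
    known = {s for s in sample_ids}
    for e in config.planted_events:
        if e.patient_id not in known or roles[e.patient_id] != "patient":
            raise ValueError(f"planted event names unknown patient {e.patient_id!r}")

    mapping = map_probes_to_regions(manifest, catalog)
    probe_region = {pid: rname for rname, pids in mapping.items() for pid in pids}
    probe_ids = [p.probe_id for p in manifest]
    n_probes, n_samples = len(probe_ids), len(sample_ids)

    # per-probe baseline means: iDMR probes at the imprinted mid-level,
    # background probes from a bimodal (mostly 0.1 / 0.9) mixture
    base_mean = np.empty(n_probes)
    for i, p in enumerate(manifest):
        if p.probe_id in probe_region:
            base_mean[i] = config.control_idmr_mean
        else:
            u = rng.random()
            base_mean[i] = 0.1 if u < 0.45 else (0.9 if u < 0.9 else 0.5)

    shift = np.zeros((n_probes, n_samples))
    for e in config.planted_events:
        col = sample_ids.index(e.patient_id)
        for i, p in enumerate(manifest):
            if probe_region.get(p.probe_id) == e.region_name:
                shift[i, col] += e.signed_shift

    mean = np.clip(base_mean[:, None] + shift, 1e-3, 1 - 1e-3)
    limit = mean * (1 - mean)
    var = np.minimum(config.control_sd**2, 0.99 * limit)
    nu = limit / var - 1.0
    raw = rng.beta(mean * nu, (1 - mean) * nu)

    # realized truth measured before the type II compression map
    ctrl_cols = [j for j, s in enumerate(sample_ids) if roles[s] == "control"]
    truth_rows = []
    for e in config.planted_events:
        col = sample_ids.index(e.patient_id)
        rows = [i for i, p in enumerate(manifest) if probe_region.get(p.probe_id) == e.region_name]
        realized = float(np.mean(raw[rows, col] - raw[np.ix_(rows, ctrl_cols)].mean(axis=1)))
        truth_rows.append(
            {
                "patient_id": e.patient_id,
                "region_name": e.region_name,
                "direction": e.direction,
                "effect_size": e.effect_size,
                "mosaic_fraction": e.mosaic_fraction,
                "realized_delta_beta": realized,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "region_name",
            "direction",
            "effect_size",
            "mosaic_fraction",
            "realized_delta_beta",
        ],
    )

    observed = raw.copy()
    is_type2 = np.array([p.design_type == DesignType.II for p in manifest])
    observed[is_type2, :] = compress_type2(observed[is_type2, :])

    # detection p-values: passing entries uniform on [0, 0.05), failing
    # entries uniform on [0.05, 1) with probability detection_fail_rate
    fails = rng.random((n_probes, n_samples)) < config.detection_fail_rate
    det = np.where(
        fails,
        0.05 + 0.95 * rng.random((n_probes, n_samples)),
        0.05 * rng.random((n_probes, n_samples)),
    )

    values = pd.DataFrame(observed, index=probe_ids, columns=sample_ids)
    det_df = pd.DataFrame(det, index=probe_ids, columns=sample_ids)
    return BetaMatrix(values, roles, detection_p=det_df), truth
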