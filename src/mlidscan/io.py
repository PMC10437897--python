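"""Readers and writers for beta matrices, probe manifests and iDMR catalogs.

All on-disk formats are plain TSV:

* beta matrix — header row of sample ids, first column ``probe_id``;
* probe manifest — one row per probe with the :class:`~mlidscan.core.ProbeRecord`
  fields;
* iDMR catalog — BED-like columns ``chrom  start  end  name
  methylated_allele  [excluded]`` (1-based closed intervals).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    IdmrRegion,
    POLYMORPHIC_REGIONS,
    ProbeRecord,
)

_MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "design_type",
    "snp_flag",
    "cross_reactive_flag",
    "cgi_context",
    "genic_context",
]


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def load_beta_matrix(
    path: str | Path,
    role_map: Mapping[str, str],
    detection_p_path: str | Path | None = None,
) -> BetaMatrix:
    """Load a probes × samples β-value TSV.

    Non-numeric cells raise; out-of-range values raise inside
    :class:`BetaMatrix`. Row and column order are preserved. The string
    ``NA`` (or empty cell) is the explicit missing-value sentinel.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.name is None or df.columns.size == 0:
        raise ValueError(f"{path}: malformed header (need probe-id column + sample ids)")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric beta value ({exc})") from exc
    det = None
    if detection_p_path is not None:
        det = pd.read_csv(detection_p_path, sep="\t", index_col=0)
    return BetaMatrix(df, role_map, detection_p=det)


def save_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    df = beta.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def save_roles(beta: BetaMatrix, path: str | Path) -> None:
    pd.Series({s: r.value for s, r in beta.sample_roles.items()}, name="role").rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t")


def load_roles(path: str | Path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col=0)["role"]
    return {str(k): str(v) for k, v in s.items()}


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids in manifest")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProbeRecord(
                probe_id=row.probe_id,
                chrom=row.chrom,
                pos=int(row.pos),
                design_type=getattr(row, "design_type", "II"),
                snp_flag=bool(getattr(row, "snp_flag", False)),
                cross_reactive_flag=bool(getattr(row, "cross_reactive_flag", False)),
                cgi_context=getattr(row, "cgi_context", "open_sea"),
                genic_context=getattr(row, "genic_context", "intergenic"),
            )
        )
    return records


def save_manifest(manifest: Iterable[ProbeRecord], path: str | Path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "chrom": p.chrom,
            "pos": p.pos,
            "design_type": p.design_type.value,
            "snp_flag": p.snp_flag,
            "cross_reactive_flag": p.cross_reactive_flag,
            "cgi_context": p.cgi_context.value,
            "genic_context": p.genic_context.value,
        }
        for p in manifest
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# iDMR catalog
# ---------------------------------------------------------------------------

def load_idmr_catalog(path: str | Path) -> list[IdmrRegion]:
    """Load a BED-like iDMR catalog TSV, sorted by (chrom, start).

    Regions named after polymorphically imprinted loci (VTRNA2-1) are
    auto-flagged ``excluded`` unless the file carries an explicit
    ``excluded`` column value for them.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "start", "end", "name", "methylated_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: catalog missing columns {sorted(missing)}")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"{path}: duplicate region names {dups}")
    has_excluded = "excluded" in df.columns
    regions = []
    for row in df.itertuples(index=False):
        if has_excluded and not pd.isna(row.excluded):
            excluded = bool(row.excluded)
        else:
            excluded = any(row.name.startswith(p) for p in POLYMORPHIC_REGIONS)
        regions.append(
            IdmrRegion(
                name=row.name,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                methylated_allele=str(row.methylated_allele),
                excluded=excluded,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def save_idmr_catalog(catalog: Iterable[IdmrRegion], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "name": r.name,
            "methylated_allele": r.methylated_allele,
            "excluded": r.excluded,
        }
        for r in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bundled_idmr_catalog() -> list[IdmrRegion]:
    """The small iDMR catalog shipped with the package (hg19)."""
    with importlib.resources.as_file(
        importlib.resources.files("mlidscan.data") / "idmr_catalog.tsv"
    ) as p:
        return load_idmr_catalog(p)


# ---------------------------------------------------------------------------
# probe ↔ region mapping
# ---------------------------------------------------------------------------

def map_probes_to_regions(
    manifest: Iterable[ProbeRecord],
    catalog: Iterable[IdmrRegion],
) -> dict[str, list[str]]:
    """Map each region name to its member probe ids, ordered by position.

    A probe belongs to a region iff ``start <= pos <= end`` on the same
    chromosome (closed interval, same genome build assumed). Output order
    is genomic regardless of manifest order; probes falling in no region
    simply do not appear.
    """
    probes = sorted(manifest, key=lambda p: (p.chrom, p.pos, p.probe_id))
    if not probes:
        return {r.name: [] for r in catalog}
    chroms = np.array([p.chrom for p in probes])
    pos = np.array([p.pos for p in probes])
    ids = np.array([p.probe_id for p in probes])
    mapping: dict[str, list[str]] = {}
    for region in catalog:
        mask = (chroms == region.chrom) & (pos >= region.start) & (pos <= region.end)
        mapping[region.name] = ids[mask].tolist()
    return mapping
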