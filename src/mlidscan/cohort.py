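"""Group-level DMP discovery and sample clustering.

The group rule mirrors the single-case one at cohort scale: a probe is a
group DMP when the mean methylation difference between patients and
controls exceeds 0.2 in absolute value with a per-probe two-sample p-value
below 0.05. The per-probe test is Welch's t by default (unequal group
sizes and variances) and can be switched to Mann–Whitney.

Clustering of samples restricted to the group-DMP probes uses
agglomerative hierarchical clustering with Euclidean distance and average
linkage, cut at k = 2 — the two-epigenotype structure such cohorts show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import BetaMatrix
from .singlecase import DELTA_THRESHOLD, P_THRESHOLD


@dataclass
class GroupDmpSet:
    """Probes passing the group rule, with per-probe effect and p."""

    table: pd.DataFrame  # index probe_id; columns mean_delta, p

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def group_dmps(
    beta: BetaMatrix,
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    test: Literal["welch", "mannwhitney"] = "welch",
) -> GroupDmpSet:
    """Probes with |mean Δβ| > ``delta_threshold`` and p < ``p_threshold``
    between the patient and control groups (both thresholds strict)."""
    controls = beta.values[beta.control_ids]
    patients = beta.values[beta.patient_ids]
    if controls.shape[1] < 2 or patients.shape[1] < 2:
        raise ValueError("group comparison needs >= 2 samples per role")

    c = controls.to_numpy()
    x = patients.to_numpy()
    mean_delta = np.nanmean(x, axis=1) - np.nanmean(c, axis=1)
    if test == "welch":
        res = stats.ttest_ind(x, c, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue)
    elif test == "mannwhitney":
        p = np.array(
            [
                stats.mannwhitneyu(
                    row_x[~np.isnan(row_x)], row_c[~np.isnan(row_c)],
                    alternative="two-sided",
                ).pvalue
                for row_x, row_c in zip(x, c)
            ]
        )
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown test {test!r}")

    with np.errstate(invalid="ignore"):
        member = (np.abs(mean_delta) > delta_threshold) & (p < p_threshold)
    member &= ~np.isnan(p)
    table = pd.DataFrame(
        {"mean_delta": mean_delta, "p": p},
        index=pd.Index(beta.probe_ids, name="probe_id"),
    )[member]
    return GroupDmpSet(table=table)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy condensed linkage matrix over samples
    sample_ids: list[str]
    labels: dict[str, int]  # k=2 flat cluster label per sample


def cluster_samples(beta: BetaMatrix, dmps: GroupDmpSet, k: int = 2) -> ClusterResult:
    """Hierarchically cluster samples on the group-DMP probes.

    Euclidean distance, average linkage, deterministic given the input;
    returns the linkage structure and flat labels at ``k`` clusters.
    """
    if len(dmps) < 2:
        raise ValueError("need >= 2 probes in the DMP set to cluster")
    sub = beta.values.loc[dmps.probe_ids]
    X = sub.to_numpy().T  # samples × probes
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        sample_ids=beta.sample_ids,
        labels={s: int(l) for s, l in zip(beta.sample_ids, flat)},
    )


def summarize_patient_counts(
    per_patient_calls: Mapping[str, pd.DataFrame],
    panel_size: int | None = None,
) -> pd.DataFrame:
    """Per-patient hyper/hypo DMP counts and panel percentages.

    One row per patient: ``n_hyper``, ``pct_hyper``, ``n_hypo``,
    ``pct_hypo``; percentages are relative to ``panel_size`` (default: the
    patient's analyzed-probe count), reported to 3 decimals.
    """
    from .singlecase import count_dmps

    rows = []
    for patient, calls in per_patient_calls.items():
        counts = count_dmps(calls, panel_size=panel_size)
        rows.append(
            {
                "patient_id": patient,
                "n_hyper": counts.n_hyper,
                "pct_hyper": round(counts.percent_hyper_panel, 3),
                "n_hypo": counts.n_hypo,
                "pct_hypo": round(counts.percent_hypo_panel, 3),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
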