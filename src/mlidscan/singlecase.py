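"""Single-case per-CpG statistics: one patient versus a small control group.

The core test is the Crawford–Howell modified t-test, which treats the
patient as a sample of size one from the control population:

    t = (x − mean(c)) / (sd(c) · √((n + 1) / n)),   df = n − 1,

with ``sd`` the n−1 (sample) standard deviation and a two-tailed p from the
Student t distribution. A differentially methylated position (DMP) is a
probe where the effect size and significance gates hold jointly:
|Δβ| > 0.2 and p < 0.05, both strict, with Δβ = patient β − mean control β.
No multiple-testing correction is applied at the probe level: the DMP rule
deliberately combines the raw p-value with the 20-percentage-point
effect-size gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix

DELTA_THRESHOLD = 0.2
P_THRESHOLD = 0.05


def crawford_howell(x: float, controls: Sequence[float] | np.ndarray) -> tuple[float, int, float]:
    """Crawford–Howell single-case t-test of ``x`` against ``controls``.

    Returns ``(t, df, p)`` with ``df = n − 1`` and a two-tailed p-value.
    Requires at least two controls with non-zero variance.
    """
    c = np.asarray(controls, dtype=float)
    n = c.size
    if n < 2:
        raise ValueError(f"need >= 2 controls, got {n}")
    sd = c.std(ddof=1)
    if sd == 0 or np.ptp(c) == 0:
        raise ValueError("control values have zero variance")
    t = (float(x) - c.mean()) / (sd * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def call_dmps(
    beta: BetaMatrix,
    patient_id: str,
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-probe Crawford–Howell results and DMP calls for one patient.

    Returns a DataFrame indexed by probe id with columns ``beta_patient``,
    ``control_mean``, ``control_sd``, ``delta_beta``, ``t``, ``df``, ``p``,
    ``direction`` ("hyper"/"hypo") and ``passes``. Probes with missing
    values or zero control variance are skipped (dropped from the output);
    the number skipped is available via the frame's ``attrs["n_skipped"]``.
    """
    beta.require_roles()
    if patient_id not in beta.patient_ids:
        raise ValueError(f"{patient_id!r} is not a patient sample")
    controls = beta.values[beta.control_ids].to_numpy()
    x = beta.values[patient_id].to_numpy()
    n = controls.shape[1]
    if n < 2:
        raise ValueError(f"need >= 2 controls, got {n}")

    cmean = controls.mean(axis=1)
    csd = controls.std(axis=1, ddof=1)
    ok = ~np.isnan(x) & ~np.isnan(cmean) & (csd > 0)

    delta = x - cmean
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / (csd * np.sqrt((n + 1) / n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)

    out = pd.DataFrame(
        {
            "beta_patient": x,
            "control_mean": cmean,
            "control_sd": csd,
            "delta_beta": delta,
            "t": t,
            "df": n - 1,
            "p": p,
        },
        index=pd.Index(beta.probe_ids, name="probe_id"),
    )[ok]
    out["direction"] = np.where(out["delta_beta"] >= 0, "hyper", "hypo")
    out["passes"] = (out["delta_beta"].abs() > delta_threshold) & (out["p"] < p_threshold)
    out.attrs["patient_id"] = patient_id
    out.attrs["n_skipped"] = int((~ok).sum())
    return out


@dataclass(frozen=True)
class DmpCounts:
    """Hyper/hypo DMP counts with panel- and significant-relative shares."""

    n_hyper: int
    n_hypo: int
    percent_hyper_panel: float  # of the analyzed panel, in %
    percent_hypo_panel: float
    percent_hyper_significant: float  # of passing DMPs, in %
    percent_hypo_significant: float


def count_dmps(calls: pd.DataFrame, panel_size: int | None = None) -> DmpCounts:
    """Summarize one patient's passing DMP calls.

    ``panel_size`` defaults to the number of analyzed probes (rows of
    ``calls``); pass the array panel size (e.g. ~850 000) to reproduce
    published per-panel percentages.
    """
    passing = calls[calls["passes"]]
    n_hyper = int((passing["direction"] == "hyper").sum())
    n_hypo = int((passing["direction"] == "hypo").sum())
    panel = panel_size if panel_size is not None else len(calls)
    n_sig = n_hyper + n_hypo
    return DmpCounts(
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        percent_hyper_panel=100.0 * n_hyper / panel if panel else 0.0,
        percent_hypo_panel=100.0 * n_hypo / panel if panel else 0.0,
        percent_hyper_significant=100.0 * n_hyper / n_sig if n_sig else 0.0,
        percent_hypo_significant=100.0 * n_hypo / n_sig if n_sig else 0.0,
    )
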