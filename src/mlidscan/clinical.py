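"""Clinical scoring systems and group-comparison statistics.

* BWS consensus score — 2 points per cardinal feature (macroglossia,
  exomphalos, lateralized overgrowth, multifocal Wilms tumor, prolonged
  hyperinsulinism, distinct pathology), 1 point per suggestive feature;
  a score ≥ 4 is classical BWS.
* Netchine–Harbison clinical scoring system (NH-CSS) for SRS — 1 point per
  each of six items.
* Pyrosequencing %mC standard deviation score (SDS) against a matched
  control panel.
* Fisher's exact test (two-sided, point-probability convention) and the
  Mann–Whitney U test for mono- vs multi-locus group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

CARDINAL_FEATURES = frozenset(
    {
        "macroglossia",
        "exomphalos",
        "lateralized_overgrowth",
        "multifocal_wilms",
        "hyperinsulinism",
        "pathology",
    }
)

SUGGESTIVE_FEATURES = frozenset(
    {
        "lga",
        "facial_nevus",
        "polyhydramnios_placentomegaly",
        "ear_creases_pits",
        "transient_hypoglycemia",
        "embryonal_tumor",
        "organomegaly",
        "umbilical_hernia_diastasis",
    }
)

NHCSS_FEATURES = frozenset(
    {
        "sga",
        "postnatal_growth_failure",
        "relative_macrocephaly",
        "protruding_forehead",
        "body_asymmetry",
        "feeding_difficulty_low_bmi",
    }
)

BWS_CLASSICAL_CUTOFF = 4


@dataclass(frozen=True)
class PhenotypeProfile:
    """Closed-vocabulary clinical feature sets for one patient."""

    patient_id: str
    cardinal: frozenset[str] = field(default_factory=frozenset)
    suggestive: frozenset[str] = field(default_factory=frozenset)
    nhcss: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for attr, vocab in (
            ("cardinal", CARDINAL_FEATURES),
            ("suggestive", SUGGESTIVE_FEATURES),
            ("nhcss", NHCSS_FEATURES),
        ):
            given = getattr(self, attr)
            unknown = set(given) - vocab
            if unknown:
                raise ValueError(f"unknown {attr} feature(s): {sorted(unknown)}")
            object.__setattr__(self, attr, frozenset(given))


def bws_score(profile: PhenotypeProfile) -> tuple[int, bool]:
    """BWS consensus score and whether it meets the classical cutoff (≥ 4)."""
    score = 2 * len(profile.cardinal) + len(profile.suggestive)
    return score, score >= BWS_CLASSICAL_CUTOFF


def nhcss_score(profile: PhenotypeProfile) -> int:
    """NH-CSS: one point per present item, maximum six."""
    return len(profile.nhcss)


def pyroseq_sds(x: float, control_panel: Sequence[float] | np.ndarray) -> float:
    """Standard deviation score of a %mC value against a control panel:
    ``(x − mean) / sd`` with the sample (n−1) standard deviation."""
    c = np.asarray(control_panel, dtype=float)
    if c.size < 2:
        raise ValueError("need >= 2 control values")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("control panel has zero standard deviation")
    return float((x - c.mean()) / sd)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability convention: the p-value sums hypergeometric
    probabilities of all tables (with the observed margins) no more
    likely than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mann_whitney(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    exact_limit: int = 12,
) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided.

    For ``m + n <= exact_limit`` the p-value is computed by full
    enumeration of all group assignments of the pooled values (handling
    ties naturally); larger samples use the normal approximation with tie
    correction. Returns ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size

    def u_stat(xs: np.ndarray, ys: np.ndarray) -> float:
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return float(gt + 0.5 * eq)

    u_obs = u_stat(x, y)
    if m + n <= exact_limit:
        pooled = np.concatenate([x, y])
        center = m * n / 2.0
        dev_obs = abs(u_obs - center)
        total = 0
        extreme = 0
        idx = np.arange(m + n)
        for chosen in combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(chosen)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
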