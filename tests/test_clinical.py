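"""Clinical scoring systems and the small-cohort comparison statistics."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from mlidscan.clinical import (
    PhenotypeProfile,
    bws_score,
    fisher_exact_2x2,
    mann_whitney,
    nhcss_score,
    pyroseq_sds,
)


def _profile(cardinal=(), suggestive=(), nhcss=(), pid="X"):
    return PhenotypeProfile(
        patient_id=pid,
        cardinal=frozenset(cardinal),
        suggestive=frozenset(suggestive),
        nhcss=frozenset(nhcss),
    )


class TestBwsScore:
    @pytest.mark.parametrize(
        "cardinal,suggestive,expected",
        [
            # macroglossia + lateralized overgrowth + ear anomalies + facial nevus
            (
                ("macroglossia", "lateralized_overgrowth"),
                ("ear_creases_pits", "facial_nevus"),
                6,
            ),
            # macroglossia + exomphalos + ear anomalies
            (("macroglossia", "exomphalos"), ("ear_creases_pits",), 5),
            ((), (), 0),
            (("macroglossia",), (), 2),
        ],
    )
    def test_two_per_cardinal_one_per_suggestive(self, cardinal, suggestive, expected):
        score, classical = bws_score(_profile(cardinal, suggestive))
        assert score == expected
        assert classical is (expected >= 4)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown cardinal"):
            _profile(cardinal=("macroglossia", "blue_eyes"))


class TestNhcssScore:
    @pytest.mark.parametrize(
        "items,expected",
        [
            (
                ("sga", "postnatal_growth_failure", "relative_macrocephaly", "body_asymmetry"),
                4,
            ),
            (
                (
                    "sga",
                    "postnatal_growth_failure",
                    "relative_macrocephaly",
                    "body_asymmetry",
                    "feeding_difficulty_low_bmi",
                ),
                5,
            ),
            (
                (
                    "sga",
                    "postnatal_growth_failure",
                    "relative_macrocephaly",
                    "protruding_forehead",
                    "body_asymmetry",
                    "feeding_difficulty_low_bmi",
                ),
                6,
            ),
            ((), 0),
        ],
    )
    def test_one_point_per_item(self, items, expected):
        assert nhcss_score(_profile(nhcss=items)) == expected


class TestPyroseqSds:
    def test_definition(self):
        panel = [48.0, 50.0, 52.0, 50.0]
        assert pyroseq_sds(50.0, panel) == pytest.approx(0.0)
        sd = np.std(panel, ddof=1)
        assert pyroseq_sds(50.0 + 2 * sd, panel) == pytest.approx(2.0)

    def test_agrees_with_independent_standardization(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            panel = rng.normal(50, 5, size=20)
            x = float(rng.normal(40, 10))
            expected = (x - panel.mean()) / panel.std(ddof=1)
            assert pyroseq_sds(x, panel) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_panel_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            pyroseq_sds(50.0, [50.0, 50.0, 50.0])
        with pytest.raises(ValueError, match=">= 2"):
            pyroseq_sds(50.0, [50.0])


def _fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration of all tables with the
    observed margins, point-probability convention."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def table_prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 4, 2, 1), 1.000),  # female: 5/9 mono vs 2/3 multi
            ((1, 8, 1, 2), 0.455),  # ART: 1/9 vs 1/3
            ((3, 6, 2, 1), 0.523),  # exomphalos: 3/9 vs 2/3
        ],
    )
    def test_reported_group_comparisons(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, abs=5e-4)

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in [(0, 3, 2, 1), (2, 2, 2, 2), (1, 5, 3, 0), (4, 1, 1, 4)]:
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                _fisher_enumeration_oracle(a, b, c, d), abs=1e-10
            )

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact_2x2(0, 0, 1, 2)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2(-1, 2, 3, 4)


def _mw_permutation_oracle(x, y):
    """Two-sided Mann–Whitney p by rank-sum enumeration (midranks)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    center = m * n / 2.0
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    dev = abs(u_obs - center)
    extreme = total = 0
    for chosen in combinations(range(m + n), m):
        u = ranks[list(chosen)].sum() - m * (m + 1) / 2.0
        total += 1
        if abs(u - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_identical_samples_center(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # m·n/2
        assert p == pytest.approx(1.0)

    def test_complete_separation_minimal_u(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))  # both tails

    def test_matches_permutation_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m, n = rng.integers(2, 6, size=2)
            x = rng.integers(0, 4, size=m).astype(float)  # integer grid → ties
            y = rng.integers(0, 4, size=n).astype(float)
            u, p = mann_whitney(x, y)
            assert p == pytest.approx(_mw_permutation_oracle(x, y), abs=1e-12)

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = mann_whitney(x, y)
            expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(float(expected), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=15)
        y = rng.normal(0.5, 1, size=20)
        u, p = mann_whitney(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(expected.pvalue), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])
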