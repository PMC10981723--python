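import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from geonorm import evaluation as ev


@pytest.fixture(scope="module")
def table1():
    return ev.load_table1()


class TestFixtureArithmetic:
    def test_detection_counts(self, table1):
        assert ev.detection_count(table1, "personalized") == 17
        assert ev.detection_count(table1, "average") == 11
        assert ev.detection_count(table1, "average", lambda f: f["patient"] < 0) == 0

    def test_subset_counts_among_radiology_strata(self, table1):
        rad_pos = lambda f: f["radiological_report"] != "NA"
        rad_neg = lambda f: f["radiological_report"] == "NA"
        assert int(rad_pos(table1).sum()) == 17
        assert ev.detection_count(table1, "average", rad_pos) == 8
        assert ev.detection_count(table1, "personalized", rad_pos) == 12
        assert ev.detection_count(table1, "average", rad_neg) == 3
        assert ev.detection_count(table1, "personalized", rad_neg) == 5

    def test_subset_counts_are_additive(self, table1):
        rad_pos = lambda f: f["radiological_report"] != "NA"
        rad_neg = lambda f: f["radiological_report"] == "NA"
        for method in ("average", "personalized"):
            assert ev.detection_count(table1, method, rad_pos) + ev.detection_count(
                table1, method, rad_neg
            ) == ev.detection_count(table1, method)

    def test_sensitivities_computed_from_counts(self, table1):
        assert ev.sensitivity(table1, "average") == 0.39
        # 17/28 = 0.607... -> 0.61 when computed from the counts themselves
        assert ev.sensitivity(table1, "personalized") == 0.61

    def test_relative_detection_gain(self, table1):
        assert ev.relative_detection_gain(table1) == 55

    def test_gain_arithmetic_cases(self, table1):
        f = table1.copy()
        f["average_outcome"] = f["personalized_outcome"]
        assert ev.relative_detection_gain(f) == 0
        g = pd.DataFrame(
            {
                "average_outcome": ["Increased"] * 10 + ["NA"] * 20,
                "personalized_outcome": ["Increased"] * 15 + ["NA"] * 15,
                "radiological_report": ["NA"] * 30,
            }
        )
        assert ev.relative_detection_gain(g) == 50

    def test_paired_counts(self, table1):
        counts = ev.paired_counts(table1)
        assert (counts.a, counts.b, counts.c, counts.d) == (11, 6, 0, 11)
        assert counts.n == 28

    def test_paired_counts_conservation(self, table1):
        counts = ev.paired_counts(table1)
        assert ev.detection_count(table1, "personalized") - ev.detection_count(
            table1, "average"
        ) == counts.b - counts.c

    def test_paired_counts_bruteforce_recount(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            f = pd.DataFrame(
                {
                    "average_outcome": rng.choice(["Increased", "NA"], size=15),
                    "personalized_outcome": rng.choice(["Increased", "NA"], size=15),
                }
            )
            counts = ev.paired_counts(f)
            a = b = c = d = 0
            for _, row in f.iterrows():
                pa = row["average_outcome"] == "Increased"
                pp = row["personalized_outcome"] == "Increased"
                a += pa and pp
                b += (not pa) and pp
                c += pa and not pp
                d += not pa and not pp
            assert (counts.a, counts.b, counts.c, counts.d) == (a, b, c, d)


class TestMcNemar:
    def test_exact_binomial_values(self):
        assert ev.mcnemar_exact(ev.PairedOutcomeCounts(11, 6, 0, 11)) == pytest.approx(
            2 * 0.5**6
        )
        assert ev.mcnemar_exact(ev.PairedOutcomeCounts(3, 0, 0, 5)) == 1.0
        assert ev.mcnemar_exact(ev.PairedOutcomeCounts(0, 5, 5, 0)) == 1.0

    def test_matches_statsmodels_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            ours = ev.mcnemar_exact(ev.PairedOutcomeCounts(int(a), int(b), int(c), int(d)))
            ref = sm_mcnemar([[a, b], [c, d]], exact=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(b=st.integers(0, 20), c=st.integers(0, 20))
    def test_symmetric_and_monotone_in_discordance(self, b, c):
        p1 = ev.mcnemar_exact(ev.PairedOutcomeCounts(0, b, c, 0))
        p2 = ev.mcnemar_exact(ev.PairedOutcomeCounts(0, c, b, 0))
        assert p1 == p2
        if b + c >= 2 and b != c:
            # pushing one discordant pair toward balance cannot lower p
            b2, c2 = (b - 1, c + 1) if b > c else (b + 1, c - 1)
            assert ev.mcnemar_exact(ev.PairedOutcomeCounts(0, b2, c2, 0)) >= p1


class TestWilcoxon:
    def test_enumeration_example(self):
        """Differences (1,2,3): all-positive signs put W- = 0 and the
        two-sided exact p over the 8 sign assignments is 2/8."""
        stat, p = ev.wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert stat == 0.0
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pairs_give_central_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([2.0, 1.0, 5.0, 2.0, 9.0, 2.0])  # diffs -1,1,-2,2,-4,4
        stat, p = ev.wilcoxon_signed_rank(a, b)
        n = 6
        assert stat == n * (n + 1) / 4
        assert p == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            stat, p = ev.wilcoxon_signed_rank(a, b)
            ref = stats.wilcoxon(a, b, method="exact")
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 20, size=40).astype(float)
        b = rng.integers(0, 20, size=40).astype(float)
        stat, p = ev.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False, zero_method="wilcox")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zeros_dropped_and_all_zero_raises(self):
        stat, p = ev.wilcoxon_signed_rank([1, 5, 5, 7], [1, 4, 3, 4])
        assert stat >= 0
        with pytest.raises(ValueError, match="zero"):
            ev.wilcoxon_signed_rank([1, 2], [1, 2])

    def test_positive_convention_configurable(self):
        stat, _ = ev.wilcoxon_signed_rank([2, 4, 6], [1, 2, 3], statistic="positive")
        assert stat == 6.0


class TestRegionCounts:
    def _frame(self, labels):
        return pd.DataFrame(
            {"structure": [f"r{i}" for i in range(len(labels))], "label": labels}
        )

    def test_all_normal(self):
        out = ev.abnormal_region_counts(self._frame(["normal"] * 5))
        assert out == {"increased": 0, "decreased_plus_increased": 0}

    def test_mixed_labels(self):
        out = ev.abnormal_region_counts(
            self._frame(["increased", "decreased", "decreased", "normal"])
        )
        assert out == {"increased": 1, "decreased_plus_increased": 3}

    def test_exclusion_removes_lesioned_structure(self):
        frame = self._frame(["increased", "increased", "normal"])
        out = ev.abnormal_region_counts(frame, exclude={"r0"})
        assert out == {"increased": 1, "decreased_plus_increased": 1}
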