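import itertools

import numpy as np
import pandas as pd
import pytest

from nfq.errors import DegenerateDataError
from nfq.phantom import REGIONS_TESTED
from nfq.stats import build_results, mann_whitney, spearman


def mw_enumeration_p(a, b):
    """Independent full-enumeration oracle for the two-sided exact
    Mann-Whitney p-value (tie-free inputs)."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.100, abs=1e-12)
        assert res.method == "mann_whitney_exact"

    def test_identical_multisets_no_evidence(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n*m/2 under symmetric ties
        assert res.p_value > 0.9
        assert res.method == "mann_whitney_normal"  # ties force the normal path

    @pytest.mark.parametrize("n,m", [(3, 3), (5, 5), (7, 5), (4, 6)])
    def test_exact_p_matches_full_enumeration(self, n, m):
        rng = np.random.default_rng(100 + n * 10 + m)
        for _ in range(25):
            a = rng.normal(size=n)
            b = rng.normal(loc=rng.uniform(-1, 1), size=m)
            res = mann_whitney(a, b)
            assert res.method == "mann_whitney_exact"
            assert res.p_value == pytest.approx(mw_enumeration_p(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = mann_whitney(rng.normal(size=10), rng.normal(size=10))
        assert res.method == "mann_whitney_normal"

    def test_exact_and_normal_agree_for_study_sizes(self):
        """Exact vs tie-corrected normal p within 0.02 at n=7 vs 5."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(77)
        worst = 0.0
        for _ in range(100):
            a = rng.normal(size=7)
            b = rng.normal(loc=rng.uniform(-1.5, 1.5), size=5)
            p_exact = mannwhitneyu(a, b, method="exact").pvalue
            p_norm = mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
            worst = max(worst, abs(p_exact - p_norm))
        assert worst < 0.02

    def test_empty_group_errors(self):
        with pytest.raises(DegenerateDataError):
            mann_whitney([], [1.0, 2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        """rho for x=[1,2,2,3], y=[1,3,2,4]: average ranks give
        rx=[1,2.5,2.5,4], ry=[1,3,2,4], Pearson = 4.5/sqrt(4.5*5)."""
        res = spearman([1, 2, 2, 3], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(4.5 / np.sqrt(4.5 * 5.0), abs=1e-12)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman(x, y).statistic == pytest.approx(spearman(y, x).statistic)
        assert spearman(np.exp(x), y).statistic == pytest.approx(
            spearman(x, y).statistic
        )

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert np.isnan(res.statistic)

    def test_too_short_errors(self):
        with pytest.raises(DegenerateDataError):
            spearman([1.0, 2.0], [3.0, 4.0])


def _tidy(values: dict, metric: str) -> pd.DataFrame:
    rows = []
    for animal, regions in values.items():
        for region, v in regions.items():
            rows.append(
                {"animal_id": animal, "region": region, "metric": metric, "value": v}
            )
    return pd.DataFrame(rows)


class TestBuildResults:
    def _cohort_tables(self, rng, effect_regions):
        animals = [f"e{i}" for i in range(7)] + [f"c{i}" for i in range(5)]
        groups = ["EAE"] * 7 + ["CTR"] * 5
        cs = [1.0 + 0.5 * i for i in range(7)] + [0.0] * 5
        suvr, spio = {}, {}
        for idx, animal in enumerate(animals):
            sev = cs[idx]
            suvr[animal] = {}
            spio[animal] = {}
            for r in REGIONS_TESTED:
                bump = 3.0 + sev if (groups[idx] == "EAE" and r in effect_regions) else 0.0
                suvr[animal][r] = 1.0 + bump + rng.normal(0, 0.05)
                spio[animal][r] = max(0.0, bump * 2 + rng.normal(0, 0.1))
        cohort = pd.DataFrame(
            {"animal_id": animals, "group": groups, "cs": cs}
        )
        return _tidy(suvr, "SUVR"), _tidy(spio, "SPIO_Vol_pct"), cohort

    def test_effect_regions_flagged_null_not(self, rng):
        effect = {"hippocampus", "thalamus", "cerebellum", "brainstem"}
        suvr, spio, cohort = self._cohort_tables(rng, effect)
        rep = build_results(suvr, spio, cohort)
        sel = rep.per_region[rep.per_region.metric == "SUVR"].set_index("region")
        for r in effect:
            assert sel.loc[r, "significant"]
        assert not sel.loc["caudate_putamen", "significant"]

    def test_monotone_link_gives_positive_pooled_rho(self, rng):
        effect = set(REGIONS_TESTED)
        suvr, spio, cohort = self._cohort_tables(rng, effect)
        rep = build_results(suvr, spio, cohort)
        cs_rows = rep.correlations[rep.correlations.pair == "CS~SUVR"]
        assert (cs_rows.rho > 0).all()

    def test_ctr_only_has_no_group_contrast(self, rng):
        suvr, spio, cohort = self._cohort_tables(rng, set())
        ctr_ids = cohort[cohort.group == "CTR"]["animal_id"]
        rep = build_results(
            suvr[suvr.animal_id.isin(ctr_ids)],
            spio[spio.animal_id.isin(ctr_ids)],
            cohort[cohort.group == "CTR"],
        )
        assert rep.per_region["p"].isna().all()
        assert not rep.per_region["significant"].any()

    def test_key_mismatch_reported(self, rng):
        suvr, spio, cohort = self._cohort_tables(rng, set())
        with pytest.raises(ValueError, match="e0"):
            build_results(suvr[suvr.animal_id != "e0"], spio, cohort)

    def test_holm_option_is_more_conservative(self, rng):
        suvr, spio, cohort = self._cohort_tables(rng, {"cerebellum"})
        plain = build_results(suvr, spio, cohort)
        holm = build_results(suvr, spio, cohort, holm=True)
        assert holm.per_region["significant"].sum() <= plain.per_region["significant"].sum()

    def test_summary_mentions_regions(self, rng):
        suvr, spio, cohort = self._cohort_tables(rng, set())
        rep = build_results(suvr, spio, cohort)
        assert "cerebellum" in rep.summary_md
        assert "SPIO_Vol_pct" in rep.summary_md
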