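"""Survey-weighted prevalence, 2x2 table and association test."""

import numpy as np
import pandas as pd
import pytest

from dualburden.descriptives import (
    SurveyDesign,
    TwoByTwo,
    chisq_association,
    crosstab,
    prevalence_table,
    table_from_percentages,
    weighted_prevalence,
)


def _srs_design(n, w=1.0):
    return SurveyDesign(np.full(n, w), np.arange(n).astype(str),
                        np.zeros(n, dtype=int))


class TestWeightedPrevalence:
    def test_reduces_to_srs(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p, se, _ = weighted_prevalence(y, _srs_design(200))
        assert p == pytest.approx(y.mean(), abs=1e-12)
        assert se == pytest.approx(
            np.sqrt(p * (1 - p) / (200 - 1)), abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        d1 = _srs_design(100, 1.0)
        d2 = _srs_design(100, 2.0)
        assert weighted_prevalence(y, d1)[:2] == weighted_prevalence(y, d2)[:2]

    def test_against_jackknife_oracle(self):
        """Linearized SE vs delete-one-cluster jackknife on clustered data."""
        rng = np.random.default_rng(2)
        n_clusters, m = 20, 25
        cluster_effect = rng.normal(0, 0.7, n_clusters)
        rows = []
        for c in range(n_clusters):
            p_c = 1 / (1 + np.exp(-(-0.8 + cluster_effect[c])))
            y = rng.binomial(1, p_c, m)
            w = rng.gamma(4, 0.25, m)
            for yi, wi in zip(y, w):
                rows.append((yi, wi, f"c{c}"))
        df = pd.DataFrame(rows, columns=["y", "w", "c"])
        design = SurveyDesign(df["w"], df["c"], np.zeros(len(df)))
        p_hat, se, _ = weighted_prevalence(df["y"].to_numpy(), design)

        # jackknife: drop each cluster, re-estimate
        reps = []
        for c in df["c"].unique():
            sub = df[df["c"] != c]
            reps.append(np.sum(sub["w"] * sub["y"]) / np.sum(sub["w"]))
        reps = np.array(reps)
        se_jk = np.sqrt((n_clusters - 1) / n_clusters
                        * np.sum((reps - reps.mean()) ** 2))
        assert se == pytest.approx(se_jk, rel=0.15)

    def test_ci_truncated_to_unit_interval(self):
        y = np.array([0, 0, 0, 1])
        p, se, (lo, hi) = weighted_prevalence(y, _srs_design(4))
        assert 0.0 <= lo <= hi <= 1.0

    def test_lonely_psu_handled(self):
        y = np.array([1, 0, 1, 0, 1])
        d = SurveyDesign(np.ones(5), ["a", "a", "b", "b", "c"],
                         ["s1", "s1", "s1", "s1", "s2"])
        p, se, _ = weighted_prevalence(y, d)
        assert np.isfinite(se)


class TestCrosstab:
    def test_example(self):
        tab = crosstab([1, 1, 0], [1, 0, 0])
        assert (tab.n11, tab.n10, tab.n01, tab.n00) == (1, 1, 0, 1)

    def test_marginals_match_outcome_sums(self):
        rng = np.random.default_rng(3)
        y1 = rng.integers(0, 2, 300)
        y2 = rng.integers(0, 2, 300)
        tab = crosstab(y1, y2)
        assert tab.n11 + tab.n10 == y1.sum()
        assert tab.n11 + tab.n01 == y2.sum()
        assert tab.n == 300

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        y1 = rng.integers(0, 2, 100)
        y2 = rng.integers(0, 2, 100)
        perm = rng.permutation(100)
        assert crosstab(y1, y2) == crosstab(y1[perm], y2[perm])


class TestReconstructedTable:
    def test_counts_from_published_margins(self):
        """n=4162 with 30.39% stunted, 6.65% wasted, 1.68% both."""
        tab = table_from_percentages(4162, 30.39, 6.65, 1.68)
        assert (tab.n11, tab.n10, tab.n01, tab.n00) == (70, 1195, 207, 2690)
        # and the rounding reproduces the printed percentages to 2 d.p.
        assert round(100 * (tab.n11 + tab.n10) / tab.n, 2) == 30.39
        assert round(100 * (tab.n11 + tab.n01) / tab.n, 1) == 6.7
        assert round(100 * tab.n11 / tab.n, 2) == 1.68


class TestChisq:
    def test_independent_table_is_zero(self):
        stat, df, p = chisq_association(TwoByTwo(10, 10, 10, 10),
                                        correction=False)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_correction_never_increases_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = TwoByTwo(*(int(x) for x in rng.integers(1, 200, 4)))
            s_corr, _, _ = chisq_association(t, correction=True)
            s_raw, _, _ = chisq_association(t, correction=False)
            assert s_corr <= s_raw + 1e-12

    def test_uncorrected_equals_closed_form(self):
        """n (n11 n00 - n10 n01)^2 / (r1 r0 c1 c0), the textbook identity."""
        t = TwoByTwo(70, 1195, 207, 2690)
        stat, _, _ = chisq_association(t, correction=False)
        n = t.n
        r1, r0 = t.n11 + t.n10, t.n01 + t.n00
        c1, c0 = t.n11 + t.n01, t.n10 + t.n00
        closed = n * (t.n11 * t.n00 - t.n10 * t.n01) ** 2 / (r1 * r0 * c1 * c0)
        assert stat == pytest.approx(closed, abs=1e-10)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            chisq_association(TwoByTwo(0, 0, 5, 5))


class TestPrevalenceTable:
    def test_structure_and_overall_row(self, small_survey):
        cfg, df, _ = small_survey
        from dualburden.preprocess import classify_frame

        clean, _ = classify_frame(df)
        tab = prevalence_table(clean)
        assert tab.iloc[0]["variable"] == "overall"
        for col in ("stunting_pct", "wasting_pct", "both_pct"):
            assert (tab[col] >= 0).all() and (tab[col] <= 100).all()
        sexes = tab[tab["variable"] == "sex"]["level"].tolist()
        assert set(sexes) == {"male", "female"}
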