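"""Panel construction, scoring, quartile dose-response."""

import math

import numpy as np
import pandas as pd
import pytest

import polyrisk as pr
from polyrisk.grs import (DegenerateCutpointsWarning, assign_quartiles,
                          quartile_or_table)


class TestBuildPanel:
    def test_bonferroni_variant_weights(self, reference_table):
        panel = pr.build_panel(reference_table, "B", m=38, weight_column="odds_ratio")
        assert len(panel.snp_ids) == 6
        assert panel.weights["rs879882"] == pytest.approx(math.log(1.63))

    def test_hla_variant_is_single_proxy(self, reference_table):
        panel = pr.build_panel(reference_table, "HLA", weight_column="odds_ratio")
        assert panel.snp_ids == ("rs4406273",)

    def test_substituted_variant_swaps_proxy_with_own_weight(self, reference_table):
        n = pr.build_panel(reference_table, "N", weight_column="odds_ratio")
        sub = pr.build_panel(reference_table, "N(subst.)", weight_column="odds_ratio")
        assert "rs4406273" in n.snp_ids and "rs4406273" not in sub.snp_ids
        assert "rs10484554" in sub.snp_ids
        assert sub.weights["rs10484554"] == pytest.approx(math.log(2.80))
        assert len(sub.snp_ids) == len(n.snp_ids)

    def test_hla_removed_variant(self, reference_table):
        n = pr.build_panel(reference_table, "N", weight_column="odds_ratio")
        minus = pr.build_panel(reference_table, "N+HLA-", weight_column="odds_ratio")
        assert set(minus.snp_ids) == set(n.snp_ids) - {"rs4406273"}

    def test_unit_or_contributes_zero_weight(self, reference_table):
        panel = pr.build_panel(reference_table, "ALL", weight_column="odds_ratio")
        assert panel.weights["rs7007032"] == pytest.approx(0.0)

    def test_missing_required_snp_named(self, reference_table):
        crippled = reference_table[reference_table["snp_id"] != "rs4406273"]
        with pytest.raises(ValueError, match="rs4406273"):
            pr.build_panel(crippled, "HLA", weight_column="odds_ratio")


class TestScore:
    @pytest.fixture()
    def two_snp_setup(self):
        panel = pr.GrsPanel(name="custom", snp_ids=("rs3212227", "rs879882"),
                            weights={"rs3212227": math.log(1.69),
                                     "rs879882": math.log(1.63)})
        dos = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [np.nan, 2.0]],
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
            columns=["rs3212227", "rs879882"])
        return panel, pr.GenotypeMatrix(dos)

    def test_weighted_sum_arithmetic(self, two_snp_setup):
        panel, gm = two_snp_setup
        ss = pr.score(gm, panel)
        assert ss.scores["s1"] == 0.0
        assert ss.scores["s2"] == pytest.approx(math.log(1.69), abs=1e-12)
        assert ss.scores["s2"] == pytest.approx(0.525, abs=1e-3)
        assert ss.scores["s3"] == pytest.approx(2 * math.log(1.69) + math.log(1.63))
        assert ss.scores["s3"] == pytest.approx(1.539, abs=1e-3)

    def test_missing_panel_dosage_flags_incomplete(self, two_snp_setup):
        panel, gm = two_snp_setup
        ss = pr.score(gm, panel)
        assert not ss.complete["s4"]
        assert np.isnan(ss.scores["s4"])
        assert ss.n_excluded == 1
        assert list(ss.complete_scores().index) == ["s1", "s2", "s3"]

    def test_imputation_keeps_incomplete_flag_but_fills_score(self, two_snp_setup):
        panel, gm = two_snp_setup
        ss = pr.score(gm, panel, impute_missing=True)
        assert not ss.complete["s4"]
        # mean dosage of rs3212227 over s1-s3 is 1.0
        assert ss.scores["s4"] == pytest.approx(
            1.0 * math.log(1.69) + 2.0 * math.log(1.63))

    def test_snp_order_irrelevant(self, two_snp_setup):
        panel, gm = two_snp_setup
        flipped = pr.GrsPanel(name="custom", snp_ids=panel.snp_ids[::-1],
                              weights=dict(panel.weights))
        a = pr.score(gm, panel).scores
        b = pr.score(gm, flipped).scores
        pd.testing.assert_series_equal(a, b)

    @pytest.mark.parametrize("start", [0.0, 1.0])
    def test_monotone_in_dosage_under_positive_weight(self, two_snp_setup, start):
        panel, gm = two_snp_setup
        base = gm.dosages.copy()
        base.loc["s2", "rs3212227"] = start
        bumped = base.copy()
        bumped.loc["s2", "rs3212227"] = start + 1
        low = pr.score(pr.GenotypeMatrix(base), panel).scores["s2"]
        high = pr.score(pr.GenotypeMatrix(bumped), panel).scores["s2"]
        assert high > low


class TestQuartiles:
    def test_even_split_of_490_controls(self):
        rng = np.random.default_rng(99)
        scores = pd.Series(rng.normal(size=490),
                           index=[f"c{i}" for i in range(490)])
        cuts = pr.quartile_cutpoints(scores)
        q = assign_quartiles(scores, cuts)
        assert q.value_counts().sort_index().tolist() == [123, 122, 122, 123]

    def test_combined_reference_splits_evenly(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        cuts = pr.quartile_cutpoints(scores)
        q = assign_quartiles(scores, cuts)
        assert q.value_counts().sort_index().tolist() == [2, 2, 2, 2]

    def test_tied_scores_warn(self):
        scores = pd.Series(np.ones(40), index=[f"s{i}" for i in range(40)])
        with pytest.warns(DegenerateCutpointsWarning):
            pr.quartile_cutpoints(scores)

    def test_too_few_reference_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            pr.quartile_cutpoints(pd.Series([1.0, 2.0, 3.0]))


def _quartile_fixture(counts):
    """Scores/phenotypes realizing given per-quartile (case, ctrl) counts."""
    rows = []
    sid = 0
    for k, (n_case, n_ctrl) in enumerate(counts, start=1):
        for status, n in (("case", n_case), ("control", n_ctrl)):
            for _ in range(n):
                rows.append((f"s{sid:04d}", status, k - 0.5))
                sid += 1
    ids = [r[0] for r in rows]
    scores = pd.Series([r[2] for r in rows], index=ids)
    ph = pd.DataFrame({
        "sample_id": ids,
        "status": [r[1] for r in rows],
        "onset_class": ["T1Ps" if r[1] == "case" else "none" for r in rows],
        "nail": "unknown", "psa": "unknown", "family_history": "unknown",
    })
    return scores, ph, np.array([1.0, 2.0, 3.0])


class TestQuartileOrTable:
    COUNTS = [(26, 123), (39, 122), (90, 122), (317, 123)]

    def test_reproduces_published_dose_response(self):
        scores, ph, cuts = _quartile_fixture(self.COUNTS)
        rep = quartile_or_table(scores, ph, cuts)
        t = rep.table.set_index("quartile")
        assert t.loc[1, "or"] == 1.0
        assert round(t.loc[2, "or"], 2) == 1.51
        assert round(t.loc[3, "or"], 2) == 3.49
        assert t.loc[4, "pct_case"] == pytest.approx(67.2, abs=0.05)
        # top-quartile count-ratio estimate, reported as computed
        assert t.loc[4, "or"] == pytest.approx(317 * 123 / (123 * 26), rel=1e-12)
        assert (t["n_ctrl"] == [123, 122, 122, 123]).all()

    def test_logistic_route_matches_count_ratios(self):
        scores, ph, cuts = _quartile_fixture(self.COUNTS)
        by_counts = quartile_or_table(scores, ph, cuts, method="counts").table
        by_model = quartile_or_table(scores, ph, cuts, method="logistic").table
        np.testing.assert_allclose(by_model["or"], by_counts["or"], rtol=1e-5)

    def test_flat_counts_give_unit_ors(self):
        scores, ph, cuts = _quartile_fixture([(30, 30)] * 4)
        t = quartile_or_table(scores, ph, cuts).table
        np.testing.assert_allclose(t["or"], 1.0)

    def test_empty_reference_quartile_rejected(self):
        scores, ph, cuts = _quartile_fixture([(0, 5), (5, 5), (5, 5), (5, 5)])
        with pytest.raises(ValueError, match="bottom quartile"):
            quartile_or_table(scores, ph, cuts)


def test_dose_response_monotone_on_simulated_cohorts(nominal_spec):
    from dataclasses import replace

    monotone = 0
    reps = 10
    for rep in range(reps):
        spec = replace(nominal_spec, seed=800 + rep, subpheno_effects={})
        gm, ph, meta = pr.simulate_cohort(spec)
        res = pr.GrsStudy(gm, ph, meta).fit(variants=("N",))
        t = res.quartiles("N").table
        ors = t["or"].to_numpy()
        monotone += bool(np.all(np.diff(ors) > 0))
    assert monotone >= 0.9 * reps
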