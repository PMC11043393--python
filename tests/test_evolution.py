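import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rtturnover import evolution
from rtturnover.core import ElementSet, HomologyHit, MarkMatrix, ValidationError, VariantTable


def eset(rows, **extra):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for key, vals in extra.items():
        df[key] = vals
    return ElementSet(df)


class TestConsensusPeaks:
    def test_identical_peaks_retained(self):
        rep = eset([("chr1", 0, 100)])
        out = evolution.consensus_peaks([rep, rep])
        assert out.df[["start", "end"]].to_numpy().tolist() == [[0, 100]]

    def test_insufficient_overlap_dropped(self):
        a = eset([("chr1", 0, 100)])
        b = eset([("chr1", 60, 100)])  # covers 40% of the merged candidate
        out = evolution.consensus_peaks([a, b])
        assert len(out) == 0

    def test_sixty_percent_overlap_retained(self):
        a = eset([("chr1", 0, 100)])
        b = eset([("chr1", 40, 100)])  # 60% of candidate [0,100)
        out = evolution.consensus_peaks([a, b])
        assert len(out) == 1
        assert out.df.iloc[0]["end"] - out.df.iloc[0]["start"] == 100

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            evolution.consensus_peaks([eset([("chr1", 0, 100)])])


class TestClassifyAge:
    def _marks(self, rows):
        species = ["focal"] + [f"s{i}" for i in range(1, 5)]
        ids = [f"e{i}" for i in range(len(rows))]
        return MarkMatrix(ids, species, np.array(rows, dtype=bool))

    def test_focal_only_is_recent(self):
        marks = self._marks([[1, 0, 0, 0, 0]])
        assert evolution.classify_age(marks).iloc[0] == "recent"

    def test_two_other_species_is_conserved(self):
        marks = self._marks([[1, 1, 1, 0, 0], [1, 1, 0, 0, 0]])
        ages = evolution.classify_age(marks)
        assert ages.tolist() == ["conserved", "recent"]

    def test_stricter_threshold_reclassifies(self):
        marks = self._marks([[1, 1, 1, 1, 0], [1, 1, 1, 1, 1]])
        loose = evolution.classify_age(marks, min_other_species=2)
        strict = evolution.classify_age(marks, min_other_species=4)
        assert loose.tolist() == ["conserved", "conserved"]
        assert strict.tolist() == ["recent", "conserved"]

    def test_focal_column_must_be_present(self):
        with pytest.raises(ValidationError):
            MarkMatrix(["e0"], ["focal", "s1"], np.array([[0, 1]], dtype=bool))


class TestTurnoverTable:
    def _elements(self, ages, groups, rt=None):
        n = len(ages)
        rows = [("chr1", i * 1000, i * 1000 + 500) for i in range(n)]
        extra = {"age": ages, "rt_quintile": groups}
        if rt is not None:
            extra["rt"] = rt
        return eset(rows, **extra)

    def test_balanced_counts_give_zero_log_ratio(self):
        el = self._elements(["recent"] * 100 + ["conserved"] * 100, [1] * 200)
        table = evolution.turnover_by_group(el)
        assert table["log_ratio"].iloc[0] == pytest.approx(0.0)

    def test_two_to_one_ratio_is_ln2(self):
        el = self._elements(["recent"] * 200 + ["conserved"] * 100, [1] * 300)
        table = evolution.turnover_by_group(el)
        assert table["log_ratio"].iloc[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_zero_count_gives_na_with_warning(self):
        el = self._elements(["recent"] * 10, [1] * 10)
        with pytest.warns(RuntimeWarning, match="zero age count"):
            table = evolution.turnover_by_group(el)
        assert np.isnan(table["log_ratio"].iloc[0])
        with_alpha = evolution.turnover_by_group(el, pseudocount=0.5)
        assert np.isfinite(with_alpha["log_ratio"].iloc[0])

    def test_counts_conserved_across_groups(self):
        rng = np.random.default_rng(0)
        ages = rng.choice(["recent", "conserved"], 500)
        groups = rng.integers(1, 6, 500)
        table = evolution.turnover_by_group(self._elements(ages, groups))
        assert (table["n_recent"] + table["n_conserved"]).sum() == 500


class TestRecentProbabilityRatio:
    def _elements(self, n_late_recent, n_late, n_early_recent, n_early):
        ages = (
            ["recent"] * n_late_recent
            + ["conserved"] * (n_late - n_late_recent)
            + ["recent"] * n_early_recent
            + ["conserved"] * (n_early - n_early_recent)
        )
        classes = ["late"] * n_late + ["early"] * n_early
        rows = [("chr1", i * 1000, i * 1000 + 500) for i in range(len(ages))]
        return eset(rows, age=ages, rt_class=classes)

    def test_twice_the_recent_fraction(self):
        el = self._elements(10, 20, 5, 20)  # 0.5 late vs 0.25 early
        assert evolution.recent_probability_ratio(el) == pytest.approx(2.0)

    def test_equal_fractions_give_one(self):
        el = self._elements(5, 20, 5, 20)
        assert evolution.recent_probability_ratio(el) == pytest.approx(1.0)

    def test_scale_invariance_under_duplication(self):
        el = self._elements(7, 20, 4, 15)
        doubled = ElementSet(pd.concat([el.df, el.df.assign(start=el.df.start + 10_000_000,
                                                            end=el.df.end + 10_000_000)]))
        assert evolution.recent_probability_ratio(doubled) == pytest.approx(
            evolution.recent_probability_ratio(el)
        )

    def test_empty_class_errors(self):
        el = self._elements(5, 20, 0, 0)
        with pytest.raises(ValidationError):
            evolution.recent_probability_ratio(el)


class TestTurnoverRegression:
    def test_collinear_points_closed_form(self):
        table = pd.DataFrame({"mean_rt": [-1.0, 0.0, 1.0], "log_ratio": [1.0, 0.0, -1.0]})
        fit = evolution.regress_turnover_rt(table)
        assert fit["slope"] == pytest.approx(-1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_p_uniform_under_permutation_null(self):
        rng = np.random.default_rng(0)
        pvals = []
        x = np.linspace(-1, 1, 12)
        y = rng.normal(0, 1, 12)
        for _ in range(300):
            pvals.append(
                evolution.regress_turnover_rt(
                    pd.DataFrame({"mean_rt": x, "log_ratio": rng.permutation(y)})
                )["p_two_sided"]
            )
        # permutation p values should look uniform on [0,1]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_groups(self):
        table = pd.DataFrame({"mean_rt": [0.0, 1.0], "log_ratio": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            evolution.regress_turnover_rt(table)


class TestTissueInteraction:
    def _table(self, slope_a, slope_b, noise_seed=0, n=18, sd=0.05):
        rng = np.random.default_rng(noise_seed)
        rt = np.linspace(-1.5, 1.5, n)
        rows = []
        for pair, slope in ((0, slope_a), (1, slope_b)):
            y = slope * rt + rng.normal(0, sd, n)
            rows.extend(zip(y, rt, [pair] * n))
        return pd.DataFrame(rows, columns=["log_ratio", "mean_rt", "tissue_pair"])

    def test_identical_slopes_give_null_interaction(self):
        table = self._table(-0.4, -0.4)
        res = evolution.tissue_interaction_test(table)
        assert abs(res["interaction_t"]) < 2.0
        assert res["p"] > 0.05

    def test_different_slopes_detected(self):
        table = self._table(-0.2, -0.8)
        res = evolution.tissue_interaction_test(table)
        assert res["p"] < 1e-6
        assert res["interaction_t"] < 0

    def test_unidentifiable_model_errors(self):
        table = pd.DataFrame(
            {"log_ratio": [0.0, 1.0, 2.0], "mean_rt": [0.0, 1.0, 2.0], "tissue_pair": [0, 1, 0]}
        )
        with pytest.raises(ValidationError):
            evolution.tissue_interaction_test(table)


class TestIntervalEnrichment:
    def _setup(self, table):
        """Build element/label/overlap geometry realizing a given 2x2 table."""
        (a, b), (c, d) = table
        rows, labels, b_rows = [], [], []
        pos = 0
        for count, label, hit in ((a, 1, 1), (b, 1, 0), (c, 0, 1), (d, 0, 0)):
            for _ in range(count):
                rows.append(("chr1", pos, pos + 100))
                labels.append(label)
                if hit:
                    b_rows.append(("chr1", pos, pos + 100))
                pos += 1000
        set_b = (
            eset(b_rows)
            if b_rows
            else ElementSet(pd.DataFrame(columns=["chrom", "start", "end"]), validate=False)
        )
        return eset(rows), np.array(labels, dtype=bool), set_b

    def test_balanced_table(self):
        set_a, labels, set_b = self._setup([[10, 10], [10, 10]])
        res = evolution.interval_enrichment(set_a, labels, set_b)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_or_sixteen_matches_hypergeometric(self):
        set_a, labels, set_b = self._setup([[8, 2], [2, 8]])
        res = evolution.interval_enrichment(set_a, labels, set_b)
        assert res["odds_ratio"] == pytest.approx(16.0)
        # exhaustive hypergeometric two-sided oracle
        dist = sps.hypergeom(20, 10, 10)
        pmf = dist.pmf(np.arange(0, 11))
        p_oracle = pmf[pmf <= pmf[8] * (1 + 1e-7)].sum()
        assert res["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_empty_b_set_gives_na_with_warning(self):
        set_a, labels, set_b = self._setup([[0, 5], [0, 5]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = evolution.interval_enrichment(set_a, labels, set_b)
        assert np.isnan(res["odds_ratio"])

    def test_min_overlap_fraction_rule(self):
        # B covers 25% of the single labeled element: only frac <= 0.25 counts it
        set_a = eset([("chr1", 0, 100), ("chr1", 1000, 1100)])
        labels = np.array([True, False])
        set_b = eset([("chr1", 0, 25)])
        with pytest.warns(RuntimeWarning):  # one-row label class makes the OR degenerate
            loose = evolution.interval_enrichment(set_a, labels, set_b, min_overlap_frac=0.25)
            strict = evolution.interval_enrichment(set_a, labels, set_b, min_overlap_frac=0.3)
        assert loose["table"][0, 0] == 1
        assert strict["table"][0, 0] == 0


class TestSingletons:
    def test_no_hits_all_singletons(self):
        res = evolution.singleton_analysis([], ["a", "b", "c"])
        assert res["singleton_fraction"] == pytest.approx(1.0)

    def test_one_reciprocal_pair_among_four(self):
        hits = [
            HomologyHit("a", "b", 1e-10, 50.0),
            HomologyHit("b", "a", 1e-10, 50.0),
        ]
        res = evolution.singleton_analysis(hits, ["a", "b", "c", "d"])
        assert res["singleton_fraction"] == pytest.approx(0.5)
        assert sorted(len(c) for c in res["components"]) == [1, 1, 2]

    def test_evalue_cutoff_is_strict(self):
        at_cutoff = [HomologyHit("a", "b", 1e-6, 50.0)]
        res = evolution.singleton_analysis(at_cutoff, ["a", "b"])
        assert res["singleton_fraction"] == pytest.approx(1.0)
        below = [HomologyHit("a", "b", 0.999e-6, 50.0)]
        res2 = evolution.singleton_analysis(below, ["a", "b"])
        assert res2["singleton_fraction"] == pytest.approx(0.0)

    def test_coverage_cutoff_and_self_hits(self):
        hits = [
            HomologyHit("a", "a", 0.0, 100.0),  # self hit ignored
            HomologyHit("a", "b", 1e-10, 20.0),  # coverage not strictly > 20
        ]
        res = evolution.singleton_analysis(hits, ["a", "b"])
        assert res["singleton_fraction"] == pytest.approx(1.0)


class TestExpectedSubstitutions:
    def test_human_macaque_inputs(self):
        val = evolution.expected_substitutions_per_kb(29, 25, 1.28e-8)
        assert val == pytest.approx(14.848)
        assert round(val) == 15

    def test_mouse_rat_inputs(self):
        assert evolution.expected_substitutions_per_kb(12, 0.5, 5e-9) == pytest.approx(120.0)

    def test_zero_divergence(self):
        assert evolution.expected_substitutions_per_kb(0, 25, 1e-8) == 0.0


class TestCancerTurnover:
    def test_disjoint_sets_all_gained_and_lost(self):
        healthy = eset([("chr1", 0, 1000)])
        tumor = eset([("chr1", 5000, 6000)])
        out = evolution.classify_cancer_turnover(healthy, tumor)
        fates = sorted(out.df["fate"])
        assert fates == ["gained", "lost"]

    def test_identical_sets_all_unchanged(self):
        peaks = eset([("chr1", 0, 1000), ("chr1", 5000, 6000)])
        out = evolution.classify_cancer_turnover(peaks, peaks)
        assert (out.df["fate"] == "unchanged").all()
        assert len(out) == 2

    def test_reciprocal_overlap_of_shorter_element(self):
        healthy = eset([("chr1", 0, 1000)])
        tumor = eset([("chr1", 700, 1100)])  # overlap 300 = 75% of the shorter (400)
        out = evolution.classify_cancer_turnover(healthy, tumor, min_overlap_frac=0.5)
        assert (out.df["fate"] == "unchanged").all()
        strict = evolution.classify_cancer_turnover(healthy, tumor, min_overlap_frac=0.8)
        assert sorted(strict.df["fate"]) == ["gained", "lost"]


class TestMutationBurden:
    def test_burden_arithmetic(self):
        el = eset([("chr1", 0, 1000)], fate=["unchanged"])
        somatic = VariantTable(
            pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 500], "daf": [0.0, 0.0]})
        )
        out = evolution.mutation_burden(el, somatic)
        assert out.df["burden"].iloc[0] == pytest.approx(0.002)

    def test_zero_variants_use_epsilon_in_log(self):
        el = eset([("chr1", 0, 1000)])
        somatic = VariantTable(pd.DataFrame({"chrom": [], "pos": [], "daf": []}))
        out = evolution.mutation_burden(el, somatic, log_epsilon=1e-5)
        assert out.df["burden"].iloc[0] == 0.0
        assert out.df["log_burden"].iloc[0] == pytest.approx(-5.0)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", i * 2000, i * 2000 + 1000) for i in range(100)]
        el = eset(rows, fate=["gained"] * 50 + ["lost"] * 50)
        positions = rng.integers(0, 200_000, 400)
        somatic = VariantTable(
            pd.DataFrame({"chrom": "chr1", "pos": positions, "daf": 0.0})
        )
        out = evolution.mutation_burden(el, somatic)
        res = evolution.burden_group_test(out, "gained", "lost")
        assert res["p"] > 0.05


class TestGainLossProportions:
    def _fated(self, per_quintile):
        rows, fates, quints = [], [], []
        pos = 0
        for q, (g, l, u) in per_quintile.items():
            for fate, n in (("gained", g), ("lost", l), ("unchanged", u)):
                for _ in range(n):
                    rows.append(("chr1", pos, pos + 100))
                    fates.append(fate)
                    quints.append(q)
                    pos += 1000
        return eset(rows, fate=fates, rt_quintile=quints)

    def test_flat_profile_for_equal_counts(self):
        fated = self._fated({q: (5, 5, 10) for q in range(1, 6)})
        table = evolution.gainloss_quintile_proportions(fated)
        assert np.allclose(table["gain_proportion"], 0.5)
        assert np.allclose(table["loss_proportion"], -0.5)

    def test_zero_unchanged_quintile_is_na(self):
        fated = self._fated({1: (5, 5, 0), 2: (5, 5, 10)})
        with pytest.warns(RuntimeWarning, match="no unchanged"):
            table = evolution.gainloss_quintile_proportions(fated)
        assert np.isnan(table.loc[table["rt_quintile"] == 1, "gain_proportion"].iloc[0])
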