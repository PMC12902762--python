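import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

import tierscreen as ts
from tierscreen.dta import (
    CorrectnessHistogram, any_disorder, confusion, cutoff_sweep,
    per_individual_correctness, pooled_positive_identification,
    prevalence_and_comorbidity, table_from_marginals,
)
from conftest import TABLE4, TABLE4_N


def random_table(rng, n=70):
    cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
    if cells.sum() == 0:
        cells[0] = 1
    return ts.ConfusionTable(*[int(c) for c in cells])


def table_to_vectors(table):
    test = [1] * table.tp + [1] * table.fp + [0] * table.fn + [0] * table.tn
    ref = [1] * table.tp + [0] * table.fp + [1] * table.fn + [0] * table.tn
    return np.array(test), np.array(ref)


class TestConcordanceTableReconstruction:
    @pytest.mark.parametrize("disorder", list(TABLE4))
    def test_published_cells_reproduce(self, disorder):
        row = TABLE4[disorder]
        table = table_from_marginals(TABLE4_N, row["ref"], row["test"],
                                     row["conc"])
        assert table.n == TABLE4_N and table.n_pos_index == row["test"]
        report = ts.metrics(table)
        assert report.sensitivity.rounded() == row["sens"]
        assert report.specificity.rounded() == row["spec"]
        assert report.ppv.rounded() == row["ppv"]
        assert report.npv.rounded() == row["npv"]
        assert report.accuracy.rounded() == row["acc"]
        from tierscreen._util import round_half_up
        assert round_half_up(report.kappa, 2) == row["kappa"]

    def test_depression_cell_assignment(self):
        table = table_from_marginals(70, 20, 33, 19)
        assert (table.tp, table.fp, table.fn, table.tn) == (19, 14, 1, 36)


class TestConfusion:
    def test_agreeing_flags_have_no_errors(self):
        idx = pd.Index(["a", "b", "c"])
        flags = pd.Series([True, False, True], index=idx)
        table = confusion(flags, flags.copy())
        assert table.fp == table.fn == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ts.DTAError, match="empty"):
            confusion(pd.Series(dtype=bool), pd.Series(dtype=bool))

    def test_id_mismatch_rejected(self):
        flags = pd.Series([True], index=["a"])
        labels = pd.Series([True], index=["b"])
        with pytest.raises(ts.DTAError, match="different respondents"):
            confusion(flags, labels)

    def test_matches_per_respondent_recount(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            idx = pd.Index([f"r{i}" for i in range(n)])
            flags = pd.Series(rng.random(n) < 0.5, index=idx)
            labels = pd.Series(rng.random(n) < 0.4, index=idx)
            table = confusion(flags, labels)
            tp = sum(bool(f) and bool(l) for f, l in zip(flags, labels))
            fp = sum(bool(f) and not l for f, l in zip(flags, labels))
            fn = sum(not f and bool(l) for f, l in zip(flags, labels))
            assert (table.tp, table.fp, table.fn) == (tp, fp, fn)
            assert table.n == n


class TestMetrics:
    def test_perfect_table_all_hundred(self):
        report = ts.metrics(ts.ConfusionTable(tp=1, fp=0, fn=0, tn=1))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(report, name).value == pytest.approx(100.0)

    def test_undefined_metric_flagged_not_zero(self):
        report = ts.metrics(ts.ConfusionTable(tp=0, fp=3, fn=0, tn=7))
        assert not report.sensitivity.defined
        with pytest.raises(ts.DTAError):
            report.sensitivity.rounded()
        assert report.specificity.defined and report.accuracy.defined

    def test_identities_on_random_tables(self, rng):
        for _ in range(200):
            t = random_table(rng)
            r = ts.metrics(t)
            if r.accuracy.defined:
                assert r.accuracy.value / 100 * t.n == pytest.approx(t.tp + t.tn)
            # Bayes consistency of PPV with sens/spec/prevalence
            if all(e.defined for e in (r.sensitivity, r.specificity, r.ppv)):
                se, sp = r.sensitivity.value / 100, r.specificity.value / 100
                prev = (t.tp + t.fn) / t.n
                denom = se * prev + (1 - sp) * (1 - prev)
                if denom > 0:
                    assert r.ppv.value / 100 == pytest.approx(
                        se * prev / denom, abs=1e-12)

    def test_wald_ci_matches_statsmodels(self, rng):
        # statsmodels uses the exact 97.5% quantile; pass it in so the
        # formula itself is what gets cross-checked (the package default
        # z=1.96 is the conventional reporting value)
        from scipy import stats
        z = stats.norm.ppf(0.975)
        for _ in range(50):
            m = int(rng.integers(2, 100))
            k = int(rng.integers(0, m + 1))
            lo, hi = ts.wald_ci(k / m, m, z=z)
            slo, shi = proportion_confint(k, m, alpha=0.05, method="normal")
            assert lo == pytest.approx(max(0.0, slo * 100), abs=1e-9)
            assert hi == pytest.approx(min(100.0, shi * 100), abs=1e-9)

    def test_wald_coverage_in_documented_band(self, rng):
        """Wald 95% CI on n=70, p=0.8: empirical coverage 90-97%
        (the known undercoverage is tolerated, not corrected)."""
        p, n, reps = 0.8, 70, 2000
        hits = 0
        draws = rng.binomial(n, p, size=reps)
        for k in draws:
            lo, hi = ts.wald_ci(k / n, n)
            hits += lo <= p * 100 <= hi
        assert 0.90 <= hits / reps <= 0.97


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert ts.cohen_kappa(ts.ConfusionTable(9, 0, 0, 21)) == pytest.approx(1.0)

    def test_exact_independence_gives_zero(self):
        # cells are exact products of margins / n: 50 * 0.4 * 0.3 etc.
        table = ts.ConfusionTable(tp=6, fp=14, fn=9, tn=21)
        assert ts.cohen_kappa(table) == pytest.approx(0.0, abs=1e-12)

    def test_constant_raters_undefined(self):
        with pytest.raises(ts.DTAError, match="undefined"):
            ts.cohen_kappa(ts.ConfusionTable(tp=10, fp=0, fn=0, tn=0))

    def test_matches_sklearn_on_random_tables(self, rng):
        for _ in range(100):
            t = random_table(rng)
            test, ref = table_to_vectors(t)
            if len(set(test)) == 1 and len(set(ref)) == 1:
                continue
            expected = cohen_kappa_score(test, ref)
            if np.isnan(expected):
                continue
            assert ts.cohen_kappa(t) == pytest.approx(expected, abs=1e-12)

    def test_bound_properties(self, rng):
        for _ in range(100):
            t = random_table(rng)
            try:
                kappa = ts.cohen_kappa(t)
            except ts.DTAError:
                continue
            po = (t.tp + t.tn) / t.n
            assert kappa <= po + 1e-12
            if t.fp == 0 and t.fn == 0:
                assert kappa == pytest.approx(1.0)
            elif kappa == pytest.approx(1.0):
                assert t.fp == 0 and t.fn == 0


class TestAggregation:
    def test_any_disorder_is_logical_or(self):
        flags = pd.DataFrame(
            [[False] * 4, [False, True, False, False]],
            columns=list(ts.DISORDERS), index=["a", "b"])
        assert any_disorder(flags).tolist() == [False, True]

    def test_any_confusion_from_headline_counts(self):
        table = table_from_marginals(70, 36, 41, 33)
        assert (table.tp, table.fp, table.fn, table.tn) == (33, 8, 3, 26)

    def test_pooled_identification_of_printed_counts(self):
        tables = [
            table_from_marginals(70, 20, 33, 19),   # 19/20 depression
            table_from_marginals(70, 17, 25, 13),   # 13/17 anxiety
            table_from_marginals(70, 20, 27, 16),   # 16/20 PTSD
            ts.ConfusionTable(tp=21, fp=11, fn=6, tn=32),  # 21/27 insomnia
        ]
        from tierscreen._util import round_half_up
        assert round_half_up(pooled_positive_identification(tables), 1) == 82.1

    def test_pooled_perfect_and_single_table(self):
        perfect = [ts.ConfusionTable(5, 0, 0, 5), ts.ConfusionTable(3, 0, 0, 7)]
        assert pooled_positive_identification(perfect) == pytest.approx(100.0)
        single = ts.ConfusionTable(16, 11, 4, 39)
        assert pooled_positive_identification([single]) == pytest.approx(
            ts.metrics(single).sensitivity.value)


class TestPerIndividualCorrectness:
    def test_all_concordant(self):
        flags = pd.DataFrame(np.eye(4, dtype=bool), columns=list(ts.DISORDERS))
        hist = per_individual_correctness(flags, flags.copy())
        assert hist.counts[4] == 4 and hist.share_fully_correct == 100.0

    def test_single_false_negative(self):
        flags = pd.DataFrame([[False] * 4], columns=list(ts.DISORDERS))
        labels = pd.DataFrame([[True, False, False, False]],
                              columns=list(ts.DISORDERS))
        hist = per_individual_correctness(flags, labels)
        assert hist.counts[3] == 1
        assert hist.false_negative_failures == 1
        assert hist.false_positive_failures == 0

    def test_matches_brute_force_recount(self, rng):
        n = 60
        idx = pd.Index([f"r{i}" for i in range(n)])
        flags = pd.DataFrame(rng.random((n, 4)) < 0.4,
                             columns=list(ts.DISORDERS), index=idx)
        labels = pd.DataFrame(rng.random((n, 4)) < 0.35,
                              columns=list(ts.DISORDERS), index=idx)
        hist = per_individual_correctness(flags, labels)
        for k in range(5):
            brute = sum(
                sum(flags.loc[i, d] == labels.loc[i, d]
                    for d in ts.DISORDERS) == k
                for i in idx)
            assert hist.counts[k] == brute
        assert sum(hist.counts.values()) == n


class TestCutoffSweep:
    def test_degenerate_cutoffs(self, rng):
        scores = pd.Series([3, 8, 12, 20], index=list("abcd"))
        labels = pd.Series([False, False, True, True], index=list("abcd"))
        sweep = cutoff_sweep(scores, labels, [0, 99])
        assert sweep[0].sensitivity.value == pytest.approx(100.0)
        assert sweep[0].specificity.value == pytest.approx(0.0)
        assert sweep[99].sensitivity.value == pytest.approx(0.0)
        assert sweep[99].specificity.value == pytest.approx(100.0)

    def test_sensitivity_non_increasing_in_cutoff(self, battery, rng):
        cohort = ts.generate_cohort(ts.CohortSpec(n=300, seed=5), battery)
        scores = cohort.dataset.responses[
            list(battery.scale("isi7").item_ids)].sum(axis=1)
        sweep = cutoff_sweep(scores, cohort.labels["insomnia"], [8, 11, 14])
        sens = [sweep[c].sensitivity.value for c in (8, 11, 14)]
        assert sens == sorted(sens, reverse=True)

    def test_empty_cutoff_list_rejected(self):
        with pytest.raises(ts.DTAError):
            cutoff_sweep(pd.Series([1]), pd.Series([True]), [])


class TestPrevalenceAndComorbidity:
    def test_no_diagnoses_all_zero(self):
        flags = pd.DataFrame(np.zeros((5, 4), bool), columns=list(ts.DISORDERS))
        rep = prevalence_and_comorbidity(flags, flags.copy())
        assert rep.reference_any == 0 and rep.test_any == 0
        assert all(v == 0 for v in rep.multimorbidity.values())

    def test_multimorbidity_share(self, rng):
        n = 70
        labels = pd.DataFrame(np.zeros((n, 4), bool),
                              columns=list(ts.DISORDERS))
        # exactly 23 respondents with two or more diagnoses
        labels.iloc[:23, :2] = True
        labels.iloc[23:36, 0] = True
        rep = prevalence_and_comorbidity(labels, labels)
        assert rep.multimorbidity[2] == 23
        from tierscreen._util import round_half_up
        assert round_half_up(rep.multimorbidity_percent(2), 1) == 32.9

    def test_pairwise_symmetric_and_bounded(self, rng):
        n = 40
        labels = pd.DataFrame(rng.random((n, 4)) < 0.4,
                              columns=list(ts.DISORDERS))
        rep = prevalence_and_comorbidity(labels, labels)
        pw = rep.pairwise
        assert (pw.values == pw.values.T).all()
        for d in ts.DISORDERS:
            assert (pw[d] <= pw.loc[d, d]).all()
            assert pw.loc[d, d] == rep.reference_counts[d]
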