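"""Correlation screen, confusion metrics, identity models, binning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxvar.contributions import ContributionProfile
from fluxvar.evaluation import (
    AlphaPolicy,
    EnvironmentBinEntry,
    PairOutcome,
    confusion_metrics,
    environment_bins,
    identity_misclassification_models,
    select_variable_metabolites,
    spearman_pair,
    spearman_screen,
    subgroup_consistency,
)


def make_outcomes(TP, FP, FN, TN, rho_key=0.9, rho_other=0.1):
    outcomes = []
    spec_counts = [(True, True, TP), (True, False, FP),
                   (False, True, FN), (False, False, TN)]
    i = 0
    for sig, key, count in spec_counts:
        for _ in range(count):
            outcomes.append(PairOutcome(
                species_id=f"s{i % 10}", metabolite_id=f"m{i // 10}",
                rho=rho_key if key else rho_other, p=0.001 if sig else 0.5,
                significant=sig, is_key_contributor=key,
            ))
            i += 1
    return outcomes


class TestVariableMetaboliteFilter:
    def test_quartile_rule(self):
        """Variances {0,1,2,3}: the 25th percentile is 0.75, so the three
        varying metabolites pass and the constant one never does."""
        base = np.array([1.0, 2.0, 3.0, 4.0, 0.0, 5.0])
        conc = pd.DataFrame({
            "m0": np.ones(6),
            "m1": base * math.sqrt(1.0 / base.var(ddof=1)),
            "m2": base * math.sqrt(2.0 / base.var(ddof=1)),
            "m3": base * math.sqrt(3.0 / base.var(ddof=1)),
        })
        assert select_variable_metabolites(conc) == {"m1", "m2", "m3"}

    def test_equal_variances_select_nothing(self):
        base = np.array([0.0, 1.0, 2.0])
        conc = pd.DataFrame({f"m{i}": base + i for i in range(5)})
        assert select_variable_metabolites(conc) == set()


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = spearman_pair(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_exact_null_matches_enumeration(self):
        """For n = 6 the p-value equals the exhaustive 6!-permutation tail
        probability, computed here by an independent brute force."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 5.7])
        rho, p = spearman_pair(x, y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = stats.pearsonr(rx, np.array(perm)).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_constant_series_is_na(self):
        rho, p = spearman_pair(np.ones(8), np.arange(8.0))
        assert math.isnan(rho) and math.isnan(p)

    def test_screen_excludes_undefined_pairs(self):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame({"s0": np.ones(10), "s1": rng.normal(size=10)})
        co = pd.DataFrame({"m0": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="constant series"):
            outcomes = spearman_screen(ab, co)
        assert len(outcomes) == 2
        undef = [o for o in outcomes if o.undefined]
        assert len(undef) == 1 and undef[0].species_id == "s0"
        report = confusion_metrics(outcomes, n_bootstrap=0)
        assert report.n_pairs == 1 and report.n_excluded == 1

    def test_bh_matched_policy_equivalent_to_raw_on_same_family(self):
        rng = np.random.default_rng(3)
        n = 20
        ab = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=[f"s{i}" for i in range(5)])
        co = pd.DataFrame(rng.normal(size=(n, 6)),
                          columns=[f"m{i}" for i in range(6)])
        co["m0"] = ab["s0"] * 2 + rng.normal(scale=0.05, size=n)
        raw = spearman_screen(ab, co, AlphaPolicy("raw", 0.01))
        matched = spearman_screen(ab, co, AlphaPolicy("bh-matched", 0.01))
        assert [o.significant for o in raw] == [o.significant for o in matched]

    def test_anticorrelated_competitor_is_false_positive(self):
        """Two strongly anticorrelated species, one of which drives a
        metabolite: both correlate significantly, so the non-contributor is
        called while contributing nothing (the false-positive mechanism)."""
        rng = np.random.default_rng(8)
        n = 20
        s0 = np.linspace(1.0, 2.0, n) + rng.normal(scale=0.02, size=n)
        s1 = 3.0 - s0 + rng.normal(scale=0.02, size=n)  # competitor
        met = 2.0 * s0 + rng.normal(scale=0.05, size=n)
        ab = pd.DataFrame({"driver": s0, "competitor": s1})
        co = pd.DataFrame({"met": met})
        outcomes = spearman_screen(
            ab, co, AlphaPolicy("raw", 0.01), key_links={("driver", "met")}
        )
        by_sp = {o.species_id: o for o in outcomes}
        assert by_sp["driver"].significant
        assert by_sp["competitor"].significant
        assert not by_sp["competitor"].is_key_contributor  # a false positive
        report = confusion_metrics(outcomes, n_bootstrap=0)
        assert report.FP == 1 and report.TP == 1


class TestConfusionMetrics:
    def test_rank_auc_matches_brute_force(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.3
        outcomes = [
            PairOutcome("s", f"m{i}", rho=scores[i], p=0.5,
                        significant=False, is_key_contributor=bool(labels[i]))
            for i in range(60)
        ]
        report = confusion_metrics(outcomes, n_bootstrap=0)
        pos = np.abs(scores[labels])
        neg = np.abs(scores[~labels])
        wins = sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in pos for b in neg
        )
        assert report.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_perfect_classifier(self):
        outcomes = make_outcomes(TP=10, FP=0, FN=0, TN=30)
        report = confusion_metrics(outcomes, n_bootstrap=50, seed=1)
        assert (report.sensitivity, report.specificity, report.ppv,
                report.accuracy, report.auc) == (1, 1, 1, 1, 1)

    def test_inverted_classifier(self):
        outcomes = make_outcomes(TP=0, FP=20, FN=10, TN=0)
        report = confusion_metrics(outcomes, n_bootstrap=0)
        assert report.sensitivity == 0 and report.specificity == 0

    def test_single_class_auc_is_na(self):
        outcomes = make_outcomes(TP=5, FP=5, FN=0, TN=0)
        outcomes = [o for o in outcomes if o.is_key_contributor]
        report = confusion_metrics(outcomes, n_bootstrap=0)
        assert math.isnan(report.auc)

    def test_relabeling_invariance(self):
        outcomes = make_outcomes(TP=7, FP=9, FN=4, TN=21)
        shuffled = list(reversed(outcomes))
        a = confusion_metrics(outcomes, n_bootstrap=0)
        b = confusion_metrics(shuffled, n_bootstrap=0)
        assert (a.TP, a.FP, a.FN, a.TN) == (b.TP, b.FP, b.FN, b.TN)
        assert a.auc == pytest.approx(b.auc)


class TestIdentityModels:
    def test_species_driven_false_positives(self):
        """FP outcomes generated by per-species Bernoulli rates: the species
        LRT is decisive, the metabolite LRT is not."""
        rng = np.random.default_rng(42)
        rates = {f"s{i}": r for i, r in enumerate([0.05, 0.1, 0.8, 0.9])}
        outcomes = []
        for sp, rate in rates.items():
            for j in range(40):
                sig = rng.random() < rate
                outcomes.append(PairOutcome(
                    sp, f"m{j % 8}", rho=0.2, p=0.5, significant=bool(sig),
                    is_key_contributor=False,
                ))
        reports = {r.stratum: r for r in identity_misclassification_models(outcomes)}
        nc = reports["non_contributors"]
        assert not nc.skipped
        assert nc.p_species < 1e-6
        assert nc.p_metabolite > 0.01
        assert reports["key_contributors"].skipped  # empty stratum

    def test_single_species_stratum_flagged(self):
        outcomes = [
            PairOutcome("only", f"m{j}", 0.1, 0.5, j % 2 == 0, False)
            for j in range(10)
        ]
        reports = {r.stratum: r for r in identity_misclassification_models(outcomes)}
        assert reports["non_contributors"].skipped

    def test_permutation_null_type_i_control(self):
        """With outcomes independent of identity, LRT p-values behave like a
        null: rejections at alpha = 0.1 stay within binomial bounds."""
        rng = np.random.default_rng(7)
        hits_sp = hits_met = 0
        n_rep = 30
        for _ in range(n_rep):
            outcomes = [
                PairOutcome(f"s{i}", f"m{j}", 0.2, 0.5,
                            bool(rng.random() < 0.3), False)
                for i in range(5) for j in range(8)
            ]
            rep = identity_misclassification_models(outcomes)[0]
            hits_sp += rep.p_species < 0.1
            hits_met += rep.p_metabolite < 0.1
        # 3 expected under the null; allow generous binomial slack.
        assert hits_sp <= 9
        assert hits_met <= 9


class TestSubgroups:
    def _data(self, flip_sign=False, seed=0):
        rng = np.random.default_rng(seed)
        groups = []
        ab_rows, co_rows = [], []
        for g in range(3):
            x = np.linspace(0, 1, 6) + rng.normal(scale=0.01, size=6)
            sign = -1.0 if (flip_sign and g == 1) else 1.0
            y = sign * x + rng.normal(scale=0.01, size=6)
            for xi, yi in zip(x, y):
                ab_rows.append({"s0": xi})
                co_rows.append({"m0": yi})
                groups.append(f"g{g}")
        idx = [f"sample_{i}" for i in range(len(groups))]
        return (pd.DataFrame(ab_rows, index=idx),
                pd.DataFrame(co_rows, index=idx),
                pd.Series(groups, index=idx))

    def test_consistent_link_confirmed(self):
        ab, co, groups = self._data()
        res = subgroup_consistency(ab, co, groups, cutoff=0.05)
        assert ("s0", "m0") in res["confirmed"]

    def test_sign_flip_not_confirmed(self):
        ab, co, groups = self._data(flip_sign=True)
        res = subgroup_consistency(ab, co, groups, cutoff=0.05)
        assert ("s0", "m0") not in res["confirmed"]

    def test_global_confounder_shrinks_confirmed_set(self):
        """A variable driven by a between-group confounder is pooled-significant
        but not subgroup-confirmed, costing sensitivity."""
        rng = np.random.default_rng(4)
        groups, ab_rows, co_rows = [], [], []
        for g in range(3):
            level = float(g)  # confounder varies between groups only
            for i in range(6):
                ab_rows.append({"s0": level + rng.normal(scale=0.05)})
                co_rows.append({"m0": 2 * level + rng.normal(scale=0.05)})
                groups.append(f"g{g}")
        idx = [f"x{i}" for i in range(len(groups))]
        ab = pd.DataFrame(ab_rows, index=idx)
        co = pd.DataFrame(co_rows, index=idx)
        pooled = spearman_screen(ab, co, AlphaPolicy("raw", 0.01))
        assert pooled[0].significant
        res = subgroup_consistency(
            ab, co, pd.Series(groups, index=idx), cutoff=0.01
        )
        assert ("s0", "m0") not in res["confirmed"]

    def test_small_subgroup_excluded(self):
        ab, co, groups = self._data()
        groups.iloc[:6] = ["tiny"] * 3 + ["g0"] * 3
        with pytest.warns(UserWarning, match="fewer than"):
            res = subgroup_consistency(ab, co, groups, cutoff=0.05,
                                       min_subgroup_size=4)
        assert "tiny" in res["excluded_subgroups"]


class TestEnvironmentBins:
    def _entry(self, c, c_env, baseline=False, in_inflow=True, n_out=4):
        c = np.asarray(c, dtype=float)
        var_M = c.sum() + c_env
        prof = ContributionProfile(
            "met", [f"s{i}" for i in range(len(c))], c, c_env, var_M,
            c / var_M, c_env / var_M, set(),
        )
        outcomes = make_outcomes(TP=1, FP=1, FN=1, TN=n_out - 3)
        return EnvironmentBinEntry(prof, outcomes, in_inflow, baseline)

    def test_baseline_category(self):
        bins = environment_bins([self._entry([1.0], 0.0, baseline=True)])
        assert set(bins) == {"constant"}

    def test_no_inflow_category(self):
        bins = environment_bins([self._entry([1.0], 0.2, in_inflow=False)])
        assert set(bins) == {"no_inflow"}

    def test_share_binning_arithmetic(self):
        """Environmental share 0.37 of the positive total lands in the
        30-40% bin."""
        entry = self._entry([0.63], 0.37)
        bins = environment_bins([entry], bin_width=0.10)
        assert set(bins) == {"(30%-40%]"}

    def test_zero_share_bin(self):
        entry = self._entry([1.0, 0.5], -0.1)
        bins = environment_bins([entry], bin_width=0.10)
        assert set(bins) == {"0"}
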