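"""Five-class promoter annotation, switch table and response integration."""

import numpy as np
import pandas as pd
import pytest

from minquant.bivalency import (
    call_k4_positive,
    class_switch_table,
    classify_promoters,
    derepression_analysis,
    h2aub_change_at_derepressed,
)
from minquant.errors import ConfigurationError
from minquant.simdata import CLASS_LABELS

GENES = [f"g{i}" for i in range(6)]


def _series(vals):
    return pd.Series(vals, index=GENES)


def _diff(lfc, padj):
    return pd.DataFrame({"log2fc": lfc, "padj": padj}, index=GENES)


@pytest.fixture
def inputs():
    """Six promoters covering every class plus an inconclusive case.

    g0: K4+ both, K27 sig higher in naive, K27+ naive  -> naive_bivalent
    g1: K4+ both, K27 sig higher in primed, K27+ primed -> primed_bivalent
    g2: K4+ both, K27+ both, no significant difference  -> common_bivalent
    g3: K4+ both, K27- both                             -> k4_only
    g4: K4- both                                        -> k4_negative
    g5: K4+ both, significant K27 shift but K27- in the higher state -> k4_only
    """
    k4 = {
        "naive": _series([True, True, True, True, False, True]),
        "primed": _series([True, True, True, True, False, True]),
    }
    k27 = {
        "naive": _series([True, False, True, False, False, False]),
        "primed": _series([False, True, True, False, True, False]),
    }
    diff = _diff(
        lfc=[1.2, -1.4, 0.1, 0.0, -2.0, 1.8],
        padj=[0.01, 0.01, 0.8, 0.9, 0.001, 0.02],
    )
    return k4, k27, diff


class TestCallK4Positive:
    def test_threshold_rule_is_min_fold_times_median(self):
        means = pd.Series({"g0": 1.0, "g1": 10.0, "g2": 2.0})
        pos = call_k4_positive(means, genome_median=1.0, min_fold=2.0)
        # exactly at the genome median -> negative; at the threshold -> positive
        assert not pos["g0"]
        assert pos["g1"]
        assert pos["g2"]

    def test_degenerate_track_rejected(self):
        with pytest.raises(ConfigurationError, match="degenerate"):
            call_k4_positive(pd.Series({"g": 1.0}), genome_median=0.0)


class TestClassifyPromoters:
    def test_worked_examples(self, inputs):
        out = classify_promoters(*inputs)
        assert out.loc["g0", "promoter_class"] == "naive_bivalent"
        assert out.loc["g1", "promoter_class"] == "primed_bivalent"
        assert out.loc["g2", "promoter_class"] == "common_bivalent"
        assert out.loc["g3", "promoter_class"] == "k4_only"
        assert out.loc["g4", "promoter_class"] == "k4_negative"
        assert out.loc["g5", "promoter_class"] == "k4_only"

    def test_k4_negative_regardless_of_k27(self, inputs):
        # g4 has a strong significant K27 difference but no K4 anywhere
        out = classify_promoters(*inputs)
        assert out.loc["g4", "promoter_class"] == "k4_negative"

    def test_partition_is_exhaustive_and_exclusive(self, inputs):
        out = classify_promoters(*inputs)
        assert out["promoter_class"].isin(CLASS_LABELS).all()
        assert len(out) == len(GENES)

    def test_label_swap_symmetry(self, inputs):
        k4, k27, diff = inputs
        out = classify_promoters(k4, k27, diff)
        swapped_k4 = {"naive": k4["primed"], "primed": k4["naive"]}
        swapped_k27 = {"naive": k27["primed"], "primed": k27["naive"]}
        swapped_diff = diff.copy()
        swapped_diff["log2fc"] = -swapped_diff["log2fc"]
        out2 = classify_promoters(swapped_k4, swapped_k27, swapped_diff)
        mapping = {"naive_bivalent": "primed_bivalent",
                   "primed_bivalent": "naive_bivalent"}
        expected = out["promoter_class"].map(lambda c: mapping.get(c, c))
        pd.testing.assert_series_equal(out2["promoter_class"], expected,
                                       check_names=False)

    def test_missing_diff_rows_warn_and_omit(self, inputs):
        k4, k27, diff = inputs
        with pytest.warns(UserWarning, match="differential"):
            out = classify_promoters(k4, k27, diff.drop("g2"))
        assert "g2" not in out.index
        assert len(out) == len(GENES) - 1


class TestSwitchTable:
    def test_all_stable_single_cell(self):
        diff = _diff([0.0] * 6, [0.9] * 6)
        tab = class_switch_table(diff, diff)
        assert tab.loc["stable", "stable"] == 6
        assert tab.to_numpy().sum() == 6

    def test_k4_up_k27_down_pattern(self):
        # a KLF4-like promoter: gains K4 and loses K27 in the naive state
        k4 = _diff([2.0] + [0.0] * 5, [0.001] + [0.9] * 5)
        k27 = _diff([-2.0] + [0.0] * 5, [0.001] + [0.9] * 5)
        tab = class_switch_table(k4, k27)
        assert tab.loc["up", "down"] == 1
        assert tab.to_numpy().sum() == 6

    def test_counts_conserved_under_promoter_subset(self):
        rng = np.random.default_rng(0)
        k4 = _diff(rng.normal(0, 2, 6), rng.random(6))
        k27 = _diff(rng.normal(0, 2, 6), rng.random(6))
        subset = GENES[:4]
        tab = class_switch_table(k4, k27, promoters=subset)
        assert tab.to_numpy().sum() == 4


class TestDerepression:
    def _classes(self):
        return pd.DataFrame(
            {"promoter_class": ["naive_bivalent", "naive_bivalent",
                                "common_bivalent", "k4_only", "k4_only",
                                "k4_negative"]},
            index=GENES,
        )

    def test_derepressed_set_and_k27_fraction(self):
        rna = _diff([2.0, 1.5, 0.2, 1.8, 0.0, -1.5],
                    [0.001, 0.01, 0.7, 0.01, 0.9, 0.01])
        k27_pos = _series([True, True, True, False, False, False])
        with pytest.warns(UserWarning):
            res = derepression_analysis(rna, self._classes(), k27_pos,
                                        alpha=0.05, fc_threshold=2.0)
        assert res.derepressed == {"g0", "g1", "g3"}
        assert res.downregulated == {"g5"}
        assert res.frac_derepressed_k27_marked == pytest.approx(2 / 3)

    def test_single_gene_class_equal_to_background(self):
        rna = _diff([1.0, 1.0, 1.0, 1.0, 1.0, 2.5], [0.01] * 6)
        classes = pd.DataFrame(
            {"promoter_class": ["k4_only"] * 5 + ["naive_bivalent"]},
            index=GENES,
        )
        classes.loc["g0", "promoter_class"] = "common_bivalent"
        with pytest.warns(UserWarning):
            res = derepression_analysis(rna, classes,
                                        _series([False] * 6), 0.05, 2.0)
        single = [r for r in res.class_responses if r.label == "common_bivalent"][0]
        assert abs(single.cohens_d) < 1.0


class TestH2aubChange:
    def test_no_change_means_zero_loss(self):
        diff = _diff([0.0] * 6, [0.5] * 6)
        out = h2aub_change_at_derepressed(diff, set(GENES),
                                          {"bivalent": set(GENES)})
        assert out.loc["bivalent", "median_loss_pct"] == 0.0

    def test_medians_match_quantile_oracle(self):
        rng = np.random.default_rng(1)
        lfc = rng.normal(-0.2, 0.3, 6)
        diff = _diff(lfc, [0.5] * 6)
        strata = {"a": set(GENES[:4]), "b": set(GENES[4:])}
        out = h2aub_change_at_derepressed(diff, set(GENES), strata)
        # brute-force: sort linear folds and pick the midpoint
        for name, members in strata.items():
            folds = sorted(2.0 ** diff.loc[sorted(members), "log2fc"])
            n = len(folds)
            expected = (folds[n // 2] if n % 2
                        else (folds[n // 2 - 1] + folds[n // 2]) / 2)
            assert out.loc[name, "median_fold"] == pytest.approx(expected)

    def test_empty_stratum_omitted_with_warning(self):
        diff = _diff([0.0] * 6, [0.5] * 6)
        with pytest.warns(UserWarning, match="empty"):
            out = h2aub_change_at_derepressed(
                diff, {"g0"}, {"bivalent": {"g0"}, "k27_devoid": set()}
            )
        assert "k27_devoid" not in out.index

    def test_empty_derepressed_set_rejected(self):
        with pytest.raises(ConfigurationError):
            h2aub_change_at_derepressed(_diff([0] * 6, [1] * 6), set(), {})


class TestTruthRecovery:
    def test_default_study_class_accuracy(self, full_run):
        assert full_run.class_accuracy >= 0.90

    def test_h2aub_loss_recovered_at_derepressed_bivalent_promoters(self, full_run):
        retention = full_run.config.sim.h2aub_derepressed_retention
        med = full_run.h2aub_at_derepressed.loc["bivalent", "median_fold"]
        assert med == pytest.approx(retention, abs=0.05)

    def test_naive_bivalent_class_derepressed_on_treatment(self, full_run):
        resp = {r.label: r for r in full_run.derepression.class_responses}
        assert resp["naive_bivalent"].median_log2fc > 0.5
        assert resp["naive_bivalent"].wilcoxon_p < 0.05
        assert resp["primed_bivalent"].median_log2fc < 0.5
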